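"""iBAQ co-enrichment analysis of bait pull-downs.

Pull-down proteomics of a tagged bait (e.g. Nsp1) quantifies how strongly
each prey protein co-purifies.  The normalization chain is:

1. median normalization — each sample is scaled so its median intensity
   over the detected-protein set matches the grand median (default detected
   set: proteins nonzero in every sample);
2. bait normalization — each sample is divided by its bait intensity, so
   every value is a prey/bait stoichiometry and the bait row becomes 1;
3. mutant-vs-wildtype fold change — each mutant sample is divided by its
   same-batch wildtype partner, cancelling per-batch multiplicative effects.

Group-level differences (e.g. central transport Nups vs cytoplasmic
filaments) are tested on log2 folds with a two-sided unpaired t-test when
both groups have more than ``min_n`` values; otherwise only descriptive
medians are reported, flagged as underpowered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_MIN_N = 4


def median_normalize(table: pd.DataFrame, detected: str = "all_samples") -> pd.DataFrame:
    """Scale each sample so its median over detected proteins equals the grand median.

    ``detected`` selects the protein set the medians are computed over:
    ``"all_samples"`` (default) uses proteins nonzero in every sample;
    ``"per_sample"`` uses each sample's own nonzero proteins.  The grand
    median is the median of the per-sample medians.
    """
    if (table < 0).to_numpy().any():
        raise ValueError("intensities must be non-negative")
    if detected == "all_samples":
        det = table.index[(table > 0).all(axis=1)]
        if len(det) == 0:
            raise ValueError("no protein is detected in all samples")
        medians = table.loc[det].median(axis=0)
    elif detected == "per_sample":
        medians = table.where(table > 0).median(axis=0)
    else:
        raise ValueError(f"unknown detected mode {detected!r}")
    if (medians <= 0).any() or medians.isna().any():
        bad = medians.index[(medians <= 0) | medians.isna()].tolist()
        raise ValueError(f"samples without positive detected intensities: {bad}")
    grand = float(medians.median())
    factors = grand / medians
    return table * factors


def bait_normalize(table: pd.DataFrame, bait: str) -> pd.DataFrame:
    """Divide every sample by its bait intensity; the bait row becomes 1.

    Samples where the bait is undetected carry no usable stoichiometry and
    are excluded with a logged warning.
    """
    if bait not in table.index:
        raise KeyError(f"bait {bait!r} not found in the intensity table")
    bait_row = table.loc[bait]
    keep = bait_row > 0
    if not keep.all():
        dropped = list(table.columns[~keep])
        logger.warning("excluding samples with zero bait intensity: %s", dropped)
    if not keep.any():
        raise ValueError("bait intensity is zero in every sample")
    sub = table.loc[:, keep]
    return sub / sub.loc[bait]


def mutant_vs_wt_fold(table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-protein fold change of each mutant sample over its same-batch wildtype.

    ``metadata`` (indexed by sample) needs columns ``genotype`` (``wildtype``
    or a mutant identifier) and ``batch``.  When a batch holds several
    wildtype samples their geometric mean is the reference.
    """
    meta = metadata.loc[[s for s in table.columns if s in metadata.index]]
    wt = meta[meta["genotype"] == "wildtype"]
    mut = meta[meta["genotype"] != "wildtype"]
    if wt.empty or mut.empty:
        raise ValueError("need both wildtype and mutant samples")
    missing = sorted(set(mut["batch"]) - set(wt["batch"]))
    if missing:
        raise ValueError(f"mutant batches without a wildtype partner: {missing}")
    folds = {}
    for sample, row in mut.iterrows():
        partners = wt.index[wt["batch"] == row["batch"]]
        ref = np.exp(np.log(table[partners]).mean(axis=1)) if len(partners) > 1 else table[partners[0]]
        folds[sample] = table[sample] / ref
    return pd.DataFrame(folds)


@dataclass
class GroupComparison:
    """Two-group comparison of log2 fold changes."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_log2_a: float
    median_log2_b: float
    t_statistic: float | None
    p_value: float | None
    tested: bool
    flag: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def group_compare(
    folds: pd.DataFrame,
    group_a: tuple[str, list[str]],
    group_b: tuple[str, list[str]],
    min_n: int = DEFAULT_MIN_N,
) -> GroupComparison:
    """Compare two protein groups on log2 fold changes.

    Each group is ``(name, [protein, ...])``; all fold values of a group's
    proteins across mutant samples are pooled.  A two-sided unpaired t-test
    is run only when both pools have more than ``min_n`` values.
    """
    name_a, members_a = group_a
    name_b, members_b = group_b
    if not members_a or not members_b:
        raise ValueError("groups must be non-empty")
    if set(members_a) & set(members_b):
        raise ValueError("groups must not overlap")
    for member in list(members_a) + list(members_b):
        if member not in folds.index:
            raise KeyError(f"protein {member!r} not in the fold table")
    vals_a = np.log2(folds.loc[members_a].to_numpy(dtype=float).ravel())
    vals_b = np.log2(folds.loc[members_b].to_numpy(dtype=float).ravel())
    vals_a = vals_a[np.isfinite(vals_a)]
    vals_b = vals_b[np.isfinite(vals_b)]
    tested = len(vals_a) > min_n and len(vals_b) > min_n
    if tested:
        t, p = stats.ttest_ind(vals_a, vals_b)
        t, p, flag = float(t), float(p), ""
    else:
        t = p = None
        flag = f"insufficient values for testing (need > {min_n} per group)"
    return GroupComparison(
        group_a=name_a,
        group_b=name_b,
        n_a=len(vals_a),
        n_b=len(vals_b),
        median_log2_a=float(np.median(vals_a)),
        median_log2_b=float(np.median(vals_b)),
        t_statistic=t,
        p_value=p,
        tested=tested,
        flag=flag,
    )


def normalized_folds(
    table: pd.DataFrame, metadata: pd.DataFrame, bait: str, detected: str = "all_samples"
) -> pd.DataFrame:
    """Full chain: median-normalize, bait-normalize, mutant-vs-wildtype folds."""
    normed = bait_normalize(median_normalize(table, detected), bait)
    return mutant_vs_wt_fold(normed, metadata)
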