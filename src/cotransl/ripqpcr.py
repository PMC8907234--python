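"""RIP-qPCR fold enrichments and the co-translational decision rule.

RNA immunoprecipitation followed by qPCR measures whether a partner's mRNA
co-purifies with a bait protein.  Enrichment is expressed over the no-bait
(wildtype background) control as

    f = E ** (Ct_control - Ct_bait),

with amplification efficiency E = 2 (one cycle = one doubling).  A target is
called co-translational when (I) the mean cycloheximide fold is at or above
the signal threshold 1.5 and (II) puromycin treatment — which releases the
nascent chain — significantly reduces the signal (two-sided paired t-test,
alpha = 0.05, with the cycloheximide mean exceeding the puromycin mean).

Technical triplicates are summarized by their mean after a simple outlier
rule: a well deviating from the replicate median by more than 0.5 Ct is
omitted and flagged; a biological replicate needing two or more omissions
fails quality control and is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05
DEFAULT_EFFICIENCY = 2.0
DEFAULT_TECH_DELTA = 0.5

TREATMENTS = ("cycloheximide", "puromycin")
NO_BAIT = "no-bait"


@dataclass
class TechSummary:
    """Technical-replicate summary for one well group."""

    mean_ct: float | None
    omitted: list[float]
    qc_pass: bool
    flag: str = ""


@dataclass
class EnrichmentCall:
    """Co-translational call for one (bait, target) pair."""

    bait: str
    target: str
    chx_folds: np.ndarray
    puro_folds: np.ndarray
    mean_chx_fold: float
    mean_puro_fold: float
    p_value: float
    threshold: float
    alpha: float
    co_translational: bool
    paired: bool = True
    qc_flags: list[str] = field(default_factory=list)


def summarize_technical(cts, delta: float = DEFAULT_TECH_DELTA) -> TechSummary:
    """Mean Ct of technical replicates with single-outlier omission.

    A value deviating from the replicate median by more than ``delta``
    (default 0.5 Ct) is omitted and flagged.  If two or more values would be
    omitted — or fewer than two values are supplied — the biological
    replicate fails QC.
    """
    cts = np.asarray(cts, dtype=float)
    if len(cts) < 2:
        return TechSummary(None, [], False, "fewer than 2 technical replicates")
    med = np.median(cts)
    outlier = np.abs(cts - med) > delta
    n_out = int(outlier.sum())
    if n_out >= 2:
        return TechSummary(
            None, list(cts[outlier]), False, f"{n_out} technical outliers — QC fail"
        )
    if n_out == 1:
        omitted = float(cts[outlier][0])
        logger.info("omitting technical replicate Ct %.3f (median %.3f)", omitted, med)
        return TechSummary(
            float(cts[~outlier].mean()), [omitted], True, f"omitted 1 well ({omitted:.2f})"
        )
    return TechSummary(float(cts.mean()), [], True)


def fold_enrichment(
    bait_ct: float, control_ct: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """Fold enrichment over the no-bait background: f = E^(control - bait)."""
    if bait_ct is None or control_ct is None:
        raise ValueError("both bait and control Ct are required (QC-passed)")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return float(efficiency ** (control_ct - bait_ct))


def _paired_p(chx: np.ndarray, puro: np.ndarray) -> float:
    diffs = chx - puro
    if np.allclose(diffs, 0):
        return 1.0  # no decrease at all — explicitly non-significant
    if np.isclose(np.std(diffs, ddof=1), 0):
        return 0.0  # identical non-zero gap in every pair
    return float(stats.ttest_rel(chx, puro).pvalue)


def call_cotranslational(
    chx_folds,
    puro_folds,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    bait: str = "bait",
    target: str = "target",
    qc_flags: list[str] | None = None,
) -> EnrichmentCall:
    """Apply the two-criterion decision rule to per-replicate folds.

    Positive iff mean(CHX folds) >= threshold, the CHX-vs-puromycin
    difference is significant (two-sided paired t, p < alpha), and the CHX
    mean exceeds the puromycin mean.  Folds are paired by biological
    replicate index; unequal lengths fall back to an unpaired two-sided t
    with a logged warning.
    """
    chx = np.asarray(chx_folds, dtype=float)
    puro = np.asarray(puro_folds, dtype=float)
    if np.any(chx <= 0) or np.any(puro <= 0):
        raise ValueError("fold enrichments must be positive")
    if len(chx) < 2 or len(puro) < 2:
        raise ValueError("need >= 2 biological replicates per treatment")
    paired = len(chx) == len(puro)
    if paired:
        p = _paired_p(chx, puro)
    else:
        logger.warning(
            "unpairable replicates (%d CHX vs %d puromycin); using unpaired t-test",
            len(chx),
            len(puro),
        )
        p = float(stats.ttest_ind(chx, puro).pvalue)
        if np.isnan(p):
            p = 1.0
    mean_chx = float(chx.mean())
    mean_puro = float(puro.mean())
    positive = (mean_chx >= threshold) and (p < alpha) and (mean_chx > mean_puro)
    return EnrichmentCall(
        bait=bait,
        target=target,
        chx_folds=chx,
        puro_folds=puro,
        mean_chx_fold=mean_chx,
        mean_puro_fold=mean_puro,
        p_value=p,
        threshold=threshold,
        alpha=alpha,
        co_translational=bool(positive),
        paired=paired,
        qc_flags=qc_flags or [],
    )


def analyze_experiment(
    wells: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    efficiency: float = DEFAULT_EFFICIENCY,
    tech_delta: float = DEFAULT_TECH_DELTA,
) -> list[EnrichmentCall]:
    """Full pipeline from a well table to co-translational calls.

    ``wells`` columns: bait, target_mrna, treatment, bio_rep, tech_rep, ct.
    Rows with bait == "no-bait" are the background controls matched by
    (target, treatment, bio_rep).
    """
    required = {"bait", "target_mrna", "treatment", "bio_rep", "tech_rep", "ct"}
    if not required.issubset(wells.columns):
        raise ValueError(f"wells table must have columns {sorted(required)}")
    if (wells["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    calls = []
    baits = sorted(set(wells["bait"]) - {NO_BAIT})
    for bait in baits:
        for target in sorted(wells.loc[wells["bait"] == bait, "target_mrna"].unique()):
            folds: dict[str, list[float]] = {t: [] for t in TREATMENTS}
            flags: list[str] = []
            for treatment in TREATMENTS:
                sel = (
                    (wells["target_mrna"] == target) & (wells["treatment"] == treatment)
                )
                bait_wells = wells[sel & (wells["bait"] == bait)]
                ctrl_wells = wells[sel & (wells["bait"] == NO_BAIT)]
                if ctrl_wells.empty:
                    raise ValueError(
                        f"missing no-bait control for {target}/{treatment}"
                    )
                for bio, grp in bait_wells.groupby("bio_rep"):
                    bsum = summarize_technical(grp["ct"].to_numpy(), tech_delta)
                    ctrl_grp = ctrl_wells[ctrl_wells["bio_rep"] == bio]
                    if ctrl_grp.empty:
                        raise ValueError(
                            f"missing no-bait control for {target}/{treatment} bio_rep {bio}"
                        )
                    csum = summarize_technical(ctrl_grp["ct"].to_numpy(), tech_delta)
                    if not (bsum.qc_pass and csum.qc_pass):
                        flags.append(f"{treatment} bio_rep {bio}: QC fail, excluded")
                        continue
                    for s, who in ((bsum, "bait"), (csum, "control")):
                        if s.flag:
                            flags.append(f"{treatment} bio_rep {bio} {who}: {s.flag}")
                    folds[treatment].append(
                        fold_enrichment(bsum.mean_ct, csum.mean_ct, efficiency)
                    )
            calls.append(
                call_cotranslational(
                    folds["cycloheximide"],
                    folds["puromycin"],
                    threshold,
                    alpha,
                    bait=bait,
                    target=target,
                    qc_flags=flags,
                )
            )
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    rows = [
        {
            "bait": c.bait,
            "target": c.target,
            "mean_chx_fold": c.mean_chx_fold,
            "mean_puro_fold": c.mean_puro_fold,
            "p_value": c.p_value,
            "co_translational": c.co_translational,
            "paired": c.paired,
            "qc_flags": "; ".join(c.qc_flags),
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
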