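"""Gene-level total-enrichment (TE) statistics with empirical-Bayes moderation.

The TE of a gene is the log2 ratio of its footprint proportion in an IP
library to that in a matched total-translatome library,

    TE = log2[(n_IP + alpha) / N_IP] - log2[(n_total + alpha) / N_total],

computed per replicate pair with pseudocount alpha = 0.5.  Across genes, a
one-sample moderated t-test in the empirical-Bayes style of limma's
moderated statistic is fitted: per-gene variances s^2 (d = n - 1 df) are
shrunk toward a prior s0^2 with d0 prior df,

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d),
    t    = beta / (s~ / sqrt(n)),     df = d0 + d,

where (d0, s0^2) are estimated across genes by method of moments on
log s^2 (matching the scaled-F marginal of the hierarchical model).
P-values are controlled for false discovery with Benjamini-Hochberg.

The statistic itself is re-implemented here — it is the module's contract —
and is cross-checked in tests against limit cases (d0 = 0 reduces exactly to
the ordinary one-sample t).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
_VAR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# TE computation


def total_enrichment(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2 TE for each IP/total replicate pair.

    Parameters
    ----------
    counts : DataFrame, genes x samples
        Per-ORF footprint counts.
    metadata : DataFrame indexed by sample
        Must have columns ``group`` (``IP`` or ``total``) and ``replicate``.
        Replicates are paired by matching labels when the label sets agree;
        otherwise each IP replicate is compared against the mean total
        log-proportion (all-vs-mean).
    library_sizes : Series, optional
        Total mapped footprints per sample; defaults to column sums.

    Returns
    -------
    DataFrame, genes x pairs, of log2 TE values.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")

    ip_samples = metadata.index[metadata["group"] == "IP"]
    tot_samples = metadata.index[metadata["group"] == "total"]
    if len(ip_samples) == 0 or len(tot_samples) == 0:
        raise ValueError("need at least one IP and one total sample")

    def logprop(sample):
        return np.log2((counts[sample] + pseudocount) / library_sizes[sample])

    ip_reps = metadata.loc[ip_samples, "replicate"]
    tot_reps = metadata.loc[tot_samples, "replicate"]
    pairs = {}
    if sorted(ip_reps) == sorted(tot_reps):
        tot_by_rep = {r: s for s, r in tot_reps.items()}
        for s, r in ip_reps.items():
            pairs[f"pair_{r}"] = logprop(s) - logprop(tot_by_rep[r])
    else:
        logger.warning("IP/total replicate labels differ; using all-vs-mean pairing")
        mean_tot = np.mean([logprop(s) for s in tot_samples], axis=0)
        for s, r in ip_reps.items():
            pairs[f"pair_{r}"] = logprop(s) - mean_tot
    return pd.DataFrame(pairs, index=counts.index)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments estimate of the prior df d0 and variance s0^2.

    Works on z = log s^2, whose mean and variance under the hierarchical
    model involve digamma/trigamma terms of d/2 and d0/2.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), _VAR_FLOOR)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return math.inf, float(np.exp(emean))
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    else:
        d0 = math.inf
        s02 = float(np.exp(emean))
    return d0, s02


def fit_moderated(te_matrix: pd.DataFrame, d0: float | None = None, s02: float | None = None) -> "ModeratedTEResults":
    """Fit the one-sample moderated t-test across genes.

    Parameters
    ----------
    te_matrix : DataFrame, genes x replicate pairs, of log2 TE values.
    d0, s02 : optional overrides of the estimated prior (``d0 = 0`` yields
        the ordinary t; ``d0 = inf`` uses the prior variance everywhere).
    """
    X = te_matrix.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need >= 2 replicate TE values per gene")
    d = n - 1
    beta = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    n_floored = int(np.sum(s2 < _VAR_FLOOR))
    if n_floored:
        logger.info("floored %d all-zero-variance genes at %g", n_floored, _VAR_FLOOR)
    s2 = np.maximum(s2, _VAR_FLOOR)

    if d0 is None:
        d0, s02_est = estimate_prior(s2, d)
        if s02 is None:
            s02 = s02_est
    elif s02 is None:
        if math.isinf(d0):
            s02 = float(np.exp(np.mean(np.log(s2))))
        else:
            s02 = float(np.mean(s2))

    if d0 == 0:
        s2_post = s2
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
    t = beta / np.sqrt(s2_post / n)
    df_total = d0 + d
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"beta": beta, "s2": s2, "s2_post": s2_post, "t": t, "p": p, "q": q},
        index=te_matrix.index,
    )
    return ModeratedTEResults(table=table, d0=d0, s02=s02, d=d, n=n)


# ---------------------------------------------------------------------------
# Model / Results objects


class ModeratedTE:
    """Moderated TE model: counts + metadata in, moderated statistics out.

    A thin statsmodels-style wrapper around :func:`total_enrichment` and
    :func:`fit_moderated`.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.counts = counts
        self.metadata = metadata
        self.pseudocount = pseudocount
        self.te_matrix = total_enrichment(counts, metadata, pseudocount)

    @classmethod
    def from_files(cls, counts_path, metadata_path, **kw) -> "ModeratedTE":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, index_col=0)
        return cls(counts, meta, **kw)

    def fit(self, **kw) -> "ModeratedTEResults":
        return fit_moderated(self.te_matrix, **kw)


@dataclass
class ModeratedTEResults:
    """Per-gene moderated TE statistics plus the fitted prior."""

    table: pd.DataFrame
    d0: float
    s02: float
    d: int
    n: int

    @property
    def params(self) -> pd.Series:
        return self.table["beta"]

    @property
    def tvalues(self) -> pd.Series:
        return self.table["t"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]

    @property
    def qvalues(self) -> pd.Series:
        return self.table["q"]

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < fdr]

    def summary(self, fdr: float = 0.05) -> str:
        n_sig = int((self.table["q"] < fdr).sum())
        lines = [
            "Moderated TE test (one-sample empirical-Bayes t)",
            f"  genes: {len(self.table)}   replicate pairs: {self.n}",
            f"  prior df d0: {self.d0:.4g}   prior variance s0^2: {self.s02:.4g}",
            f"  residual df per gene: {self.d}   total df: {self.d0 + self.d:.4g}",
            f"  genes with q < {fdr:g}: {n_sig}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# FDR and event density


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, p_(j) * m / j), returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def event_density(n_events: int, n_proteins: int) -> float:
    """Co-translational events per protein in a group.

    Collective or secondary bindings must be collapsed to one event by the
    caller before counting.
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return n_events / n_proteins
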