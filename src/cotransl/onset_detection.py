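"""Onset calling for co-translational engagement.

The onset codon is the first codon at which IP footprints are sustainably
enriched over the total translatome.  The caller is deliberately simple and
background-relative: the baseline b is the median enrichment over a
background region (default: the 5' quarter of the ORF, at least 20 codons),
and the onset is the first codon where E(c) >= theta * b holds for
``min_run`` consecutive codons.  A call is only reported as detected when
the signal is sustained, i.e. the mean enrichment from the onset to the stop
codon also clears theta * b — positive SeRP profiles stay elevated to the
end of the ORF, transient spikes do not.

Because ~30-40 residues of the nascent chain are buried in the ribosome
exit tunnel, the protein segment exposed when the onset is reached is the
residue window [c0 - 40, c0 - 30] (clipped at residue 1); annotated motifs
intersecting that window are candidate assembly interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .serp_profiles import EnrichmentProfile

logger = logging.getLogger(__name__)

DEFAULT_THETA = 2.0
DEFAULT_MIN_RUN = 10
#: exit-tunnel offsets in amino acids
DELTA_MIN = 30
DELTA_MAX = 40
#: background region: max(orf_len // 4, BACKGROUND_MIN_CODONS) leading codons
BACKGROUND_MIN_CODONS = 20


@dataclass
class OnsetCall:
    """Result of onset detection for one transcript."""

    transcript_id: str
    detected: bool
    onset_codon: int | None
    background: float
    threshold_ratio: float
    min_run: int
    exposure_window: tuple[int, int] | None = None
    motif_overlaps: list[str] = field(default_factory=list)


def exposed_residue_window(c0: int, delta_min: int = DELTA_MIN, delta_max: int = DELTA_MAX):
    """Residue interval exposed outside the exit tunnel at onset codon ``c0``.

    Returns ``[max(1, c0 - delta_max), max(1, c0 - delta_min)]`` (1-based,
    inclusive).
    """
    if c0 < 1:
        raise ValueError("onset codon must be >= 1")
    if delta_min > delta_max:
        raise ValueError("delta_min must be <= delta_max")
    if delta_min < 0:
        raise ValueError("offsets must be non-negative")
    return (max(1, c0 - delta_max), max(1, c0 - delta_min))


def _first_run_start(mask: np.ndarray, run: int) -> int | None:
    """Index of the first position opening >= ``run`` consecutive True values."""
    if run > len(mask):
        return None
    ok = np.convolve(mask.astype(int), np.ones(run, dtype=int), mode="valid") == run
    hits = np.nonzero(ok)[0]
    return int(hits[0]) if len(hits) else None


def call_onset(
    profile: EnrichmentProfile,
    theta: float = DEFAULT_THETA,
    min_run: int = DEFAULT_MIN_RUN,
    background_region: slice | None = None,
) -> OnsetCall:
    """Call the co-translational onset codon from an enrichment profile.

    Parameters
    ----------
    theta : float
        Enrichment-over-background ratio that must be reached (> 1).
    min_run : int
        Number of consecutive codons that must clear ``theta * background``.
    background_region : slice, optional
        0-based codon slice used for the baseline median; defaults to the 5'
        quarter of the ORF with a floor of 20 codons.  ORFs shorter than the
        floor fall back to a whole-ORF median (logged).
    """
    if theta <= 1:
        raise ValueError("theta must be > 1")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    E = np.asarray(profile.enrichment, dtype=float)
    L = len(E)
    if background_region is None:
        n_bg = max(L // 4, BACKGROUND_MIN_CODONS)
        if n_bg >= L:
            logger.info(
                "%s: ORF (%d codons) shorter than background minimum, using whole-ORF median",
                profile.transcript_id,
                L,
            )
            n_bg = L
        background_region = slice(0, n_bg)
    b = float(np.median(E[background_region]))
    if b <= 0:
        raise ValueError("background enrichment must be positive")

    cutoff = theta * b
    start = _first_run_start(E >= cutoff, min_run)
    detected = False
    onset = None
    if start is not None:
        onset = start + 1  # 1-based codon
        sustained = float(np.mean(E[start:])) >= cutoff
        detected = sustained
        if not sustained:
            onset = None

    return OnsetCall(
        transcript_id=profile.transcript_id,
        detected=detected,
        onset_codon=onset,
        background=b,
        threshold_ratio=theta,
        min_run=min_run,
        exposure_window=exposed_residue_window(onset) if detected else None,
    )


def annotate_motif_overlap(call: OnsetCall, motif_table: pd.DataFrame) -> OnsetCall:
    """Fill ``motif_overlaps`` with motifs intersecting the exposure window.

    ``motif_table`` columns: transcript_id, motif_name, start_res, end_res
    (1-based inclusive).  Intervals touching at a shared residue count as
    overlapping; adjacency (end < start) does not.
    """
    if len(motif_table) and (motif_table["start_res"] > motif_table["end_res"]).any():
        bad = motif_table[motif_table["start_res"] > motif_table["end_res"]]
        raise ValueError(f"motif intervals with start > end: {bad['motif_name'].tolist()}")
    overlaps: list[str] = []
    if call.detected and call.exposure_window is not None and len(motif_table):
        lo, hi = call.exposure_window
        sub = motif_table[motif_table["transcript_id"] == call.transcript_id]
        for _, row in sub.iterrows():
            if row["start_res"] <= hi and row["end_res"] >= lo:
                overlaps.append(str(row["motif_name"]))
    call.motif_overlaps = overlaps
    return call


def calls_to_frame(calls) -> pd.DataFrame:
    """Tabulate onset calls (one row per transcript) for TSV output."""
    rows = []
    for c in calls:
        lo, hi = c.exposure_window if c.exposure_window else (None, None)
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "detected": c.detected,
                "onset_codon": c.onset_codon,
                "background": c.background,
                "exposure_lo": lo,
                "exposure_hi": hi,
                "motifs": ",".join(c.motif_overlaps),
            }
        )
    return pd.DataFrame(rows)
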