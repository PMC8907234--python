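"""Selective ribosome profiling (SeRP) enrichment profiles.

SeRP compares ribosome-protected footprints from an affinity-purified (IP)
library against the total translatome.  This module turns per-position
footprint count tables into normalized, replicate-combined, smoothed
per-codon IP/total enrichment profiles E(c).  The enrichment at codon c is

    E(c) = (smooth(IP density)(c) + alpha) / (smooth(total density)(c) + alpha)

where densities are reads-per-million (RPM), smoothing is a centered gliding
average over an odd window of ``w`` codons (truncated at the ORF edges), and
``alpha`` is a pseudocount in RPM units keeping the ratio finite over
zero-coverage codons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("IP", "total")

#: default smoothing window (codons); must be odd
DEFAULT_WINDOW = 15
#: default pseudocount (RPM)
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class FootprintTrack:
    """Per-codon footprint counts for one transcript/sample/condition/replicate.

    Parameters
    ----------
    transcript_id : str
    sample_id : str
        Free-form library identifier.
    condition : {"IP", "total"}
    replicate : int
    counts : ndarray of int
        Non-negative counts indexed by codon (position 0 = codon 1).
    library_size : int
        Total mapped footprints in the library; must be >= counts.sum().
    """

    transcript_id: str
    sample_id: str
    condition: str
    replicate: int
    counts: np.ndarray
    library_size: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if np.any(self.counts < 0):
            raise ValueError("footprint counts must be non-negative")
        if self.library_size < int(self.counts.sum()):
            raise ValueError("library_size must be >= sum of track counts")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    @property
    def n_codons(self) -> int:
        return len(self.counts)


@dataclass
class CombinedTrack:
    """Replicate-combined RPM density for one (transcript, condition)."""

    transcript_id: str
    condition: str
    density: np.ndarray
    n_replicates: int


@dataclass
class EnrichmentProfile:
    """Smoothed per-codon IP/total enrichment with provenance metadata."""

    transcript_id: str
    enrichment: np.ndarray
    ip_density: np.ndarray
    total_density: np.ndarray
    window: int
    pseudocount: float
    n_ip_reps: int
    n_total_reps: int

    def __len__(self) -> int:
        return len(self.enrichment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": np.arange(1, len(self.enrichment) + 1),
                "E": self.enrichment,
                "ip_density": self.ip_density,
                "total_density": self.total_density,
            }
        )

    def metadata(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "window": self.window,
            "pseudocount": self.pseudocount,
            "n_ip_reps": self.n_ip_reps,
            "n_total_reps": self.n_total_reps,
        }


def load_position_counts(
    path,
    annotation: Mapping[str, int],
    *,
    condition: str = "total",
    sample_id: str = "sample",
    replicate: int = 1,
    psite_offset: int = 0,
    library_size: int | None = None,
) -> list[FootprintTrack]:
    """Read a per-nucleotide counts TSV and collapse positions to codons.

    The TSV must have columns ``transcript_id``, ``pos_nt`` (1-based within
    the ORF) and ``count``.  Positions are shifted by ``psite_offset``
    nucleotides (P-site assignment; input is assumed already P-site assigned
    by default) and collapsed via ``codon(p) = (p - 1) // 3 + 1``.  Positions
    falling outside the annotated ORF are dropped and their total is logged.

    Parameters
    ----------
    annotation : mapping of transcript_id -> ORF length in codons
    library_size : total mapped footprints; defaults to the file's count sum.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "pos_nt", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts TSV must have columns {sorted(required)}")
    bad = df[~np.isfinite(df["pos_nt"]) | ~np.isfinite(df["count"])]
    if len(bad):
        raise ValueError(f"malformed rows at lines {list(bad.index + 2)}")
    unknown = sorted(set(df["transcript_id"]) - set(annotation))
    if unknown:
        raise KeyError(f"transcripts absent from annotation: {unknown}")

    if library_size is None:
        library_size = int(df["count"].sum())

    tracks = []
    for tid, sub in df.groupby("transcript_id", sort=True):
        n_codons = annotation[tid]
        pos = sub["pos_nt"].to_numpy(dtype=int) + psite_offset
        codon = (pos - 1) // 3 + 1
        inside = (pos >= 1) & (codon <= n_codons)
        n_dropped = int(sub["count"].to_numpy()[~inside].sum())
        if n_dropped:
            logger.info(
                "%s: dropped %d reads outside the ORF (%d codons)", tid, n_dropped, n_codons
            )
        counts = np.bincount(
            codon[inside] - 1, weights=sub["count"].to_numpy()[inside], minlength=n_codons
        ).astype(int)
        tracks.append(
            FootprintTrack(
                transcript_id=str(tid),
                sample_id=sample_id,
                condition=condition,
                replicate=replicate,
                counts=counts,
                library_size=library_size,
            )
        )
    return tracks


def normalize_track(track: FootprintTrack) -> np.ndarray:
    """Library-size normalization: density(c) = counts(c) * 1e6 / library_size."""
    if track.library_size <= 0:
        raise ValueError("library_size must be positive")
    return track.counts * 1e6 / track.library_size


def combine_replicates(
    tracks: Sequence[FootprintTrack], method: str = "mean_rpm"
) -> CombinedTrack:
    """Combine replicate tracks of one (transcript, condition).

    ``mean_rpm`` (default) averages per-replicate RPM densities; ``pooled``
    sums raw counts and library sizes before normalizing.
    """
    if not tracks:
        raise ValueError("no tracks to combine")
    tid = tracks[0].transcript_id
    cond = tracks[0].condition
    n = tracks[0].n_codons
    for t in tracks:
        if t.transcript_id != tid or t.condition != cond:
            raise ValueError("tracks must share transcript and condition")
        if t.n_codons != n:
            raise ValueError(
                f"replicate length mismatch for {tid}: {t.n_codons} vs {n} codons"
            )
    if method == "mean_rpm":
        density = np.mean([normalize_track(t) for t in tracks], axis=0)
    elif method == "pooled":
        counts = np.sum([t.counts for t in tracks], axis=0)
        libsize = sum(t.library_size for t in tracks)
        density = counts * 1e6 / libsize
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return CombinedTrack(tid, cond, density, n_replicates=len(tracks))


def gliding_average(values, w: int) -> np.ndarray:
    """Centered moving mean over an odd window of ``w`` positions.

    At the edges the window truncates to the available positions, so the
    output has the same length as the input.  ``w = 1`` is the identity.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {w}")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(w, center=True, min_periods=1).mean().to_numpy()


def enrichment_profile(
    ip_combined: CombinedTrack,
    total_combined: CombinedTrack,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentProfile:
    """Smoothed IP/total enrichment; smoothing is applied *before* the ratio."""
    if ip_combined.transcript_id != total_combined.transcript_id:
        raise ValueError("IP and total tracks are for different transcripts")
    if len(ip_combined.density) != len(total_combined.density):
        raise ValueError("IP and total tracks have different lengths")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ip_s = gliding_average(ip_combined.density, window)
    tot_s = gliding_average(total_combined.density, window)
    if pseudocount == 0 and np.any(tot_s == 0):
        raise ValueError(
            "zero total density encountered with pseudocount = 0; "
            "use a positive pseudocount"
        )
    enr = (ip_s + pseudocount) / (tot_s + pseudocount)
    return EnrichmentProfile(
        transcript_id=ip_combined.transcript_id,
        enrichment=enr,
        ip_density=ip_s,
        total_density=tot_s,
        window=window,
        pseudocount=pseudocount,
        n_ip_reps=ip_combined.n_replicates,
        n_total_reps=total_combined.n_replicates,
    )


def profiles_from_tracks(
    tracks: Iterable[FootprintTrack],
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "mean_rpm",
) -> dict[str, EnrichmentProfile]:
    """Convenience pipeline: group tracks, combine replicates, build profiles."""
    by_key: dict[tuple[str, str], list[FootprintTrack]] = {}
    for t in tracks:
        by_key.setdefault((t.transcript_id, t.condition), []).append(t)
    profiles = {}
    for tid in sorted({k[0] for k in by_key}):
        ip_tracks = by_key.get((tid, "IP"))
        tot_tracks = by_key.get((tid, "total"))
        if not ip_tracks or not tot_tracks:
            logger.warning("%s: missing IP or total tracks, skipped", tid)
            continue
        ip_c = combine_replicates(ip_tracks, method=method)
        tot_c = combine_replicates(tot_tracks, method=method)
        profiles[tid] = enrichment_profile(ip_c, tot_c, window, pseudocount)
    return profiles


def write_profile(profile: EnrichmentProfile, out_dir) -> Path:
    """Write a profile TSV plus a JSON run-metadata sidecar; returns TSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{profile.transcript_id}.profile.tsv"
    profile.to_frame().to_csv(tsv, sep="\t", index=False)
    with open(out_dir / f"{profile.transcript_id}.profile.json", "w") as fh:
        json.dump(profile.metadata(), fh, indent=2)
    return tsv


def read_profile(tsv_path) -> EnrichmentProfile:
    """Read a profile TSV written by :func:`write_profile`."""
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    meta_path = tsv_path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {
            "transcript_id": tsv_path.name.split(".")[0],
            "window": DEFAULT_WINDOW,
            "pseudocount": DEFAULT_PSEUDOCOUNT,
            "n_ip_reps": 1,
            "n_total_reps": 1,
        }
    return EnrichmentProfile(
        transcript_id=meta["transcript_id"],
        enrichment=df["E"].to_numpy(),
        ip_density=df["ip_density"].to_numpy(),
        total_density=df["total_density"].to_numpy(),
        window=meta["window"],
        pseudocount=meta["pseudocount"],
        n_ip_reps=meta["n_ip_reps"],
        n_total_reps=meta["n_total_reps"],
    )
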