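"""Seeded generators for every input the analysis pipeline consumes.

Three families of synthetic data are produced:

* SeRP footprint tracks — per-codon negative-binomial counts for total and
  IP libraries, with a step-like IP enrichment beginning at a chosen onset
  codon (the signature of a co-translational interaction).
* RIP-qPCR well tables — Ct triplets for bait and no-bait pull-downs where
  cycloheximide preserves the enrichment and puromycin collapses it to 1
  (puromycin releases the nascent chain, so only RNA-level binding remains).
* iBAQ intensity tables — log-normal protein intensities from pull-down
  proteomics with bait-proportional signal, per-batch multiplicative
  effects, and known injected fold changes.

All generators are pure functions of their spec plus seed: the same inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .serp_profiles import FootprintTrack

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SerpSimSpec:
    """Conditions for a synthetic SeRP experiment.

    ``nb_dispersion`` is the negative-binomial overdispersion coefficient
    alpha in the standard count-sequencing parameterization,
    var = mu + alpha * mu**2 (NB size parameter r = 1/alpha); alpha -> 0
    recovers Poisson noise.  ``onset_codons`` holds one entry per transcript
    (``None`` marks a transcript with no co-translational onset, i.e.
    IP == total).  ``ramp_width`` > 0 replaces the hard step by a linear
    ramp of that many codons, for robustness experiments.
    """

    n_transcripts: int = 1
    orf_lengths_codons: int | Sequence[int] = 300
    onset_codons: Sequence[int | None] | None = None
    enrichment_fold: float = 4.0
    mean_depth: float = 5.0
    nb_dispersion: float = 0.3
    n_replicates: int = 4
    ramp_width: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        lengths = self.lengths()
        if any(L < 10 for L in lengths):
            raise ValueError("ORF lengths must be >= 10 codons")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0 (0 = Poisson)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.onset_codons is not None:
            if len(self.onset_codons) != self.n_transcripts:
                raise ValueError("need one onset entry per transcript")
            for c0, L in zip(self.onset_codons, lengths):
                if c0 is not None and not (1 <= c0 < L):
                    raise ValueError(f"onset codon {c0} outside ORF of {L} codons")

    def lengths(self) -> list[int]:
        if isinstance(self.orf_lengths_codons, (int, np.integer)):
            return [int(self.orf_lengths_codons)] * self.n_transcripts
        lengths = [int(x) for x in self.orf_lengths_codons]
        if len(lengths) != self.n_transcripts:
            raise ValueError("orf_lengths_codons must match n_transcripts")
        return lengths

    def transcript_ids(self) -> list[str]:
        return [f"ORF{i + 1:04d}" for i in range(self.n_transcripts)]


@dataclass(frozen=True)
class QpcrSimSpec:
    """Conditions for a synthetic RIP-qPCR experiment.

    ``true_fold`` is the bait-over-background mRNA enrichment under
    cycloheximide; puromycin wells are always centered on fold 1.  ``ct_sd``
    is the biological Ct standard deviation (cycles); technical wells share
    the biological mean with sd ``tech_sd`` (default ``ct_sd / 3``).
    """

    true_fold: float = 4.0
    ct_sd: float = 0.3
    n_bio: int = 5
    n_tech: int = 3
    tech_sd: float | None = None
    base_ct: float = 28.0
    bait: str = "bait"
    target_mrna: str = "target"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fold <= 0:
            raise ValueError("true_fold must be positive")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")
        if self.n_tech < 2:
            raise ValueError("n_tech must be >= 2")
        if self.n_bio < 2:
            import warnings

            warnings.warn("n_bio < 2: paired test downstream is impossible", stacklevel=2)

    @property
    def effective_tech_sd(self) -> float:
        return self.ct_sd / 3.0 if self.tech_sd is None else self.tech_sd


@dataclass
class Annotation:
    """Toy ORF annotation: GFF3-writable records plus coding sequences."""

    lengths_codons: dict[str, int]
    sequences: dict[str, str]

    def __getitem__(self, tid: str) -> int:  # mapping protocol used by loaders
        return self.lengths_codons[tid]

    def __iter__(self):
        return iter(self.lengths_codons)

    def __contains__(self, tid) -> bool:
        return tid in self.lengths_codons

    def keys(self):
        return self.lengths_codons.keys()

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for tid in sorted(self.lengths_codons):
                L_nt = 3 * self.lengths_codons[tid]
                fh.write(
                    f"{tid}\tcotransl\tCDS\t1\t{L_nt}\t.\t+\t0\tID={tid};Name={tid}\n"
                )

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[tid]), id=tid, description="")
            for tid in sorted(self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_gff3(cls, path) -> "Annotation":
        lengths = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                seqid, _, ftype, start, end = cols[0], cols[1], cols[2], int(cols[3]), int(cols[4])
                if ftype != "CDS":
                    continue
                span = end - start + 1
                if span % 3:
                    raise ValueError(f"CDS span for {seqid} is not a multiple of 3")
                lengths[seqid] = span // 3
        return cls(lengths_codons=lengths, sequences={})


def make_annotation(spec: SerpSimSpec) -> Annotation:
    """Generate a toy annotation: one CDS per transcript, seeded sequences.

    Sequences start with ATG, end with TAA, and are 3x the codon length;
    coordinates are 1-based inclusive as in GFF3.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA]))
    lengths = dict(zip(spec.transcript_ids(), spec.lengths()))
    sequences = {}
    for tid, L in lengths.items():
        middle = rng.choice(_SENSE_CODONS, size=L - 2)
        sequences[tid] = "ATG" + "".join(middle) + "TAA"
    return Annotation(lengths_codons=lengths, sequences=sequences)


def _ip_mean_profile(L: int, c0: int | None, fold: float, depth: float, ramp: int) -> np.ndarray:
    mu = np.full(L, depth, dtype=float)
    if c0 is None or fold == 1.0:
        return mu
    if ramp <= 0:
        mu[c0 - 1 :] = depth * fold
    else:
        ramp_end = min(c0 - 1 + ramp, L)
        frac = np.linspace(1 / ramp, 1.0, ramp_end - (c0 - 1))
        mu[c0 - 1 : ramp_end] = depth * (1 + (fold - 1) * frac)
        mu[ramp_end:] = depth * fold
    return mu


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, var mu + alpha*mu^2); alpha = 0 degenerates to Poisson."""
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_footprints(spec: SerpSimSpec) -> list[FootprintTrack]:
    """Simulate total and IP footprint tracks for all transcripts/replicates.

    Total counts are NB(mean_depth, alpha) at every codon; IP counts have mean
    ``mean_depth`` before the onset codon and ``mean_depth * enrichment_fold``
    from the onset onward.  Library sizes are the summed counts of each
    (condition, replicate) library, so downstream RPM normalization sees a
    realistically inflated IP library when many transcripts are enriched.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF]))
    lengths = spec.lengths()
    ids = spec.transcript_ids()
    onsets = spec.onset_codons if spec.onset_codons is not None else [None] * spec.n_transcripts

    tracks: list[FootprintTrack] = []
    for rep in range(1, spec.n_replicates + 1):
        for condition in ("total", "IP"):
            per_transcript = []
            for tid, L, c0 in zip(ids, lengths, onsets):
                if condition == "total":
                    mu = np.full(L, spec.mean_depth)
                else:
                    mu = _ip_mean_profile(
                        L, c0, spec.enrichment_fold, spec.mean_depth, spec.ramp_width
                    )
                per_transcript.append(_nb_draw(rng, mu, spec.nb_dispersion))
            libsize = int(sum(c.sum() for c in per_transcript))
            libsize = max(libsize, 1)
            for tid, counts in zip(ids, per_transcript):
                tracks.append(
                    FootprintTrack(
                        transcript_id=tid,
                        sample_id=f"{condition}_rep{rep}",
                        condition=condition,
                        replicate=rep,
                        counts=counts,
                        library_size=libsize,
                    )
                )
    return tracks


def write_footprint_tsv(tracks: Sequence[FootprintTrack], path) -> None:
    """Write tracks as the per-nucleotide TSV dialect the loaders consume.

    Each codon's count is placed on the first nucleotide of the codon.
    """
    rows = []
    for t in tracks:
        codons = np.nonzero(t.counts)[0]
        for c in codons:
            rows.append((t.transcript_id, t.sample_id, t.condition, t.replicate, 3 * c + 1, int(t.counts[c])))
    df = pd.DataFrame(
        rows, columns=["transcript_id", "sample_id", "condition", "replicate", "pos_nt", "count"]
    )
    df.to_csv(path, sep="\t", index=False)


def simulate_qpcr(spec: QpcrSimSpec) -> pd.DataFrame:
    """Simulate a RIP-qPCR well table (CHX + puromycin, bait + no-bait).

    Per biological replicate and treatment, a no-bait control Ct and a bait
    Ct are drawn with biological noise ``ct_sd``; the bait Ct sits
    ``log2(fold)`` cycles below the control, where fold = ``true_fold`` under
    cycloheximide and 1 under puromycin.  Technical wells add ``tech_sd``
    noise around the shared biological mean.

    Returns a DataFrame with columns bait, target_mrna, treatment, bio_rep,
    tech_rep, ct.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x51]))
    rows = []
    tech_sd = spec.effective_tech_sd
    for treatment, fold in (("cycloheximide", spec.true_fold), ("puromycin", 1.0)):
        for bio in range(1, spec.n_bio + 1):
            control_bio = spec.base_ct + rng.normal(0, spec.ct_sd)
            bait_bio = spec.base_ct - math.log2(fold) + rng.normal(0, spec.ct_sd)
            for tech in range(1, spec.n_tech + 1):
                rows.append(
                    (spec.bait, spec.target_mrna, treatment, bio, tech,
                     bait_bio + rng.normal(0, tech_sd))
                )
                rows.append(
                    ("no-bait", spec.target_mrna, treatment, bio, tech,
                     control_bio + rng.normal(0, tech_sd))
                )
    return pd.DataFrame(
        rows, columns=["bait", "target_mrna", "treatment", "bio_rep", "tech_rep", "ct"]
    )


def simulate_ibaq(
    n_proteins: int = 40,
    groups: Mapping[str, Sequence[str]] | None = None,
    fold_changes: Mapping[str, float] | None = None,
    n_batches: int = 4,
    batch_effects: Sequence[float] | None = None,
    noise_log2_sd: float = 0.25,
    bait: str = "NSP1",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate an iBAQ pull-down table with wildtype/mutant pairs per batch.

    Intensities are log-normal around per-protein baselines; the bait is the
    most abundant protein and present in every sample.  Each batch carries a
    multiplicative factor applied to both its wildtype and mutant sample, and
    each sample gets an additional random scale (exercising median
    normalization).  ``fold_changes`` maps group names (from ``groups``) or
    individual protein names to the true mutant/wildtype fold applied on top.

    Returns ``(table, metadata, true_folds)``: proteins x samples intensity
    DataFrame, per-sample metadata (genotype, batch), and the per-protein
    injected fold.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1B]))
    groups = dict(groups or {})
    fold_changes = dict(fold_changes or {})

    proteins = [bait] + [f"P{i + 1:03d}" for i in range(n_proteins - 1)]
    for members in groups.values():
        for p in members:
            if p not in proteins:
                proteins.append(p)
    if bait not in proteins:
        raise ValueError("bait must be present in the protein set")

    true_fold = pd.Series(1.0, index=proteins)
    for key, f in fold_changes.items():
        members = groups.get(key, [key])
        for p in members:
            if p not in true_fold.index:
                raise KeyError(f"fold change refers to unknown protein {p!r}")
            true_fold[p] = f
    true_fold[bait] = 1.0  # bait defines the reference channel

    baseline = pd.Series(
        10 ** rng.normal(6.0, 0.5, size=len(proteins)), index=proteins
    )
    baseline[bait] = 10 ** 7.5

    if batch_effects is None:
        batch_factors = 2.0 ** rng.normal(0, 0.5, size=n_batches)
    else:
        batch_factors = np.asarray(batch_effects, dtype=float)
        n_batches = len(batch_factors)

    columns, meta_rows, data = [], [], []
    for b in range(n_batches):
        for genotype in ("wildtype", "mutant"):
            name = f"{genotype}_b{b + 1}"
            sample_scale = 2.0 ** rng.normal(0, 0.3)
            vals = baseline.copy()
            if genotype == "mutant":
                vals = vals * true_fold
            noise = 2.0 ** rng.normal(0, noise_log2_sd, size=len(proteins))
            vals = vals * batch_factors[b] * sample_scale * noise
            vals[bait] = baseline[bait] * batch_factors[b] * sample_scale  # bait noise-free anchor
            columns.append(name)
            meta_rows.append((name, genotype, b + 1))
            data.append(vals)
    table = pd.concat(data, axis=1)
    table.columns = columns
    metadata = pd.DataFrame(meta_rows, columns=["sample", "genotype", "batch"]).set_index("sample")
    return table, metadata, true_fold
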