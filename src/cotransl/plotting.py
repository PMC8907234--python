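"""Plotting helpers for enrichment profiles and yield curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .onset_detection import OnsetCall
from .serp_profiles import EnrichmentProfile


def plot_profile(profile: EnrichmentProfile, call: OnsetCall | None = None, ax=None):
    """Plot a per-codon enrichment profile with the onset call, if any."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    codons = np.arange(1, len(profile) + 1)
    ax.plot(codons, profile.enrichment, lw=1.2, color="#1f5fa8", label="IP / total")
    ax.axhline(1.0, color="grey", lw=0.8, ls=":")
    if call is not None:
        ax.axhline(
            call.threshold_ratio * call.background, color="#b02020", lw=0.8, ls="--",
            label=f"threshold ({call.threshold_ratio:g} x background)",
        )
        if call.detected:
            ax.axvline(call.onset_codon, color="#b02020", lw=1.0)
            ax.annotate(
                f"onset {call.onset_codon}",
                (call.onset_codon, ax.get_ylim()[1]),
                textcoords="offset points",
                xytext=(4, -12),
                fontsize=8,
            )
    ax.set_xlabel("codon")
    ax.set_ylabel("enrichment E(c)")
    ax.set_title(profile.transcript_id)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_yield_curves(curves, ax=None):
    """Plot Y(n) curves (output of :func:`cotransl.assembly_model.yield_vs_n`)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for curve in curves:
        ax.semilogy(curve["n"], curve["yield"], marker="o", ms=3, label=curve["topology"])
    ax.set_xlabel("number of subunits n")
    ax.set_ylabel("assembly yield Y")
    ax.legend(frameon=False, fontsize=8)
    return ax
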