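import numpy as np
import pandas as pd
import pytest

from cotransl.serp_profiles import CombinedTrack, EnrichmentProfile
from cotransl.synthetic_data import QpcrSimSpec, SerpSimSpec


@pytest.fixture
def step_profile():
    """Noise-free enrichment step: E = 1 for codons 1-129, E = 4 from codon 130."""
    L = 300
    enr = np.ones(L)
    enr[129:] = 4.0
    return EnrichmentProfile(
        transcript_id="NIC96",
        enrichment=enr,
        ip_density=enr * 5,
        total_density=np.full(L, 5.0),
        window=1,
        pseudocount=0.0,
        n_ip_reps=1,
        n_total_reps=1,
    )


@pytest.fixture
def small_serp_spec():
    return SerpSimSpec(
        n_transcripts=3,
        orf_lengths_codons=200,
        onset_codons=[50, 120, None],
        enrichment_fold=4.0,
        mean_depth=20.0,
        nb_dispersion=0.1,
        n_replicates=2,
        seed=7,
    )


@pytest.fixture
def qpcr_spec():
    return QpcrSimSpec(true_fold=4.0, ct_sd=0.3, n_bio=5, n_tech=3, seed=11)


def make_combined(density, tid="T1", condition="total", n_reps=1):
    return CombinedTrack(tid, condition, np.asarray(density, dtype=float), n_reps)


@pytest.fixture
def te_toy():
    """Two genes, IP counts {10, 40} vs total {10, 10}, equal libraries of 100."""
    counts = pd.DataFrame(
        {"IP_1": [10, 40], "total_1": [10, 10], "IP_2": [10, 40], "total_2": [10, 10]},
        index=["geneA", "geneB"],
    )
    meta = pd.DataFrame(
        {
            "group": ["IP", "total", "IP", "total"],
            "replicate": [1, 1, 2, 2],
        },
        index=counts.columns,
    )
    libs = pd.Series(100.0, index=counts.columns)
    return counts, meta, libs
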