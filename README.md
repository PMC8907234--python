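# cotransl

Analysis toolkit for **co-translational protein-complex assembly**: the
process by which a fully synthesized subunit binds the nascent chain of its
partner while that partner is still on the ribosome.  The package implements
the computational stack used to study such events in large assemblies like
the yeast nuclear pore complex:

* **Selective ribosome profiling (SeRP)** — per-codon enrichment profiles
  `E(c)` comparing affinity-purified (IP) ribosome footprints to the total
  translatome, and calling of the *onset codon* where a bait first engages
  the nascent chain.  With ~30–40 residues of nascent chain buried in the
  ribosome exit tunnel, an onset at codon `c0` maps to the exposed residue
  window `[c0 − 40, c0 − 30]`, which is intersected with annotated
  interaction motifs.
* **Translatome-wide TE statistics** — per-gene total enrichment
  `TE = log2(pIP) − log2(ptotal)` tested with a re-implemented
  empirical-Bayes moderated t (variance shrinkage toward a prior `s0²` with
  `d0` prior degrees of freedom) and Benjamini–Hochberg FDR control.
* **RIP-qPCR calling** — ΔCt fold enrichments over a no-bait background,
  `f = 2^(Ct_control − Ct_bait)`, and the two-criterion decision rule: mean
  cycloheximide fold ≥ 1.5 *and* a significant signal decrease under
  puromycin (two-sided paired t, α = 0.05).  Puromycin releases the nascent
  chain, so its sensitivity separates co-translational binding from plain
  RNA binding.
* **iBAQ co-enrichment** — median- and bait-normalized pull-down proteomics,
  batch-stratified mutant-vs-wildtype fold changes, and group comparison
  (e.g. central transport Nups vs cytoplasmic filaments).
* **Assembly-yield model** — for an n-subunit complex assembled along a
  binary pathway tree, the expected yield

      Y = ∏_joins s_eff · exp(−λ Σ_parts a_u)

  combines per-join specificity competition (`s`, boosted to
  `s_eff = sδ/(sδ + 1 − s)` by the dwell factor `δ ≥ 1` of co-translational
  capture) with an orphan hazard `λ` acting over each part's exposure time
  `a_u` between synthesis and joining.  A sequential chain with `λ = 0`
  reduces to `Y = s^(n−1)` — yield decays exponentially with subunit count —
  and hierarchical (balanced) pathways or co-translational capture provably
  improve it.  A seeded Monte-Carlo simulator doubles as an independent
  oracle for the closed form.

Every pipeline input can be generated by the built-in seeded simulators
(`cotransl.synthetic_data`), so the full stack is testable without any
sequencing or MS downloads.

## Worked example

Call an onset from simulated SeRP data (one 300-codon transcript, true onset
at codon 130, 4-fold IP enrichment, 5 reads/codon, 4 replicates):

```python
from cotransl.synthetic_data import SerpSimSpec, simulate_footprints
from cotransl.serp_profiles import profiles_from_tracks
from cotransl.onset_detection import call_onset, annotate_motif_overlap
import pandas as pd

spec = SerpSimSpec(n_transcripts=1, orf_lengths_codons=300, onset_codons=[130],
                   enrichment_fold=4.0, mean_depth=5.0, nb_dispersion=0.3,
                   n_replicates=4, seed=1)
profiles = profiles_from_tracks(simulate_footprints(spec))
call = call_onset(profiles["ORF0001"])
motifs = pd.DataFrame([("ORF0001", "IM-1", 85, 120)],
                      columns=["transcript_id", "motif_name", "start_res", "end_res"])
call = annotate_motif_overlap(call, motifs)
print(f"detected={call.detected} onset={call.onset_codon} "
      f"exposure={call.exposure_window} motifs={call.motif_overlaps}")
```

prints

```
detected=True onset=126 exposure=(86, 96) motifs=['IM-1']
```

— the onset is recovered within a few codons of the simulated truth (the
15-codon smoothing window spreads the step slightly upstream), the exposed
nascent-chain window is residues 86–96, and it overlaps the annotated
interaction motif.

The yield model runs from a pathway YAML:

```sh
$ cat pathway.yaml
tree: [[[CTN, NIC96], NUP53], NUP170]
specificity: 0.9
hazard: 0.1
wait: 1.0
cotranslational: [NIC96]
dwell_factor: 4.0
translation_wait: 0.5

$ cotransl model-yield --pathway pathway.yaml --simulate --trials 20000 --seed 1
assembly yield Y = 0.411429
  specificity component: 0.788108
  hazard component:      0.522046
  total orphan exposure: 6.5 time units
assembly yield Y = 0.4111
  ...
  Monte-Carlo: 8222/20000 trials, SE 0.00348
```

41% of assembly attempts succeed: the three joins win their specificity
competition 79% of the time (the co-translational join at 4× dwell wins
97%), and orphan intermediates survive the accumulated 6.5 time units of
hazard exposure 52% of the time.  The Monte-Carlo estimate agrees with the
closed form within one standard error.

Other CLI entry points: `cotransl simulate serp|qpcr|ibaq`,
`cotransl serp-profile`, `cotransl call-onsets`, `cotransl translatome-test`,
`cotransl qpcr-call`, `cotransl ms-fold`.

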