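# Methods

This note documents the models implemented in `cotransl`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions.

## SeRP enrichment profiles

Input is a per-nucleotide footprint count table per library.  Positions are
assumed already P-site-assigned; an optional `psite_offset` (default 0 nt)
shifts 5′-end coordinates for pipelines that defer the assignment.
Nucleotide positions collapse to codons via `codon(p) = ⌊(p−1)/3⌋ + 1`;
positions outside the annotated ORF are dropped and counted in the log.

Densities are reads-per-million (RPM), `density = counts · 10⁶ / library
size`.  Replicates are combined by the mean of per-replicate RPM densities
(a pooled-raw-counts mode is available); because the mean and the gliding
average are both linear, combining before or after smoothing is equivalent.
Smoothing is a centered gliding average over an odd window `w` (default 15
codons) that truncates at the ORF edges, so the profile keeps the ORF
length.  The enrichment is

    E(c) = (smooth(IP RPM)(c) + α) / (smooth(total RPM)(c) + α)

with pseudocount α = 0.5 RPM (default), applied after smoothing.  As α → 0,
E is invariant to rescaling either library.  Both `w` and α are recorded in
each profile's JSON sidecar.

## Onset calling

The baseline `b` is the median of E over the 5′ quarter of the ORF (at
least 20 codons; shorter ORFs fall back to a whole-ORF median).  The median
is used because baselines in real profiles carry isolated spikes.  The
onset is the first codon where `E(c) ≥ θ·b` holds for `r` consecutive
codons (defaults θ = 2, r = 10); ties resolve to the smallest index.  A
call is reported only if the signal is *sustained*: the mean of E from the
onset to the stop codon must also clear `θ·b`.  Genuine co-translational
profiles stay elevated to the stop codon, so this rejects transient spikes
without a changepoint model.  Note the smoothing window biases called
onsets slightly upstream (the smoothed step begins rising ~w/2 codons
early); at the default w = 15 the bias is 2–3 codons, well inside the ±5
codon resolution the caller is validated to.

The exposed-residue window uses exit-tunnel offsets Δmin = 30,
Δmax = 40 aa: onset `c0` maps to residues `[max(1, c0−40), max(1, c0−30)]`.
Motif overlap is closed-interval intersection.

## TE statistics

Per replicate pair, `TE = log2[(nIP + α)/NIP] − log2[(ntot + α)/Ntot]` with
α = 0.5 counts (finite logs for zero-count genes).  Replicates are paired
by matching replicate labels; when the label sets differ, each IP replicate
is compared to the mean total log-proportion.

The one-sample moderated t shrinks per-gene variances `s²` (d = n−1 df)
toward a prior `s0²` with `d0` prior df:
`s̃² = (d0·s0² + d·s²)/(d0 + d)`, `t = β/(s̃/√n)` on `d0 + d` df.  The prior
is estimated across genes by method of moments on `log s²` (digamma/
trigamma matching of the scaled-F marginal, trigamma inverted by Newton
iteration), chosen over ML for determinism.  `d0 = 0` recovers the ordinary
t exactly; `d0 = ∞` uses the prior variance everywhere.  Zero-variance
genes are floored at 1e-12 and logged.  FDR control is the
Benjamini–Hochberg step-up, re-implemented and oracle-tested against the
brute-force definition.

## RIP-qPCR

Technical triplicates: a well deviating from the triplicate median by more
than 0.5 Ct is omitted and flagged; two or more such wells fail the
biological replicate.  This deviation-from-median rule is a deterministic
stand-in for instrument-software QC heuristics; the 0.5 Ct cutoff is
configurable and every omission is logged.  Amplification efficiency is
fixed at 2 (configurable): `f = 2^(Ct_control − Ct_bait)` over the matched
no-bait background, which makes f invariant to constant Ct shifts.

The decision rule is the conjunction of (I) mean cycloheximide fold ≥ 1.5
(inclusive at the boundary), (II) two-sided paired t-test p < 0.05 between
cycloheximide and puromycin folds (paired by biological replicate; unequal
replicate counts fall back to an unpaired test with a warning), and
(III) the cycloheximide mean actually exceeding the puromycin mean.
All-zero difference vectors return p = 1 (non-significant) rather than an
undefined statistic; a constant non-zero gap returns p = 0.

## iBAQ co-enrichment

Median normalization equalizes per-sample medians over the detected-protein
set (default: proteins nonzero in every sample; configurable to per-sample
nonzero) to the grand median (median of per-sample medians).  Bait
normalization divides each sample by its bait intensity (samples with an
undetected bait are excluded).  Mutant-vs-wildtype folds divide each mutant
sample by its same-batch wildtype partner (geometric mean when several),
which cancels any per-batch multiplicative factor exactly.  Group
comparisons run a two-sided unpaired t on log2 folds (variance
stabilization for ratios) only when both groups exceed `min_n = 4` values;
otherwise medians are reported with an "untested" flag.

## Assembly-yield model

An n-subunit complex assembles along a binary tree with n−1 joins.  Two
independent failure modes multiply:

* **Specificity.**  Each join succeeds with probability `s ∈ (0,1]`.  A
  co-translational join holds the nascent partner at the ribosome; the
  dwell factor `δ ≥ 1` multiplies the odds of the specific interaction in
  the kinetic competition, `s_eff = sδ/(sδ + 1 − s)`.
* **Orphan hazard.**  Every part (subunit or intermediate) accrues exposure
  from its birth (t = 0 for subunits, its own join time for intermediates)
  to its joining, and survives with probability `exp(−λ·a_u)`.

Joins are scheduled level-synchronously: `t(join) = max(t(children)) + τ`,
with `τ_tr` replacing τ at co-translational joins (assembly limited by
translation speed rather than diffusion of a scarce partner), and captured
leaves accrue no exposure.  Level-synchronous scheduling with a fixed wait
per level was chosen for analytic tractability; it makes the closed form

    Y = ∏_joins s_eff · exp(−λ Σ_u a_u)

exact.  Consequences used as test oracles: a sequential chain with λ = 0
gives `Y = s^(n−1)` (log-linear with slope log s); with λ > 0 the chain's
total exposure is `n(n−1)/2 + (n−1)` wait units, so log Y is concave in n
with quadratic coefficient −λτ/2; a balanced tree's exposure sum is
strictly smaller, so hierarchy helps whenever λ > 0 and is neutral at
λ = 0; flagging any join co-translational (δ ≥ 1) never decreases Y.

The Monte-Carlo engine replays the same process per trial (deterministic
waits reproduce the closed form's distribution; the exponential-wait mode
draws diffusive waits from Exp(mean τ) while τ_tr stays fixed).  With
exponential waits two effects oppose each other: Jensen's inequality on
`exp(−λX)` *raises* the expected yield of a pure chain, while the inflated
expectation of max(child times) at branch points *lowers* it for branched
topologies.  On balanced trees the branching effect dominates, so
exponential waits yield less than deterministic ones there; on pure chains
the direction reverses.  The test suite asserts the inequality on the
balanced topology, where it holds.

Out of scope by design: spatial diffusion, concentration-dependent
mass-action kinetics, and fitting the model to experimental data.

## Synthetic data

The generators are pure functions of (spec, seed) — identical inputs give
byte-identical outputs — and reproduce the statistical structure the
pipeline assumes, not any particular organism's data:

* **SeRP.**  Per-codon counts are negative-binomial with overdispersion
  `nb_dispersion` = α in the standard count-sequencing convention
  (var = μ + αμ²; α = 0 is exactly Poisson).  Total libraries have constant
  mean `mean_depth`; IP libraries step from `mean_depth` to
  `mean_depth × enrichment_fold` at the onset codon (an optional
  `ramp_width` linearizes the step for robustness tests).  Library sizes
  are the summed counts per library, so the IP library is realistically
  inflated when many transcripts are enriched.  Default conditions: fold 4,
  depth 5 reads/codon, α = 0.3, 4 replicates — a moderately noisy but
  detectable experiment.  Not emulated: codon-level pausing structure,
  positional coverage biases, ligation/PCR artifacts, or shared noise
  between IP and total libraries; calibration results on these simulations
  therefore validate the statistical machinery, not any guarantee about a
  particular deposited dataset.
* **qPCR.**  Gaussian noise on the Ct scale (the standard assumption):
  biological sd `ct_sd` on both bait and no-bait background Cts, technical
  sd `ct_sd/3` around the shared biological mean (triplicates are tighter
  than biological replicates).  The bait Ct sits log2(fold) cycles below
  the background; puromycin wells always regress to fold 1.
* **iBAQ.**  Log-normal baseline abundances (sd 0.5 decades), an abundant
  noise-free bait anchor, per-batch and per-sample multiplicative factors,
  multiplicative log-normal measurement noise (log2 sd 0.25, a ~20%
  CV typical of AP-MS), and user-injected true fold changes on named
  protein groups.

## Problem sizes

The validation suite and `scripts/acceptance.py` use desk-scale sizes
chosen to keep Monte-Carlo error well below the decision margins: 200
transcripts × 300 codons × 4 replicates for onset recovery, 200 seeded
experiments for qPCR power, 20,000 trials per Monte-Carlo yield estimate,
1,000 genes for null FDR calibration, and 4 batches for iBAQ recovery.  The
whole acceptance run completes in seconds.

## Known limitations

* The onset caller is a single-changepoint rule; multi-onset profiles
  return only the first onset, and the upstream smoothing bias (2–3 codons
  at default settings) is not corrected.
* The moderated model fits one coefficient (IP vs total) with no batch
  covariates or mean-variance (voom-style) weighting.
* The qPCR chain assumes a single no-bait reference per treatment; no
  standard-curve efficiency estimation or multi-reference normalization.
* The yield model's level-synchronous schedule is an idealization; fully
  asynchronous kinetics are available only through the Monte-Carlo engine.
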