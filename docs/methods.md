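# Methods

This note documents the models behind `grazekit`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Batch-culture kinetics

**Model.** A closed bottle with predator F(t) and prey B(t). During the
exponential phase (t ≤ t_e) the latent trajectories are F(t) = F₁·e^{μt} and
B(t) = B₁·e^{−gt}; afterwards the prey holds constant and the predator decays
at rate d. This piecewise-exponential form is exactly the model the
log-linear estimators assume (Frost's and Heinbokel's grazing formulas are
derived under exponential prey decay against exponential predator growth), so
the noiseless generator→estimator round trip is exact — a deliberate design
choice over a mechanistic functional-response ODE, which would make recovery
tests depend on an arbitrary integration tolerance without testing anything
extra about the estimators.

**Estimation.** All rates are natural-log based; time is in hours everywhere
(ingest your day-scaled series as hours). Growth and decay rates are OLS
slopes of ln(abundance) on time. A constant series has slope 0 and its R²
(a 0/0) is reported as 0 by convention. The exponential window, when not given
explicitly, is the longest contiguous window whose fit reaches R² ≥ 0.99
(configurable), with ties broken toward steeper |slope| and then the earlier
start — deterministic, and matching the practice of fitting "the linear part"
of the log curve. Note that a clean stationary decay is itself log-linear:
when a series spans both phases, restrict the search to the rising limb (the
pipeline does this by slicing at the abundance maximum) or pass the window
explicitly.

**Grazing.** g is minus the prey's fitted slope; B̄ and F̄ come from the
window's endpoint observations. Two mean conventions are implemented and
recorded in every output:

- geometric: √(x₁·x₂);
- integral: the time average of an exponential between the endpoints,
  (x₂−x₁)/ln(x₂/x₁); for the predator this is evaluated as (F₂−F₁)/(μ·Δt)
  when a growth rate is supplied (Heinbokel's growing-population form; the
  two coincide when μ equals the endpoint-implied rate).

Defaults: prey geometric, predator integral. The field's wording ("geometric
mean of flagellates and bacteria") and its cited formulas (integral means)
differ, so the choice is explicit and switchable rather than asserted. Then
I = g·B̄/F̄ and C = g/F̄, which satisfy I·F̄ = g·B̄ and C·B̄ = I to machine
precision by construction. A geometric predator mean over a ~200-fold growth
window underestimates F̄ badly and is not the cited convention; it is
available but not the default.

**Carbon and efficiency.** Per-cell carbon from the equivalent spherical
diameter: V = (π/6)·ESD³ μm³, C = a·V^b pg with defaults a = 0.216,
b = 0.939 — conventional protist coefficients, both configurable because
volume-to-carbon conversions are taxon- and fixation-dependent. GE =
μ·C_F/(I·C_B) is validated by formula consistency (balanced budget ⇒ GE = 1),
not by reproducing any particular percentage: the cell sizes behind published
efficiency figures are not part of this package's inputs.

**Survival.** Half-life of the stationary decline is ln 2/|slope| of the
fitted log-linear decay; a non-declining series is an error, not a NaN.

## Synthetic batch cultures

Observation noise is multiplicative lognormal with a specified CV
(σ² = ln(1+CV²), mean-one factors), the natural model for microscope counts
spanning orders of magnitude; a Poisson mode is available for
small-count studies (its draws are floored at one cell mL⁻¹ so log-based
estimators always apply; at realistic abundances the floor is never hit).
Default CV = 0.05 is a counting-precision convention, not a measured value.
Because the noise is mean-one multiplicative, E[ln(obs)] differs from
ln(latent) only by the constant −σ²/2, so fitted slopes are unbiased — this
is why the recovery tests can demand tight agreement on the mean estimate.

Default conditions are the study conditions the estimators target: μ = 0.16
h⁻¹, F₁ = 378 cells mL⁻¹ (rising to ~8×10⁴ over the 34 h exponential phase),
B₁ = 2.5×10⁷ cells mL⁻¹ decaying at g = ln(25/3.5)/34 ≈ 0.0578 h⁻¹, a
stationary half-life of 130 h, and a 20-fold dilution event. The default
sampling design is 9 counts through the exponential phase and 10 through the
stationary phase out to 40 days.

The dilution model divides both populations by the dilution factor, lets the
predator complete at most 2 further doublings (configurable; growth on
pre-dilution reserves) before decaying at d, and lets the prey double at most
once before holding constant (no bacterial growth in sterile seawater). The
post-dilution regrowth rate is taken equal to μ for both populations — a
simplification; only the division caps are quantitatively interpreted.

What the generator does **not** emulate: latency phases, functional-response
saturation, bottle effects, cell-size dynamics, or correlated counting errors
between the two populations. Passing recovery tests therefore demonstrates
estimator correctness under the estimators' own assumptions, not robustness
to model misspecification in real cultures.

## Expression

Counts are negative-binomial, NB(μ_g, α) with Var = μ + αμ², gene baselines
uniform in log₁₀ over (0.5, 3) in TPM-scale units, common dispersion α = 0.1
(moderate for bulk RNA-seq), transcript lengths uniform in 300–3000 bp. A
`de_fraction` of genes (half up in each direction) receive ±log₂FC shifts
between the first and last phase, interpolated linearly in log space across
the phase order — emulating the observation that starvation-by-dilution
states sit between exponential and stationary expression.

**DE test.** Columns are library-size normalized to their median total. The
common dispersion is a pooled method-of-moments estimate using within-group
moments (numerator Σ(s²−m), denominator Σ(m²−s²/n), the latter the unbiased
estimate of μ²), clipped at 0. Per gene, the identity-link score statistic of
equal means,

    Z = (ȳ_A − ȳ_B) / sqrt((μ̂₀ + α μ̂₀²)(1/n_A + 1/n_B)),

with μ̂₀ the pooled null mean, is referred to a standard normal. The normal
reference is appropriate here because the null variance comes from the
mean–variance relation with a dispersion shared across thousands of genes,
not from a per-gene sample variance: a calibration simulation at the null
conditions above (2000 genes, 3 vs 3, 200 replicates) shows rejection at
p < 0.05 within a point of nominal, while a t correction with replicate-level
degrees of freedom is several-fold conservative. logFC is
log₂((ȳ_A+pc)/(ȳ_B+pc)) with pseudocount pc = 0.5 for stability at low
counts. This engine is a documented, simple stand-in for the field's standard
tools (no TMM normalization, no tagwise dispersion shrinkage); the
classification, partition and aggregation steps all accept external
(logFC, FDR) tables so any engine's output can be pushed through the same
accounting.

**Thresholds** are strict inequalities as printed in the classification
conventions they implement: DE iff |log₂FC| > 2 and BH FDR < 10⁻³; highly
expressed iff phase-mean TPM > 500 in at least one phase. Phase means pool
biological and technical replicates (they are empirically indistinguishable
in this design). Category aggregation sums phase-mean TPM over genes of a
category and scales each row by its maximum, so every row peaks at exactly
100%; the row maximum TPM is reported alongside. Zero-variance samples yield
missing (NaN) correlations, never 0.

## Curation

Stage order: longest isoform per gene (ties to the lexicographically smallest
transcript id, for determinism) → keep transcripts with genome,
transcriptome, or eukaryote-annotation evidence → prevalence filter →
contaminant removal (a second, later screen; a contaminant flag always wins
over positive evidence) → multi-ORF splitting. "Detected" in the prevalence
filter means count ≥ 1 in a sample, configurable — raw-count detection is the
natural reading and the threshold is exposed because the convention varies.
All filters are idempotent. TPM uses annotated transcript length, not
effective length; no fragment-length correction is attempted because none is
defined for the inputs this package accepts. Split records inherit the
parent's per-sample counts unless per-ORF counts are supplied upstream. The
split accounting identity — final count = base + Σ count·(parts−1) — is
tested against literal record expansion.

## Enrichment

One-sided hypergeometric upper tail per domain present in the background,
P(X ≥ k), evaluated via log-gamma-stable survival functions and verified
against exhaustive enumeration for all small populations (N ≤ 25). A gene
contributes at most once per domain (presence/absence). BH adjustment spans
all tested domains; domains with k = 0 are reported with a −∞ log₂ fold
rather than dropped. Only enrichment is tested, not depletion.

## Occupancy binning

Bins on per-sample relative abundances (percent): exactly 0 ("absent"),
(0, 0.1), [0.1, 1), [1, 10), [10, ∞). Edges are closed on the left (0.1 falls
in "0.1–1"), a documented convention where the tabulated sources do not state
one; "absent" means exactly zero target reads. Bin percentages sum to 100 by
construction; mean and median are reported together because their divergence
is the signature of patchy distributions.

## Problem sizes and determinism

The test suite and the acceptance script use simulation sizes chosen to make
the statistical assertions sharp while keeping the whole suite fast on a
laptop: 100 seeds for rate-recovery means, 200 replicates of 2000 genes for
null calibration of the DE test, 100 seeds of 1000 genes × 40 domains for
planted-enrichment recovery, and exhaustive enumeration for the small-N
oracles. All randomness flows through `numpy.random.default_rng` seeds held
in parameter objects; fixed seeds give bit-identical outputs, including
byte-identical pipeline output files.

## Known limitations

- The DE engine is intentionally minimal; published DE totals obtained with
  shrinkage-based engines are treated as accounting inputs to the classifier,
  not as numbers this engine should reproduce from raw counts.
- Grazing estimates use window-endpoint observations, not fitted values; with
  very noisy endpoints a practitioner may prefer to pass fitted endpoints.
- The carbon model's coefficients are conventions; efficiency values inherit
  their uncertainty multiplicatively.
- The dilution generator's regrowth-rate simplification (see above) means
  only its division caps, not its transient shape, should be interpreted.
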