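# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `turnoverkit`. It describes what the code
computes and why each open design choice was resolved the way it was; no
number quoted here is asserted anywhere except by the tests and
`scripts/acceptance.py`, which recompute them.

## Turnover model and fitting

Pulse-SILAC measures, per peptide and time point, the ratio of pre-existing
(medium-label) and newly synthesised (heavy-label) protein to a constant
spiked-in light reference. Under first-order turnover at steady state the
pre-existing pool decays as `D(t) = C + A·exp(−t/τ)` and the new pool
accumulates as the complement `S(t) = (C+A) − D(t) = A·(1 − exp(−t/τ))`, so
the labelled total `S + D = C + A` is conserved at every time point and the
two curves cross at `t½ = τ·ln 2` when `C ≈ 0`. The offset `C` absorbs
amino-acid recycling and any degradation-refractory fraction; no explicit
precursor-pool model is fitted.

Parameters and defaults:

| parameter | units | default / bound | role |
|---|---|---|---|
| `A` | ratio | ≥ 0 | labelled amplitude between t=0 and the asymptote |
| `τ` | h | (0, 300] | time constant; 300 h cap ⇒ 208 h half-life ceiling |
| `C` | ratio | ≥ 0 | decay asymptote (recycling) |

**Loss.** Measurement noise on SILAC ratios is multiplicative and
heteroscedastic, so the generator applies log-normal noise and the fitter
minimises log-residuals `ln(obs/model)` — ordinary nonlinear least squares
on the log scale, which is the maximum-likelihood loss under the declared
noise and keeps the parameter covariance honest. Fitting on the raw ratio
scale would overweight early decay points and miscalibrate the downstream
z-test.

**Optimisation.** Bounded trust-region least squares with an analytic
Jacobian, three starts (τ₀ ∈ {5, 20, 80} h), tolerances 1e-10, best cost
kept. Both curves share (A, τ, C); the joint fit roughly halves parameter
variance relative to fitting either curve alone and enforces conservation.
Replicates enter as independent observations. A fit is flagged *degenerate*
when the amplitude collapses to numerical zero (τ unidentifiable, e.g. a
flat series) or the Gauss–Newton covariance is singular; a fit ending at
the τ ceiling is flagged *tau_capped*.

**Errors.** Two τ errors are reported: the fit-covariance error
(`σ² (JᵀJ)⁻¹` with the residual variance estimated from ~39 degrees of
freedom on the standard 7×3×2-point design) and the replicate-spread error
(SE of τ across per-replicate fits). The fit-covariance error is used
downstream: with three replicates the spread estimate has ~2 degrees of
freedom, and standardising Δt½ by it would give |z|>1.96 under the null
about 12% of the time instead of 5%.

**Aggregation.** Protein-level fits use the per-time-point mean of peptide
ratios, intensity-weighted by default (configurable to uniform); per-peptide
fits and their relative deviation from the aggregate are reported for
concordance inspection.

**Paired filters.** A protein enters the differential half-life analysis
only when, in both conditions, τ ≤ 72 h (the pulse duration, read literally
in τ units), σ_τ < 12 h (strict) and C > 0, and neither fit is degenerate.

## Differential testing

**Abundance.** The SILAC design yields one log2(4-OHT/CTRL) ratio per
replicate, so the test is a one-sample moderated t against zero per protein
per time point. Per-protein variances are shrunk toward a common target
with the analytic optimal intensity
`λ* = clip(Σ Var̂(v_k) / Σ (v_k − v_target)², 0, 1)`. Two small-sample
choices matter at triplicate scale:

* `Var̂(v_k) = 2 v_k²/(n+1)`, the normal-theory unbiased estimate of the
  sampling variance of a sample variance. The distribution-free plug-in is
  biased low by about half at n=3, which under-shrinks and makes the test
  wildly conservative.
* `v_target` = median of the raw variances rescaled by
  `(n−1)/median(χ²_{n−1})` (≈1.44 at n=3), making the robust median target
  unbiased on the variance scale under normal sampling.

p-values use Student t with effective degrees of freedom `(n−1)/(1−λ*)`,
which is the classical t at λ*=0 and the normal as λ*→1 (the moderated-t
limit). Classification is `up`/`down` at ≥2-fold and p<0.01 (both
configurable); BH q-values are emitted as an extra column but the headline
classification uses raw p, matching the analysis being reproduced.

**Half-life.** `z = Δt½ / √(σ²_CTRL + σ²_OHT)` with two-sided normal p.
The significance threshold is configurable (default α=0.01; the looser 95%
CI convention is a documented alternative).

## Response-kinetics clustering

Only *complete* profiles (all three replicates at all seven time points)
are clustered: k-means with k=30, 50 initialisations, Euclidean distance on
replicate-averaged log2 profiles without standardisation (shared units).
Cluster mean profiles are agglomerated into six classes by explicit rules
replacing an inherently manual step: max |fold| < 3 ⇒ NC; an up response
reversing by ≥25% of its peak ⇒ UD; otherwise the sign of the extreme
change gives up/down and the linearly interpolated half-maximal crossing
time splits early (≤12 h) from mid (>12 h). The boundaries are config
fields; output metadata records that the rules are an automated
approximation.

## Abundance statistics

Copy numbers anchor total histone intensity to the DNA mass of a diploid
human cell (6.5 pg default, configurable): `mass_i = I_i·m_DNA/Σ_hist I`,
`N_i = mass_i·N_A/MW_i`. The result is invariant to global intensity
rescaling and linear in the anchor mass. The abundance-weighted median
half-life is the first half-life (values ascending, ties by stable order)
at which cumulative copy number reaches half the total — no interpolation,
so with uniform weights it matches the lower-middle convention. Weighting
matters only when half-life and abundance are correlated; the tests verify
both the correlated and the uncorrelated behaviour.

## Enrichment

Half-lives are split into ten equal-count bins (ties broken by protein id).
Per-bin term enrichment is a hypergeometric upper tail against the measured
background with BH FDR (reported at ≤0.01); the annotation map is a
user-supplied two-column TSV or GMT, not a bundled database. The Pscore of
a term is the fraction of 10,000 same-size random protein sets (drawn
without replacement from the measured background) whose mean half-life
falls below the term's, with exact ties counted half — the midpoint rule
makes the score symmetric (a term spanning the whole background scores
exactly 0.5, and reversing the half-life ranks complements every score).
Terms with Pscore < 0.001 / > 0.999 are called short-/long-lived; terms
smaller than 5 are reported not-significant with a flag. The permutation
count and unit (protein sets) are configurable; 10,000 is the default.

## Complex coherence

Per-complex sample SD of member half-lives (complexes with ≥2 measured
members), compared against decoy pseudo-complexes that preserve the exact
size multiset and draw members without replacement (within a complex) from
the measured background — sampling decoys from the same measurement filter
as targets avoids detection-bias artefacts. The summary statistic per
iteration is the median per-complex SD (robust, matching the CDF-shift
claim being tested); the empirical p over 1000 seeded iterations uses the
add-one rule `(1+k)/(n+1)`, which is exactly uniform under exchangeability
and reports a 1/(n+1) floor for a never-beaten target.

## Signature and survival

The signed signature contains every complete-profile gene changing ≥2-fold,
with coefficient ±1 from the direction of its extreme change. Patient
scores are the dot product of the coefficients with per-gene z-scored
expression (z-scoring makes unit coefficients comparable across genes;
rank or provider normalisation can be substituted via the `normalize`
option). Cohorts are the top/bottom 20% score quantiles; survival is
compared by Kaplan–Meier curves (median = earliest time with S(t) ≤ 0.5),
the two-group log-rank test, and the top/bottom median-survival ratio. The
bootstrap FDR redraws 1000 random same-length signatures carrying the
target's ±1 multiset in random order (preserving sign balance is the
stricter null), recomputes the ratio, and reports the fraction of decoys at
or below the target's ratio — "< 0.001" when none is. Iterations whose
cohorts never reach 50% survival have no median and are excluded, with the
exclusion count reported.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions rather than tunables:

* 7 time points (1–72 h) × 3 replicates; 1–50 peptides per protein
  (log-normal, median 5).
* log10 copy-number SD 1.15, chosen so ~5000 draws span ~8 decades; a
  10-histone subset rescaled so its intensity share is exactly the
  configured fraction (5%); intensities follow I = copies × MW.
* τ log-normal with median 16 h (log10 SD 0.35) giving an ~11 h median
  half-life; offsets uniform on [0.02, 0.15] with A = 1 − C; multiplicative
  ratio noise of ln-SD 0.05.
* 3% responsive proteins split evenly over five piecewise-linear log2
  archetypes of amplitude 2 (4-fold): EU saturating by 6 h, MU by 24 h,
  their mirrored down versions, and UD peaking by 8–12 h then reversing
  75% of its peak by 72 h; replicate noise SD 0.25 log2 units.
* complexes drawn size 3–6 with member half-lives at a complex mean ±
  `coherence` hours (0 ⇒ identical; ∞ ⇒ uncoupled control).
* patients with standard-normal expression and exponential survival whose
  hazard is `h₀·exp(effect·z(score))`; censoring hits each patient with the
  configured probability at a uniform time before the event.

What the generator does *not* emulate — and therefore what passing tests do
not demonstrate about real data: peptide-level identification artefacts and
missingness structure (missingness is planted uniformly at random), shared
precursor-pool recycling dynamics beyond the offset term, correlated noise
across peptides of one protein, batch effects across replicates, covariate
structure in patient cohorts, and any correlation between half-life and
abundance (drawn independently by default, so the weighted and unweighted
medians agree on synthetic bundles).

## Numerical and degenerate-input conventions

Model evaluations are floored at 1e-12 before taking logs; r² is clipped to
[0, 1]; chi2 points with zero or undefined SE are excluded with a warning;
proteins with a single replicate in a time-point cell are skipped with a
warning; all-equal patient scores trigger a warned stable-order split;
bootstrap iterations without a defined median survival are excluded and
counted. All generators and permutation procedures take explicit seeds and
are deterministic given them; the pipeline writes every float with a fixed
format so reruns are byte-identical.

## Problem sizes used in validation

The self-validation harness (`turnoverkit.benchmarks`, driven by the test
suite and `scripts/acceptance.py`) uses: 1,000 proteins for τ recovery;
10,000 proteins for t-test calibration; 2,500 proteins for the paired
z-test null; 500 weighted-median instances; 1,500 profiles for class
recovery; 500 null terms × 10,000 permutations for the Pscore; 200
uncoupled runs × 1,000 decoy iterations for complex-coherence calibration;
100 cohorts of 500 patients for log-rank power; 1,000 bootstrap decoys for
the signature FDR; and a 500-protein bundle for the deterministic
end-to-end run. These sizes keep each check's Monte-Carlo error well inside
the band it asserts.

## Known limitations

The agglomeration rules approximate an unrecorded manual grouping; the
enrichment backend is a plain hypergeometric test over user-supplied maps,
not a semantic annotation service; no multiple-testing correction is
applied to the headline 2-fold/p<0.01 classification (by design, q-values
are provided); CORUM-style catalogs must be pre-converted to the two-column
TSV; and the survival module implements stratified comparison and bootstrap
FDR but not Cox modelling or real-cohort retrieval.
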