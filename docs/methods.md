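# Methods

## Estimation model

All estimators operate on harmonized per-variant summary pairs
(β̂_Xj, σ_Xj, β̂_Yj, σ_Yj) under the standard two-sample MR sampling model:
estimates are independent across variants and across samples, normally
distributed around their true values, with known SEs. The true outcome effect
of variant j is β_Yj = θ·β_Xj + α_j, where θ is the causal effect of the
exposure and α_j a direct (pleiotropic) effect, zero for a valid instrument.

**Wald ratio.** θ̂_j = β̂_Yj/β̂_Xj. The default SE is the first-order delta
approximation σ_Yj/|β̂_Xj|, the convention in two-sample practice; a
second-order form sqrt(σ_Yj²/β̂_Xj² + β̂_Yj²σ_Xj²/β̂_Xj⁴) is available via
`se_order="second"`. For instruments with F ≫ 10 the difference is
negligible (≲1% at F > 100).

**Fixed-effect IVW** pools ratios by inverse variance. With one instrument it
returns that ratio exactly (short-circuited to avoid rounding the weighted
mean). Cochran's Q with n−1 df is provided as a heterogeneity companion.

**MR-Egger.** Weighted least squares of β̂_Yj on β̂_Xj with intercept, weights
σ_Yj⁻², after orienting each instrument to β̂_Xj > 0 (the fit depends on
allele coding, so a convention is required; orientation makes it coding
invariant). SEs use multiplicative residual inflation: the variance scale
Σw·r²/(n−2) is floored at 1, so overdispersion widens intervals and
underdispersion never narrows them. Inference for all estimators, including
Egger, uses the normal distribution with the 95% multiplier fixed at
Φ⁻¹(0.975) = 1.959964; some R implementations use t-quantiles for Egger,
which would widen intervals slightly at 3 instruments. The intercept's
two-sided z-test is the directional-pleiotropy diagnostic; the slope is
consistent under InSIDE (instrument strength independent of direct effects).

**Weighted median.** Per-variant ratios carry normalized first-order
inverse-variance weights; the estimate interpolates the sorted ratios against
cumulative weights s_j = Σ_{k≤j}w_k − w_j/2 at 0.5, so equal weights
reproduce the simple median. The SE is the standard deviation of the
estimate over parametric-bootstrap draws β̂_Xj ~ N(β̂_Xj, σ_Xj),
β̂_Yj ~ N(β̂_Yj, σ_Yj); default 10,000 replicates, seeded, vectorized.
The estimator is consistent while valid instruments carry >50% of the weight.

## Harmonization

Both summary files are assumed to report the forward strand; complement
resolution is attempted only when direct and swapped matching both fail
(summary tables carry no strand column). Swapped alleles negate the outcome
beta and reflect its EAF. Palindromic (A/T, C/G) variants default to
`drop_ambiguous`: dropped when either EAF is missing or within 0.08 of 0.5,
otherwise oriented by EAF concordance. The window mirrors common MR practice;
the classic three iron instruments are non-palindromic, so the policy never
affects that design. Duplicate rsids within a file are a hard error —
instrument sets here are tiny and curated, so silent deduplication would hide
upstream mistakes. Exposure effects can be re-expressed per SD *decrease*
(`orient_exposure`), the conventional reading for transferrin, whose level
falls as iron status rises.

## Instrument grading

`gw_filter` applies P < 5×10⁻⁸. `ld_prune` greedily keeps the smallest
p-value and removes partners with r² ≥ 0.01 from a user-supplied matrix
(computing LD from a reference panel is out of scope; designs here use a
handful of curated variants). Ties break lexicographically by rsid for
determinism. Both F formulations are reported — (β/σ)² always, and
R²(n−2)/(1−R²) with R² = 2p(1−p)β² when EAF and N are known — because
published instrument tables rarely state which was used.

## Power

Power of the two-sided level-α test uses the non-centrality approximation:
NCP = N·R²_gx·b², power = Φ(−z_{1−α/2}+√NCP) + Φ(−z_{1−α/2}−√NCP), with b the
causal effect in SD/SD units and N the outcome sample size. For binary
outcomes the odds ratio is attenuated to the linear-probability scale,
b = K(1−K)·ln(OR) with case fraction K, the 0/1 outcome's residual variance
is K(1−K) − b², and NCP = N·R²_gx·b²/(K(1−K) − b²). This choice keeps power
exactly α at OR = 1, monotone in N, R², |ln OR|, and symmetric under
OR ↔ 1/OR. It is a small-effect approximation: when b² approaches K(1−K)
the formula saturates and power is reported as 1.

## Synthetic data

The generator simulates at the summary level: true per-variant exposure
effects (a fixed vector or a uniform range), direct effects α_j for a chosen
fraction of invalid instruments (balanced: mean 0; directional: mean ≠ 0),
observed estimates with normal sampling error, and p-values from the observed
z-statistics. Binary outcomes are generated directly on the log-odds scale,
an approximation valid for small per-variant effects; no individual-level
logistic layer exists. Defaults emulate a 3-instrument iron design: exposure
betas (0.33, 0.19, 0.18) SD/allele, σ_X = 0.01 (≈49k exposure sample),
σ_Y = 0.05 (biobank-scale continuous outcome), EAF ~ U(0.1, 0.9) steered out
of the palindromic-ambiguity window unless harmonization stress is enabled,
and a configurable fraction of outcome rows emitted with swapped or
complemented alleles to exercise harmonization (default 0).

What the generator does *not* emulate: LD between instruments (they are
independent by construction, matching an r² < 0.01 design), sample overlap
between the two GWAS, winner's-curse selection of instruments, EAF
discrepancies between cohorts, and case-control ascertainment effects.
Passing tests therefore validate the estimators under their stated sampling
model, not robustness to those real-data complications.

The packaged iron-style fixture is a hand-written constant table (not an RNG
draw): three strong instruments whose outcome effects equal 0.5·β_X plus
fixed offsets smaller than one outcome SE, so the documented causal effect of
0.5 is recovered within sampling error by construction.

## Pipeline

`run_study` composes read → orient → harmonize → per-variant ratios → pooled
estimates for every exposure×outcome×method cell and emits forest-plot-ready
rows (Egger contributes slope and intercept rows). Outcome-scale transforms —
division by a phenotypic SD for natural-unit biomarkers, division by μ(1−μ)
to convert linear-model betas on a 0/1 outcome to log-odds — are explicit
per-outcome configuration and never inferred, because published analyses
rarely print them. Instruments missing from an outcome file shrink the
analysis to the remaining set (recorded in `n_snps`); an empty intersection
yields a status-flagged row, not a crash. Sex strata are pure configuration
(different outcome files, same pooled exposure effects — sex-specific
instrument effects for iron status are generally unavailable). Significance
is annotated at the nominal P < 0.05 only; no multiplicity correction is
applied, matching the analysis convention this design follows. Reverse MR
(disease liability as exposure, biomarkers as outcomes) reuses the identical
machinery with roles swapped in the configuration.

## Validation problem sizes

The acceptance script and test suite use 100 random instrument sets for
closed-form oracle agreement (tolerance 1e-10), 1000 replicates for parameter
recovery at θ = 0.3 (mean within 3 Monte-Carlo SEs; empirical/analytic SE
ratio within 10%), 2000 replicates for the type-I error of IVW at θ = 0
(binomial 95% bounds around 0.05), and 400 replicates each for the
pleiotropy-robustness comparison (40% invalid instruments, directional mean
0.05) and Egger-intercept recovery (all instruments invalid, InSIDE held).
These sizes make every Monte-Carlo check stable across seeds while the whole
suite runs in seconds.
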