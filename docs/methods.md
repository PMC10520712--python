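# Methods

This note records the statistical procedures the package implements, the
defaults it ships, and the choices made where more than one convention is
defensible.

## Composite health index

Indicators are min-max standardized with explicit polarity: positive
indicators map their group minimum to 0 and maximum to 1; negative
indicators are reversed.  The standardization group is the cross-section
within each year by default (`scope="per_year"`), so a province's score is
relative to that year's best and worst; a pooled variant is available and
is what the industry development levels use, since entropy weighting is
conventionally computed over the pooled panel.  A degenerate group
(all regions identical) maps to 0.5 — any constant is defensible and the
midpoint avoids polarity bias — with a warning.

Entropy weights are computed over the pooled region-year observations:
proportions `q_ij = p_ij / Σ_i p_ij`, entropy
`e_j = −(1/ln N) Σ_i q_ij ln q_ij` with `0·ln 0 := 0`, divergence
`d_j = 1 − e_j`, weight `w_j = d_j / Σ d_j`.  One weight vector applies to
all years; time-varying weights would make the index incomparable across
years.  No epsilon shift is applied by default because the shift changes
the weights; callers wanting the common `p + ε` variant must pass `shift`
explicitly.  An indicator that is constant across all observations carries
no information and receives weight zero; if every indicator is constant
the computation refuses.

## Convergence scoring

Each industry's development level `U` chains the same standardize →
entropy-weight → composite machinery over employment, fixed-asset
investment and output (all positive polarity, pooled standardization,
per-industry weights).  Development levels are computed per industry
separately rather than jointly over an industry pair's six indicators.

The pairwise score uses the two-system coupling degree
`C = 2√(U1·U2)/(U1+U2)` (equal to the common
`{U1U2/[(U1+U2)/2]²}^(1/2)` form), `C = 0` when both levels are zero,
coordination level `T = αU1 + (1−α)U2` with `α = 0.5` by default (no
argument for prioritizing either subsystem), and degree `D = √(CT)`.
`C ≤ 1` by AM–GM with equality iff `U1 = U2 > 0`; the implementation
clips the one-ulp overshoot that subnormal products can cause.  The
overall HICD entropy-weights the pairwise `D` columns by default
(consistent with pairing the coordination model with the entropy method);
an equal-weight mean is available as a sensitivity option.  When every
pairwise column is constant the entropy synthesis falls back to equal
weights, which returns the common value.

## Spatial weights and Moran diagnostics

The weight matrix is binary contiguity built from an edge list, with
islands kept as zero rows and reported rather than silently rewired.
Moran's I is computed on the binary matrix exactly as the statistic is
defined (its `Σw` denominator makes row scaling immaterial up to row-sum
weighting); model fitting and effect decomposition use the
row-standardized matrix, the spatial-econometrics convention that bounds
the admissible parameter above by 1 and makes spillovers interpretable.
Inference uses the randomization-assumption (permutation) moments with a
one-sided upper-tail p-value, matching the positive-clustering question;
the moments are undefined at n = 3 and reported as NaN there.  No
multiple-testing correction is applied across yearly tests.  Local
statistics classify regions into HH/LH/LL/HL by the signs of the own
deviation and the weighted neighbour deviation, with zero treated as low.

## Spatial panel likelihoods

All families operate on within-transformed data (individual, time or
two-way demeaning).  Without demeaning an explicit intercept is added;
its spatial lag is collinear under row standardization and is excluded
from the Durbin block.  SLM/SDM estimation concentrates the likelihood to
a scalar function of ρ through the standard two auxiliary regressions,
evaluates the Jacobian `ln|I − ρW|` from pre-computed eigenvalues, and
maximizes by bounded scalar search on the admissible interval with a
1e−5 inset; estimates within 1e−4 of a boundary are flagged and refuse
effect decomposition.  SEM concentrates over λ with spatially filtered
variables.  Standard errors come from the analytic information matrix;
the degenerate case where the spatial lag has no residual variation after
the regressors (exactly noiseless data) leaves ρ unidentified and is
resolved to ρ = 0 with a warning.

Short-panel demeaning bias: naive demeaned ML loses one effective time
period to individual demeaning and one effective region to time
demeaning, which biases the variance and, through the Jacobian, ρ itself
(about −0.045 at n = 30, T = 18 in our recovery experiments).  With
`bias_correct` (default on for two-way effects) the likelihood is the
orthonormal-transformation one: effective dimensions (n−1) and/or (T−1),
and — because the constant vector is an eigenvector of a row-standardized
W with eigenvalue 1 — the cross-section transform drops one unit
eigenvalue from the log-determinant, `ln|I − ρW| − ln(1 − ρ)`.  The
information matrix is evaluated on the Helmert-transformed problem.  This
removes the bias (recovery simulations at n = 30, T = 18 show mean ρ bias
below 0.005 and 95% Wald coverage near nominal).  The point estimates are
obtained directly from this likelihood; no post-hoc correction step is
applied.

R² conventions differ across the literature, so both are reported:
`r2_within` (squared correlation of fitted and observed on the demeaned
scale) and `r2_naive` (same on the original scale with recovered fixed
effects added back).

Specification tests: LR statistics are `2(LL_full − LL_restricted)`
clipped at zero, with df equal to the number of restrictions (k for SDM
vs SLM, and k supplied explicitly for SDM vs SEM, whose common-factor
restriction has the same count).  The fixed-effects LR comparison fits
both the pooled and two-way models with the naive (untransformed)
likelihood so the two log-likelihoods live on the same nT observations.
The Hausman test compares the individual-effects FE estimator with a
Swamy–Arora feasible-GLS random-effects estimator of the non-spatial
model — the paper-style model-selection step, not the headline method —
using a pseudo-inverse with a warning when the variance difference is not
positive definite.  Random effects for the spatial-error family are out
of scope.

## Effect decomposition

For SLM/SDM fits the marginal-effect matrix is
`S_r(W) = (I − ρW)⁻¹(Iβ_r + Wθ_r)`; direct = mean diagonal, total = mean
row sum, indirect = total − direct, with the reported total stored as
direct + indirect so the additivity identity is exact in floating point.
`(I − ρW)⁻¹` is a dense solve — adequate to a few hundred regions; no
sparse path is provided.  Inference simulates parameters from the
asymptotic normal implied by the fit covariance (1,000 draws by default,
seeded), rejecting draws whose ρ leaves the admissible interval, and
reports draw standard deviations, t ratios and two-sided normal p-values;
a covariance submatrix that is not PSD is repaired by eigenvalue clipping
with a warning.  A delta-method alternative is not implemented.
Regional heterogeneity re-fits the SDM per macro-region on the
re-standardized principal submatrix of W; a subset that creates islands
or fails to fit is skipped with a logged message rather than aborting the
study.

## Synthetic data

The generator emulates the study's scale, not its joint distribution: a
5×6 rook lattice (30 regions, 49 edges) over 18 years, with east/central/
west assigned by column bands.  Outcomes solve the spatial Durbin system
`(I − ρW) y_t = X_t β + W X_t θ + μ + v_t 1 + ε_t` exactly by linear
solve each year — no series truncation — with defaults mirroring the
study's magnitudes (ρ = 0.24, β on the log convergence degree 0.58, the
remaining β/θ at the published coefficient values, innovation sd 0.1 on
the log scale, individual-effect sd 0.3, time-effect sd 0.05).  The
generator refuses ρ outside the stationarity interval of the
row-standardized W.  Fixed effects are redrawn per panel by default;
callers running Monte-Carlo replications with frozen effects pass them in
explicitly.

Covariates are log-normal with moments matched to provincial scales
(aging 9.6 ± 2.1%, education 8.7 ± 1.0 years, real GDP per capita
28,800 ± 24,500 yuan, urbanization 52 ± 15%, government health share
5.4 ± 2.0%), a persistent regional component smoothed over neighbours
(a spatial moving average, since neighbouring provinces share
demographics), and i.i.d. year noise.  Health indicators are monotone
noisy transforms of a latent health level clipped into the published
ranges (life expectancy 65–85 years, perinatal mortality 1.8–25‰,
maternal mortality 1–161 per 100,000).  Industry tables give each region
a persistent log-normal scale and each indicator an independent regional
multiplier with 3–6% yearly growth; the independence across indicators
keeps pooled maxima on different region-years so derived
coupling-coordination degrees span roughly 0.1–0.65 rather than
saturating.  No missing data are generated: the cleaning/imputation
applied to the original yearbooks is undocumented, so the package models
none.

In synthetic study runs the SDM-simulated outcome is the modeled health
variable, because its generating parameters are known and recoverable.
The indicator-index stage still runs end to end on raw indicator tables
derived from the same latent surface, and its reconstructed composite is
reported descriptively with its correlation to the simulated outcome in
the run metadata; feeding the reconstruction back into the regression
would push the outcome through a data-driven min-max/entropy map and
destroy the known-parameter contract.  Consequently, passing tests
demonstrate correctness of each statistical component and of their
composition — not that the generator reproduces the real data's
inter-variable correlations, which it does not attempt.

## Problem sizes and determinism

Recovery and test-size experiments run 200 replications at the study
scale (30 × 18); the acceptance script uses 100 replications and a full
study run, a few seconds each on one CPU.  All randomness flows from
explicit integer seeds through `numpy` generators (study sub-stages use
spawned seed sequences), so a repeated run with the same seed writes
byte-identical outputs, including the Monte-Carlo inference stages.

## Known limitations

- No GMM/IV or dynamic spatial panels; no higher-order spatial lags; no
  inverse-distance or economic weight matrices; no polygon-based
  contiguity derivation.
- The composite index attains exactly 0 at each year's worst region under
  per-year standardization, so a log-transformed model of the index
  itself refuses to run rather than silently shifting; rescale or model
  levels (`log_transform=False`) instead.
- SEM random effects, three-or-more-system coupling models, and
  input-output (Leontief) convergence measures are out of scope.
- The Moran permutation moments use the normal approximation; exact
  permutation p-values are only cross-checked in tests.
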