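# Methods

## Scope and data model

One record per animal: snout-vent length (SVL, cm), total body mass (g),
wet-fat mass of the dissected coelomic fat bodies (g), sex, and an optional
specimen-handling flag (fresh/frozen). All three measurements must be
strictly positive (every quantity is log-transformed somewhere downstream)
and fat must be strictly below total mass. Units are fixed; nothing is
auto-detected, because silently mixing metres and centimetres is a classic
source of allometry errors. Analyses are stratum-local: every fit, reference
length and index is computed within one sex, since the sexes carry different
allometric exponents.

## Line fitting

Three bivariate line-fitting methods share one closed-form core (moments of
the two vectors):

* OLS: b = r·s_y/s_x — vertical residuals, assumes error only in y;
* SMA (reduced major axis): b = sign(r)·s_y/s_x — symmetric in x and y up to
  inversion, the standard choice when both variables carry error;
* MA (major axis): the first principal axis of the covariance matrix.

All pass through the centroid. Residuals are always *vertical* (observed
minus expected y), including for MA and SMA, because condition indices
interpret a residual as mass relative to expectation at the animal's length.

Confidence intervals: SMA uses the F-based closed form
B = F(1−α; 1, n−2)·(1−r²)/(n−2), CI = b·(√(B+1) ∓ √B); OLS the t-based
interval; MA the Jolicoeur eigenvalue form with tangent-addition limits
(b ∓ A)/(1 ± bA), A² = H/(1−H), H = t²/[(λ₁/λ₂ + λ₂/λ₁ − 2)(n−2)]. Simulated
coverage of the SMA and MA intervals at n = 100 is 95 ± 1% (checked in the
test suite for SMA). Logarithms are natural internally; every reported
quantity on log-log axes (slopes, r, r², residual ranks) is invariant to the
base, which is nevertheless recorded on each fit for transparency.

The common-slope hypothesis (do k groups share one SMA slope?) is tested
with the likelihood-ratio statistic LR(b) = −Σᵢ nᵢ·ln(1 − rᵢ²(b)), where
rᵢ(b) is the within-group correlation between the residual axis u = y − b·x
and the major axis v = y + b·x; rᵢ vanishes exactly when b is group i's SMA
slope. The statistic is minimised over b by bounded scalar minimisation on
[min slope/3, max slope×3] and referred to χ²(k−1). No small-sample
(Bartlett-type) correction is applied; at the sample sizes this package
targets (n > 100 per group) the correction changes p only marginally.

## Condition indices and true-condition measures

The 11 BCIs per stratum, with L = SVL, M = mass, natural logs:
M/L, M/L², M/L³, M/prM (prM = exp(a + b·ln L) from the SMA fit of
ln M on ln L, back-transformed without a smearing correction — a constant
factor is rank-neutral where the ratio is used), ln M/ln L, ln M/ln prM,
vertical residuals of ln M on ln L under OLS/MA/SMA, SMA residuals of raw M
on raw L³, and the scaled mass index SMI = M·(X₀/L)^b with b the SMA slope
of ln M on ln L. X₀ defaults to the stratum's arithmetic mean SVL (the
choice only rescales the index) and can be overridden per stratum.

True condition: percent fat = fat/mass; scaled fat = fat·(X₀/L)^b_f with
b_f from the SMA of ln fat on ln L; residual fat = that fit's vertical
residuals. Two identities are load-bearing and tested exactly: the mean of
residual fat (and of each residual BCI) is zero on its own stratum, because
the fitted line passes through the centroid; and ln SMI = (a + b·ln X₀) +
SMAres, an increasing affine map, so Kendall's τ between SMI and the SMA
residual index is exactly 1.

## Diagnostics

Kendall's τ is the tie-corrected tau-b; the statistic is assembled from
integer pair counts (concordant, discordant, three tie classes), making it
exact at the ±1 boundaries, with the p-value from the tie-corrected normal
approximation (exact enumeration for small untied samples). Mann-Whitney
reports U of the first sample with half-credit for cross-group ties (so
W ∈ [0, n₁n₂]); the p-value is exact for pooled n ≤ 20 without ties, else
normal with continuity and tie corrections. The size-bias partition takes
the BCI values of animals in [mean−w, mean) and (mean, mean+w] of SVL
(default w = 25 cm, giving two adjacent 0.25 m bands whose members differ
by at most 0.5 m); animals exactly at the mean are excluded to keep the
classes disjoint.

The regression-assumption battery fits OLS of y on x and runs Ramsey's
RESET (fitted-value powers 2 and 3, joint F-test) for linearity and the
studentised (Koenker) Breusch–Pagan LM test for homoscedasticity; residual
normality uses Shapiro–Wilk, with the D'Agostino skewness and
Anscombe–Glynn kurtosis tests run when normality is rejected (or always, on
request — callers can supply the residual vector, e.g. MA or SMA residuals,
while RESET/BP stay on the OLS scaffold). No multiple-testing correction is
applied across the battery.

## Synthetic populations

The generator draws, per sex, ln L ~ N(μ, s²) and
ln Y = α + ρ·b·(ln L − μ) + ε with sd(ε) = b·s·√(1−ρ²), separately for
Y = mass (b_m, ρ_m) and fat (b_f, ρ_f). This parameterises the population
directly by the *SMA* slope and correlation: sd(ln Y)/sd(ln L) = b and
corr = ρ exactly, so the headline quantities of the analysis are the
generator's own dials. Defaults encode the study design the package is
validated against: n = 114 females / 134 males; b_m = 3.21/3.04 and
r² = 0.96; b_f = 5.16/4.37 and r² = 0.85/0.81; log-SVL sd 0.33 (F) / 0.25
(M), placing the observed SVL ranges (70–482 cm F, 76–347 cm M) near ±3 sd;
μ and the intercepts α set so the expected SVL, mass and fat match the
reported means (235 cm / 11 852 g / 1 226 g F; 214 cm / 7 683 g / 571 g M)
via the lognormal mean correction α = ln(target) − sd²/2.

The mass and fat residuals are correlated at ρ_mf = 0.75 by default. Fat
bodies are part of total mass, so a fat animal is also heavy for its
length; with independent residuals the BCIs (mass given length) would be
statistically independent of all three fat-based condition measures and
every "accuracy" correlation would be noise around zero. The value 0.75
follows from the rank correlation of ~0.55 observed between
residual-family BCIs and residual fat in real pythons through the Gaussian
relation ρ = sin(πτ/2); it reproduces accuracy structure of realistic
magnitude (residual BCIs vs scaled/residual fat τ ≈ 0.5–0.6, ratio BCIs
vs percent fat r² ≈ 0.45) without entering the marginal slope/r²
construction at all. Setting `resid_cross_corr=0` restores conditional
independence.

Residuals are Gaussian by default; an optional skew-normal shape parameter
(`resid_skew`, standardised to zero mean and unit sd) mimics the left skew
real fat residuals show, and is off by default. Records violating
fat < mass are resampled (with a cap that turns a pathological
configuration into an error); at the defaults violations are vanishingly
rare, leaving the marginal structure intact.

### What the generator does not emulate

Real morphometric samples are not log-normal in length (field collections
mix cohorts and are truncated by catchability), fat residuals are
left-skewed and leptokurtic, and handling (fresh vs frozen) may shift
measurements. Passing tests on synthetic data therefore demonstrate the
*estimators and battery*, not field-data conclusions. One concrete
consequence: with Gaussian log-log structure at r² = 0.96 and slope ≈ 3.2,
the population τ between MA and SMA residual indices is ≈ 0.947 (exact via
the residual cross-correlation and τ = (2/π)·arcsin ρ) — r² ≈ 0.995 would
be needed to reach 0.98 — so the near-perfect three-way interchangeability
of the MA-residual, SMA-residual and scaled-mass indices reported for real
pythons is *not* reproduced by a Gaussian generator with the published r²;
only the analytic SMI/SMAres identity (τ = 1) carries over. The acceptance
suite states the stronger claim and is allowed to fail it, as an honest
record of this model-vs-data gap.

## Verification report and numerical choices

`run_verification` stratifies by sex, runs common-slope tests (sex always;
handling when both fresh and frozen appear with n ≥ 3), fits the
allometries, computes the condition table, and assembles: the
condition-vs-length table (OLS of each measure on ln SVL — an ideal measure
has slope ≈ 0 and r² ≈ 0); the 11×4 accuracy/bias matrix (τ, its p, and
OLS r² of each BCI on each measure and on SVL, with r² taken from OLS of
the BCI on the reference since the BCI is the error-bearing variable); the
symmetric 11×11 BCI τ matrix; the assumption battery for the four
regression BCIs (RESET/BP on each BCI's own regression scaffold, normality
on its own residuals); and the size-bias Mann-Whitney test, by default on
each stratum's best percent-fat performer by OLS r² (configurable). The
whole pipeline is deterministic given records and options; reports are
written as tidy CSVs plus a JSON summary that round-trips to the same
tables and a plain-text digest.

Degenerate inputs fail loudly with context: zero variance on an axis, MA
at r = 0 (slope undefined), strata below n = 3, empty size-bias classes,
constant vectors passed to τ. Stage and stratum names are attached to any
error escaping the orchestrator.

## Problem sizes

Simulation-based tests use the design sample sizes (114/134) with 100–500
replicates, 200 replicates for slope-recovery means, and 2 000 replicates
for test-size checks — enough for the Monte-Carlo error (±0.5 pp on a 5%
rate at 2 000 replicates) to sit well inside the asserted bands.
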