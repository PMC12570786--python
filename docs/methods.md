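# Methods

This note records the models, conventions and numerical choices behind
`antelopy`, and what the synthetic-data experiments do and do not show.

## Signal model and burst features

Raw collar counts span 0–4095 corresponding to −4..+4 G, i.e. 512
counts/G around an offset of 2048; centering is `(raw − 2048)/512`. The
x axis is surge (along the neck), so the static neck pitch is
`asin(mean static x in G)` (clamped to ±1 G with a warning before asin —
violent motion can push the mean outside the gravity ball). The yz-plane
magnitude `sqrt(y² + z²)` is invariant to collar rotation about the neck,
which is why features are computed on x and yz only; z alone is never
interpreted (and never sign-flipped).

Per burst (109 samples = round(33 Hz × 3.3 s)) we compute, on x and yz:
mean, population variance (1/n), SD, max, min, range; and from the
mean-removed DFT: the bin-center frequency of maximal power (DC excluded,
so posture cannot masquerade as a frequency), its amplitude 2|c|/n, and
the Shannon entropy of the normalised power spectrum divided by
log(#bins) (so entropy ∈ [0, 1]; an all-zero series is defined as
entropy 1 and flagged). ODBA subtracts a per-axis static component — a
22-sample (0.67 s) running mean — and averages the summed absolute
dynamic components over samples.

**ODBA edge rule.** The running-mean window is kept at its full 22-sample
length everywhere: centered in the interior, slid inward at the burst
edges (no padding, no shrinking). This is the one simple convention under
which a window as long as the burst makes the static component the global
mean at every sample — the natural degenerate limit — and it avoids the
edge bias that shrinking windows give on periodic signals.

**Orientation harmonisation.** An axis (x or y) is flipped for an
individual iff the sign of its grand mean disagrees with the training
reference and both magnitudes exceed a noise floor of 0.05 G. The floor
prevents spurious flips when an axis mean is essentially zero.

## Classification

Features are ranked by single-feature 5-fold CV accuracy of a shallow
decision tree (ties broken alphabetically; constant features have
undefined correlation, are treated as uncorrelated and ranked last), then
greedily retained iff |Pearson r| < 0.9 with every already-retained
feature. The classifier is a gradient-boosted tree ensemble
(scikit-learn `HistGradientBoostingClassifier`, learning rate 0.1,
150 iterations, seeded — deterministic across runs). Contribution scores
are forward-stepwise gains in held-out accuracy over the retained
features, with the empty-set accuracy defined as the majority-class rate.
The classifier predicts the 12 raw labels; the head-up/head-down feeding
split happens downstream from pitch, because pitch — not the label — is
the field definition of the split (boundary −30° inclusive to head-up).

## Time budgets

Days are local calendar days at a fixed UTC+2 (Namibia, no DST). Per
individual, the first 10 calendar days (collaring recovery) and the final
date (de-collaring/predation) are excluded; the exclusion is flagged on
the result so re-application is a no-op. Daily proportions use burst
counts (each burst stands for its 5-min slot); days with fewer than 216
bursts (75% of 288) are dropped — the completeness rule is ours, chosen
so that a "day" always aggregates at least three quarters of the diel
cycle. Species-level values weight individuals equally (mean of
individual means). Diel matrices are 96 quarter-hour local bins × day of
year; bins without data are missing, not zero.

## Ephemeris and the moonlight contrast

The lunar illuminated fraction uses the classical low-precision
trigonometric series for solar and lunar ecliptic coordinates (7 lunar
longitude terms, 4 latitude terms), elongation ψ from
`cos ψ = cos β cos(λm − λs)`, and the phase-angle approximation
i = 180° − ψ, giving k = (1 − cos ψ)/2. The distance-ratio correction to
i is below 0.2° and irrelevant at the documented accuracy bound of
|Δk| ≤ 0.02 — night classification only needs threshold-level precision
at 0.9/0.1. The test suite checks this bound against an independent
high-order series (24 longitude / 20 latitude / 20 distance terms with
full phase-angle geometry) on 1000 random instants. Sun events use the
NOAA solar-position equations at zenith 90.833°, re-evaluated once at the
provisional event time; accuracy ±2 min against an independently
implemented iterated hour-angle solution.

A night is labelled by the local date containing its 00:00–00:59 window
and its illumination is evaluated at that local midnight; moonlit means
k > 0.9 strictly, dark k < 0.1 strictly, all else excluded. The
rank-sum test uses midranks, reports the first-sample Mann–Whitney
W ∈ [0, n₁n₂], enumerates the exact null distribution when n₁n₂ ≤ 400
with no ties (the count recurrence is equivalent to full enumeration),
and otherwise uses the tie-corrected normal approximation with a 0.5
continuity correction; two-sided p = min(1, 2·min(tails)).

## The synthetic generator

The generator is the study design in code, not a fit to any dataset. Per
5-minute slot it draws an analysis class from
`p ∝ diel_weight(hour) × exp(coupling·(NDVI − 0.3) + individual offset)`,
then a raw label from fixed within-class weights. Defaults: five
individuals; one calendar year; hourly diel curves with feeding peaks
after sunrise and before sunset, a pre-dawn rumination peak and nocturnal
resting; seasonal couplings (+2.5 head-up feeding, +1.5 head-down, −1.2
resting, per unit NDVI on the log scale) emulating the woody-flush
vs grass-growth phenology; per-individual class offsets with SD 0.30;
NDVI from a noise-free double logistic (green-up midpoint ~10 Dec,
senescence ~10 May, base 0.15, amplitude 0.35) so the curve is
analytically checkable; temperature a sinusoid (mean 23 °C, amplitude
6 °C, peak mid-December) plus N(0, 1.2) noise. In night slots (between
local sunset and sunrise) the combined feeding probability is shifted
additively by `lunar_effect × k(night)` — full-moon minus new-moon nights
differ by ≈ lunar_effect (default 0.10) before clamping — split between
head-up and head-down in proportion and rescaling the rest. Slot draws
are i.i.d. by default; an optional first-order stickiness parameter
(default 0) adds behavioural persistence.

Waveforms: gravity oriented by the label's static pitch (head-down
feeding below −30°, browsing above), plus a periodic component (walking
2 Hz at 0.4 G on surge/heave, running/trotting faster and stronger,
ruminating ~1 Hz at 0.08 G on sway, resting none) with ±3% frequency
jitter and 0.03 G white noise, rotated by the individual's neck angle,
optionally sign-flipped, quantised at 512 counts/G and clipped to
0–4095.

**What passing tests show.** Recovery tests demonstrate that the pipeline
is correct under its own assumptions — known schedules, additive effects,
stationary signal shapes, independent slots. They do not show robustness
to real-collar phenomena the generator omits: behaviour transitions
within a burst, non-stationary gaits, temperature-dependent sensor drift,
label noise in training video, or NDVI measurement error.

**Midnight-hour sampler.** Replicated power/calibration studies draw only
the twelve 00:00–00:59 slots per night from the same probability model
(`simulate_midnight_budgets`); full-day schedules would add nothing to a
midnight-hour contrast.

**Calibration requires exchangeable nights.** With the default seasonal
coupling active, moonlit and dark night clumps interleave along the
seasonal trend; nights are then not exchangeable and the rank-sum test is
markedly conservative (rejection ~0.01 at nominal 0.05). The type-I
calibration study therefore zeroes the seasonal coupling (all other
defaults intact), under which the measured rejection rate is ~0.04–0.05.
The conservatism under seasonal confounding is a property of the design
worth knowing, not a defect of the test.

## GAM, smoothing and partitioning

Bases follow the value-parametrised regression-spline construction: the
coefficients are the spline's values at the knots, second derivatives
come from the banded value-to-curvature system, and the penalty is the
integrated squared second derivative in quadratic form. The month basis
is cyclic on the period [1, 13) (value, first and second derivative
continuous across the boundary); NDVI and temperature use natural cubic
splines on quantile knots (near-coincident quantiles are thinned at 1e−3
of the range — the curvature penalty otherwise blows up as 1/h³) with
linear extension outside the knot range. Each smooth is sum-to-zero
constrained via the null space of 1ᵀX; each block's penalty is clipped to
exact positive semi-definiteness and normalised to unit Frobenius norm so
smoothing parameters of different terms live on comparable scales.
Individual intercepts are an identity-penalized dummy block (ridge ≡
random effect).

Fitting is penalized IRLS (logit link, variance μ(1−μ)/w) with
step-halving on the penalized deviance; convergence at relative change
< 1e−8 or 200 iterations (at the cap the fit is accepted with a warning
if the remaining relative change is below 1e−3 — quasi-separable rows
with clipped linear predictors can otherwise cycle indefinitely at
numerical noise level — and an error is raised beyond that). Prior
weights (daily burst counts) are normalised to mean 1 — quasi-likelihood
weights are defined up to proportionality — so rescaling all weights
leaves the fit invariant and only the dispersion φ (Pearson/(n − edf),
reported on the raw weight scale) absorbs the scale.

Smoothing parameters minimise deviance GCV, `n·D/(n − γ·edf)²`, by
coordinate descent (coarse log-grid then golden-section refinement, two
sweeps) with the standard inflation γ = 1.4: plain GCV's well-known
flat-profile undersmoothing left null smooths at edf ≈ 5, while with
γ = 1.4 null effects collapse to negligible amplitude (a few hundredths
of a logit). Note that under a true null the GCV-selected *edf* remains
noisy even then; it is the fitted amplitude that shrinks, and the tests
assert exactly that.

Explained deviance is 1 − D/D₀ with D₀ from the intercept-only weighted
fit (defined as 0, with a warning, for a constant response).
Hierarchical partitioning refits every non-empty subset of the predictor
groups {month, NDVI, temperature, individual}, each with its own GCV
selection (each submodel is a legitimate GAM — fixing λ from the full
model would make subsets inherit smoothing chosen under different
confounding), and Shapley-averages the gains: independent
I_g = Σ_S |S|!(G−|S|−1)!/G! · (R(S∪g) − R(S)); unique
U_g = R(full) − R(full∖g); shared S_g = I_g − U_g (negative shared values
are reported with a warning, never hidden; Σ I_g = R(full) holds as an
identity). Concurvity of ordered term pair (i, j) is
‖P_j f_i‖²/‖f_i‖² with P_j the projection onto term j's basis columns.

Random slopes are excluded by design (they did not converge in the
original analysis either); only per-dataset (per-species) models are fit,
since the partitions of interest are per species.

## Problem sizes and defaults in the test-bed

Recovery experiments use 2000 labelled bursts per analysis class for the
classifier; one simulated year × 5 individuals (≈73 moonlit and 73 dark
nights) per lunar replicate with 100 power and 1000 calibration
replicates; and n = 3000 individual-days (8 individuals × 375 days) for
GAM recovery — sizes chosen to match the magnitudes a single-species
subset of a real deployment would give.

## Known limitations

- The ephemeris is geocentric; topocentric lunar altitude, moonrise/set
  and twilight are out of scope, so "night" is purely sunset-to-sunrise.
- GCV (not REML) selects smoothing; REML would be less prone to
  undersmoothing but heavier. The choice is isolated in one function.
- The quasibinomial fit treats days as independent; no autocorrelation
  structure is modelled.
- Exact Wilcoxon enumeration refuses ties; tied small samples fall back
  to the tie-corrected normal approximation.
- The pitch split assumes the static surge mean estimates gravity; fast
  gaits bias it, which is why feeding-type labels alone are re-split.
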