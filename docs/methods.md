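# Methods

This note documents the models and procedures implemented in
`dendrovigor`, the parameter choices that matter, what the synthetic data
generator does and does not emulate, and the numerical conventions adopted
where the field leaves them open.

## Climate preparation

Reference evapotranspiration follows FAO-56 Penman-Monteith at the daily
step:

ET₀ = [0.408 Δ (Rn − G) + γ (900/(Tm+273)) u₂ (es − ea)] / [Δ + γ (1 + 0.34 u₂)]

with G = 0 at daily resolution. When radiation, wind or humidity are not
measured — the common case for long precipitation/temperature stations —
the FAO-56 reduced-data procedure substitutes: solar radiation from
extraterrestrial radiation via Hargreaves, Rs = 0.16 √(Tx−Tn) · Ra (0.16
is the interior-location coefficient), actual vapour pressure from the
minimum temperature as a dewpoint proxy (ea = e°(Tn)), and u₂ = 2 m/s.
The clear-sky ratio Rs/Rso is clipped to [0.3, 1]. ET₀ is floored at 0.
The reduced-data pathway is the default; measured `rs`, `u2`, `rh`
columns switch each substitution off independently.

Seasons are DJF/MAM/JJA/SON with December assigned to the *following*
year's winter, so seasonal predictors align with the growth year they
precede. Periods missing calendar days are dropped from aggregates, with
a logged warning — as are all silent data edits in the package (gap
interpolation up to 5 days for temperature, zero-filling of missing
precipitation).

Trends use the Mann-Kendall S statistic with tie-corrected variance, a
continuity-corrected normal approximation for p, and the Theil-Sen slope.
No autocorrelation (block/prewhitening) correction is applied to the
trend test; the annual series it is used on here are close to serially
independent. Drought thresholds are one-sided normal quantiles
(mean − 1.645·sd and mean − 2.326·sd) of a reference climatology.

## Chronology building

Raw ring-width series are ratio-detrended: RWI = RW / fitted, where the
fitted growth curve is Friedman's variable-span super smoother. The
smoother runs local-linear fits at three fixed spans (5%, 20%, 50% of the
series), picks the span with the smallest smoothed leave-one-out absolute
residual at each point, applies bass enhancement toward the widest span
(the "intermediate" setting, bass = 5, is the default; `low`/`high` map
to 2/8), and interpolates between the fixed-span smooths. Two numerical
guards matter in practice: the local window never drops below 5 points
(a 2-point window interpolates exactly, which silently degenerates the
span selection on series shorter than ~60 years), and the fitted curve is
floored at a small positive value before division.

Prewhitening fits an AR(p) model with p chosen by AIC (p ≤ 10, capped on
short series); the residuals are recentred to mean 1. Order 0 is allowed.
The chronology is the per-year Tukey biweight robust mean (c = 9, centre
initialized at the median, MAD scale, iterated to convergence, median
fallback at MAD = 0). Both variants are kept: **standard** (detrended
only) feeds the resilience indices and the growth-model calibration;
**residual** (prewhitened) feeds the climate-growth correlations.

Signal strength: rbar is the mean pairwise between-tree Pearson
correlation in 20-year windows shifted annually, with radii of the same
tree averaged to the tree level first (EPS is about between-tree signal;
radii are pseudo-replicates), and only trees completely covering a window
counted. EPS = N·rbar/(1 + (N−1)·rbar); windows with EPS > 0.85 are
flagged well replicated. The per-series correlation-with-mean statistic
uses a chronology rebuilt without the focal tree, avoiding
self-correlation inflation.

## Pointer years and resilience

Cropper values standardize each tree's index within a centred 7-year
window (sample SD; undefined at the 3-year edges and in zero-variance
windows). A year is a negative pointer year when ≥75% of trees with
defined values fall below −0.75 (positive symmetrically), evaluated only
with ≥4 trees. Resilience components around an event year y use 3-year
flanks: Rt = Dr/PreDr, Rc = PostDr/Dr, Rs = PostDr/PreDr, so Rs = Rt·Rc
identically; trees without complete flanks are skipped and logged. The
default event years (1983, 2001, 2009, 2015) are the severe
Iberian-range droughts the pipeline was designed around; they are
config-driven. Group contrasts use two-sided Mann-Whitney tests (exact
when n₁·n₂ ≤ 400 without ties). The defoliation-growth association uses
Spearman rank correlation, because crown defoliation is visually binned.

## Climate-growth correlations

The predictor matrix holds monthly Tx, Tn and P − PET for the 13 months
from the previous September to the current September (previous-year
months suffixed `_prev`); arbitrary monthly covariates, e.g. an external
soil-moisture series, can be appended. Correlations are Pearson r with
percentile confidence intervals from a paired bootstrap over years
(default 1000 resamples); a cell is significant when its 95% CI excludes
zero. The bootstrap is a simple paired one, not a block bootstrap — the
chronology side is prewhitened, so serial dependence is weak; a Holm
correction exists but is off by default, matching the per-cell display
convention of dendroclimatological correlation tables. Moving
correlations repeat the procedure in 30-year windows shifted annually.

## The daily growth model

The simulator is a Vaganov-Shashkin-style ring-level model: it produces a
daily growth rate, not cell anatomy. Modifiers are trapezoids —
gT rises linearly from T1 to T2, is 1 on [T2, T3], falls to 0 at T4;
gW mirrors this over W1..W4 (volumetric soil moisture). Insolation
gE is day length from solar-declination geometry normalized by its
annual maximum (measured radiation, normalized per year, is a drop-in
replacement). The soil bucket, updated every day including dormancy:

- precipitation falls as snow when Tm ≤ Tsnow; melt = min(snowpack,
  ksm·(Tm − Tsnow));
- infiltration I = min(k1·(rain + melt), Pmax);
- transpiration E = k2·Gr(previous day) — coupling water use to activity;
- drainage D = k3·W·Droot;
- W ← clip(W + (I − E − D)/Droot, 0, Wcap), clipping logged as runoff/
  dry-out.

Growth activates each year once Σ max(Tm, 0) from 1 January reaches
Tbeg, and terminates at year end or after 10 consecutive gT = 0 days past
midsummer (DOY 182) — a convention, config-exposed. Active days have
Gr = gE·min(gT, gW) and are classified temperature-limited (gT < gW),
moisture-limited (gW < gT), optimal (gT = gW = 1) or co-limited
(gT = gW < 1); reporting merges co-limited into moisture by default,
giving a three-class partition of active days. The annual index is Σ Gr,
standardized over a reference period; since calibration is
correlation-based (scale-free), RMSE is computed after affinely mapping
the standardized index to the observed chronology's mean/SD on the
calibration period.

The 18 parameters (T1–T4, W1–W4, Wcap, W0, k1, Pmax, k2, k3, Tbeg,
Tsnow, ksm, Droot) are calibrated by seeded differential evolution
(Sobol initialization, no polishing, `updating="deferred"`) maximizing
Pearson r between simulated and observed annual indices on the
calibration period; knot orderings are enforced by optimizing increments
(T1, T2−T1, …) rather than raw knots, so every candidate is valid by
construction. Verification recomputes r and RMSE on a held-out period
without refitting. An automated, seeded global search replaces manual
parameter tuning because reproducibility requires it. Default bounds are
wide but physiological (e.g. T1 ∈ [−2, 8] °C, rooting depth
200–1000 mm); defaults for simulation (T = 4/14/22/32 °C,
W = 0.02/0.12/0.25/0.35 v/v, Wcap 0.40, k2 = 2.5 mm/day) describe a
drought-tolerant Mediterranean conifer on a shallow sandy-loam soil.

Within-budget problem sizes: a 100-year calibration (differential
evolution, ~3·10³ simulations) takes a few seconds with the numba-JIT
daily core; the 10-seed recovery experiment runs in under a minute.

## Smooth seasonal models

Daily simulated Gr is modelled with penalized regression built from
cyclic cubic B-spline bases over DOY (the season is periodic) and
ordinary B-splines over covariates, second-difference penalties, and
sum-to-zero constraints so each smooth is orthogonal to the intercept and
group offsets. Year intercepts enter as a ridge-penalized block — the
penalized-regression form of a random intercept. Smoothing parameters
minimize GCV with an edf inflation factor γ = 1.4, the standard guard
against GCV undersmoothing under residual correlation. AR(1) residuals
are handled by within-year Cochrane-Orcutt quasi-differencing, iterated
with re-selection of the penalties. Reported per-smooth edf is 1 + the
trace of the smooth's effective-parameter block (a flat smooth reports
edf 1); approximate F statistics and the vigor-contrast t follow the
usual penalized-regression forms. Dormant days (structural zeros) are
excluded by default.

The DOY × spring-water-balance interaction is an interaction-only tensor
product of the constrained marginal bases (so it is orthogonal to both
main effects). Because the spring balance is constant within a year, its
effect is a *year-level* quantity, and a parametric F test computed on
thousands of correlated daily residuals is badly anti-conservative. The
interaction is therefore tested by permuting the year → balance
assignment (99 permutations by default): main-effect penalties and the
AR(1) coefficient are selected once on the observed data and held fixed,
while the tensor penalty is re-selected identically for the observed and
every permuted arrangement, making the two F statistics exchangeable
under the null. Seeded null simulations keep the empirical size at or
below the nominal level; a constructed wet-spring effect is detected at
p ≤ 0.05.

## Synthetic data generator

The generator defines the study conditions for all tests. Daily
temperature is a sinusoid (annual mean 12 °C, amplitude 9.5 °C, peak DOY
205) plus AR(1) noise (φ = 0.7, innovation SD 2 °C) and an optional
linear trend; Tx/Tn add/subtract half a seasonally varying diurnal range.
Precipitation is a monthly two-state Markov occurrence chain with gamma
amounts whose monthly normals sum to 423 mm with a May maximum, an
October secondary maximum and a June-August drought; an optional drying
trend scales the normals linearly over time. Realized climatologies hit
the targets within sampling error (verified across seeds).

Pseudo-trees share a common signal: the standardized annual index of the
growth model run under a known ("true") parameter set — so calibration
against the generated chronologies is a well-posed recovery experiment.
An optional mismatch parameter set generates the signal from a different
model member to probe robustness. Per tree: negative-exponential age
trend (random a, b, c), ring width = age trend × (1 + 0.25·signal z) ×
lognormal noise, two radii with within-tree noise, a staggered first
year, and — for D trees — a linear decline ramp after the divergence year
(2% per year, floored at 0.3). A constructed drought year (all trees'
width × 0.45-0.5) provides pointer-year ground truth. Defoliation is
drawn inversely to the last-5-year mean width plus noise; its only
contract is that inverse association. Everything derives from one master
seed, and regeneration is byte-identical.

What the generator does **not** emulate: spatial correlation between
sites, age-dependent climate sensitivity, missing rings, measurement
error correlated between radii, disturbance pulses other than the
constructed ones, multi-day storm structure, or humidity/wind records.
Passing tests therefore demonstrate the correctness and internal
consistency of the methods under a realistic but idealized regime — not
the field validity of any ecological conclusion.

## Numerical conventions and degenerate inputs

- Cropper normalization uses the window SD (not MAD); edges are
  undefined rather than computed from shrunk windows.
- Constant series: detrending returns RWI ≡ 1 with a warning; MS = 0 and
  AR1 = 0 with a flag; Cropper values are missing.
- Biweight: median fallback when MAD = 0; convergence tolerance 1e-12.
- The bucket and all simulator state are double precision; the water
  mass balance closes to 1e-9 mm over clip-free intervals (tested).
- Bootstrap and permutation procedures, the optimizer, and the generator
  all take explicit seeds; identical seeds give byte-identical outputs.
- Chronology years with no series are absent (not NaN); sample depth is
  recorded in both radii and trees.

## Known limitations

- The growth model omits the cambial/tracheid submodel; it cannot produce
  absolute growth or intra-ring density structure.
- Correlation-based calibration identifies parameters only up to the
  features the annual index is sensitive to; several of the 18 parameters
  (e.g. snow parameters in a mild climate) are weakly identified, and
  recovery is assessed on predictive skill (calibration/verification r),
  not parameter-wise error.
- The moving-correlation display performs no multiplicity correction, by
  design; isolated significant windows should be read accordingly.
- The GAM machinery is a deliberate small penalized-regression engine;
  it does not implement REML smoothing selection, smooth interactions
  beyond one tensor term, or non-Gaussian families.
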