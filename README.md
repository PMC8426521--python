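# dendrovigor

Dendroecological analysis of drought-driven forest dieback for conifer
stands with contrasting crown vigor. The package was built around a common
field situation: within one stand, some trees are declining (D, heavily
defoliated crowns) while their neighbours are not (ND), and the question is
whether the two groups differ in growth, in drought response, and in what
climatically limits their wood formation. It provides, as a single tested
Python library with a CLI:

- **Climate preparation** — FAO-56 Penman-Monteith reference
  evapotranspiration ET₀ (full-data and reduced-data pathways), the
  climatic water balance P − PET at monthly/seasonal/annual resolution,
  Mann-Kendall trend tests (τ, Sen slope), and standardized drought
  anomalies with one-sided α = 0.05 / 0.01 thresholds.
- **Tree-ring chronologies** — Tucson `.rwl` I/O, ratio detrending against
  Friedman's super smoother, AIC-selected autoregressive prewhitening,
  Tukey biweight robust mean chronologies (standard and residual
  variants), and replication statistics: mean sensitivity
  MS = mean 2|xₜ−xₜ₋₁|/(xₜ+xₜ₋₁), first-order autocorrelation,
  leave-one-out correlation with the mean series, and running rbar / EPS
  with EPS = N·rbar / (1 + (N−1)·rbar) over 20-year windows.
- **Disturbance analysis** — pointer years from window-standardized
  (Cropper) deviations (7-year window, ±0.75 deviation, 75% of trees),
  and drought resilience components over 3-year flanks: resistance
  Rt = Dr/PreDr, recovery Rc = PostDr/Dr, resilience Rs = PostDr/PreDr,
  compared between vigor groups with Mann-Whitney tests.
- **Climate-growth coupling** — bootstrapped Pearson correlations of a
  residual chronology with monthly Tx, Tn and P − PET from the previous
  September to the current September, and 30-year moving windows shifted
  annually to expose non-stationary coupling.
- **A process-based daily growth model** in the Vaganov-Shashkin
  tradition: daily growth rate Gr = gE · min(gT, gW), with trapezoidal
  temperature (T1..T4) and soil-moisture (W1..W4) modifiers, normalized
  day length gE, a leaky-bucket soil-moisture store (snow, infiltration,
  growth-coupled transpiration, drainage), temperature-sum phenology, and
  18 parameters calibrated by seeded differential evolution against an
  observed chronology on one period (default 1930–1969) and verified on a
  held-out period (1970–2019). Each active day is classified as
  temperature-limited (gT < gW), moisture-limited (gW < gT) or optimal
  (gT = gW = 1).
- **Smooth seasonal models** of the simulated daily growth rates:
  penalized cyclic-spline curves per vigor class with year random
  intercepts and AR(1) residuals, and a tensor-product
  day-of-year × spring-water-balance surface whose interaction is tested
  by a year-level permutation test.
- **A seeded synthetic-data generator** that emulates the study system —
  continental-Mediterranean daily climate (≈12 °C, ≈423 mm with spring
  and autumn maxima and summer drought, optional drying trend) and two
  vigor classes of pseudo-trees sharing a known growth signal with a
  configurable post-divergence decline — so the entire pipeline is
  testable with recorded ground truth.

## Worked example

```python
import numpy as np
from dendrovigor import chronology as chron, climate as cl, vs_model as vs
from dendrovigor.synthetic_data import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(seed=42, drying_trend=-0.3))

pet = cl.penman_monteith_pet(ds.climate)
wb = cl.water_balance(ds.climate, pet, "year")
trend = cl.mann_kendall_trend(wb["balance"].to_numpy())
print(f"mean annual P-PET: {wb['balance'].mean():.0f} mm "
      f"(tau = {trend.tau:.2f}, p = {trend.p_value:.1e})")

nd = [s for s in ds.rings if s.vigor == "ND"]
std, res, det, pw = chron.build_group_chronologies(nd, vigor="ND")
rb = chron.running_rbar_eps(det)
print(f"ND chronology: {len(nd)} radii, rbar = {np.nanmean(rb['rbar']):.2f}, "
      f"max EPS = {np.nanmax(rb['eps']):.2f}")

fit = vs.calibrate(ds.climate, std.as_series(), calib_period=(1930, 1969), seed=1)
fit = vs.verify(fit, ds.climate, std.as_series(), verif_period=(1970, 2019))
print(f"VS calibration r = {fit.r_calibration:.2f}, "
      f"verification r = {fit.r_verification:.2f}")

sim = vs.simulate(ds.climate, fit.params)
out = vs.limitation_summary(sim, (1970, 1989), (2000, 2019))
fa, fb = out["A"]["class_fractions"], out["B"]["class_fractions"]
print(f"moisture-limited fraction of active days: "
      f"{fa.get('moisture', 0):.2f} (1970-89) -> {fb.get('moisture', 0):.2f} (2000-19)")
```

Output:

```
mean annual P-PET: -648 mm (tau = -0.40, p = 4.1e-09)
ND chronology: 30 radii, rbar = 0.51, max EPS = 0.97
VS calibration r = 0.93, verification r = 0.93
moisture-limited fraction of active days: 0.70 (1970-89) -> 0.72 (2000-19)
```

Read: this drying-scenario stand sits in a strongly negative water-balance
regime with a significant drying trend; fifteen trees (two radii each)
yield a well-replicated chronology (EPS above the conventional 0.85
threshold); the calibrated growth model transfers to the held-out half of
the record (verification r ≈ 0.9 on synthetic data, where the generating
model family is known); and soil moisture, not temperature, limits most of
the growing season, increasingly so in the recent dry-warm decades.

The same analysis runs from the shell:

```bash
dendrovigor simulate-data --outdir fixture --seed 42
dendrovigor run-all --config run.yml    # paths + options in YAML
```

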