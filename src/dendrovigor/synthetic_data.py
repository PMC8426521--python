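"""Seeded synthetic climate and pseudo tree-ring data with known ground truth.

No station record or core measurements were deposited with the study this
pipeline emulates, so every stage is exercised against generated data whose
truth is recorded. The default configuration mimics a continental
Mediterranean regime: mean annual temperature ≈ 12 °C with a strong
seasonal cycle, ≈ 423 mm annual precipitation with spring and autumn maxima
and a summer drought, and two vigor classes of trees (non-declining ND,
declining D) sharing a common climate-driven growth signal, with D trees
ramping into a growth decline after a configurable divergence year.

The common signal itself is produced by the process growth model
(:mod:`dendrovigor.vs_model`) under a known parameter set, so calibration
is a well-posed parameter-recovery experiment; an optional "mismatch"
parameter set generates the signal from a different model member to probe
robustness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import DailyClimateSeries
from .rwl import RingWidthSeries, write_rwl
from .vs_model import VSParameters, simulate

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_daily_climate",
    "generate_tree_rings",
    "generate_dataset",
    "make_fixture",
    "MONTHLY_PRECIP_MM",
]

# monthly precipitation normals (mm) summing to 423, spring maximum in May,
# secondary autumn maximum in October, June-onset summer drought
MONTHLY_PRECIP_MM = {1: 25.0, 2: 25.0, 3: 30.0, 4: 45.0, 5: 55.0, 6: 35.0,
                     7: 15.0, 8: 20.0, 9: 35.0, 10: 50.0, 11: 45.0, 12: 43.0}

# stationary wet-day probability per month (two-state Markov occurrence)
MONTHLY_WET_PROB = {1: 0.25, 2: 0.25, 3: 0.26, 4: 0.32, 5: 0.34, 6: 0.22,
                    7: 0.10, 8: 0.12, 9: 0.22, 10: 0.30, 11: 0.28, 12: 0.28}


@dataclass
class SyntheticConfig:
    start_year: int = 1920
    end_year: int = 2019
    latitude: float = 41.1
    elevation: float = 800.0
    # temperature model
    annual_mean_temp: float = 12.0
    seasonal_amplitude: float = 9.5
    temp_peak_doy: int = 205
    temp_ar1: float = 0.7
    temp_noise_sd: float = 2.0       # innovation sd, °C
    diurnal_range_mean: float = 11.0
    diurnal_range_amplitude: float = 3.0
    warming_trend: float = 0.0       # °C per century
    # precipitation model
    annual_precip: float = 423.0
    gamma_shape: float = 0.8
    wet_persistence: float = 0.35    # added to the wet-day prob when wet
    drying_trend: float = 0.0        # fractional precip change per century (<0 dries)
    # stand design
    n_trees_per_class: int = 15
    n_radii: int = 2
    signal_scale: float = 0.25       # index units per signal z-score
    noise_sd: float = 0.2            # lognormal sigma of per-tree noise
    radius_noise_sd: float = 0.05
    divergence_year: int = 1995
    divergence_rate: float = 0.02    # fractional decline per year for D trees
    decline_floor: float = 0.3
    # optional constructed drought event: all trees' ring width in this year
    # is multiplied by the severity factor (a known pointer-year ground truth)
    drought_year: int | None = None
    drought_severity: float = 0.5
    tree_start_jitter: int = 10      # max years a tree's record starts late
    defoliation_noise_sd: float = 12.0
    # generating growth model
    true_params: VSParameters = field(default_factory=VSParameters)
    mismatch_params: VSParameters | None = None
    seed: int = 20201

    def __post_init__(self) -> None:
        if not (self.start_year <= self.divergence_year <= self.end_year):
            raise ValueError("divergence year outside simulated span")
        for name in ("temp_noise_sd", "noise_sd", "radius_noise_sd",
                     "defoliation_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticDataset:
    climate: DailyClimateSeries
    rings: list[RingWidthSeries]
    metadata: pd.DataFrame  # one row per tree: tree_id, site, vigor, defoliation, dbh
    truth: dict


def generate_daily_climate(config: SyntheticConfig, seed: int | None = None
                           ) -> DailyClimateSeries:
    """Daily Tm/Tx/Tn and precipitation for the configured span.

    Tm = seasonal sinusoid + AR(1) noise + optional linear warming;
    Tx/Tn = Tm ± half a seasonally varying diurnal range; precipitation from
    a monthly two-state Markov occurrence chain with gamma amounts whose
    monthly means follow the bimodal Mediterranean climatology.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dates = pd.date_range(f"{config.start_year}-01-01",
                          f"{config.end_year}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)
    years_frac = (dates.year.to_numpy() - config.start_year
                  + doy / 365.25) / 100.0

    seasonal = config.annual_mean_temp + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.temp_peak_doy) / 365.25)
    noise = np.empty(n)
    e = rng.standard_normal(n) * config.temp_noise_sd
    prev = 0.0
    phi = config.temp_ar1
    for i in range(n):
        prev = phi * prev + e[i]
        noise[i] = prev
    tm = seasonal + noise + config.warming_trend * years_frac
    drange = (config.diurnal_range_mean + config.diurnal_range_amplitude
              * np.cos(2 * np.pi * (doy - config.temp_peak_doy) / 365.25))
    tx = tm + drange / 2.0
    tn = tm - drange / 2.0

    month = dates.month.to_numpy()
    dim = dates.days_in_month.to_numpy(float)
    precip_factor = config.annual_precip / 423.0
    pw = np.array([MONTHLY_WET_PROB[m] for m in month])
    mean_mm = np.array([MONTHLY_PRECIP_MM[m] for m in month]) * precip_factor
    mean_mm = mean_mm * (1.0 + config.drying_trend * years_frac)
    mean_mm = np.maximum(mean_mm, 0.0)
    # Markov occurrence: p11 = pw + persistence, p01 chosen to keep the
    # stationary wet probability at pw
    p11 = np.minimum(pw + config.wet_persistence, 0.95)
    p01 = np.clip(pw * (1.0 - p11) / (1.0 - pw), 0.0, 1.0)
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    prev_wet = False
    for i in range(n):
        p = p11[i] if prev_wet else p01[i]
        prev_wet = u[i] < p
        wet[i] = prev_wet
    # gamma amounts: per-wet-day mean = monthly mean / (pw * days in month)
    wet_day_mean = mean_mm / np.maximum(pw * dim, 1e-9)
    scale = wet_day_mean / config.gamma_shape
    amounts = rng.gamma(config.gamma_shape, 1.0, size=n) * scale
    prec = np.where(wet, amounts, 0.0)

    df = pd.DataFrame({"tx": tx, "tn": tn, "tm": tm, "prec": prec},
                      index=pd.DatetimeIndex(dates, name="date"))
    return DailyClimateSeries(df, latitude=config.latitude,
                              elevation=config.elevation)


def _negexp_age_trend(n_years: int, a: float, b: float, c: float) -> np.ndarray:
    t = np.arange(n_years, dtype=float)
    return a * np.exp(-b * t) + c


def generate_tree_rings(clim: DailyClimateSeries, config: SyntheticConfig,
                        seed: int | None = None
                        ) -> tuple[list[RingWidthSeries], pd.DataFrame, dict]:
    """Pseudo ring-width series for an ND and a D vigor class, plus truth.

    Per-tree ring width = negative-exponential age trend × (1 + scale ×
    common signal z) × lognormal noise; D trees additionally ramp down after
    the divergence year. Defoliation is drawn inversely to the mean ring
    width of the last five years. Each tree contributes ``n_radii`` measured
    radii with within-tree noise.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    signal_params = config.mismatch_params or config.true_params
    sim = simulate(clim, signal_params)
    ann = sim.annual
    z = (ann - ann.mean()) / ann.std(ddof=1)
    years = z.index.to_numpy()
    nyears = len(years)

    rings: list[RingWidthSeries] = []
    meta_rows = []
    truth_trees = {}
    site = "SYN"
    for vigor, prefix in (("ND", "N"), ("D", "D")):
        for t in range(config.n_trees_per_class):
            tree_id = f"{prefix}{t + 1:02d}"
            a = rng.uniform(1.5, 3.0)
            b = rng.uniform(0.005, 0.02)
            c = rng.uniform(0.3, 0.8)
            start_off = int(rng.integers(0, config.tree_start_jitter + 1))
            ny = nyears - start_off
            age = _negexp_age_trend(ny, a, b, c)
            zs = z.to_numpy()[start_off:]
            base = age * np.maximum(1.0 + config.signal_scale * zs, 0.05)
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=ny))
            width = base * noise
            if vigor == "D":
                yrs = years[start_off:]
                ramp = np.ones(ny)
                after = yrs > config.divergence_year
                ramp[after] = np.maximum(
                    1.0 - config.divergence_rate * (yrs[after] - config.divergence_year),
                    config.decline_floor)
                width = width * ramp
            if config.drought_year is not None:
                width[years[start_off:] == config.drought_year] *= \
                    config.drought_severity
            width = np.maximum(width, 0.01)
            recent = float(np.mean(width[-5:]))
            truth_trees[tree_id] = {"age_a": a, "age_b": b, "age_c": c,
                                    "start_year": int(years[start_off]),
                                    "vigor": vigor}
            for r in range(config.n_radii):
                rnoise = np.exp(rng.normal(0.0, config.radius_noise_sd, size=ny))
                rings.append(RingWidthSeries(
                    series_id=f"{site}{tree_id}{chr(ord('A') + r)}",
                    first_year=int(years[start_off]),
                    widths=np.maximum(width * rnoise, 0.001),
                    tree_id=tree_id, site=site, vigor=vigor))
            meta_rows.append({"tree_id": tree_id, "site": site, "vigor": vigor,
                              "recent_rw": recent,
                              "dbh": float(rng.normal(30 if vigor == "ND" else 25, 4))})
    meta = pd.DataFrame(meta_rows)
    # defoliation inversely related to recent growth (rank-based with noise)
    rw = meta["recent_rw"].to_numpy()
    rel = (rw - rw.min()) / max(rw.max() - rw.min(), 1e-9)
    defol = 90.0 * (1.0 - rel) + rng.normal(0.0, config.defoliation_noise_sd,
                                            size=len(meta))
    meta["defoliation"] = np.clip(defol, 0.0, 100.0)
    truth = {
        "true_params": config.true_params.to_dict(),
        "signal_params": signal_params.to_dict(),
        "signal_years": [int(y) for y in years],
        "signal_z": [float(v) for v in z],
        "divergence_year": config.divergence_year,
        "divergence_rate": config.divergence_rate,
        "drought_year": config.drought_year,
        "drought_severity": config.drought_severity,
        "trees": truth_trees,
        "seed": config.seed if seed is None else seed,
    }
    return rings, meta, truth


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Climate + rings + metadata + truth from one master seed."""
    config = config or SyntheticConfig()
    base = config.seed if seed is None else seed
    clim = generate_daily_climate(config, seed=base)
    rings, meta, truth = generate_tree_rings(clim, config, seed=base)
    return SyntheticDataset(climate=clim, rings=rings, metadata=meta,
                            truth=truth)


def make_fixture(config: SyntheticConfig, outdir) -> dict:
    """Write the dataset to disk (climate CSV, .rwl, metadata CSV, truth
    JSON) together with a manifest of sha256 hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config)
    clim_path = outdir / "climate.csv"
    cdf = ds.climate.data.reset_index()
    cdf["date"] = cdf["date"].dt.strftime("%Y-%m-%d")
    cdf.to_csv(clim_path, index=False, float_format="%.3f")
    rwl_path = outdir / "rings.rwl"
    write_rwl(ds.rings, rwl_path)
    meta_path = outdir / "metadata.csv"
    ds.metadata.to_csv(meta_path, index=False, float_format="%.3f")
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(ds.truth, indent=1, sort_keys=True))
    manifest = {}
    for p in (clim_path, rwl_path, meta_path, truth_path):
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    # config echo for provenance
    cfg = asdict(config)
    cfg["true_params"] = config.true_params.to_dict()
    cfg["mismatch_params"] = (config.mismatch_params.to_dict()
                              if config.mismatch_params else None)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
    return manifest
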