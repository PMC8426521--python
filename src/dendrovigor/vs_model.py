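"""Process-based daily radial-growth simulator in the Vaganov-Shashkin
tradition, with split-period calibration and growth-limitation diagnostics.

The model computes, for every day, partial growth rates due to temperature
(gT, a trapezoid over four temperature knots T1..T4) and soil moisture (gW,
a trapezoid over volumetric-moisture knots W1..W4), modulates their minimum
by relative insolation gE (normalized day length, or measured radiation),
and integrates the daily growth rate Gr = gE·min(gT, gW) into an annual
ring-width index. Soil moisture follows a single-layer leaky bucket driven
by rain/snowmelt infiltration, growth-coupled transpiration and linear
drainage. Growth starts once the accumulated temperature sum reaches Tbeg
and each active day is classified by its binding constraint
(temperature-limited when gT < gW, moisture-limited when gW < gT, optimal
when gT = gW = 1).

The 18 calibratable parameters are T1..T4, W1..W4, Wcap, W0, k1, Pmax, k2,
k3, Tbeg, Tsnow, ksm and Droot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VSParameters",
    "VSSimulation",
    "CalibrationResult",
    "growth_modifier_temperature",
    "growth_modifier_moisture",
    "solar_modifier",
    "soil_moisture_step",
    "simulate",
    "annual_growth_index",
    "calibrate",
    "verify",
    "limitation_summary",
    "DEFAULT_BOUNDS",
    "CLASS_LABELS",
]

CLASS_LABELS = {0: "dormant", 1: "temperature", 2: "moisture",
                3: "optimal", 4: "co-limited"}


@dataclass
class VSParameters:
    """The 18-parameter set of the daily growth model.

    Temperature knots (°C): growth is zero at/below t1 and at/above t4,
    rises linearly to 1 between t1 and t2, stays at 1 on [t2, t3].
    Moisture knots (volumetric, v/v) mirror this over w1..w4.
    wcap: bucket capacity (v/v); w0: initial moisture (v/v);
    k1: infiltration fraction of throughfall (0-1); pmax: max daily
    infiltration (mm); k2: transpiration per unit growth rate (mm/day);
    k3: drainage rate (1/day); tbeg: temperature sum (°C·day) starting
    growth; tsnow: rain/snow threshold (°C); ksm: degree-day snowmelt
    coefficient (mm/°C/day); droot: rooting depth (mm).
    """

    t1: float = 4.0
    t2: float = 14.0
    t3: float = 22.0
    t4: float = 32.0
    w1: float = 0.02
    w2: float = 0.12
    w3: float = 0.25
    w4: float = 0.35
    wcap: float = 0.40
    w0: float = 0.25
    k1: float = 0.8
    pmax: float = 20.0
    k2: float = 2.5
    k3: float = 0.005
    tbeg: float = 100.0
    tsnow: float = 0.0
    ksm: float = 3.0
    droot: float = 500.0

    def __post_init__(self) -> None:
        if not (self.t1 < self.t2 <= self.t3 < self.t4):
            raise ValueError("temperature knots must satisfy T1 < T2 <= T3 < T4")
        if not (self.w1 < self.w2 <= self.w3 < self.w4 <= self.wcap):
            raise ValueError("moisture knots must satisfy W1 < W2 <= W3 < W4 <= Wcap")
        if not (0.0 <= self.k1 <= 1.0):
            raise ValueError("k1 must be in [0, 1]")
        if not (0.0 <= self.w0 <= self.wcap):
            raise ValueError("W0 must be in [0, Wcap]")
        for name in ("pmax", "k2", "k3", "ksm", "droot", "tbeg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_vector(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3, self.t4,
                         self.w1, self.w2, self.w3, self.w4,
                         self.wcap, self.w0, self.k1, self.pmax, self.k2,
                         self.k3, self.tbeg, self.tsnow, self.ksm, self.droot])

    def to_dict(self) -> dict:
        return asdict(self)


def _trapezoid(x, k1, k2, k3, k4):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    rising = (x > k1) & (x < k2)
    out[rising] = (x[rising] - k1) / (k2 - k1)
    out[(x >= k2) & (x <= k3)] = 1.0
    falling = (x > k3) & (x < k4)
    out[falling] = (k4 - x[falling]) / (k4 - k3)
    return out


def growth_modifier_temperature(tm, params: VSParameters):
    """Trapezoidal temperature modifier gT in [0, 1]."""
    return _trapezoid(tm, params.t1, params.t2, params.t3, params.t4)


def growth_modifier_moisture(w, params: VSParameters):
    """Trapezoidal soil-moisture modifier gW in [0, 1]."""
    return _trapezoid(w, params.w1, params.w2, params.w3, params.w4)


def day_length_hours(doy, latitude: float):
    """Astronomical day length (hours) from solar declination geometry."""
    doy = np.asarray(doy, dtype=float)
    phi = math.radians(latitude)
    delta = 0.409 * np.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = np.clip(-math.tan(phi) * np.tan(delta), -1.0, 1.0)
    return 24.0 / math.pi * np.arccos(x)


def solar_modifier(doy, latitude: float):
    """Relative insolation gE: day length normalized by its annual maximum."""
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes are not supported")
    dl = day_length_hours(doy, latitude)
    dl_max = day_length_hours(np.arange(1, 366), latitude).max()
    return dl / dl_max


def soil_moisture_step(w: float, snowpack: float, p: float, tm: float,
                       gr_prev: float, params: VSParameters):
    """One daily leaky-bucket update.

    Precipitation falls as snow when Tm ≤ Tsnow; melt follows a degree-day
    rule. Infiltration is the k1 fraction of rain + melt, capped at Pmax;
    transpiration is k2·Gr of the previous day; drainage is k3·W·Droot.
    Returns (W', snowpack', infiltration, transpiration, drainage, clipped).
    """
    if tm <= params.tsnow:
        rain, snowfall = 0.0, p
        melt = 0.0
    else:
        rain, snowfall = p, 0.0
        melt = min(snowpack, params.ksm * (tm - params.tsnow))
    snowpack = snowpack + snowfall - melt
    infil = min(params.k1 * (rain + melt), params.pmax)
    transp = params.k2 * gr_prev
    drain = params.k3 * w * params.droot
    w_new = w + (infil - transp - drain) / params.droot
    clipped = w_new < 0.0 or w_new > params.wcap
    w_new = min(max(w_new, 0.0), params.wcap)
    return w_new, snowpack, infil, transp, drain, clipped


# ---------------------------------------------------------------------------
# daily simulation core (numba-jitted when available)
# ---------------------------------------------------------------------------

def _core(tm, prec, ge, doy, year_id,
          t1, t2, t3, t4, w1, w2, w3, w4, wcap, w0, k1, pmax, k2, k3,
          tbeg, tsnow, ksm, droot):
    n = tm.shape[0]
    w_arr = np.empty(n)
    snow_arr = np.empty(n)
    gt_arr = np.empty(n)
    gw_arr = np.empty(n)
    gr_arr = np.empty(n)
    cls_arr = np.zeros(n, dtype=np.int8)
    active_arr = np.zeros(n, dtype=np.bool_)
    w = w0
    snow = 0.0
    gr_prev = 0.0
    tsum = 0.0
    terminated = False
    zero_run = 0
    cur_year = -1
    for i in range(n):
        if year_id[i] != cur_year:
            cur_year = year_id[i]
            tsum = 0.0
            terminated = False
            zero_run = 0
        t = tm[i]
        # temperature modifier
        if t <= t1 or t >= t4:
            gt = 0.0
        elif t < t2:
            gt = (t - t1) / (t2 - t1)
        elif t <= t3:
            gt = 1.0
        else:
            gt = (t4 - t) / (t4 - t3)
        # bucket update
        p = prec[i]
        if t <= tsnow:
            rain = 0.0
            snow += p
            melt = 0.0
        else:
            rain = p
            melt = min(snow, ksm * (t - tsnow))
            snow -= melt
        infil = min(k1 * (rain + melt), pmax)
        transp = k2 * gr_prev
        drain = k3 * w * droot
        w = w + (infil - transp - drain) / droot
        if w < 0.0:
            w = 0.0
        elif w > wcap:
            w = wcap
        # moisture modifier
        if w <= w1 or w >= w4:
            gw = 0.0
        elif w < w2:
            gw = (w - w1) / (w2 - w1)
        elif w <= w3:
            gw = 1.0
        else:
            gw = (w4 - w) / (w4 - w3)
        # phenology
        if t > 0.0:
            tsum += t
        if doy[i] > 182:
            if gt == 0.0:
                zero_run += 1
                if zero_run >= 10:
                    terminated = True
            else:
                zero_run = 0
        active = (tsum >= tbeg) and (not terminated)
        if active:
            m = gt if gt < gw else gw
            gr = ge[i] * m
            if gt < gw:
                cls = 1
            elif gw < gt:
                cls = 2
            elif gt == 1.0:
                cls = 3
            else:
                cls = 4
        else:
            gr = 0.0
            cls = 0
        w_arr[i] = w
        snow_arr[i] = snow
        gt_arr[i] = gt
        gw_arr[i] = gw
        gr_arr[i] = gr
        cls_arr[i] = cls
        active_arr[i] = active
        gr_prev = gr
    return w_arr, snow_arr, gt_arr, gw_arr, gr_arr, cls_arr, active_arr


try:  # pragma: no cover - exercised implicitly
    import numba

    _core_fast = numba.njit(cache=False)(_core)
except Exception:  # pragma: no cover
    _core_fast = _core


@dataclass
class VSSimulation:
    daily: pd.DataFrame
    annual: pd.Series  # raw annual index sum(Gr)
    params: VSParameters

    @property
    def years(self) -> np.ndarray:
        return self.annual.index.to_numpy()


def _forcing_arrays(clim, use_radiation: bool = False):
    df = clim.data
    if df["tm"].isna().any() or df["prec"].isna().any():
        raise ValueError("climate record has gaps; fill before simulating")
    idx = df.index
    full = pd.date_range(idx[0], idx[-1], freq="D")
    if len(full) != len(idx):
        raise ValueError("climate record has missing days")
    tm = df["tm"].to_numpy(float)
    prec = df["prec"].to_numpy(float)
    doy = idx.dayofyear.to_numpy(np.int64)
    year = idx.year.to_numpy(np.int64)
    if use_radiation and "rs" in df.columns and df["rs"].notna().all():
        rs = df["rs"].to_numpy(float)
        ge = np.empty_like(rs)
        for y in np.unique(year):
            m = year == y
            mx = rs[m].max()
            ge[m] = rs[m] / mx if mx > 0 else 0.0
    else:
        ge = solar_modifier(doy, clim.latitude)
    return tm, prec, ge, doy, year


def simulate(clim, params: VSParameters, use_radiation: bool = False) -> VSSimulation:
    """Run the daily growth model over a complete climate record."""
    tm, prec, ge, doy, year = _forcing_arrays(clim, use_radiation)
    res = _core_fast(tm, prec, ge, doy, year, *params.to_vector())
    w, snow, gt, gw, gr, cls, active = res
    daily = pd.DataFrame({
        "w": w, "snowpack": snow, "gt": gt, "gw": gw, "gr": gr,
        "limitation": cls, "active": active, "doy": doy, "year": year,
    }, index=clim.data.index)
    annual = daily.groupby("year")["gr"].sum()
    annual.index.name = "year"
    return VSSimulation(daily=daily, annual=annual, params=params)


def annual_growth_index(sim: VSSimulation, period: tuple[int, int],
                        rescale_to: pd.Series | None = None) -> pd.Series:
    """Standardize the annual index (z-score over ``period``).

    With ``rescale_to`` the z-scores are affinely mapped to the observed
    chronology's mean and SD over the same period, which puts RMSE in
    observed index units (the correlation-based calibration leaves the
    simulated scale free).
    """
    y0, y1 = period
    sel = sim.annual.loc[(sim.annual.index >= y0) & (sim.annual.index <= y1)]
    if len(sel) < 10:
        raise ValueError("standardization period must contain >= 10 years")
    sd = sel.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate simulation: zero inter-annual variance")
    z = (sim.annual - sel.mean()) / sd
    if rescale_to is not None:
        obs = rescale_to.loc[(rescale_to.index >= y0) & (rescale_to.index <= y1)]
        z = z * obs.std(ddof=1) + obs.mean()
    return z


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

# optimizer search space, expressed as increments so knot ordering is
# enforced by construction:
# [t1, t2-t1, t3-t2, t4-t3, w1, w2-w1, w3-w2, w4-w3, wcap-w4, w0/wcap,
#  k1, pmax, k2, k3, tbeg, tsnow, ksm, droot]
DEFAULT_BOUNDS = [
    (-2.0, 8.0), (2.0, 14.0), (0.0, 12.0), (2.0, 14.0),
    (0.0, 0.08), (0.02, 0.2), (0.0, 0.2), (0.02, 0.25), (0.0, 0.15),
    (0.2, 1.0),
    (0.5, 1.0), (5.0, 50.0), (0.5, 6.0), (0.0, 0.02),
    (30.0, 300.0), (-3.0, 3.0), (0.5, 8.0), (200.0, 1000.0),
]


def vector_to_params(v: np.ndarray) -> VSParameters:
    """Map an increment-parameterized optimizer vector to VSParameters."""
    t1, dt2, dt3, dt4 = v[0], v[1], v[2], v[3]
    w1, dw2, dw3, dw4, dwcap, fw0 = v[4], v[5], v[6], v[7], v[8], v[9]
    wcap = w1 + dw2 + dw3 + dw4 + dwcap
    return VSParameters(
        t1=t1, t2=t1 + dt2, t3=t1 + dt2 + dt3, t4=t1 + dt2 + dt3 + dt4 + 1e-6,
        w1=w1, w2=w1 + dw2, w3=w1 + dw2 + dw3, w4=w1 + dw2 + dw3 + dw4,
        wcap=wcap + 1e-9, w0=fw0 * wcap,
        k1=v[10], pmax=v[11], k2=v[12], k3=v[13],
        tbeg=v[14], tsnow=v[15], ksm=v[16], droot=v[17])


@dataclass
class CalibrationResult:
    params: VSParameters
    r_calibration: float
    r_verification: float = float("nan")
    rmse_calibration: float = float("nan")
    rmse_verification: float = float("nan")
    calib_period: tuple[int, int] = (1930, 1969)
    verif_period: tuple[int, int] | None = None
    seed: int = 0
    trace: list = field(default_factory=list)
    converged: bool = True


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def calibrate(clim, observed: pd.Series, bounds=None,
              calib_period: tuple[int, int] = (1930, 1969), seed: int = 0,
              maxiter: int = 30, popsize: int = 6,
              use_radiation: bool = False) -> CalibrationResult:
    """Fit the 18 parameters by maximizing r(simulated, observed index).

    A seeded differential-evolution search over increment-parameterized
    bounds (knot order enforced by construction). ``observed`` is the
    standard (non-prewhitened) chronology indexed by year. Returns the best
    parameters with calibration r and RMSE (after affine rescaling to
    observed units); verification metrics are filled by :func:`verify`.
    """
    from scipy.optimize import differential_evolution

    bounds = bounds or DEFAULT_BOUNDS
    y0, y1 = calib_period
    # forcing restricted to the calibration window (no spin-up beyond W0)
    mask = (clim.data.index.year >= y0) & (clim.data.index.year <= y1)
    sub = type(clim)(clim.data.loc[mask], latitude=clim.latitude,
                     elevation=clim.elevation)
    tm, prec, ge, doy, year = _forcing_arrays(sub, use_radiation)
    obs = observed.loc[(observed.index >= y0) & (observed.index <= y1)]
    obs_years = obs.index.to_numpy()
    uyears = np.unique(year)
    sel = np.isin(uyears, obs_years)
    obs_v = obs.loc[uyears[sel]].to_numpy(float)
    trace: list[float] = []

    def objective(v):
        try:
            p = vector_to_params(v)
        except ValueError:
            return 1.0
        res = _core_fast(tm, prec, ge, doy, year, *p.to_vector())
        gr = res[4]
        ann = np.zeros(len(uyears))
        np.add.at(ann, np.searchsorted(uyears, year), gr)
        r = _pearson(ann[sel], obs_v)
        if not np.isfinite(r):
            return 1.0
        return -r

    result = differential_evolution(
        objective, bounds, seed=seed, maxiter=maxiter, popsize=popsize,
        tol=1e-6, polish=False, updating="deferred", init="sobol",
        callback=lambda xk, convergence=0.0: trace.append(float(objective(xk))))
    best = vector_to_params(result.x)
    r_cal = -float(result.fun)
    converged = np.isfinite(r_cal) and r_cal > -1.0
    if not converged:
        logger.warning("calibration did not improve; returning best-so-far")
    # RMSE on calibration period after affine rescaling
    sim = simulate(clim, best, use_radiation)
    scaled = annual_growth_index(sim, calib_period, rescale_to=observed)
    common = np.intersect1d(scaled.index, obs_years)
    rmse = float(np.sqrt(np.mean((scaled.loc[common] - obs.loc[common]) ** 2)))
    return CalibrationResult(params=best, r_calibration=r_cal,
                             rmse_calibration=rmse, calib_period=calib_period,
                             seed=seed, trace=trace, converged=converged)


def verify(result: CalibrationResult, clim, observed: pd.Series,
           verif_period: tuple[int, int] = (1970, 2019),
           use_radiation: bool = False) -> CalibrationResult:
    """Held-out evaluation of a calibrated parameter set (no refitting)."""
    sim = simulate(clim, result.params, use_radiation)
    y0, y1 = verif_period
    scaled = annual_growth_index(sim, result.calib_period, rescale_to=observed)
    obs = observed.loc[(observed.index >= y0) & (observed.index <= y1)]
    common = np.intersect1d(scaled.index, obs.index)
    common = common[(common >= y0) & (common <= y1)]
    if len(common) < 3:
        raise ValueError("verification period has too few overlapping years")
    a = scaled.loc[common].to_numpy(float)
    b = obs.loc[common].to_numpy(float)
    result.r_verification = _pearson(a, b)
    result.rmse_verification = float(np.sqrt(np.mean((a - b) ** 2)))
    result.verif_period = verif_period
    return result


def limitation_summary(sim: VSSimulation, period_a: tuple[int, int],
                       period_b: tuple[int, int],
                       merge_colimited: bool = True) -> dict:
    """Limitation-class climatology for two periods.

    For each period: fractions of each class over active days, per-DOY class
    fractions, and per-DOY mean Gr/gT/gW/W profiles. Co-limited days
    (gT = gW < 1) are merged into the moisture class by default, so that
    exactly three classes (temperature / moisture / optimal) partition the
    active days.
    """
    out = {}
    for name, (y0, y1) in (("A", period_a), ("B", period_b)):
        d = sim.daily[(sim.daily["year"] >= y0) & (sim.daily["year"] <= y1)]
        if d.empty:
            raise ValueError(f"period {name} ({y0}-{y1}) not covered by simulation")
        act = d[d["active"]].copy()
        if merge_colimited:
            act.loc[act["limitation"] == 4, "limitation"] = 2
        labels = act["limitation"].map(CLASS_LABELS)
        frac = labels.value_counts(normalize=True).to_dict()
        by_doy = (pd.crosstab(act["doy"], labels, normalize="index")
                  if len(act) else pd.DataFrame())
        profiles = d.groupby("doy")[["gr", "gt", "gw", "w"]].mean()
        out[name] = {"period": (y0, y1), "class_fractions": frac,
                     "class_by_doy": by_doy, "profiles": profiles,
                     "n_active_days": int(len(act))}
    return out
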