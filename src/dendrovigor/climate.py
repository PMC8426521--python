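"""Daily station climate: reading, FAO-56 reference evapotranspiration, water
balance, seasonal aggregation, trends and standardized anomalies.

The climatic water balance P − PET (precipitation minus FAO-56 Penman-Monteith
reference evapotranspiration) is the central drought descriptor of the
pipeline; everything downstream (drought years, climate-growth correlations,
the soil-moisture forcing of the growth model) consumes the quantities
produced here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DailyClimateSeries",
    "TrendResult",
    "read_daily_climate",
    "penman_monteith_pet",
    "water_balance",
    "seasonal_summary",
    "mann_kendall_trend",
    "standardized_anomaly",
    "anomaly_thresholds",
]

SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

# one-sided standard-normal quantiles used for drought thresholds
Z_ONE_SIDED = {0.05: 1.6448536269514722, 0.01: 2.3263478740408408}


@dataclass
class DailyClimateSeries:
    """Validated daily climate record for one station.

    ``data`` holds columns ``tx``, ``tn``, ``tm`` (°C), ``prec`` (mm/day) and
    optionally ``rs`` (MJ m-2 day-1), ``u2`` (m/s), ``rh`` (%), indexed by a
    strictly increasing daily DatetimeIndex.
    """

    data: pd.DataFrame
    latitude: float
    elevation: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        idx = self.data.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("dates must be strictly increasing without duplicates")
        bad = self.data["tn"] > self.data["tx"]
        if bad.any():
            day = self.data.index[bad.to_numpy()][0]
            raise ValueError(f"Tn > Tx on {day.date()}")
        if (self.data["prec"] < 0).any():
            raise ValueError("negative precipitation")

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.data.index.year)

    def __len__(self) -> int:
        return len(self.data)


def read_daily_climate(path, latitude: float, elevation: float,
                       max_temp_gap: int = 5) -> DailyClimateSeries:
    """Read a daily climate CSV (columns date, tx, tn[, tm], prec, ...).

    Temperature gaps of at most ``max_temp_gap`` consecutive days are linearly
    interpolated (and flagged); longer gaps raise.  Missing precipitation is
    zero-filled with a warning.  A missing/empty ``tm`` column is recomputed
    as (tx + tn) / 2.
    """
    raw = pd.read_csv(path)
    raw.columns = [c.strip().lower() for c in raw.columns]
    required = {"date", "tx", "tn", "prec"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    try:
        dates = pd.to_datetime(raw["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in climate CSV: {exc}") from None
    df = raw.drop(columns=["date"]).set_index(pd.DatetimeIndex(dates, name="date"))
    df = df.apply(pd.to_numeric, errors="coerce")

    flags: list[str] = []
    for col in ("tx", "tn", "tm"):
        if col not in df.columns:
            continue
        isna = df[col].isna()
        if isna.any():
            # longest run of consecutive NaNs
            runs = isna.astype(int).groupby((~isna).cumsum()).sum()
            longest = int(runs.max())
            if col != "tm" and longest > max_temp_gap:
                row = int(np.argmax(isna.to_numpy())) + 2  # header + 1-based
                raise ValueError(
                    f"{col} gap of {longest} days (> {max_temp_gap}) near row {row}")
            if col != "tm" or isna.sum() < len(df):
                n = int(isna.sum())
                if col == "tm" and isna.all():
                    continue
                df[col] = df[col].interpolate(limit_area="inside")
                flags.append(f"interpolated {n} missing {col} values")
                logger.info("climate read: interpolated %d missing %s values", n, col)
    if "tm" not in df.columns or df["tm"].isna().all():
        df["tm"] = (df["tx"] + df["tn"]) / 2.0
        flags.append("tm derived as (tx+tn)/2")
    elif df["tm"].isna().any():
        df.loc[df["tm"].isna(), "tm"] = (df["tx"] + df["tn"]) / 2.0
    if df["prec"].isna().any():
        n = int(df["prec"].isna().sum())
        df["prec"] = df["prec"].fillna(0.0)
        flags.append(f"zero-filled {n} missing precipitation values")
        logger.warning("climate read: zero-filled %d missing precipitation values", n)
    bad = df["tn"] > df["tx"]
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 2
        raise ValueError(f"Tn > Tx at row {row}")
    return DailyClimateSeries(df, latitude=latitude, elevation=elevation, flags=flags)


# ---------------------------------------------------------------------------
# FAO-56 Penman-Monteith reference evapotranspiration
# ---------------------------------------------------------------------------

_GSC = 0.0820          # solar constant, MJ m-2 min-1
_SIGMA = 4.903e-9      # Stefan-Boltzmann, MJ K-4 m-2 day-1
_ALBEDO = 0.23
_KRS_INTERIOR = 0.16   # Hargreaves radiation coefficient, interior locations


def _sat_vp(t: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure e0(T), kPa."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def extraterrestrial_radiation(doy: np.ndarray, latitude: float) -> np.ndarray:
    """Daily extraterrestrial radiation Ra, MJ m-2 day-1."""
    phi = math.radians(latitude)
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = np.clip(-math.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / math.pi) * _GSC * dr * (
        ws * math.sin(phi) * np.sin(delta)
        + math.cos(phi) * np.cos(delta) * np.sin(ws))
    return np.maximum(ra, 0.0)


def penman_monteith_pet(clim: DailyClimateSeries) -> pd.Series:
    """Daily FAO-56 Penman-Monteith reference evapotranspiration ET0, mm/day.

    When radiation, wind or humidity are absent the FAO-56 reduced-data
    procedure is used: Rs from extraterrestrial radiation and sqrt(Tx−Tn)
    with the interior coefficient 0.16, actual vapour pressure from Tn as
    the dewpoint, wind speed 2 m/s, and soil heat flux G = 0 at daily step.
    """
    df = clim.data
    if clim.latitude is None or clim.elevation is None:
        raise ValueError("latitude and elevation are required for PET")
    tx = df["tx"].to_numpy(float)
    tn = df["tn"].to_numpy(float)
    tm = df["tm"].to_numpy(float)
    if np.any(tx - tn < 0):
        raise ValueError("Tx - Tn < 0: inconsistent temperature range")
    doy = df.index.dayofyear.to_numpy()

    delta = 4098.0 * _sat_vp(tm) / (tm + 237.3) ** 2
    patm = 101.3 * ((293.0 - 0.0065 * clim.elevation) / 293.0) ** 5.26
    gamma = 0.000665 * patm

    es = (_sat_vp(tx) + _sat_vp(tn)) / 2.0
    if "rh" in df.columns and df["rh"].notna().all():
        ea = df["rh"].to_numpy(float) / 100.0 * es
    else:
        ea = _sat_vp(tn)
    ea = np.minimum(ea, es)

    ra = extraterrestrial_radiation(doy, clim.latitude)
    if "rs" in df.columns and df["rs"].notna().all():
        rs = df["rs"].to_numpy(float)
    else:
        rs = _KRS_INTERIOR * np.sqrt(np.maximum(tx - tn, 0.0)) * ra
    rso = (0.75 + 2e-5 * clim.elevation) * ra
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0, np.clip(rs / np.where(rso > 0, rso, 1.0), 0.3, 1.0), 1.0)
    rns = (1.0 - _ALBEDO) * rs
    rnl = (_SIGMA * ((tx + 273.16) ** 4 + (tn + 273.16) ** 4) / 2.0
           * (0.34 - 0.14 * np.sqrt(ea)) * (1.35 * rel - 0.35))
    rn = rns - rnl

    u2 = (df["u2"].to_numpy(float) if "u2" in df.columns and df["u2"].notna().all()
          else np.full_like(tm, 2.0))
    g = 0.0
    et0 = ((0.408 * delta * (rn - g)
            + gamma * (900.0 / (tm + 273.0)) * u2 * (es - ea))
           / (delta + gamma * (1.0 + 0.34 * u2)))
    return pd.Series(np.maximum(et0, 0.0), index=df.index, name="pet")


# ---------------------------------------------------------------------------
# Water balance aggregation
# ---------------------------------------------------------------------------

def _season_year(index: pd.DatetimeIndex) -> pd.Series:
    """Growth-aligned season year: December of year y-1 belongs to winter of y."""
    year = index.year.to_numpy().copy()
    year[index.month.to_numpy() == 12] += 1
    return pd.Series(year, index=index)


def water_balance(clim: DailyClimateSeries, pet: pd.Series,
                  aggregation: str = "year") -> pd.DataFrame:
    """Aggregate P and PET to monthly / seasonal / annual sums; balance = P − PET.

    Incomplete terminal periods are excluded (with a warning in the log).
    Returns a tidy DataFrame with columns depending on aggregation:
    ``year`` (+ ``month`` or ``season``), ``p``, ``pet``, ``balance``.
    """
    if aggregation not in ("month", "season", "year"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    df = pd.DataFrame({"p": clim.data["prec"], "pet": pet})
    idx = df.index
    if aggregation == "month":
        keys = [idx.year, idx.month]
        names = ["year", "month"]
        ndays = pd.Series(idx.days_in_month, index=idx)
    elif aggregation == "year":
        keys = [idx.year]
        names = ["year"]
        ndays = pd.Series(np.where(idx.is_leap_year, 366, 365), index=idx)
    else:
        sy = _season_year(idx)
        seas = pd.Series([SEASON_OF_MONTH[m] for m in idx.month], index=idx)
        keys = [sy, seas]
        names = ["year", "season"]
        ndays = None
    grouped = df.groupby(keys)
    out = grouped.sum()
    out.index.names = names
    count = grouped.size()
    if ndays is not None:
        expected = ndays.groupby(keys).first()
        # a month/year is complete only when every calendar day is present
        full = count >= expected
    else:
        full = count >= 88  # shortest season (DJF non-leap = 90; allow leap edge)
    if (~full).any():
        logger.warning("water_balance: dropping %d incomplete %s period(s)",
                       int((~full).sum()), aggregation)
    out = out[full]
    out["balance"] = out["p"] - out["pet"]
    return out.reset_index()


def seasonal_summary(clim: DailyClimateSeries, pet: pd.Series | None = None) -> pd.DataFrame:
    """Seasonal mean temperatures and total precipitation (and balance if PET given).

    Seasons: winter = DJF (labelled by the Jan/Feb year), spring = MAM,
    summer = JJA, autumn = SON.
    """
    idx = clim.data.index
    sy = _season_year(idx)
    seas = pd.Series([SEASON_OF_MONTH[m] for m in idx.month], index=idx)
    g = clim.data.groupby([sy, seas])
    out = pd.DataFrame({
        "tm": g["tm"].mean(),
        "tx": g["tx"].mean(),
        "tn": g["tn"].mean(),
        "p": g["prec"].sum(),
    })
    count = g.size()
    out = out[count >= 88]
    out.index.names = ["year", "season"]
    out = out.reset_index()
    if pet is not None:
        wb = water_balance(clim, pet, "season")
        out = out.merge(wb[["year", "season", "pet", "balance"]],
                        on=["year", "season"], how="left")
    return out


# ---------------------------------------------------------------------------
# Trends and anomalies
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    tau: float
    s: int
    p_value: float
    sen_slope: float
    n: int


def mann_kendall_trend(x) -> TrendResult:
    """Mann-Kendall trend test with tie-corrected variance and Sen slope.

    S = sum over i<j of sign(x_j − x_i); tau uses the tie-corrected
    denominator; the p-value uses the normal approximation with continuity
    correction. The Sen slope is the median of pairwise slopes per unit index.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall requires at least 3 values")
    if n < 8:
        logger.warning("Mann-Kendall p-value unreliable for n=%d < 8", n)
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, 1).sum())
    # tie correction
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    n0 = n * (n - 1) / 2.0
    nt = (ties * (ties - 1) / 2.0).sum()
    denom = math.sqrt(n0 - nt) * math.sqrt(n0)
    tau = s / denom if denom > 0 else 0.0
    var_s = (n * (n - 1) * (2 * n + 5) - (ties * (ties - 1) * (2 * ties + 5)).sum()) / 18.0
    if var_s <= 0:
        p = 1.0
    else:
        if s > 0:
            z = (s - 1) / math.sqrt(var_s)
        elif s < 0:
            z = (s + 1) / math.sqrt(var_s)
        else:
            z = 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    slope = stats.theilslopes(x, np.arange(n)).slope if n >= 2 else float("nan")
    return TrendResult(tau=float(tau), s=s, p_value=float(p),
                       sen_slope=float(slope), n=n)


def standardized_anomaly(x, reference_mean: float, reference_sd: float):
    """z = (x − mean) / sd against a fixed reference climatology."""
    if reference_sd <= 0:
        raise ValueError("reference sd must be positive")
    return (np.asarray(x, dtype=float) - reference_mean) / reference_sd


def anomaly_thresholds(series, alphas=(0.05, 0.01)) -> dict[float, float]:
    """One-sided lower thresholds mean − z_alpha * sd for drought flagging.

    z_0.05 = 1.645 and z_0.01 = 2.326 mark balances significantly below the
    long-term mean at those levels.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd <= 0:
        raise ValueError("zero-variance reference series")
    out = {}
    for a in alphas:
        z = Z_ONE_SIDED.get(a, float(stats.norm.isf(a)))
        out[a] = mu - z * sd
    return out
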