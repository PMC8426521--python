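"""Bootstrapped and moving climate-growth correlations.

Monthly climate predictors (maximum/minimum temperature and the P − PET
water balance, plus arbitrary covariates such as an external soil-moisture
series) over a 13-month window from the previous September to the current
September are correlated with a residual ring-width chronology. Confidence
intervals come from a paired bootstrap over years; the moving variant
repeats the analysis in sliding multi-decade windows to expose
non-stationary coupling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "monthly_climate_table",
    "build_monthly_window",
    "bootstrap_correlations",
    "moving_correlations",
]

# previous September ... current September, relative to the growth year
WINDOW_MONTHS = [(-1, m) for m in range(9, 13)] + [(0, m) for m in range(1, 10)]

_MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec"]


def month_label(offset: int, month: int) -> str:
    lab = _MONTH_ABBR[month - 1]
    return f"{lab}_prev" if offset else lab


def monthly_climate_table(clim, pet: pd.Series) -> pd.DataFrame:
    """Monthly mean Tx/Tn and water balance, indexed by (year, month)."""
    idx = clim.data.index
    g = clim.data.groupby([idx.year, idx.month])
    out = pd.DataFrame({
        "tx": g["tx"].mean(),
        "tn": g["tn"].mean(),
    })
    bal = (clim.data["prec"] - pet).groupby([idx.year, idx.month]).sum()
    out["wb"] = bal
    out.index.names = ["year", "month"]
    return out


def build_monthly_window(monthly: pd.DataFrame, growth_years,
                         variables=("tx", "tn", "wb")) -> pd.DataFrame:
    """Predictor matrix: one row per growth year, one column per (variable, month).

    Months run from the previous September (suffixed ``_prev``) to the
    current September. Rows with any missing month are dropped with a
    warning.
    """
    growth_years = np.asarray(growth_years, dtype=int)
    cols = {}
    for var in variables:
        if var not in monthly.columns:
            raise ValueError(f"variable {var!r} absent from monthly table")
        wide = monthly[var].unstack("month")
        for offset, m in WINDOW_MONTHS:
            key = f"{var}_{month_label(offset, m)}"
            src_years = growth_years + offset
            if m not in wide.columns:
                raise ValueError(f"month {m} missing from monthly climate")
            vals = wide[m].reindex(src_years).to_numpy()
            cols[key] = vals
    mat = pd.DataFrame(cols, index=pd.Index(growth_years, name="year"))
    missing_rows = mat.isna().any(axis=1)
    if missing_rows.any():
        first_bad = mat.loc[missing_rows].isna().any()
        logger.warning("build_monthly_window: dropping %d year(s) with missing "
                       "months (%s)", int(missing_rows.sum()),
                       ", ".join(first_bad.index[first_bad][:3]))
        mat = mat.loc[~missing_rows]
    if mat.empty:
        raise ValueError("no growth year has complete monthly coverage")
    return mat


def _pearson_matrix(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson r of y against each column of x."""
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((yc ** 2).sum() * (xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, yc @ xc / denom, np.nan)


def bootstrap_correlations(chronology: pd.Series, matrix: pd.DataFrame,
                           nboot: int = 1000, seed: int = 0,
                           min_years: int = 30,
                           ci: tuple[float, float] = (2.5, 97.5),
                           holm: bool = False) -> pd.DataFrame:
    """Bootstrapped Pearson correlations of a chronology with each predictor.

    Years are resampled in pairs with replacement; the CI is the percentile
    interval over ``nboot`` resamples and a cell is significant when its CI
    excludes zero. Constant predictor columns are skipped with a warning.
    Deterministic under a fixed seed.
    """
    common = chronology.index.intersection(matrix.index)
    if len(common) < min_years:
        raise ValueError(f"only {len(common)} common years (< {min_years})")
    y = chronology.loc[common].to_numpy(dtype=float)
    x = matrix.loc[common]
    const = x.std(axis=0) == 0
    if const.any():
        logger.warning("bootstrap_correlations: skipping constant column(s): %s",
                       ", ".join(x.columns[const]))
        x = x.loc[:, ~const]
    xv = x.to_numpy(dtype=float)
    n = len(y)
    r = _pearson_matrix(y, xv)
    rng = np.random.default_rng(seed)
    boot = np.empty((nboot, xv.shape[1]))
    for b in range(nboot):
        ii = rng.integers(0, n, size=n)
        boot[b] = _pearson_matrix(y[ii], xv[ii])
    lo, hi = np.nanpercentile(boot, ci, axis=0)
    out = pd.DataFrame({"r": r, "ci_lower": lo, "ci_upper": hi},
                       index=x.columns)
    out["significant"] = (out["ci_lower"] > 0) | (out["ci_upper"] < 0)
    if holm:
        # Holm on bootstrap-z p approximations (off by default; the study
        # reports per-cell significance)
        from statsmodels.stats.multitest import multipletests
        se = boot.std(axis=0, ddof=1)
        z = np.where(se > 0, r / se, 0.0)
        from scipy import stats as sps
        p = 2 * sps.norm.sf(np.abs(z))
        out["significant"] = multipletests(p, alpha=0.05, method="holm")[0]
    out["n"] = n
    return out


def moving_correlations(chronology: pd.Series, matrix: pd.DataFrame,
                        window: int = 30, shift: int = 1, nboot: int = 500,
                        seed: int = 0) -> pd.DataFrame:
    """Bootstrapped correlations in sliding windows of fixed length.

    Returns a long DataFrame keyed by the first year of each window.
    Significance is per-window at the bootstrap CI level, with no
    multiplicity correction.
    """
    common = chronology.index.intersection(matrix.index).sort_values()
    if len(common) < window:
        raise ValueError(f"series length {len(common)} < window {window}")
    frames = []
    years = common.to_numpy()
    for start in range(0, len(years) - window + 1, shift):
        wyears = years[start:start + window]
        tab = bootstrap_correlations(chronology.loc[wyears],
                                     matrix.loc[wyears], nboot=nboot,
                                     seed=seed + start, min_years=window)
        tab = tab.reset_index(names="predictor")
        tab.insert(0, "start_year", int(wyears[0]))
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["window"] = window
    return out
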