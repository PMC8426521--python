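"""Pointer-year detection, drought resilience components and vigor-group tests.

Pointer years follow the normalized-deviation (Cropper) approach: each
tree's index is standardized within a moving window, and a calendar year is
flagged when a super-majority of trees exceed a common deviation threshold.
Resilience to specific drought events is quantified by the resistance /
recovery / resilience ratios over 3-year pre- and post-drought windows.
Group contrasts use the Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "cropper_values",
    "pointer_years",
    "resilience_components",
    "GroupComparison",
    "compare_groups",
    "vigor_growth_association",
    "DEFAULT_EVENT_YEARS",
]

# the four most severe droughts after the wet-cool 1970s at the study region
DEFAULT_EVENT_YEARS = (1983, 2001, 2009, 2015)


def cropper_values(rwi: pd.Series, window: int = 7) -> pd.Series:
    """Window-standardized growth deviations C_t = (x_t − μ_win) / σ_win.

    The window is centred on and includes the focal year; the first and last
    (window−1)/2 years are undefined (NaN), as are years whose window has
    zero variance.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x = rwi.to_numpy(dtype=float)
    n = len(x)
    if n < window:
        raise ValueError(f"series length {n} < window {window}")
    half = window // 2
    c = np.full(n, np.nan)
    for t in range(half, n - half):
        win = x[t - half: t + half + 1]
        sd = win.std(ddof=1)
        if sd > 0:
            c[t] = (x[t] - win.mean()) / sd
    return pd.Series(c, index=rwi.index, name="cropper")


def pointer_years(cropper_by_tree: pd.DataFrame, deviation: float = 0.75,
                  proportion: float = 0.75, min_trees: int = 4) -> pd.DataFrame:
    """Flag site-level pointer years from per-tree Cropper values.

    ``cropper_by_tree``: years × trees. A year is flagged negative when at
    least ``proportion`` of the trees with defined values fall below
    −``deviation`` (positive symmetrically). Years with fewer than
    ``min_trees`` defined values are not evaluated.
    """
    if cropper_by_tree.shape[1] < min_trees:
        raise ValueError(f"need at least {min_trees} trees")
    defined = cropper_by_tree.notna()
    n_def = defined.sum(axis=1)
    frac_neg = (cropper_by_tree < -deviation).sum(axis=1) / n_def.where(n_def > 0)
    frac_pos = (cropper_by_tree > deviation).sum(axis=1) / n_def.where(n_def > 0)
    flag = np.where(n_def < min_trees, "not_evaluated",
                    np.where(frac_neg >= proportion, "negative",
                             np.where(frac_pos >= proportion, "positive", "none")))
    return pd.DataFrame({
        "n_trees": n_def,
        "frac_negative": frac_neg,
        "frac_positive": frac_pos,
        "flag": flag,
    }, index=cropper_by_tree.index)


def resilience_components(rwi: pd.Series, event_year: int,
                          window: int = 3) -> dict[str, float] | None:
    """Resistance, recovery and resilience ratios around one drought year.

    With PreDr the mean index over [y−window, y−1], Dr the index in the
    event year and PostDr the mean over [y+1, y+window]:
    Rt = Dr/PreDr, Rc = PostDr/Dr, Rs = PostDr/PreDr (so Rs = Rt·Rc).
    Returns None (logged) when the flanking windows are incomplete.
    """
    years = rwi.index.to_numpy()
    pre_years = np.arange(event_year - window, event_year)
    post_years = np.arange(event_year + 1, event_year + window + 1)
    needed = np.concatenate([pre_years, [event_year], post_years])
    if not np.isin(needed, years).all():
        logger.info("resilience: event %d skipped (incomplete flanking years)",
                    event_year)
        return None
    sel = rwi.loc[needed]
    if sel.isna().any():
        logger.info("resilience: event %d skipped (missing values)", event_year)
        return None
    pre = float(rwi.loc[pre_years].mean())
    dr = float(rwi.loc[event_year])
    post = float(rwi.loc[post_years].mean())
    if pre <= 0 or dr <= 0:
        logger.info("resilience: event %d skipped (non-positive index)", event_year)
        return None
    return {"event_year": event_year, "resistance": dr / pre,
            "recovery": post / dr, "resilience": post / pre}


def resilience_table(rwi_by_tree: pd.DataFrame,
                     event_years=DEFAULT_EVENT_YEARS,
                     window: int = 3) -> pd.DataFrame:
    """Per tree × event resilience components as a tidy table."""
    rows = []
    for tree in rwi_by_tree.columns:
        series = rwi_by_tree[tree].dropna()
        for ev in event_years:
            res = resilience_components(series, ev, window)
            if res is not None:
                rows.append({"tree_id": tree, **res})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    u: float
    p_value: float
    median_1: float
    median_2: float
    n1: int
    n2: int


def compare_groups(values_1, values_2) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two groups.

    Exact enumeration when n1·n2 ≤ 400 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(values_1, dtype=float)
    b = np.asarray(values_2, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(u=float(res.statistic), p_value=float(res.pvalue),
                           median_1=float(np.median(a)), median_2=float(np.median(b)),
                           n1=len(a), n2=len(b))


def vigor_growth_association(recent_rw, defoliation) -> tuple[float, float]:
    """Spearman rank correlation between recent growth and crown defoliation.

    Defoliation is a visually binned percentage, so a rank correlation is
    used. Returns (rho, p).
    """
    x = np.asarray(recent_rw, dtype=float)
    y = np.asarray(defoliation, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise ValueError("need at least 5 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
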