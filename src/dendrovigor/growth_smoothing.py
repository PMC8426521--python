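"""Smooth seasonal models of simulated daily growth rates.

Two additive models over the simulator's daily output Gr:

* ``fit_doy_smooth_by_group`` — Gr ~ s(DOY) per vigor class + vigor offset
  + year random intercept, with AR(1) residual structure within years;
* ``fit_doy_wb_interaction`` — Gr ~ te(DOY, spring water balance), a
  tensor-product surface testing whether the seasonal growth curve changes
  with spring water availability, against the additive null.

Both are penalized-regression fits: cyclic cubic B-spline bases over DOY
(the season closes on itself), an ordinary B-spline basis over the water
balance, second-difference penalties, year intercepts shrunk by a ridge
penalty (the random effect), smoothing parameters chosen by GCV, and AR(1)
handled by within-year quasi-differencing (Cochrane-Orcutt). Reported
per-smooth edf counts the smooth's mean level plus the trace of its
effective-parameter block, matching the convention that a flat smooth has
edf 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = [
    "assemble_gr_dataset",
    "fit_doy_smooth_by_group",
    "fit_doy_wb_interaction",
    "SmoothFitResult",
    "InteractionFitResult",
    "cyclic_bspline_basis",
    "bspline_basis",
]


# ---------------------------------------------------------------------------
# spline bases and penalties
# ---------------------------------------------------------------------------

def cyclic_bspline_basis(x, k: int = 10, period: float = 366.0):
    """Cyclic cubic B-spline basis (k columns) and its circulant
    second-difference penalty."""
    x = np.mod(np.asarray(x, dtype=float), period)
    h = period / k
    knots = h * np.arange(-3, k + 4)
    dm = BSpline.design_matrix(x, knots, 3).toarray()  # k + 3 columns
    basis = dm[:, :k].copy()
    basis[:, :3] += dm[:, k:k + 3]  # periodic wrap of the last 3 splines
    d2 = np.zeros((k, k))
    for i in range(k):
        d2[i, i] = -2.0
        d2[i, (i - 1) % k] = 1.0
        d2[i, (i + 1) % k] = 1.0
    return basis, d2.T @ d2


def bspline_basis(x, k: int = 6, lo: float | None = None, hi: float | None = None):
    """Ordinary cubic B-spline basis (k columns) with a second-difference
    penalty; boundary knots padded so evaluation is defined on [lo, hi]."""
    x = np.asarray(x, dtype=float)
    lo = float(x.min()) if lo is None else lo
    hi = float(x.max()) if hi is None else hi
    if hi <= lo:
        raise ValueError("degenerate covariate range")
    inner = np.linspace(lo, hi, k - 2)
    h = inner[1] - inner[0]
    knots = np.concatenate([inner[0] - h * np.arange(3, 0, -1), inner,
                            inner[-1] + h * np.arange(1, 4)])
    basis = BSpline.design_matrix(np.clip(x, lo, hi), knots, 3).toarray()
    d = np.diff(np.eye(basis.shape[1]), n=2, axis=0)
    return basis, d.T @ d


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _sum_zero(k: int) -> np.ndarray:
    """Orthonormal basis of the coefficient-sum-to-zero subspace.

    B-spline bases are partitions of unity, so constraining coefficients to
    sum to zero removes exactly the constant function from a smooth,
    keeping it identifiable next to an intercept or group offset.
    """
    from scipy.linalg import null_space

    return null_space(np.ones((1, k)))  # k × (k-1)


def _constrain(basis: np.ndarray, penalty: np.ndarray, z: np.ndarray):
    return basis @ z, z.T @ penalty @ z


# ---------------------------------------------------------------------------
# penalized additive fitting machinery
# ---------------------------------------------------------------------------

class _Block:
    def __init__(self, name, mat, penalty=None, center=True):
        self.name = name
        self.center = center
        self.mean = mat.mean(axis=0) if center else np.zeros(mat.shape[1])
        self.mat = mat - self.mean
        self.penalty = penalty  # None → unpenalized


def _assemble(blocks):
    x = np.hstack([b.mat for b in blocks])
    slices, start = {}, 0
    for b in blocks:
        slices[b.name] = slice(start, start + b.mat.shape[1])
        start += b.mat.shape[1]
    return x, slices


def _fit_once(xtx, xty, yty, blocks, slices, lambdas):
    """Solve the penalized normal equations from precomputed cross-products."""
    p = xtx.shape[0]
    pen = np.zeros((p, p))
    for b in blocks:
        if b.penalty is not None:
            sl = slices[b.name]
            pen[sl, sl] += lambdas[b.name] * b.penalty
    a = xtx + pen + 1e-10 * np.eye(p)
    ainv = np.linalg.solve(a, np.eye(p))
    beta = ainv @ xty
    hdiag_blocks = {}
    m = ainv @ xtx  # effective-parameter matrix; tr(M) = total edf
    for b in blocks:
        sl = slices[b.name]
        hdiag_blocks[b.name] = float(np.trace(m[sl, sl]))
    rss = float(yty - 2.0 * beta @ xty + beta @ xtx @ beta)
    return beta, hdiag_blocks, max(rss, 0.0), ainv


def _gcv_select(x, y, blocks, slices, grids, gamma: float = 1.4):
    """Grid-search GCV over a dict of per-block lambda grids (shared keys).

    ``gamma`` inflates the edf in the GCV denominator; values around 1.4
    guard against the undersmoothing GCV is prone to with serially
    correlated residuals.
    """
    n = len(y)
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    keys = list(grids)
    best = None
    from itertools import product
    for combo in product(*(grids[k] for k in keys)):
        lambdas = dict(zip(keys, combo))
        for b in blocks:
            if b.penalty is not None and b.name not in lambdas:
                lambdas[b.name] = lambdas.get("smooth", 1.0)
        beta, edf_blocks, rss, ainv = _fit_once(xtx, xty, yty, blocks,
                                                slices, lambdas)
        edf = sum(edf_blocks.values())
        dfe = n - gamma * edf
        gcv = n * rss / dfe ** 2 if dfe > 0 else np.inf
        if best is None or gcv < best[0]:
            best = (gcv, lambdas, beta, edf_blocks, rss, ainv, xtx)
    return best


def _ar1_quasi_difference(y, x, groups, phi):
    """Within-group Cochrane-Orcutt transform of response and design."""
    y2 = y.copy()
    x2 = x.copy()
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        y2[idx[1:]] = y[idx[1:]] - phi * y[idx[:-1]]
        x2[idx[1:]] = x[idx[1:]] - phi * x[idx[:-1]]
        s = np.sqrt(max(1.0 - phi * phi, 1e-6))
        y2[idx[0]] *= s
        x2[idx[0]] *= s
    return y2, x2


def _estimate_phi(resid, groups):
    num = den = 0.0
    for g in np.unique(groups):
        r = resid[groups == g]
        if len(r) > 2:
            num += float(r[1:] @ r[:-1])
            den += float(r[:-1] @ r[:-1])
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def assemble_gr_dataset(sims: dict, spring_wb: pd.Series,
                        include_dormant: bool = False) -> pd.DataFrame:
    """Stack VS simulations into a tidy (year, doy, vigor, gr, spring_wb) table.

    ``sims`` maps vigor label → VSSimulation; ``spring_wb`` is the annual
    March-May water balance indexed by year. Dormant (Gr = 0, inactive)
    days are structural zeros and excluded by default.
    """
    frames = []
    for vigor, sim in sims.items():
        d = sim.daily[["year", "doy", "gr", "active"]].copy()
        d["vigor"] = vigor
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    if not include_dormant:
        out = out[out["active"]]
    out = out.drop(columns="active")
    out["spring_wb"] = out["year"].map(spring_wb)
    out = out.dropna(subset=["spring_wb"])
    return out.reset_index(drop=True)


@dataclass
class SmoothFitResult:
    edf: dict
    f_stats: dict
    t_vigor: float
    p_vigor: float
    r_squared: float
    ar1: float
    curves: pd.DataFrame
    lambdas: dict = field(default_factory=dict)
    sigma2: float = float("nan")
    n: int = 0


def _block_f(beta, slices, xtx, edf_blocks, sigma2, name):
    sl = slices[name]
    b = beta[sl]
    quad = float(b @ xtx[sl, sl] @ b)
    edf = max(edf_blocks[name], 0.1)
    return (quad / edf) / sigma2


def fit_doy_smooth_by_group(data: pd.DataFrame, k: int = 12,
                            lambda_grid=None, year_lambda_grid=None,
                            ar1_iterations: int = 2) -> SmoothFitResult:
    """Seasonal growth curves per vigor class with year random intercepts.

    Model: Gr = a + b·[vigor=D] + f_ND(DOY) + f_D(DOY) + u_year + AR(1)
    noise, where the f are cyclic penalized splines and u_year is a
    ridge-shrunk intercept per year. Reports per-smooth edf and approximate
    F, the vigor-contrast t, R² and the AR(1) coefficient.
    """
    vigors = sorted(data["vigor"].unique())
    if len(vigors) > 2:
        raise ValueError("expected at most two vigor classes")
    if len(vigors) == 1:
        logger.warning("single vigor class: fitting without contrast")
    if data["year"].nunique() < 10:
        raise ValueError("need >= 10 years")
    data = data.sort_values(["vigor", "year", "doy"]).reset_index(drop=True)
    y = data["gr"].to_numpy(float)
    doy = data["doy"].to_numpy(float)
    n = len(y)

    basis_raw, pen_raw = cyclic_bspline_basis(doy, k=k)
    z = _sum_zero(k)
    basis_all, pen = _constrain(basis_raw, pen_raw, z)
    blocks = [_Block("const", np.ones((n, 1)), center=False)]
    if len(vigors) == 2:
        vig_ind = (data["vigor"] == vigors[1]).to_numpy(float)
        blocks.append(_Block("vigor", vig_ind[:, None]))
    for v in vigors:
        m = (data["vigor"] == v).to_numpy()
        bmat = np.where(m[:, None], basis_all, 0.0)
        blocks.append(_Block(f"s_doy_{v}", bmat, penalty=pen))
    years = data["year"].to_numpy()
    uyears = np.unique(years)
    zyear = (years[:, None] == uyears[None, :]).astype(float)
    blocks.append(_Block("year", zyear, penalty=np.eye(len(uyears))))

    x, slices = _assemble(blocks)
    lambda_grid = lambda_grid if lambda_grid is not None else 10.0 ** np.arange(-1, 8)
    year_lambda_grid = (year_lambda_grid if year_lambda_grid is not None
                        else 10.0 ** np.arange(0, 5))
    # the two group smooths share one grid dimension to keep the search small
    grids = {"smooth": lambda_grid, "year": year_lambda_grid}

    groups = data.groupby(["vigor", "year"], sort=False).ngroup().to_numpy()
    phi = 0.0
    yw, xw = y, x
    for _ in range(max(1, ar1_iterations)):
        gcv, lambdas, beta, edf_blocks, rss, ainv, xtx = _gcv_select(
            xw, yw, blocks, slices, grids)
        resid = y - x @ beta
        phi_new = float(np.clip(_estimate_phi(resid, groups), -0.98, 0.98))
        if abs(phi_new - phi) < 0.01:
            phi = phi_new
            break
        phi = phi_new
        yw, xw = _ar1_quasi_difference(y, x, groups, phi)
    # final statistics on the (possibly) transformed scale
    edf_total = sum(edf_blocks.values())
    sigma2 = rss / max(n - edf_total, 1.0)
    edf = {f"s_doy_{v}": 1.0 + edf_blocks[f"s_doy_{v}"] for v in vigors}
    f_stats = {f"s_doy_{v}": _block_f(beta, slices, xtx, edf_blocks,
                                      sigma2, f"s_doy_{v}") for v in vigors}
    if len(vigors) == 2:
        sl = slices["vigor"]
        cov = sigma2 * ainv[sl, sl]
        t_vigor = float(beta[sl][0] / np.sqrt(cov[0, 0]))
        p_vigor = float(2 * stats.t.sf(abs(t_vigor), max(n - edf_total, 1)))
    else:
        t_vigor, p_vigor = float("nan"), float("nan")
    fitted = x @ beta
    ybar = y.mean()
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / float(np.sum((y - ybar) ** 2))

    # fitted curves on a DOY grid, year effect at its mean (0)
    grid = np.arange(1, 367, dtype=float)
    gbasis_raw, _ = cyclic_bspline_basis(grid, k=k)
    gbasis = gbasis_raw @ z
    rows = []
    for v in vigors:
        xrow = np.zeros((len(grid), x.shape[1]))
        xrow[:, slices["const"]] = 1.0
        if len(vigors) == 2 and v == vigors[1]:
            xrow[:, slices["vigor"]] = 1.0 - blocks[1].mean
        elif len(vigors) == 2:
            xrow[:, slices["vigor"]] = -blocks[1].mean
        bl = next(b for b in blocks if b.name == f"s_doy_{v}")
        xrow[:, slices[f"s_doy_{v}"]] = gbasis - bl.mean
        mu = xrow @ beta
        se = np.sqrt(np.maximum(
            sigma2 * np.einsum("ij,jk,ik->i", xrow, ainv, xrow), 0.0))
        rows.append(pd.DataFrame({"doy": grid, "vigor": v, "fit": mu,
                                  "lower": mu - 1.96 * se,
                                  "upper": mu + 1.96 * se}))
    curves = pd.concat(rows, ignore_index=True)
    return SmoothFitResult(edf=edf, f_stats=f_stats, t_vigor=t_vigor,
                           p_vigor=p_vigor, r_squared=max(r2, 0.0), ar1=phi,
                           curves=curves, lambdas=lambdas, sigma2=sigma2, n=n)


@dataclass
class InteractionFitResult:
    f_interaction: float
    p_interaction: float
    edf_interaction: float
    r_squared: float
    ar1: float
    surface: pd.DataFrame
    lambdas: dict = field(default_factory=dict)
    n: int = 0


def fit_doy_wb_interaction(data: pd.DataFrame, k_doy: int = 10, k_wb: int = 6,
                           grid_size: int = 40, ar1_iterations: int = 2,
                           n_permutations: int = 99,
                           seed: int = 0) -> InteractionFitResult:
    """Tensor-product surface Gr ~ te(DOY, spring water balance).

    Fits the additive model s(DOY) + s(wb) + year intercepts and the full
    model with an interaction-only tensor smooth (constrained marginals, so
    the tensor is orthogonal to both main effects), both with AR(1)
    quasi-differenced residuals. The interaction is tested by permuting the
    year-to-spring-balance assignment: the balance is constant within a
    year, so exchanging it across years is the exact null of "the seasonal
    curve does not depend on water availability", and the permutation
    distribution of the F statistic remains valid under the strong
    within-year correlation that a parametric F would ignore. Smoothing
    parameters and the AR(1) coefficient are selected once on the observed
    data and held fixed across permutations.
    """
    if data["year"].nunique() < 10:
        raise ValueError("need >= 10 years")
    year_wb = data.groupby("year")["spring_wb"].first()
    wb_sd = year_wb.std()
    if not np.isfinite(wb_sd) or wb_sd == 0:
        raise ValueError("spring water balance does not vary across years")
    data = data.sort_values(["year", "doy"]).reset_index(drop=True)
    y = data["gr"].to_numpy(float)
    doy = data["doy"].to_numpy(float)
    wb = data["spring_wb"].to_numpy(float)
    n = len(y)

    zd, zw = _sum_zero(k_doy), _sum_zero(k_wb)
    bdoy_raw, pdoy_raw = cyclic_bspline_basis(doy, k=k_doy)
    bdoy, pdoy = _constrain(bdoy_raw, pdoy_raw, zd)
    wb_lo, wb_hi = float(wb.min()), float(wb.max())
    years = data["year"].to_numpy()
    uyears = np.unique(years)
    zyear = (years[:, None] == uyears[None, :]).astype(float)
    lam_grid = 10.0 ** np.arange(-1, 8)
    year_grid = 10.0 ** np.arange(0, 5)

    def build_blocks(wb_values):
        bwb_raw, pwb_raw = bspline_basis(wb_values, k=k_wb, lo=wb_lo, hi=wb_hi)
        bwb, pwb = _constrain(bwb_raw, pwb_raw, zw)
        # interaction-only tensor from constrained marginals: orthogonal to
        # both main effects, so its edf measures pure interaction
        tens = _row_kron(bdoy, bwb)
        kd, kw = bdoy.shape[1], bwb.shape[1]
        ptens = (np.kron(pdoy, np.eye(kw)) + np.kron(np.eye(kd), pwb)
                 + 1e-6 * np.eye(kd * kw))
        base = [
            _Block("const", np.ones((n, 1)), center=False),
            _Block("s_doy", bdoy, penalty=pdoy),
            _Block("s_wb", bwb, penalty=pwb),
            _Block("year", zyear, penalty=np.eye(len(uyears))),
        ]
        return base, base + [_Block("tensor", tens, penalty=ptens)]

    def fit_model(blocks, grids, phi_fixed=None):
        x, slices = _assemble(blocks)
        phi = 0.0 if phi_fixed is None else phi_fixed
        yw, xw = (y, x) if phi == 0.0 else _ar1_quasi_difference(y, x, years, phi)
        out = _gcv_select(xw, yw, blocks, slices, grids)
        if phi_fixed is None:
            for _ in range(max(1, ar1_iterations) - 1):
                beta = out[2]
                resid = y - x @ beta
                phi_new = float(np.clip(_estimate_phi(resid, years), -0.98, 0.98))
                if abs(phi_new - phi) < 0.01:
                    phi = phi_new
                    break
                phi = phi_new
                yw, xw = _ar1_quasi_difference(y, x, years, phi)
                out = _gcv_select(xw, yw, blocks, slices, grids)
        gcv, lambdas, beta, edf_blocks, rss, ainv, xtx = out
        return x, slices, beta, edf_blocks, rss, ainv, phi, lambdas

    def f_stat(rss_add, rss_full, edf_add, edf_full):
        d_edf = max(edf_full - edf_add, 1e-6)
        df_res = max(n - edf_full, 1.0)
        sigma2 = rss_full / df_res
        return max(rss_add - rss_full, 0.0) / d_edf / sigma2, d_edf, df_res

    # stage 1: additive fit selects the main-effect and year penalties and
    # the AR(1) coefficient; stage 2 selects only the tensor penalty. The
    # permutation loop repeats stage 2 identically for every reassignment,
    # so observed and permuted F statistics come from the same procedure.
    base_blocks, full_blocks = build_blocks(wb)
    xa, sla, ba, edfa, rssa, _, phif, lama = fit_model(
        base_blocks, {"smooth": lam_grid, "year": year_grid})
    grids_main = {k: [v] for k, v in lama.items()
                  if k in ("smooth", "year")}
    xf, slf, bf, edff, rssf, ainvf, _, lamf = fit_model(
        full_blocks, {**grids_main, "tensor": lam_grid}, phi_fixed=phif)
    f_int, d_edf, df_res = f_stat(rssa, rssf, sum(edfa.values()),
                                  sum(edff.values()))

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        wb_by_year = year_wb.to_numpy()
        for _ in range(n_permutations):
            perm = rng.permutation(len(uyears))
            wb_p = pd.Series(wb_by_year[perm], index=uyears).loc[years].to_numpy()
            bb, fb = build_blocks(wb_p)
            _, _, _, ea, ra, _, _, _ = fit_model(bb, grids_main,
                                                 phi_fixed=phif)
            _, _, _, ef, rf, _, _, _ = fit_model(
                fb, {**grids_main, "tensor": lam_grid}, phi_fixed=phif)
            fp, _, _ = f_stat(ra, rf, sum(ea.values()), sum(ef.values()))
            if fp >= f_int:
                exceed += 1
        p_int = (1.0 + exceed) / (n_permutations + 1.0)
    else:
        p_int = float(stats.f.sf(f_int, d_edf, df_res))

    fitted = xf @ bf
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / float(np.sum((y - y.mean()) ** 2))

    # surface on a grid
    gd = np.linspace(1, 366, grid_size)
    gw = np.linspace(wb.min(), wb.max(), grid_size)
    dd, ww = np.meshgrid(gd, gw, indexing="ij")
    bd_raw, _ = cyclic_bspline_basis(dd.ravel(), k=k_doy)
    bw_raw, _ = bspline_basis(ww.ravel(), k=k_wb, lo=float(wb.min()),
                              hi=float(wb.max()))
    bd, bw = bd_raw @ zd, bw_raw @ zw
    tt = _row_kron(bd, bw)
    xg = np.zeros((grid_size * grid_size, xf.shape[1]))
    xg[:, slf["const"]] = 1.0
    xg[:, slf["s_doy"]] = bd - full_blocks[1].mean
    xg[:, slf["s_wb"]] = bw - full_blocks[2].mean
    xg[:, slf["year"]] = -full_blocks[3].mean  # year effect at its mean
    xg[:, slf["tensor"]] = tt - full_blocks[4].mean
    surface = pd.DataFrame({"doy": dd.ravel(), "spring_wb": ww.ravel(),
                            "fit": xg @ bf})
    return InteractionFitResult(
        f_interaction=float(f_int), p_interaction=p_int,
        edf_interaction=float(edff["tensor"]), r_squared=max(r2, 0.0),
        ar1=phif, surface=surface, lambdas={**lama, **{f"full_{k}": v for k, v in lamf.items()}},
        n=n)
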