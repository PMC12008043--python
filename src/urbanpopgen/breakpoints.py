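"""Piecewise (segmented) regression of ln(Ne) against years before sampling.

Under exponential growth or decay with per-year rate r, Ne changes as
Ne(t) = Ne0 * (1+r)^t, so ln Ne is piecewise linear in time with slope
b = ln(1+r) within each period of constant rate. Because the trajectory
runs backwards in time, the forward-time growth rate is recovered with the
sign reverted: r = -(exp(b) - 1); its confidence interval is the slope CI
transformed endpoint-wise with the order swapped (the transform is
decreasing).

Breakpoints are estimated with Muggeo's iterative linearization: at each
iteration, y is regressed on {1, t, (t - psi_k)_+, -1[t > psi_k]} and each
breakpoint is updated by psi_k <- psi_k + gamma_k / beta_k until the
updates fall below tolerance. Fits are built up one breakpoint at a time
with an exhaustive-scan safeguard so the residual sum of squares is
non-increasing in the number of breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .demography import NeTrajectory

# subsampling scheme: yearly to 100, every 19th year to 2000, every 130th to 15000
SUBSAMPLE_RANGES = ((1, 100, 1), (100, 2000, 19), (2000, 15000, 130))


@dataclass
class SubsampledSeries:
    t: np.ndarray
    y: np.ndarray                   # ln(median Ne)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        order = np.argsort(self.t)
        self.t, self.y = self.t[order], self.y[order]
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing after sorting")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")


def subsample_grid(t_max: float = 15000.0) -> np.ndarray:
    parts = [np.arange(lo, hi + 1, step) for lo, hi, step in SUBSAMPLE_RANGES]
    grid = np.unique(np.concatenate(parts)).astype(float)
    return grid[grid <= t_max]


def subsample_years(traj: NeTrajectory) -> SubsampledSeries:
    """Evaluate ln(median Ne) on the systematic year grid.

    The stepwise trajectory is read with step-function semantics (most
    recent step at or before t). Trajectories that do not reach year
    15,000 yield a truncated grid with a warning.
    """
    coverage = float(traj.years[-1]) if len(traj.years) else 0.0
    grid = subsample_grid(max(coverage, 15000.0))
    # a step trajectory whose last step starts before 15000 still defines
    # Ne beyond it; truncation only applies if the caller marked coverage
    t_max = traj.meta.get("t_max_years", 15000.0)
    if t_max < 15000.0:
        warnings.warn(f"trajectory covers only [1, {t_max:g}] years; "
                      "subsampling grid truncated", stacklevel=2)
        grid = grid[grid <= t_max]
    ne = traj.median_at(grid)
    if np.any(ne <= 0):
        raise ValueError("non-positive Ne on the subsampling grid")
    return SubsampledSeries(grid, np.log(ne))


# ---------------------------------------------------------------------------
# Muggeo iterative linearization
# ---------------------------------------------------------------------------

@dataclass
class BreakpointModel:
    psi: np.ndarray                 # breakpoint years, increasing
    psi_se: np.ndarray
    slopes: np.ndarray              # per segment, len k+1
    slope_ci: np.ndarray            # (k+1, 2)
    rates: np.ndarray = field(default=None)
    rate_ci: np.ndarray = field(default=None)
    rss: float = np.nan
    converged: bool = False
    n_iter: int = 0
    t_range: tuple[float, float] = (np.nan, np.nan)

    def segment_bounds(self) -> np.ndarray:
        return np.concatenate([[self.t_range[0]], self.psi, [self.t_range[1]]])

    def to_frame(self) -> pd.DataFrame:
        bounds = self.segment_bounds()
        rows = []
        for s in range(len(self.slopes)):
            row = {
                "segment": s,
                "start_year": bounds[s],
                "end_year": bounds[s + 1],
                "b": self.slopes[s],
                "b_lo": self.slope_ci[s, 0],
                "b_hi": self.slope_ci[s, 1],
            }
            if self.rates is not None:
                row.update(r=self.rates[s], r_lo=self.rate_ci[s, 0],
                           r_hi=self.rate_ci[s, 1])
            if s < len(self.psi):
                row.update(psi=self.psi[s], psi_se=self.psi_se[s])
            rows.append(row)
        return pd.DataFrame(rows)


def _design(t: np.ndarray, psi: np.ndarray, with_gap: bool):
    cols = [np.ones_like(t), t]
    for p in psi:
        cols.append(np.maximum(t - p, 0.0))
    if with_gap:
        for p in psi:
            cols.append(-(t > p).astype(float))
    return np.column_stack(cols)


def _ols(x: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid), rank


def _enforce_spacing(psi: np.ndarray, t: np.ndarray, min_pts: int = 2):
    """Sort, clip to the interior, and merge breakpoints with fewer than
    ``min_pts`` grid points strictly between them."""
    psi = np.sort(psi)
    psi = np.clip(psi, t[1], t[-2])
    kept: list[float] = []
    for p in psi:
        if kept:
            between = np.sum((t > kept[-1]) & (t < p))
            if between < min_pts:
                warnings.warn("breakpoints collapsed; merging", stacklevel=3)
                continue
        kept.append(float(p))
    return np.asarray(kept)


def _muggeo(t, y, psi0, tol, max_iter):
    """Core iteration; returns (psi, converged, n_iter, last fit pieces)."""
    psi = _enforce_spacing(np.asarray(psi0, dtype=float), t)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        if len(psi) == 0:
            break
        x = _design(t, psi, with_gap=True)
        beta, rss, _ = _ols(x, y)
        k = len(psi)
        b = beta[2:2 + k]
        gam = beta[2 + k:2 + 2 * k]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(b) > 1e-12, gam / b, 0.0)
        # dampen steps that would jump outside the interior
        new = psi + step
        new = np.clip(new, t[1], t[-2])
        delta = np.max(np.abs(new - psi))
        psi = _enforce_spacing(new, t)
        if len(psi) < k:
            continue
        if delta < tol:
            converged = True
            break
    return psi, converged, n_iter


def _final_fit(t, y, psi, converged, n_iter):
    """Assemble slopes, CIs and breakpoint SEs for fixed psi."""
    k = len(psi)
    x = _design(t, psi, with_gap=False)
    beta, rss, rank = _ols(x, y)
    n, p = x.shape
    dof = max(n - p, 1)
    # numerical noise floor: an exact interpolation must not turn
    # round-off-level slopes into significant effects
    floor = (1e-8 * max(1.0, float(np.max(np.abs(y))))) ** 2
    sigma2 = max(rss / dof, floor)
    xtx_inv = np.linalg.pinv(x.T @ x)
    cov = sigma2 * xtx_inv
    tcrit = stats.t.ppf(0.975, dof)

    slopes = np.empty(k + 1)
    ci = np.empty((k + 1, 2))
    for s in range(k + 1):
        c = np.zeros(p)
        c[1] = 1.0
        c[2:2 + s] = 1.0
        slopes[s] = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        ci[s] = (slopes[s] - tcrit * se, slopes[s] + tcrit * se)

    # delta-method psi SEs from one refit with gap columns
    psi_se = np.full(k, np.nan)
    if k:
        xg = _design(t, psi, with_gap=True)
        beta_g, rss_g, _ = _ols(xg, y)
        dof_g = max(len(t) - xg.shape[1], 1)
        cov_g = (rss_g / dof_g) * np.linalg.pinv(xg.T @ xg)
        for j in range(k):
            bj = beta_g[2 + j]
            gj = beta_g[2 + k + j]
            var_g = cov_g[2 + k + j, 2 + k + j]
            var_b = cov_g[2 + j, 2 + j]
            cov_bg = cov_g[2 + j, 2 + k + j]
            if abs(bj) > 1e-12:
                # Var(gamma/beta) by the delta method at gamma ~ 0
                psi_se[j] = float(np.sqrt(max(
                    (var_g + (gj / bj) ** 2 * var_b - 2 * (gj / bj) * cov_bg), 0.0))
                    / abs(bj))
    model = BreakpointModel(
        psi=np.asarray(psi, dtype=float), psi_se=psi_se, slopes=slopes,
        slope_ci=ci, rss=rss, converged=converged, n_iter=n_iter,
        t_range=(float(t[0]), float(t[-1])))
    return slopes_to_rates(model)


def _staged_candidates(t, y, k: int) -> list[np.ndarray]:
    """Initial breakpoint sets: quantile placements overall and pooled from
    per-range initial fits over the three subsampling periods."""
    cands = [np.quantile(t, np.linspace(0, 1, k + 2)[1:-1])]
    ranges = [(lo, hi) for lo, hi, _ in SUBSAMPLE_RANGES]
    pooled = []
    share = max(k // len(ranges), 1)
    for lo, hi in ranges:
        m = (t >= lo) & (t <= hi)
        if m.sum() < 2 * (share + 2):
            continue
        sub_t, sub_y = t[m], y[m]
        psi0 = np.quantile(sub_t, np.linspace(0, 1, share + 2)[1:-1])
        psi, _, _ = _muggeo(sub_t, sub_y, psi0, 1e-4, 30)
        pooled.extend(psi.tolist())
    if pooled:
        pooled = np.sort(np.asarray(pooled))
        if len(pooled) >= k:
            take = np.linspace(0, len(pooled) - 1, k).round().astype(int)
            cands.append(pooled[take])
        else:
            extra = np.quantile(t, np.linspace(0, 1, k - len(pooled) + 2)[1:-1])
            cands.append(np.sort(np.concatenate([pooled, extra])))
    return cands


def fit_piecewise(series: SubsampledSeries, k_breakpoints: int = 8,
                  init=None, tol: float = 1e-6, max_iter: int = 100,
                  seed: int | None = None) -> BreakpointModel:
    """Fit a segmented regression with ``k_breakpoints`` change points.

    ``init`` may be an explicit breakpoint list; by default a staged
    initialization (per-subsampling-range fits pooled with quantile
    placements) seeds the Muggeo iteration. Models are grown one
    breakpoint at a time with an exhaustive single-breakpoint scan as a
    safeguard, which makes the RSS non-increasing in k. Non-convergence
    returns the best iterate with ``converged=False``.
    """
    t, y = series.t, series.y
    if not k_breakpoints < (len(t) - 2) / 2:
        raise ValueError("too many breakpoints for the number of points")
    if k_breakpoints == 0:
        return _final_fit(t, y, np.array([]), True, 0)
    if init is not None:
        psi, conv, it = _muggeo(t, y, np.asarray(init, dtype=float), tol, max_iter)
        return _final_fit(t, y, psi, conv, it)

    best_prev: np.ndarray = np.array([])
    model = _final_fit(t, y, best_prev, True, 0)
    for k in range(1, k_breakpoints + 1):
        candidates: list[np.ndarray] = []
        # exhaustive augmentation of the previous solution
        interior = t[2:-2]
        best_fixed, best_fixed_rss = None, np.inf
        for p_new in interior:
            trial = _enforce_spacing(np.append(best_prev, p_new), t)
            if len(trial) != k:
                continue
            _, rss, _ = _ols(_design(t, trial, with_gap=False), y)
            if rss < best_fixed_rss:
                best_fixed_rss, best_fixed = rss, trial
        if best_fixed is not None:
            candidates.append(best_fixed)
        candidates.extend(_staged_candidates(t, y, k))

        best_model = None
        for cand in candidates:
            psi, conv, it = _muggeo(t, y, cand, tol, max_iter)
            if len(psi) != k:
                continue
            m = _final_fit(t, y, psi, conv, it)
            if best_model is None or m.rss < best_model.rss:
                best_model = m
        if best_fixed is not None and (best_model is None
                                       or best_fixed_rss < best_model.rss):
            best_model = _final_fit(t, y, best_fixed, False, 0)
        if best_model is None:
            warnings.warn(f"could not place breakpoint {k}; returning k={k-1} fit",
                          stacklevel=2)
            return model
        model, best_prev = best_model, best_model.psi
    return model


def slopes_to_rates(model: BreakpointModel) -> BreakpointModel:
    """Attach growth rates r = -(e^b - 1) with endpoint-swapped CIs."""
    b = model.slopes
    model.rates = -(np.exp(b) - 1.0)
    lo = -(np.exp(model.slope_ci[:, 1]) - 1.0)
    hi = -(np.exp(model.slope_ci[:, 0]) - 1.0)
    model.rate_ci = np.column_stack([lo, hi])
    return model
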