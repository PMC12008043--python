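"""Folded site-frequency spectra and effective-population-size histories.

The SFS is folded (GBS data have no ancestral-state polarization) and
projected down to a fixed even number of allele copies by hypergeometric
subsampling, so SNPs with uneven missingness can contribute.

The Ne reconstruction is a stairway-style composite-likelihood estimator:
the history is parameterized by one Ne value per coalescent lineage-count
interval (optionally grouped into contiguous blocks to control model
complexity), under which the expected unfolded spectrum is

    E[xi_i] = mu * L * sum_k  k * E[T_k] * p(i | k),
    E[T_k]  = 2 * N_k / C(k, 2),
    p(i|k)  = C(n-i-1, k-2) / C(n-1, k-1),

i.e. linear in the N_k. Folded bin counts are treated as independent
Poisson draws (a composite likelihood; equivalent to the multinomial up to
the total-S term). The number of free Ne blocks is chosen on a held-out
33% split of segregating sites, and uncertainty comes from multinomial
bootstrap resampling of SNPs. Times convert generations to years with the
configured generation time.

An exact expectation engine for arbitrary piecewise-constant (time-grid)
histories is also provided: the lineage-count process is a pure death
chain whose per-epoch transition and occupancy integrals follow from the
matrix exponential of the bidiagonal generator; a Monte Carlo genealogy
mode backs it up for cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special

from .geno_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

# resolution floor for block Ne estimates; fits pinned here are degenerate
NE_FLOOR = 1.0


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

@dataclass
class FoldedSFS:
    """Minor-allele-count spectrum at a fixed projection size."""

    counts: np.ndarray          # length n_chrom // 2, bins 1..n/2
    n_chrom: int
    total_sites: int            # L, nucleotide sites behind the spectrum
    n_dropped_low_coverage: int = 0
    n_dropped_monomorphic: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_chrom % 2 != 0:
            raise ValueError("projection size must be even")
        if len(self.counts) != self.n_chrom // 2:
            raise ValueError("counts length must be n_chrom/2")
        if np.any(self.counts < 0):
            raise ValueError("negative SFS counts")

    @property
    def segregating_sites(self) -> float:
        return float(self.counts.sum())


def build_folded_sfs(g: GenotypeMatrix, idx: np.ndarray | None = None,
                     n_chrom: int | None = None, seed: int | None = None,
                     mode: str = "sample") -> FoldedSFS:
    """Project each SNP's minor-allele count down to ``n_chrom`` copies.

    ``mode='sample'`` draws one hypergeometric subsample per SNP (seeded);
    ``'expected'`` adds the exact hypergeometric expectation instead
    (fractional counts). SNPs with fewer called copies than the projection
    are dropped and counted; so are SNPs that become monomorphic.
    """
    geno = g.genotypes if idx is None else g.genotypes[idx]
    called = geno != MISSING
    ac = np.where(called, geno, 0).sum(axis=0)
    an = 2 * called.sum(axis=0)
    if n_chrom is None:
        n_chrom = int(0.8 * an.max())
        n_chrom -= n_chrom % 2
    if n_chrom % 2 != 0:
        raise ValueError("projection size must be even")
    if n_chrom < 4:
        raise ValueError("projection size must be >= 4")

    half = n_chrom // 2
    counts = np.zeros(half)
    dropped_cov = dropped_mono = 0
    rng = np.random.default_rng(seed)
    for a, c in zip(ac, an):
        if 0 >= a or a >= c:
            continue  # monomorphic in this unit: not a segregating site
        if c < n_chrom:
            dropped_cov += 1
            continue
        if mode == "sample":
            j = int(rng.hypergeometric(a, c - a, n_chrom))
            mac = min(j, n_chrom - j)
            if mac == 0:
                dropped_mono += 1
            else:
                counts[mac - 1] += 1
        elif mode == "expected":
            j = np.arange(n_chrom + 1)
            pmf = np.exp(
                _log_comb(a, j) + _log_comb(c - a, n_chrom - j) - _log_comb(c, n_chrom))
            mac = np.minimum(j, n_chrom - j)
            dropped_mono += float(pmf[mac == 0].sum())
            for b in range(1, half + 1):
                counts[b - 1] += float(pmf[mac == b].sum())
        else:
            raise ValueError("mode must be 'sample' or 'expected'")
    return FoldedSFS(counts, n_chrom, g.total_sites, dropped_cov, int(dropped_mono))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


# ---------------------------------------------------------------------------
# expected SFS under a piecewise-constant (time-grid) history
# ---------------------------------------------------------------------------

def _fold(unfolded: np.ndarray) -> np.ndarray:
    n = len(unfolded) + 1
    half = n // 2
    out = np.empty(half)
    for i in range(1, half + 1):
        out[i - 1] = unfolded[i - 1] + (unfolded[n - i - 1] if i != n - i else 0.0)
    return out


def _branch_prob_matrix(n: int) -> np.ndarray:
    """P[i-1, k-2] = k * p(i|k): expected number of branches subtending i
    leaves while k ancestral lineages exist."""
    i = np.arange(1, n)[:, None]
    k = np.arange(2, n + 1)[None, :]
    logp = _log_comb(n - i - 1, k - 2) - _log_comb(n - 1, k - 1)
    return np.exp(logp) * k


def expected_lineage_times(epochs: list[tuple[float, float]], n: int) -> np.ndarray:
    """E[T_k] (generations while k lineages) for k = 2..n under a
    piecewise-constant history ``[(start_gen, Ne), ...]`` starting at 0."""
    if epochs[0][0] != 0:
        raise ValueError("first epoch must start at generation 0")
    if any(ne <= 0 for _, ne in epochs):
        raise ValueError("Ne must be positive")
    m = n - 1                       # states k = 2..n
    ks = np.arange(2, n + 1)
    rates = ks * (ks - 1) / 2.0
    gen = np.zeros((m, m))          # dq/dt = G q, q over states (index k-2)
    gen[np.arange(m), np.arange(m)] = -rates
    gen[np.arange(m - 1), np.arange(1, m)] = rates[1:]
    q = np.zeros(m)
    q[-1] = 1.0                     # start with n lineages
    t_k = np.zeros(m)
    starts = [e[0] for e in epochs] + [np.inf]
    for e, (t0, ne) in enumerate(epochs):
        dur = starts[e + 1] - t0
        g_scaled = gen / (2.0 * ne)
        if np.isinf(dur):
            integral = -linalg.solve(g_scaled, q)
            t_k += integral
            break
        q_next = linalg.expm(g_scaled * dur) @ q
        t_k += linalg.solve(g_scaled, q_next - q)
        q = q_next
    return t_k


def expected_sfs(epochs: list[tuple[float, float]], n_chrom: int, mu: float,
                 total_sites: float, mode: str = "exact", n_mc: int = 2000,
                 seed: int | None = None, folded: bool = True) -> np.ndarray:
    """Expected (folded) SFS under a piecewise-constant Ne history.

    ``mode='exact'`` integrates the lineage-count death chain;
    ``'mc'`` averages branch lengths over ``n_mc`` simulated genealogies.
    """
    if mode == "exact":
        t_k = expected_lineage_times(epochs, n_chrom)
        unfolded = mu * total_sites * (_branch_prob_matrix(n_chrom) @ t_k)
    elif mode == "mc":
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        b = _mc_branch_lengths(epochs, n_chrom, n_mc, seed)
        unfolded = mu * total_sites * b
    else:
        raise ValueError("mode must be 'exact' or 'mc'")
    return _fold(unfolded) if folded else unfolded


def _mc_branch_lengths(epochs, n, n_mc, seed):
    """Mean branch length (generations) subtending i leaves, i = 1..n-1."""
    rng = np.random.default_rng(seed)
    starts = np.array([e[0] for e in epochs])
    nes = np.array([e[1] for e in epochs])
    total = np.zeros(n - 1)
    for _ in range(n_mc):
        sizes = [1] * n
        t = 0.0
        epoch = 0
        k = n
        while k > 1:
            rate_coal = k * (k - 1) / 2.0
            while True:
                ne = nes[epoch]
                wait = rng.exponential(2.0 * ne / rate_coal)
                nxt = starts[epoch + 1] if epoch + 1 < len(starts) else np.inf
                if t + wait <= nxt:
                    break
                t = nxt
                epoch += 1
            dt = wait
            for s in sizes:
                total[s - 1] += dt
            t += dt
            i, j = rng.choice(k, size=2, replace=False)
            merged = sizes[i] + sizes[j]
            sizes = [s for idx, s in enumerate(sizes) if idx not in (i, j)]
            sizes.append(merged)
            k -= 1
    return total / n_mc


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class DemographyConfig:
    """Settings for the Ne-history reconstruction."""

    mu: float = 1.8e-8              # per site per generation
    gen_time: float = 2.0           # years per generation
    n_bootstrap: int = 200
    train_fraction: float = 0.67
    complexity_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    year_grid_max: int = 15_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_time <= 0:
            raise ValueError("mu and gen_time must be positive")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")


@dataclass
class NeTrajectory:
    """Stepwise median and percentile Ne per year before sampling."""

    years: np.ndarray               # step start years, increasing, >= 0
    ne_median: np.ndarray
    ne_lo: np.ndarray               # 2.5th percentile
    ne_hi: np.ndarray               # 97.5th percentile
    chosen_complexity: int = 0
    n_failed_bootstrap: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        for name in ("ne_median", "ne_lo", "ne_hi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.ne_median <= 0):
            raise ValueError("Ne must be positive")
        if np.any(self.ne_lo > self.ne_median) or np.any(self.ne_median > self.ne_hi):
            raise ValueError("percentiles must bracket the median")

    def median_at(self, t) -> np.ndarray:
        """Step-function lookup: the most recent step value at or before t."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.years, t, side="right") - 1, 0, None)
        return self.ne_median[idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_years": self.years, "ne_median": self.ne_median,
                             "ne_lo": self.ne_lo, "ne_hi": self.ne_hi})


def _block_assignment(n_intervals: int, boundaries: list[int]) -> np.ndarray:
    """Map the n-1 lineage intervals (ordered k = n..2) to contiguous blocks
    delimited by the sorted interior ``boundaries`` (interval indices)."""
    cuts = np.asarray(sorted(boundaries), dtype=int)
    return np.searchsorted(cuts, np.arange(n_intervals), side="right")


class _SfsModel:
    """Poisson composite likelihood of a folded SFS, linear in block Ne."""

    def __init__(self, n_chrom: int, mu: float, total_sites: float,
                 boundaries: list[int] | None = None):
        self.n = n_chrom
        ks = np.arange(self.n, 1, -1)            # k = n..2 (recent -> ancient)
        self.coal_rates = ks * (ks - 1) / 2.0
        p = _branch_prob_matrix(self.n)          # (n-1, k=2..n)
        p = p[:, ::-1]                           # columns now k = n..2
        # fold the linear map: folded bin b collects unfolded i=b and n-b
        half = self.n // 2
        fmap = np.zeros((half, self.n - 1))
        for b in range(1, half + 1):
            fmap[b - 1, b - 1] = 1.0
            if b != self.n - b:
                fmap[b - 1, self.n - b - 1] = 1.0
        self.design = mu * total_sites * (fmap @ (p / self.coal_rates[None, :]) * 2.0)
        self.boundaries = sorted(boundaries or [])
        self.block = _block_assignment(self.n - 1, self.boundaries)
        self.c = len(self.boundaries) + 1

    def means(self, ne_blocks: np.ndarray) -> np.ndarray:
        return self.design @ np.asarray(ne_blocks)[self.block]

    def _block_design(self) -> np.ndarray:
        d = np.zeros((self.design.shape[0], self.c))
        for b in range(self.c):
            d[:, b] = self.design[:, self.block == b].sum(axis=1)
        return d

    def fit(self, counts: np.ndarray, ne0: float):
        """Maximize the Poisson composite likelihood over block Ne.

        The mean vector is linear in Ne, so the negative log-likelihood is
        convex on the positive orthant and the box-constrained quasi-Newton
        fit finds the global optimum.
        """
        bd = self._block_design()

        def nll_grad(ne):
            mu_i = np.maximum(bd @ ne, 1e-300)
            nll = float(np.sum(mu_i - counts * np.log(mu_i)))
            grad = bd.T @ (1.0 - counts / mu_i)
            return nll, grad

        res = optimize.minimize(
            nll_grad, np.full(self.c, float(ne0)), jac=True, method="L-BFGS-B",
            bounds=[(NE_FLOOR, 1e12)] * self.c,
            options={"maxiter": 500, "ftol": 1e-12})
        # a block pinned at the lower box bound is a time-collapse
        # degeneracy (the likelihood is flat in the duration of a
        # vanishing epoch); callers treat such fits as unusable
        res.degenerate = bool(np.any(res.x <= 1.5 * NE_FLOOR))
        return res

    def trajectory_steps(self, ne_blocks: np.ndarray, gen_time: float):
        """(step start years, Ne values) going back in time."""
        ne = np.asarray(ne_blocks)[self.block]
        t_k = 2.0 * ne / self.coal_rates       # E[T_k] generations
        starts_gen = np.concatenate([[0.0], np.cumsum(t_k)[:-1]])
        return starts_gen * gen_time, ne


def poisson_loglik(counts: np.ndarray, means: np.ndarray) -> float:
    means = np.maximum(means, 1e-300)
    return float(np.sum(counts * np.log(means) - means))


def infer_ne_trajectory(sfs: FoldedSFS, cfg: DemographyConfig) -> NeTrajectory:
    """Reconstruct a stepwise Ne history from a folded SFS.

    Complexity (number of free Ne blocks) is chosen by thinning the
    spectrum into a 67%/33% train/test split and scoring the held-out
    Poisson composite likelihood; bootstrap replicates (multinomial over
    SFS bins) at the chosen complexity give the 2.5/50/97.5 percentile
    trajectory on a common year grid.
    """
    if sfs.segregating_sites < 100:
        raise ValueError("need at least 100 segregating sites")
    rng = np.random.default_rng(cfg.seed)
    counts = sfs.counts
    n = sfs.n_chrom
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    theta_w = sfs.segregating_sites / a1
    ne0 = float(theta_w / (4.0 * cfg.mu * sfs.total_sites))

    # --- adaptive blocking: exhaustive boundary search at low complexity,
    # greedy augmentation beyond, parsimony-penalized held-out scoring
    train = rng.binomial(counts.astype(int), cfg.train_fraction).astype(float)
    test = counts - train
    c_max = min(max(cfg.complexity_grid), n - 1, len(counts))
    n_int = n - 1

    def train_fit(bnds):
        model = _SfsModel(n, cfg.mu, sfs.total_sites, bnds)
        res = model.fit(train / cfg.train_fraction, ne0)
        return model, res

    candidates: dict[int, list[int]] = {1: []}
    if c_max >= 2:
        fits = [(train_fit([cut])[1].fun, cut) for cut in range(1, n_int)]
        candidates[2] = [min(fits)[1]]
    if c_max >= 3:
        fits3 = [(train_fit([c1, c2])[1].fun, [c1, c2])
                 for c1 in range(1, n_int - 1) for c2 in range(c1 + 1, n_int)]
        candidates[3] = min(fits3)[1]
    for c in range(4, c_max + 1):
        base = candidates[c - 1]
        fits = [(train_fit(sorted(base + [cut]))[1].fun, cut)
                for cut in range(1, n_int) if cut not in base]
        candidates[c] = sorted(base + [min(fits)[1]])

    best_c, best_score = 1, -np.inf
    for c in sorted(candidates):
        if c not in cfg.complexity_grid:
            continue
        model, res = train_fit(candidates[c])
        if not res.success or res.degenerate:
            continue
        # each extra free Ne must buy at least one unit of held-out
        # composite log-likelihood (parsimony penalty)
        score = poisson_loglik(test / (1.0 - cfg.train_fraction),
                               model.means(res.x)) - float(c)
        if score > best_score:
            best_score, best_c = score, c

    # --- re-place the chosen number of boundaries on the full spectrum
    def full_fit(bnds):
        res = _SfsModel(n, cfg.mu, sfs.total_sites, bnds).fit(counts, ne0)
        return res.fun if (res.success and not res.degenerate) else np.inf

    if best_c == 1:
        final_bounds: list[int] = []
    elif best_c == 2:
        final_bounds = [min((full_fit([cut]), cut) for cut in range(1, n_int))[1]]
    else:
        final_bounds = min(((full_fit([c1, c2]), [c1, c2])
                            for c1 in range(1, n_int - 1)
                            for c2 in range(c1 + 1, n_int)))[1]
        for _ in range(best_c - 3):
            fits = [(full_fit(sorted(final_bounds + [cut])), cut)
                    for cut in range(1, n_int) if cut not in final_bounds]
            final_bounds = sorted(final_bounds + [min(fits)[1]])
    model = _SfsModel(n, cfg.mu, sfs.total_sites, final_bounds)

    # --- bootstrap over SNPs (multinomial across bins)
    s = counts.sum()
    probs = counts / s
    year_grid = np.unique(np.concatenate([
        [1.0], np.geomspace(1.0, cfg.year_grid_max, 400), [cfg.year_grid_max]]))
    trajs = []
    failed = 0
    for _ in range(cfg.n_bootstrap):
        bc = rng.multinomial(int(round(s)), probs).astype(float)
        res = model.fit(bc, ne0)
        if not res.success or res.degenerate:
            failed += 1
            continue
        starts_yr, ne = model.trajectory_steps(res.x, cfg.gen_time)
        idx = np.clip(np.searchsorted(starts_yr, year_grid, side="right") - 1, 0, None)
        trajs.append(ne[idx])
    if failed:
        logger.warning("infer_ne_trajectory: %d bootstrap replicates failed", failed)
    if not trajs:
        raise RuntimeError("all bootstrap replicates failed to converge")
    arr = np.vstack(trajs)
    lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5], axis=0)
    lo = np.minimum(lo, med)
    hi = np.maximum(hi, med)
    return NeTrajectory(year_grid, med, lo, hi, chosen_complexity=best_c,
                        n_failed_bootstrap=failed,
                        meta={"mu": cfg.mu, "gen_time": cfg.gen_time,
                              "seed": cfg.seed, "S": float(s)})


def sensitivity_sweep(sfs: FoldedSFS, mu_grid, gen_time_grid,
                      base: DemographyConfig | None = None) -> dict:
    """Re-run the reconstruction over a mutation-rate / generation-time grid.

    Returns {(mu, gen_time): NeTrajectory}; the decline-onset summary (year
    of the steepest drop of the median trajectory) is attached to each
    trajectory's ``meta``.
    """
    base = base or DemographyConfig()
    out = {}
    for mu in mu_grid:
        for gt in gen_time_grid:
            cfg = DemographyConfig(mu=mu, gen_time=gt, n_bootstrap=base.n_bootstrap,
                                   train_fraction=base.train_fraction,
                                   complexity_grid=base.complexity_grid,
                                   year_grid_max=base.year_grid_max, seed=base.seed)
            traj = infer_ne_trajectory(sfs, cfg)
            steps = np.diff(np.log(traj.ne_median))
            onset = float(traj.years[int(np.argmax(steps))]) if len(steps) else np.nan
            traj.meta["decline_onset_year"] = onset
            out[(mu, gt)] = traj
    return out
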