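"""Spatial genetic structure: genotype PCA, Mantel correlograms, and
Moran-eigenvector-map (MEM) regression.

The MEM analysis builds orthogonal spatial basis functions from a
minimum-spanning-tree-truncated geographic distance matrix and forward
selects them as predictors of genotype PC scores, with seeded permutation
tests. Together with the correlogram it provides the null-versus-structure
verdict for a set of georeferenced genotypes: no selected MEM and no
significant short-distance autocorrelation is reported as consistent with
a single panmictic population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix
from .differentiation import imputed_allele_matrix


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(g: GenotypeMatrix, n_components: int = 10, scale: bool = False):
    """PCA of the mean-imputed, centered genotype matrix.

    Returns ``(scores, explained_variance_fractions)``; components are
    deterministic (full SVD with sign convention from scikit-learn).
    """
    from sklearn.decomposition import PCA

    x = imputed_allele_matrix(g)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, min(x.shape) - 1)
    if n_components < 1:
        raise ValueError("need at least 2 individuals")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return scores, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Mantel correlogram
# ---------------------------------------------------------------------------

def _mantel_r(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    a = vec_a - vec_a.mean()
    b = vec_b - vec_b.mean()
    den = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / den) if den > 0 else np.nan


def mantel_correlogram(gen_dist: np.ndarray, geo_dist: np.ndarray,
                       n_classes: int | None = None, n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """Multivariate correlogram of genetic distance against geographic
    distance classes.

    Distance classes are equal-width over the geographic range with the
    class count from Sturges' rule on the number of pairs. Per class, the
    Mantel statistic is the correlation between the genetic distances and
    the class-membership indicator, sign-flipped so that positive values
    mean genetic similarity within the class (positive spatial
    autocorrelation). p-values come from joint row/column permutations of
    the genetic matrix and receive a progressive Holm correction; classes
    beyond the one containing the median distance are flagged low-power.
    """
    gd = np.asarray(gen_dist, dtype=float)
    xy = np.asarray(geo_dist, dtype=float)
    if gd.shape != xy.shape or gd.shape[0] != gd.shape[1]:
        raise ValueError("matrices must be square and conformable")
    n = gd.shape[0]
    iu = np.triu_indices(n, k=1)
    gvec, dvec = gd[iu], xy[iu]
    m = len(dvec)
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(m) + 1))
    edges = np.linspace(dvec.min(), dvec.max(), n_classes + 1)
    edges[-1] += 1e-9
    cls = np.digitize(dvec, edges) - 1
    median_class = int(cls[np.argsort(dvec)][m // 2])

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]

    rows = []
    for c in range(n_classes):
        member = (cls == c).astype(float)
        n_pairs = int(member.sum())
        if n_pairs == 0:
            rows.append({"class": c, "lo_km": edges[c], "hi_km": edges[c + 1],
                         "n_pairs": 0, "r": np.nan, "p": np.nan,
                         "p_corrected": np.nan, "low_power": True})
            continue
        r_obs = -_mantel_r(gvec, member)
        ge = 0
        for perm in perms:
            gp = gd[np.ix_(perm, perm)][iu]
            if abs(-_mantel_r(gp, member)) >= abs(r_obs):
                ge += 1
        p = (1 + ge) / (1 + n_perm)
        rows.append({"class": c, "lo_km": float(edges[c]), "hi_km": float(min(edges[c + 1], dvec.max())),
                     "n_pairs": n_pairs, "r": r_obs, "p": p,
                     "p_corrected": np.nan, "low_power": c > median_class})
    tab = pd.DataFrame(rows)
    # progressive Holm: class k is corrected within the first k+1 classes
    pvals = tab["p"].to_numpy()
    corrected = np.full_like(pvals, np.nan)
    for k in range(len(pvals)):
        if not np.isfinite(pvals[k]):
            continue
        finite = np.flatnonzero(np.isfinite(pvals[: k + 1]))
        sub = pvals[finite]
        order = np.argsort(sub)
        adj = np.empty(len(sub))
        run = 0.0
        for rank, idx in enumerate(order):
            run = max(run, (len(sub) - rank) * sub[idx])
            adj[idx] = min(1.0, run)
        corrected[k] = adj[np.searchsorted(finite, k)]
    tab["p_corrected"] = corrected
    return tab


# ---------------------------------------------------------------------------
# Moran eigenvector maps
# ---------------------------------------------------------------------------

@dataclass
class MemResult:
    n_candidates: int
    selected: list[int]
    r2_adj: float
    global_r2_adj: float
    p_values: list[float]
    eigenvectors: np.ndarray
    verdict: str


def mem_basis(geo_dist: np.ndarray) -> np.ndarray:
    """Orthonormal spatial eigenvectors from MST-truncated distances.

    The truncation threshold is the largest minimum-spanning-tree edge;
    distances beyond it are set to 4x the threshold, the matrix is
    converted to -d^2/2, doubly centered, and eigenvectors with positive
    eigenvalues are returned (columns, unit norm).
    """
    from scipy.sparse.csgraph import minimum_spanning_tree

    d = np.asarray(geo_dist, dtype=float)
    n = d.shape[0]
    mst = minimum_spanning_tree(d).toarray()
    thresh = mst.max()
    if thresh <= 0:
        raise ValueError("degenerate coordinates: MST threshold is zero")
    dt = np.where(d <= thresh, d, 4.0 * thresh)
    np.fill_diagonal(dt, 0.0)
    a = -0.5 * dt**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0) * 1e-10
    return v[:, pos]


def _ezekiel_adj(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def mem_analysis(g: GenotypeMatrix | np.ndarray, geo_dist: np.ndarray,
                 alpha: float = 0.05, n_perm: int = 999, seed: int | None = None,
                 n_axes: int = 10) -> MemResult:
    """Forward selection of MEM spatial predictors of genotype variation.

    ``g`` is a genotype matrix (PC scores are computed internally on up to
    ``n_axes`` axes) or a precomputed response matrix. Selection adds the
    MEM with the largest incremental R-squared, tests it with a
    max-statistic permutation of the response rows, and stops at the first
    candidate with p > alpha or when the selected model's Ezekiel-adjusted
    R-squared exceeds the full-basis model's (double stopping rule).
    """
    if isinstance(g, GenotypeMatrix):
        y, _ = pca_genotypes(g, n_components=n_axes)
    else:
        y = np.asarray(g, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise ValueError("need >= 5 locations")
    mems = mem_basis(geo_dist)
    m = mems.shape[1]
    if m == 0:
        return MemResult(0, [], 0.0, 0.0, [], mems, "no positive-eigenvalue MEMs")

    yc = y - y.mean(axis=0)
    ss_total = float((yc**2).sum())
    if ss_total == 0:
        return MemResult(m, [], 0.0, 0.0, [], mems, "no genotypic variance")

    def added_r2(resp: np.ndarray) -> np.ndarray:
        # MEM columns are orthonormal & centered -> incremental R2 is a
        # per-column squared cross-product
        return ((mems.T @ resp) ** 2).sum(axis=1) / ss_total

    r2_full = float(added_r2(yc).sum())
    global_adj = _ezekiel_adj(r2_full, n, m)

    rng = np.random.default_rng(seed)
    selected: list[int] = []
    pvals: list[float] = []
    available = np.ones(m, dtype=bool)
    r2_sel = 0.0
    while available.any():
        gains = added_r2(yc)
        gains[~available] = -np.inf
        best = int(np.argmax(gains))
        gain_obs = gains[best]
        ge = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            gp = added_r2(yp)
            gp[~available] = -np.inf
            if gp.max() >= gain_obs:
                ge += 1
        p = (1 + ge) / (1 + n_perm)
        if p > alpha:
            break
        trial = selected + [best]
        r2_trial = r2_sel + gain_obs
        if _ezekiel_adj(r2_trial, n, len(trial)) > global_adj and len(trial) < m:
            break
        selected.append(best)
        pvals.append(p)
        r2_sel = r2_trial
        available[best] = False
        # residualize the response on the selected MEM (orthonormal basis)
        yc = yc - np.outer(mems[:, best], mems[:, best] @ yc)

    adj = _ezekiel_adj(r2_sel, n, len(selected)) if selected else 0.0
    verdict = ("spatial structure detected" if selected
               else "consistent with a single panmictic population")
    return MemResult(m, selected, float(adj), float(global_adj), pvals, mems, verdict)
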