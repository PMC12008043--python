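"""Genetic differentiation: Hudson F_ST, hierarchical AMOVA, PERMANOVA,
and PERMDISP.

Hudson's F_ST is estimated as a ratio of averages across SNPs (numerator
and denominator summed separately before dividing), which is robust when
per-SNP denominators are small. The AMOVA partitions squared Euclidean
distances between individual allele-count vectors over a
group / site / individual hierarchy; missing genotypes are mean-imputed
per SNP before distances are formed. All permutation tests use the
add-one p-value (1 + #{stat_perm >= stat_obs}) / (1 + n_perm) and are
reproducible from a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, group_indices


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def hudson_fst_components(p1, p2, n1, n2):
    """Per-SNP numerator and denominator of the Hudson estimator.

    p are alternate-allele frequencies; n are the sampling-correction
    denominators (allele copies by default elsewhere). SNPs with n <= 1 in
    either group contribute NaN.
    """
    p1, p2, n1, n2 = (np.asarray(x, dtype=float) for x in (p1, p2, n1, n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1.0 - p1) / (n1 - 1.0)
               - p2 * (1.0 - p2) / (n2 - 1.0))
        den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    bad = (n1 <= 1) | (n2 <= 1)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def hudson_fst_pair(p1, p2, n1, n2) -> float:
    """Ratio-of-averages Hudson F_ST across SNPs; NaN if the summed
    denominator is zero (no usable polymorphism)."""
    num, den = hudson_fst_components(p1, p2, n1, n2)
    ok = np.isfinite(num) & np.isfinite(den)
    d = float(np.sum(den[ok]))
    if d == 0.0:
        return np.nan
    return float(np.sum(num[ok])) / d


@dataclass
class FstResult:
    matrix: pd.DataFrame            # site x site Hudson F_ST (NaN diagonal)
    n_snps: pd.DataFrame            # SNPs used per pair
    group_means: dict[str, float]   # e.g. urban-urban / rural-rural / urban-rural
    excluded_sites: list[str]


def fst_matrix(g: GenotypeMatrix, site_assignment, habitat: dict | None = None,
               min_individuals: int = 2, n_convention: str = "copies") -> FstResult:
    """Pairwise Hudson F_ST between sampling sites.

    Sites with fewer than ``min_individuals`` genotyped individuals are
    excluded (single-individual sites make the sampling correction
    undefined). ``n_convention`` selects the correction denominator:
    ``'copies'`` (allele copies, default) or ``'individuals'``.
    ``habitat`` optionally maps site -> label to produce within/between
    group mean summaries.
    """
    if n_convention not in ("copies", "individuals"):
        raise ValueError("n_convention must be 'copies' or 'individuals'")
    groups = group_indices(g, site_assignment)
    sites = [s for s, idx in groups.items() if len(idx) >= min_individuals]
    excluded = [s for s in groups if s not in sites]

    freqs, ns = {}, {}
    for s in sites:
        ac, an = g.allele_counts(groups[s])
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[s] = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        ns[s] = an.astype(float) if n_convention == "copies" else an / 2.0

    k = len(sites)
    mat = np.full((k, k), np.nan)
    cnt = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            p1, p2 = freqs[sites[i]], freqs[sites[j]]
            n1, n2 = ns[sites[i]], ns[sites[j]]
            ok = np.isfinite(p1) & np.isfinite(p2) & (n1 > 1) & (n2 > 1)
            cnt[i, j] = cnt[j, i] = int(ok.sum())
            f = hudson_fst_pair(p1[ok], p2[ok], n1[ok], n2[ok])
            mat[i, j] = mat[j, i] = f

    matrix = pd.DataFrame(mat, index=sites, columns=sites)
    n_snps = pd.DataFrame(cnt, index=sites, columns=sites)
    means: dict[str, float] = {}
    if habitat is not None:
        pair_vals: dict[str, list[float]] = {}
        for i in range(k):
            for j in range(i + 1, k):
                if not np.isfinite(mat[i, j]):
                    continue
                key = "-".join(sorted((str(habitat[sites[i]]), str(habitat[sites[j]]))))
                pair_vals.setdefault(key, []).append(mat[i, j])
        means = {kk: float(np.mean(v)) for kk, v in sorted(pair_vals.items())}
    return FstResult(matrix, n_snps, means, excluded)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def imputed_allele_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Individuals x SNPs float matrix of alt-allele counts with missing
    entries replaced by the per-SNP mean."""
    x = g.genotypes.astype(float)
    x[g.genotypes == MISSING] = np.nan
    col = np.nanmean(x, axis=0)
    col = np.where(np.isfinite(col), col, 0.0)
    nan = np.isnan(x)
    x[nan] = np.broadcast_to(col, x.shape)[nan]
    return x


def euclidean_distance_matrix(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(x, metric="euclidean"))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    table: pd.DataFrame             # component, df, SS, MS, variance, percent, p
    phi: dict[str, float]
    n_perm: int
    seed: int | None = None
    components: dict[str, float] = field(default_factory=dict)


def _amova_ss(d2: np.ndarray, site_codes: np.ndarray, group_codes: np.ndarray,
              n_sites: int, n_groups: int):
    """Sums of squares for total / within-group / within-site from squared
    distances, via block sums."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_wg = 0.0
    for gcode in range(n_groups):
        m = group_codes == gcode
        ng = int(m.sum())
        if ng:
            ss_wg += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    ss_ws = 0.0
    for s in range(n_sites):
        m = site_codes == s
        ns = int(m.sum())
        if ns:
            ss_ws += d2[np.ix_(m, m)].sum() / (2.0 * ns)
    return ss_total, ss_wg, ss_ws


def _amova_components(d2, site_codes, group_codes, site_group, sizes):
    """Variance components for the group / site-in-group / within-site
    hierarchy with the standard unbalanced-design coefficients."""
    n = d2.shape[0]
    n_sites = len(sizes)
    n_groups = int(site_group.max()) + 1
    ss_total, ss_wg, ss_ws = _amova_ss(d2, site_codes, group_codes, n_sites, n_groups)
    ss_ag = ss_total - ss_wg
    ss_asg = ss_wg - ss_ws

    df_a, df_b, df_c = n_groups - 1, n_sites - n_groups, n - n_sites
    group_totals = np.array([sizes[site_group == gc].sum() for gc in range(n_groups)],
                            dtype=float)
    sum_sq_by_group = np.array(
        [np.sum(sizes[site_group == gc] ** 2) for gc in range(n_groups)], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (n - np.sum(sum_sq_by_group / group_totals)) / df_b if df_b > 0 else np.nan
        n_cp = ((np.sum(sum_sq_by_group / group_totals) - np.sum(sizes**2) / n) / df_a
                if df_a > 0 else np.nan)
        n_cpp = (n - np.sum(group_totals**2) / n) / df_a if df_a > 0 else np.nan

    ms_c = ss_ws / df_c if df_c > 0 else np.nan
    ms_b = ss_asg / df_b if df_b > 0 else np.nan
    ms_a = ss_ag / df_a if df_a > 0 else np.nan
    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / n_c if df_b > 0 else np.nan
    sigma_a = ((ms_a - sigma_c - n_cp * sigma_b) / n_cpp if df_a > 0 else np.nan)
    return {
        "ss": (ss_ag, ss_asg, ss_ws, ss_total),
        "df": (df_a, df_b, df_c),
        "ms": (ms_a, ms_b, ms_c),
        "sigma": (sigma_a, sigma_b, sigma_c),
    }


def amova(g: GenotypeMatrix | np.ndarray, sites, groups, n_perm: int = 999,
          seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA on Euclidean distances of allele counts.

    ``sites`` and ``groups`` assign each individual to a sampling site and
    each site to a habitat group (sequences aligned with individuals, or
    dicts keyed by individual id when ``g`` is a GenotypeMatrix).
    Significance: the among-group component permutes whole sites among
    groups; the among-site component permutes individuals among sites
    within their group; the within-site component permutes individuals
    across all sites (alternative: observed component smaller).
    """
    if isinstance(g, GenotypeMatrix):
        x = imputed_allele_matrix(g)
        if isinstance(sites, (dict, pd.Series)):
            sites = [sites[i] for i in g.individual_ids]
        if isinstance(groups, (dict, pd.Series)):
            groups = [groups[i] for i in g.individual_ids]
    else:
        x = np.asarray(g, dtype=float)
    sites = np.asarray([str(s) for s in sites], dtype=object)
    groups = np.asarray([str(s) for s in groups], dtype=object)
    n = x.shape[0]
    d2 = euclidean_distance_matrix(x) ** 2

    site_names, site_codes = np.unique(sites, return_inverse=True)
    sizes = np.bincount(site_codes).astype(float)
    site_group_names = []
    for s in site_names:
        labs = set(groups[sites == s])
        if len(labs) != 1:
            raise ValueError(f"site {s} maps to multiple groups")
        site_group_names.append(labs.pop())
    group_names, site_group = np.unique(site_group_names, return_inverse=True)
    group_codes = site_group[site_codes]

    obs = _amova_components(d2, site_codes, group_codes, site_group, sizes)
    sigma_a, sigma_b, sigma_c = obs["sigma"]
    total_var = np.nansum([sigma_a, sigma_b, sigma_c])

    rng = np.random.default_rng(seed)
    ge_a = ge_b = le_c = 0
    for _ in range(n_perm):
        # among groups: permute site -> group assignment
        perm_sg = rng.permutation(site_group)
        comp = _amova_components(d2, site_codes, perm_sg[site_codes], perm_sg, sizes)
        if np.isfinite(comp["sigma"][0]) and comp["sigma"][0] >= sigma_a:
            ge_a += 1
        # among sites within groups: permute individuals within their group
        perm_sites = site_codes.copy()
        for gcode in range(len(group_names)):
            m = np.flatnonzero(group_codes == gcode)
            perm_sites[m] = site_codes[m][rng.permutation(len(m))]
        comp = _amova_components(d2, perm_sites, site_group[perm_sites], site_group, sizes)
        if np.isfinite(comp["sigma"][1]) and comp["sigma"][1] >= sigma_b:
            ge_b += 1
        # within sites: permute individuals across everything
        perm_all = site_codes[rng.permutation(n)]
        comp = _amova_components(d2, perm_all, site_group[perm_all], site_group, sizes)
        if comp["sigma"][2] <= sigma_c:
            le_c += 1

    p_a = (1 + ge_a) / (1 + n_perm)
    p_b = (1 + ge_b) / (1 + n_perm)
    p_c = (1 + le_c) / (1 + n_perm)

    if total_var > 0:
        pct = [100.0 * s / total_var for s in (sigma_a, sigma_b, sigma_c)]
    else:
        pct = [np.nan] * 3
    table = pd.DataFrame({
        "component": ["among_groups", "among_sites_within_groups", "within_sites"],
        "df": obs["df"],
        "SS": obs["ss"][:3],
        "MS": obs["ms"],
        "variance": (sigma_a, sigma_b, sigma_c),
        "percent": pct,
        "p": (p_a, p_b, p_c),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = {
            "phi_ct": sigma_a / total_var if total_var else np.nan,
            "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else np.nan,
            "phi_st": (sigma_a + sigma_b) / total_var if total_var else np.nan,
        }
    return AmovaResult(table, phi, n_perm, seed,
                       components={"among_groups": sigma_a,
                                   "among_sites_within_groups": sigma_b,
                                   "within_sites": sigma_c,
                                   "SS_total": obs["ss"][3]})


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for c in range(k):
        m = codes == c
        nc = int(m.sum())
        if nc:
            ss += d2[np.ix_(m, m)].sum() / (2.0 * nc)
    return ss


def permanova(dist: np.ndarray, labels, n_perm: int = 999, seed: int | None = None):
    """Pseudo-F partition of a distance matrix by group labels.

    Equivalent to the Gower-centered inner-product partition; returns
    ``(pseudo_F, p)`` with the add-one permutation p-value.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray([str(x) for x in labels], dtype=object)
    names, codes = np.unique(labels, return_inverse=True)
    k = len(names)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n = d.shape[0]
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)

    def f_stat(c):
        ssw = _ss_within(d2, c, k)
        ssa = ss_total - ssw
        return (ssa / (k - 1)) / (ssw / (n - k))

    f_obs = f_stat(codes)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        if f_stat(codes[rng.permutation(n)]) >= f_obs:
            ge += 1
    return float(f_obs), (1 + ge) / (1 + n_perm)


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _pcoa_embed(dist: np.ndarray, warn_negative: float = 0.10):
    """Principal-coordinate embedding on the positive-eigenvalue axes."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gmat = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh((gmat + gmat.T) / 2.0)
    neg_mass = float(np.sum(np.abs(w[w < 0])))
    tot_mass = float(np.sum(np.abs(w)))
    if tot_mass > 0 and neg_mass / tot_mass > warn_negative:
        warnings.warn("distance matrix is strongly non-Euclidean "
                      f"({100*neg_mass/tot_mass:.1f}% negative eigenvalue mass)",
                      stacklevel=2)
    pos = w > max(w.max(), 0) * 1e-12
    return v[:, pos] * np.sqrt(w[pos])


def _spatial_median(x: np.ndarray, max_iter: int = 200, tol: float = 1e-9) -> np.ndarray:
    """Geometric median via Weiszfeld iterations."""
    c = x.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(x - c, axis=1)
        if np.any(d < 1e-12):
            return c
        w = 1.0 / d
        new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - c) < tol:
            return new
        c = new
    return c


def permdisp(dist: np.ndarray, labels, n_perm: int = 999, seed: int | None = None,
             center: str = "median"):
    """Homogeneity of multivariate dispersions.

    Embeds the distances by principal coordinates, measures each
    individual's distance to its own-group center (spatial median by
    default, ``'centroid'`` optional), and tests the one-way ANOVA F on
    those distances by label permutation. Returns ``(F, p)``.
    """
    labels = np.asarray([str(x) for x in labels], dtype=object)
    names, codes = np.unique(labels, return_inverse=True)
    k = len(names)
    if k < 2:
        raise ValueError("PERMDISP needs at least two groups")
    if np.bincount(codes).min() < 2:
        raise ValueError("each group needs >= 2 individuals")
    coords = _pcoa_embed(dist)
    n = coords.shape[0]

    def dispersion_f(c):
        z = np.empty(n)
        for gc in range(k):
            m = c == gc
            cen = (_spatial_median(coords[m]) if center == "median"
                   else coords[m].mean(axis=0))
            z[m] = np.linalg.norm(coords[m] - cen, axis=1)
        grand = z.mean()
        ssb = sum((c == gc).sum() * (z[c == gc].mean() - grand) ** 2 for gc in range(k))
        ssw = sum(((z[c == gc] - z[c == gc].mean()) ** 2).sum() for gc in range(k))
        if ssw == 0:
            return np.inf
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = dispersion_f(codes)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        if dispersion_f(codes[rng.permutation(n)]) >= f_obs:
            ge += 1
    return float(f_obs), (1 + ge) / (1 + n_perm)
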