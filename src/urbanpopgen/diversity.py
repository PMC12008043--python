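"""Genetic-diversity statistics: pi, Watterson's theta, heterozygosity and
F_IS, windowed Tajima's D with t-tests, and the site-level urbanization
regression.

Per-site nucleotide diversity uses the unbiased pairwise estimator
pi_s = 2 * n_alt * n_ref / (n * (n - 1)) over non-missing allele copies
and is scaled by the *total* genotyped nucleotide sites (variant plus
invariant, from the per-locus site counts), so values are comparable to
whole-locus per-site diversity. Unequal missingness across SNPs is handled
by evaluating the harmonic-number constants at the median allele-copy
count of the unit or window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import MISSING, GenotypeMatrix, group_indices


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def per_site_pi(g: GenotypeMatrix, idx: np.ndarray | None = None):
    """Return (pi_s, n_copies, n_alt) arrays over SNPs for a unit."""
    geno = g.genotypes if idx is None else g.genotypes[idx]
    called = geno != MISSING
    ac = np.where(called, geno, 0).sum(axis=0).astype(float)
    an = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_s = np.where(an > 1, 2.0 * ac * (an - ac) / (an * (an - 1.0)), 0.0)
    return pi_s, an, ac


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise ValueError("need at least 2 allele copies")
    return float(np.sum(1.0 / np.arange(1, n)))


def _segregating(an: np.ndarray, ac: np.ndarray) -> np.ndarray:
    return (ac > 0) & (ac < an)


# ---------------------------------------------------------------------------
# unit-level statistics
# ---------------------------------------------------------------------------

def nucleotide_diversity(g: GenotypeMatrix, idx: np.ndarray | None = None,
                         per: str = "all_sites") -> float:
    """Nucleotide diversity of a unit, per genotyped site.

    ``per='all_sites'`` divides the summed per-SNP diversity by the total
    genotyped sequence length (variant + invariant sites); ``'variant'``
    divides by the number of variant sites only.
    """
    pi_s, an, ac = per_site_pi(g, idx)
    total = float(np.sum(pi_s))
    if per == "all_sites":
        denom = g.total_sites
    elif per == "variant":
        denom = int(np.sum(_segregating(an, ac)))
    else:
        raise ValueError("per must be 'all_sites' or 'variant'")
    if denom == 0:
        raise ValueError("zero total sites")
    return total / denom


def wattersons_theta(g: GenotypeMatrix, idx: np.ndarray | None = None) -> float:
    """Watterson's theta per site: S / (a1 * L), a1 at the unit's median copy count."""
    _, an, ac = per_site_pi(g, idx)
    seg = _segregating(an, ac)
    s = int(seg.sum())
    if s == 0:
        return 0.0
    n = int(np.median(an[seg]))
    if n < 2:
        raise ValueError("fewer than 2 allele copies")
    return s / (harmonic(n) * g.total_sites)


def heterozygosity_fis(g: GenotypeMatrix, idx: np.ndarray | None = None):
    """Mean observed/expected heterozygosity and F_IS over variant sites.

    h_exp uses the small-sample correction 2p(1-p) * n/(n-1) with n allele
    copies. Per-site F_IS = 1 - h_obs/h_exp where h_exp > 0; sites that are
    monomorphic within the unit are excluded from the averages.
    """
    geno = g.genotypes if idx is None else g.genotypes[idx]
    called = geno != MISSING
    n_called = called.sum(axis=0).astype(float)
    ac = np.where(called, geno, 0).sum(axis=0).astype(float)
    an = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        h_obs = np.where(n_called > 0, (geno == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
        h_exp = np.where(an > 1, 2.0 * p * (1.0 - p) * an / np.maximum(an - 1.0, 1), np.nan)
    poly = np.isfinite(h_exp) & (h_exp > 0)
    if not poly.any():
        return np.nan, np.nan, np.nan
    fis_site = 1.0 - h_obs[poly] / h_exp[poly]
    return float(np.mean(h_obs[poly])), float(np.mean(h_exp[poly])), float(np.mean(fis_site))


def diversity_table(g: GenotypeMatrix, assignment=None, per: str = "all_sites") -> pd.DataFrame:
    """Per-unit diversity summary (one row per group; pass ``None`` for the
    entire population as a single unit labelled 'all')."""
    groups = ({"all": np.arange(g.n_individuals)} if assignment is None
              else group_indices(g, assignment))
    rows = []
    for lab, idx in groups.items():
        pi = nucleotide_diversity(g, idx, per=per)
        theta = wattersons_theta(g, idx)
        h_obs, h_exp, fis = heterozygosity_fis(g, idx)
        rows.append({"unit": lab, "n_individuals": len(idx), "pi": pi,
                     "theta_w": theta, "h_obs": h_obs, "h_exp": h_exp, "f_is": fis})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Canonical a1, a2, b1, b2, c1, c2, e1, e2 at n allele copies."""
    if n < 3:
        raise ValueError("Tajima's D needs n >= 3 copies")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d(s: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating sites, summed pairwise diversity, and
    allele-copy count; NaN when S < 2."""
    if s < 2:
        return np.nan
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    return (pi_sum - s / k["a1"]) / np.sqrt(var)


def tajimas_d_windows(g: GenotypeMatrix, idx: np.ndarray | None = None,
                      window_bp: int = 100_000) -> pd.DataFrame:
    """Tajima's D in half-open windows tiling each chromosome from position 1.

    Windows with S < 2 are retained but flagged ``defined=False`` and carry
    NaN D. The copy count per window is the median across its segregating
    SNPs (robust to uneven missingness).
    """
    pi_s, an, ac = per_site_pi(g, idx)
    seg = _segregating(an, ac)
    rows = []
    for chrom in pd.unique(g.chrom):
        on = g.chrom == chrom
        if not on.any():
            continue
        last = int(g.pos[on].max())
        start = 1
        while start <= last:
            end = start + window_bp
            inw = on & (g.pos >= start) & (g.pos < end)
            snps = inw & seg
            s = int(snps.sum())
            if s >= 2:
                n = int(np.median(an[snps]))
                d = tajimas_d(s, float(pi_s[snps].sum()), n)
                defined = np.isfinite(d)
            else:
                d, defined = np.nan, False
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "S": s, "D": d, "defined": defined})
            start = end
    return pd.DataFrame(rows)


def d_tests(windows_a: pd.DataFrame, windows_b: pd.DataFrame | None = None) -> pd.DataFrame:
    """One-sample t vs 0 per window table; Welch two-sample t when two given."""
    rows = []

    def _usable(tab):
        d = tab.loc[tab["defined"], "D"].to_numpy(dtype=float)
        return d[np.isfinite(d)]

    da = _usable(windows_a)
    if len(da) < 2:
        raise ValueError("need >= 2 defined windows")
    for name, d in [("a", da)] + ([("b", _usable(windows_b))] if windows_b is not None else []):
        if np.std(d) == 0:
            rows.append({"test": f"one_sample_{name}", "mean_D": float(np.mean(d)),
                         "t": np.nan, "p": np.nan, "n": len(d), "degenerate": True})
            continue
        t, p = stats.ttest_1samp(d, 0.0)
        rows.append({"test": f"one_sample_{name}", "mean_D": float(np.mean(d)),
                     "t": float(t), "p": float(p), "n": len(d), "degenerate": False})
    if windows_b is not None:
        db = _usable(windows_b)
        if np.allclose(da, db) and len(da) == len(db):
            rows.append({"test": "two_sample", "mean_D": 0.0, "t": 0.0, "p": 1.0,
                         "n": len(da) + len(db), "degenerate": False})
        else:
            t, p = stats.ttest_ind(da, db, equal_var=False)
            rows.append({"test": "two_sample", "mean_D": float(np.mean(da) - np.mean(db)),
                         "t": float(t), "p": float(p), "n": len(da) + len(db),
                         "degenerate": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# urbanization regression (site-level linear model)
# ---------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    response: str
    predictor: str
    coefficients: dict[str, float]
    wald_chi2: float
    p: float
    r2: float
    n_sites: int


def urbanization_model(site_table: pd.DataFrame, response: str, predictor: str,
                       min_individuals: int = 2) -> ModelFitResult:
    """Linear model: response ~ predictor + n_individuals, on sampling sites.

    Sites with fewer than ``min_individuals`` genotyped individuals are
    excluded. The predictor's significance is the type-II Wald chi-square
    (single-df terms, so identical to the squared Wald z), mirroring an
    ANOVA with type-II sums of squares on a fixed-effects ML fit.
    """
    import statsmodels.api as sm

    tab = site_table[site_table["n_individuals"] >= min_individuals].dropna(
        subset=[response, predictor])
    if len(tab) < 3:
        raise ValueError("fewer than 3 usable sampling sites")
    x = sm.add_constant(tab[[predictor, "n_individuals"]].astype(float))
    fit = sm.OLS(tab[response].astype(float), x).fit()
    chi2 = float((fit.params[predictor] / fit.bse[predictor]) ** 2)
    p = float(stats.chi2.sf(chi2, df=1))
    return ModelFitResult(
        response=response, predictor=predictor,
        coefficients={k: float(v) for k, v in fit.params.items()},
        wald_chi2=chi2, p=p, r2=float(fit.rsquared), n_sites=len(tab),
    )
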