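"""Genotype matrices, VCF/metadata I/O, SNP filtering and relatedness pruning.

The pipeline starts from a called VCF of biallelic SNPs (GBS-style short
loci, one or a few SNPs each). Genotypes are stored as alternate-allele
counts in {0, 1, 2} with ``-1`` for missing calls. Each SNP belongs to a
locus; the per-locus number of genotyped nucleotide sites (variant plus
invariant) is carried separately so that per-site diversity statistics can
be scaled by the total amount of sequence actually genotyped, not just the
variant positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

METADATA_COLUMNS = ("sample_id", "site_id", "lat", "lon")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs with missingness and locus annotations.

    Attributes
    ----------
    genotypes : (n_individuals, n_snps) int8 array
        Count of the alternate allele per call; ``-1`` marks a missing call.
    individual_ids : list of str
        Unique sample identifiers, row-aligned with ``genotypes``.
    chrom, pos, ref, alt, locus_ids : per-SNP arrays
        Chromosome, 1-based position, alleles, and the locus each SNP
        belongs to. Positions are strictly increasing within a chromosome.
    locus_sites : dict
        locus id -> genotyped nucleotide sites (variant + invariant) for
        *all* loci, including loci whose SNPs were filtered out or that are
        monomorphic; the values sum to the total sequence length used to
        scale per-site diversity.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    locus_ids: np.ndarray
    locus_sites: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids must be unique")
        ok = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if self.genotypes.shape != (len(self.individual_ids), len(self.pos)):
            raise ValueError("genotypes shape does not match ids/snp table")
        for arr in (self.chrom, self.ref, self.alt, self.locus_ids):
            if len(arr) != len(self.pos):
                raise ValueError("per-SNP annotation length mismatch")
        if self.locus_sites:
            if any(v < 1 for v in self.locus_sites.values()):
                raise ValueError("sites per locus must be >= 1")

    # -- basic views ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def total_sites(self) -> int:
        """Total genotyped nucleotide sites across all loci."""
        if not self.locus_sites:
            raise ValueError("locus_sites not set; cannot scale per site")
        return int(sum(self.locus_sites.values()))

    def called(self) -> np.ndarray:
        return self.genotypes != MISSING

    def allele_counts(self, individuals: np.ndarray | None = None):
        """Return (alt copies, called copies) per SNP for a subset of rows."""
        g = self.genotypes if individuals is None else self.genotypes[individuals]
        called = g != MISSING
        ac = np.where(called, g, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        return ac.astype(np.int64), an.astype(np.int64)

    def alt_frequency(self, individuals: np.ndarray | None = None) -> np.ndarray:
        ac, an = self.allele_counts(individuals)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNP columns; locus_sites is kept (loci remain genotyped)."""
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            locus_ids=self.locus_ids[index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        ids = [self.individual_ids[i] for i in np.atleast_1d(index)]
        return replace(self, genotypes=self.genotypes[index], individual_ids=ids)

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "locus_id": self.locus_ids,
            }
        )


@dataclass
class FilterConfig:
    """SNP-dataset filtering thresholds.

    ``mmaf`` is a minor-allele-frequency floor computed on non-missing
    allele copies; ``r`` is the minimum fraction of individuals with a
    valid call; ``single_snp_per_locus`` keeps only the first-position SNP
    of each locus (the short-locus linkage-pruning convention).
    """

    mmaf: float = 0.0
    r: float = 0.0
    single_snp_per_locus: bool = False
    relatedness_bounds: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mmaf <= 0.5:
            raise ValueError("mmaf must be in [0, 0.5]")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in (0, 1]")
        low, high = self.relatedness_bounds
        if not (0.0 <= low < high <= 1.0):
            raise ValueError("relatedness bounds must satisfy 0 <= low < high <= 1")

    @classmethod
    def permissive(cls, n_individuals: int) -> "FilterConfig":
        """Rare-variant-retaining settings: mmaf = 2/n individuals, R = 0.5.

        Keeps a SNP as long as the minor allele is present in at least two
        individuals of a fully genotyped sample.
        """
        return cls(mmaf=2.0 / n_individuals, r=0.5, single_snp_per_locus=True)

    @classmethod
    def strict(cls) -> "FilterConfig":
        """Structure-analysis settings: mmaf = 0.05, R = 0.75."""
        return cls(mmaf=0.05, r=0.75, single_snp_per_locus=True)


# ---------------------------------------------------------------------------
# VCF / metadata I/O
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample table (sample_id, site_id, lat, lon[, urban_score])."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vcf(path, metadata: pd.DataFrame | None = None, locus_span: int = 1000,
             locus_sites: dict[str, int] | None = None,
             default_locus_length: int = 74) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (count logged). The locus
    id is the VCF ID field when present, otherwise ``chrom:floor(pos/locus_span)``.
    ``locus_sites`` optionally supplies genotyped site counts per locus
    (e.g. from a loci table written alongside a simulated VCF); loci without
    an entry get ``default_locus_length``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if metadata is not None:
        known = set(metadata["sample_id"].astype(str))
        for s in samples:
            if s not in known:
                raise ValueError(f"VCF sample {s!r} absent from metadata")

    # cyvcf2 gts012 codes: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
    code_map = np.array([0, 1, 2, MISSING], dtype=np.int8)

    cols, chrom, pos, ref, alt, loci = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        cols.append(code_map[np.asarray(v.gt_types)])
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        lid = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS // locus_span}"
        loci.append(lid)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not cols:
        raise ValueError(f"no biallelic SNPs found in {path}")

    geno = np.stack(cols, axis=1)
    sites = dict(locus_sites) if locus_sites else {}
    for lid in loci:
        sites.setdefault(lid, default_locus_length)
    g = GenotypeMatrix(geno, samples, chrom, pos, ref, alt, loci, sites)
    return sort_by_position(g)


def sort_by_position(g: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((g.pos, g.chrom.astype(str)))
    return g.take_snps(order)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal, byte-deterministic VCF 4.2 with GT fields only."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=urbanpopgen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individual_ids) + "\n")
        for j in range(g.n_snps):
            calls = "\t".join(gt_str[int(c)] for c in g.genotypes[:, j])
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.locus_ids[j]}\t{g.ref[j]}\t"
                     f"{g.alt[j]}\t.\tPASS\t.\tGT\t{calls}\n")


def write_loci_table(g: GenotypeMatrix, path) -> None:
    rows = sorted(g.locus_sites.items())
    pd.DataFrame(rows, columns=["locus_id", "n_sites"]).to_csv(path, sep="\t", index=False)


def read_loci_table(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    return dict(zip(df["locus_id"], df["n_sites"].astype(int)))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_snps(g: GenotypeMatrix, cfg: FilterConfig):
    """Apply MAF / completeness / one-SNP-per-locus filters.

    Returns ``(filtered, report)`` where report is a DataFrame with one row
    per removed SNP (chrom, pos, locus_id, reason_removed). An empty result
    triggers a warning, not an error.
    """
    ac, an = g.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    maf = np.fmin(p, 1.0 - p)
    call_frac = (g.genotypes != MISSING).sum(axis=0) / g.n_individuals

    reason = np.full(g.n_snps, "", dtype=object)
    # NaN MAF (zero called copies) fails any positive threshold
    fail_maf = np.where(np.isnan(maf), cfg.mmaf > 0, maf < cfg.mmaf).astype(bool)
    fail_call = call_frac < cfg.r
    reason[fail_call] = "callrate"
    reason[fail_maf] = "maf"  # maf reason wins when both fail
    keep = ~(fail_maf | fail_call)

    if cfg.single_snp_per_locus:
        # first SNP of each locus = smallest position; ties by (ref, alt)
        idx = np.flatnonzero(keep)
        order = sorted(idx, key=lambda j: (g.locus_ids[j], g.pos[j], g.ref[j], g.alt[j]))
        seen: set = set()
        for j in order:
            if g.locus_ids[j] in seen:
                keep[j] = False
                reason[j] = "not_first_in_locus"
            else:
                seen.add(g.locus_ids[j])

    removed = np.flatnonzero(~keep)
    report = pd.DataFrame(
        {
            "chrom": g.chrom[removed],
            "pos": g.pos[removed],
            "locus_id": g.locus_ids[removed],
            "reason_removed": reason[removed],
        }
    )
    if not keep.any():
        logger.warning("filter_snps removed every SNP")
    logger.info("filter_snps: retained %d of %d SNPs", int(keep.sum()), g.n_snps)
    return g.take_snps(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def pairwise_relatedness(g: GenotypeMatrix, method: str = "pi_hat") -> pd.DataFrame:
    """Method-of-moments IBD-sharing estimate for every individual pair.

    ``pi_hat`` solves the three-point IBS/IBD moment equations per pair
    using sample allele frequencies (the PLINK ``--genome`` analogue):
    PI_HAT = P(IBD=2) + P(IBD=1)/2. ``ibs`` returns the plain mean identity
    fraction (shared alleles / 2) instead.
    """
    if method not in ("pi_hat", "ibs"):
        raise ValueError("method must be 'pi_hat' or 'ibs'")
    geno = g.genotypes
    n = g.n_individuals
    ac, an = g.allele_counts()
    p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    # expected IBS-state probabilities under IBD 0/1, with small-sample
    # factorial-moment corrections for the sample-estimated frequencies
    # (the PLINK --genome convention); x = alt copies, y = ref copies
    x, y, m = ac.astype(float), (an - ac).astype(float), an.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f4 = m * (m - 1) * (m - 2) * (m - 3)
        p2q2 = x * (x - 1) * y * (y - 1) / f4
        p3q = x * (x - 1) * (x - 2) * y / f4
        pq3 = x * y * (y - 1) * (y - 2) / f4
        pq = x * y / (m * (m - 1))
    pr_ibs0_z0 = 2.0 * p2q2
    pr_ibs1_z0 = 4.0 * p3q + 4.0 * pq3
    pr_ibs1_z1 = 2.0 * pq

    rows = []
    for i in range(n):
        gi = geno[i]
        for j in range(i + 1, n):
            gj = geno[j]
            both = (gi != MISSING) & (gj != MISSING) & np.isfinite(p) & (p > 0) & (p < 1)
            m = int(both.sum())
            if m == 0:
                rows.append((g.individual_ids[i], g.individual_ids[j], np.nan, 0))
                continue
            diff = np.abs(gi[both] - gj[both])
            if method == "ibs":
                est = float(np.mean((2 - diff) / 2.0))
            else:
                n0 = int(np.sum(diff == 2))
                n1 = int(np.sum(diff == 1))
                e0 = float(pr_ibs0_z0[both].sum())
                e1_z0 = float(pr_ibs1_z0[both].sum())
                e1_z1 = float(pr_ibs1_z1[both].sum())
                z0 = n0 / e0 if e0 > 0 else 0.0
                z1 = (n1 - z0 * e1_z0) / e1_z1 if e1_z1 > 0 else 0.0
                z0, z1 = max(z0, 0.0), max(z1, 0.0)
                if z0 + z1 > 1.0:
                    s = z0 + z1
                    z0, z1 = z0 / s, z1 / s
                z2 = 1.0 - z0 - z1
                est = z2 + z1 / 2.0
            rows.append((g.individual_ids[i], g.individual_ids[j], est, m))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "relatedness", "n_snps"])


def relatedness_prune(g: GenotypeMatrix, bounds: tuple[float, float] = (0.25, 0.75),
                      method: str = "pi_hat", min_snps: int = 1000):
    """Remove one member of each pair whose relatedness falls in ``bounds``.

    The member with more missing calls is dropped; ties go to the
    lexicographically larger id. Pairs sharing fewer than ``min_snps``
    informative markers are never acted on (the moment estimator's noise
    at a few hundred markers would flag unrelated pairs), and a warning is
    issued when that guard suppresses the whole pruning step. Returns
    ``(pruned, report)``.
    """
    import warnings

    low, high = bounds
    rel = pairwise_relatedness(g, method=method)
    n_missing = {iid: int((g.genotypes[k] == MISSING).sum())
                 for k, iid in enumerate(g.individual_ids)}
    removed: list[tuple[str, str, float]] = []
    gone: set[str] = set()
    enough = rel["n_snps"] >= min_snps
    if not enough.any():
        warnings.warn(f"relatedness pruning skipped: fewer than {min_snps} "
                      "shared markers per pair", stacklevel=2)
    flagged = rel[(rel["relatedness"] >= low) & (rel["relatedness"] <= high)
                  & enough]
    for _, row in flagged.sort_values(["id_a", "id_b"]).iterrows():
        a, b = row["id_a"], row["id_b"]
        if a in gone or b in gone:
            continue
        if n_missing[a] != n_missing[b]:
            drop = a if n_missing[a] > n_missing[b] else b
        else:
            drop = max(a, b)
        gone.add(drop)
        removed.append((drop, f"{a}|{b}", float(row["relatedness"])))
    keep_idx = np.array([k for k, iid in enumerate(g.individual_ids) if iid not in gone],
                        dtype=int)
    report = pd.DataFrame(removed, columns=["removed_id", "pair", "relatedness"])
    return g.take_individuals(keep_idx), report


# ---------------------------------------------------------------------------
# Grouped allele frequencies
# ---------------------------------------------------------------------------

def group_indices(g: GenotypeMatrix, assignment) -> dict[str, np.ndarray]:
    """Map group label -> row indices. ``assignment`` is a dict/Series
    keyed by individual id, or a sequence of labels aligned with rows."""
    if isinstance(assignment, (dict, pd.Series)):
        labels = [assignment[i] for i in g.individual_ids]
    else:
        labels = list(assignment)
        if len(labels) != g.n_individuals:
            raise ValueError("assignment length does not match individuals")
    out: dict[str, np.ndarray] = {}
    for lab in sorted(set(str(x) for x in labels)):
        out[lab] = np.flatnonzero([str(x) == lab for x in labels])
    return out


def allele_frequencies(g: GenotypeMatrix, assignment) -> pd.DataFrame:
    """Per-group per-SNP alternate-allele frequency and allele-copy count.

    Frequency is NaN (flagged undefined) where a group has zero called
    copies at a SNP.
    """
    groups = group_indices(g, assignment)
    frames = []
    for lab, idx in groups.items():
        ac, an = g.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        frames.append(pd.DataFrame({
            "group": lab,
            "chrom": g.chrom,
            "pos": g.pos,
            "alt_freq": freq,
            "n_copies": an,
        }))
    return pd.concat(frames, ignore_index=True)
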