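"""Coalescent-simulated GBS-style datasets with known truth.

Generates the statistical structure the analysis assumes: thousands of
short (74 nt) independent loci sampled from a piecewise-constant-Ne
coalescent (optionally two demes exchanging migrants), individuals spread
over an urban/rural sampling landscape around a city center, uniform
genotype missingness, and planted full-sib pairs. Every dataset is
regenerable byte-identically from its scenario and seed, which are written
to a truth sidecar together with the true Ne history and the island-model
F_ST expectation.

Scenario presets
----------------
``null_panmixia``  one panmictic population at constant Ne (labels are
                   arbitrary halves);
``fragmentation``  two demes with little exchange (scaled migration 4,
                   E[F_ST] ~ 1/(1+4) = 0.2);
``facilitation``   two demes with high exchange (scaled migration 24,
                   E[F_ST] ~ 0.04);
``decline``        one population that collapsed 100-fold 500 generations
                   ago.

The ``scaled_migration`` knob M is calibrated so that the two-deme Hudson
F_ST expectation is 1/(1+M): for a symmetric pair of demes of size N the
ratio of between- to within-deme coalescence times gives
F_ST = 1/(1+8Nm), so the per-lineage migration rate is set to m = M/(8N).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix
from . import urban_class

DEFAULT_MU = 1.8e-8
DEFAULT_LOCUS_LENGTH = 74
# constant-Ne default chosen so that ~2,000 loci at 40 sampled copies carry
# about 3,000 segregating sites (theta_W scale of a large outcrossing plant)
DEFAULT_NE = 65_000.0


@dataclass
class SimulationScenario:
    model: str = "null_panmixia"
    epochs: list = field(default_factory=lambda: [(0.0, DEFAULT_NE)])
    n_demes: int = 1
    scaled_migration: float = 0.0      # M with E[F_ST] = 1/(1+M) for 2 demes
    n_individuals: int = 20
    n_loci: int = 1000
    locus_length: int = DEFAULT_LOCUS_LENGTH
    locus_spacing: int = 1000
    mu: float = DEFAULT_MU
    seed: int = 1

    def __post_init__(self) -> None:
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("Ne must be positive")
        if self.scaled_migration < 0:
            raise ValueError("scaled migration must be >= 0")
        if self.locus_length < 1:
            raise ValueError("locus length must be >= 1")

    def truth(self) -> dict:
        exp_fst = (1.0 / (1.0 + self.scaled_migration)
                   if self.n_demes == 2 and self.scaled_migration > 0 else 0.0)
        return {
            "scenario": {**asdict(self), "epochs": [list(e) for e in self.epochs]},
            "true_ne_trajectory": [list(e) for e in self.epochs],
            "expected_fst": exp_fst,
        }


def scenario_preset(name: str, **overrides) -> SimulationScenario:
    presets = {
        "null_panmixia": dict(model="null_panmixia", epochs=[(0.0, DEFAULT_NE)],
                              n_demes=1, scaled_migration=0.0),
        "fragmentation": dict(model="fragmentation", epochs=[(0.0, DEFAULT_NE)],
                              n_demes=2, scaled_migration=4.0),
        "facilitation": dict(model="facilitation", epochs=[(0.0, DEFAULT_NE)],
                             n_demes=2, scaled_migration=24.0),
        "decline": dict(model="decline",
                        epochs=[(0.0, 1_000.0), (500.0, 100_000.0)],
                        n_demes=1, scaled_migration=0.0),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario preset {name!r}; "
                         f"choose from {sorted(presets)}")
    kw = presets[name]
    kw.update(overrides)
    return SimulationScenario(**kw)


def _demography(scn: SimulationScenario):
    import msprime

    demog = msprime.Demography()
    if scn.n_demes == 1:
        demog.add_population(name="pop0", initial_size=scn.epochs[0][1])
        for start, ne in scn.epochs[1:]:
            demog.add_population_parameters_change(time=start, initial_size=ne,
                                                   population="pop0")
    elif scn.n_demes == 2:
        ne = scn.epochs[0][1]
        demog.add_population(name="pop0", initial_size=ne)
        demog.add_population(name="pop1", initial_size=ne)
        m = scn.scaled_migration / (8.0 * ne) if scn.scaled_migration > 0 else 0.0
        demog.set_symmetric_migration_rate(["pop0", "pop1"], m)
        for start, ne_t in scn.epochs[1:]:
            for p in ("pop0", "pop1"):
                demog.add_population_parameters_change(time=start, initial_size=ne_t,
                                                       population=p)
    else:
        raise ValueError("only 1 or 2 demes supported")
    return demog


def simulate_coalescent(scn: SimulationScenario):
    """Simulate independent short loci; returns (GenotypeMatrix, truth dict).

    One genealogy per locus (no intra-locus recombination), infinite-sites
    mutations mapped to distinct integer positions within the locus; if a
    locus accrues more mutations than nucleotide sites the surplus is
    dropped and counted in the truth record (finite-sites fallback). Loci
    are laid on one chromosome every ``locus_spacing`` bp so windowed
    statistics see a realistic position axis. Diploids are formed by
    msprime's individual pairing; for two demes the first half of
    individuals sit in deme 0 ("urban"), the rest in deme 1 ("rural").
    """
    import msprime

    rng = np.random.default_rng(scn.seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    demog = _demography(scn)
    if scn.n_demes == 2:
        n0 = scn.n_individuals // 2
        samples = {"pop0": n0, "pop1": scn.n_individuals - n0}
    else:
        samples = {"pop0": scn.n_individuals}

    reps = msprime.sim_ancestry(
        samples=samples, demography=demog, sequence_length=scn.locus_length,
        ploidy=2, num_replicates=scn.n_loci, random_seed=int(anc_seed))

    cols, chrom, pos, loci = [], [], [], []
    locus_sites: dict[str, int] = {}
    n_overflow = 0
    mut_rng = np.random.default_rng(mut_seed)
    n_hap = 2 * scn.n_individuals
    for li, ts in enumerate(reps):
        lid = f"L{li:06d}"
        locus_sites[lid] = scn.locus_length
        gm = _mutate_tree(ts, scn.mu * scn.locus_length, n_hap, mut_rng)
        if gm is None:
            continue
        nvar = gm.shape[0]
        keep = min(nvar, scn.locus_length)
        if nvar > scn.locus_length:
            n_overflow += nvar - scn.locus_length
            gm = gm[:keep]
        dip = gm[:, ::2] + gm[:, 1::2]             # individuals are paired haplotypes
        ipos = np.sort(mut_rng.choice(scn.locus_length, size=keep, replace=False))
        base = li * scn.locus_spacing
        for s in range(keep):
            cols.append(dip[s].astype(np.int8))
            chrom.append("1")
            pos.append(base + int(ipos[s]) + 1)
            loci.append(lid)

    ids = [f"ind{k:04d}" for k in range(scn.n_individuals)]
    if cols:
        geno = np.stack(cols, axis=1)
    else:
        geno = np.zeros((scn.n_individuals, 0), dtype=np.int8)
    g = GenotypeMatrix(geno, ids, chrom, pos, ["A"] * len(pos), ["T"] * len(pos),
                       loci, locus_sites)
    truth = scn.truth()
    truth["n_overflow_mutations"] = n_overflow
    truth["deme_of"] = {iid: ("urban" if k < scn.n_individuals // 2 else "rural")
                        for k, iid in enumerate(ids)} if scn.n_demes == 2 else None
    return g, truth


def _mutate_tree(ts, theta_branch: float, n_hap: int, rng) -> np.ndarray | None:
    """Poisson infinite-sites mutations on a single-tree genealogy.

    Each mutation lands on a branch with probability proportional to its
    length and derives every leaf below it; returns a (sites x haplotypes)
    0/1 matrix, or None for a monomorphic locus. Statistically equivalent
    to a binary infinite-sites mutation pass over the tree sequence, but
    without per-locus table rebuilding.
    """
    tables = ts.tables
    child = tables.edges.child
    parent = tables.edges.parent
    time = tables.nodes.time
    lengths = time[parent] - time[child]
    total = float(lengths.sum())
    n_mut = rng.poisson(theta_branch * total)
    if n_mut == 0:
        return None
    # leaf sets per node: edges are sorted with children before parents
    desc = np.zeros((len(time), n_hap), dtype=bool)
    desc[np.arange(n_hap), np.arange(n_hap)] = True
    for e in range(len(child)):
        desc[parent[e]] |= desc[child[e]]
    hit = rng.choice(len(child), size=n_mut, p=lengths / total)
    return desc[child[hit]].astype(np.int8)


def simulate_two_habitat(scn: SimulationScenario):
    """Two-deme (or labelled-panmixia) dataset with urban/rural labels.

    Returns (GenotypeMatrix, labels array aligned to individuals, truth).
    """
    g, truth = simulate_coalescent(scn)
    half = scn.n_individuals // 2
    labels = np.array(["urban"] * half + ["rural"] * (scn.n_individuals - half),
                      dtype=object)
    return g, labels, truth


# ---------------------------------------------------------------------------
# sampling landscape
# ---------------------------------------------------------------------------

def _km_offset_to_latlon(lat0, lon0, dx_km, dy_km):
    lat = lat0 + dy_km / 111.32
    lon = lon0 + dx_km / (111.32 * np.cos(np.radians(lat0)))
    return lat, lon


def simulate_landscape(n_urban_sites: int = 63, n_rural_sites: int = 61,
                       transect: bool = False, seed: int = 1,
                       max_individuals_per_site: int = 5) -> pd.DataFrame:
    """Sampling-site layout around the city center.

    Urban sites occupy 2.5 km grid cells within 30 km of the center; rural
    sites occupy 10 km cells beyond 30 km. Each site holds 1-5 individuals
    separated by more than 3 m (distinct ramets). An optional transect adds
    sites spanning the gradient. A synthetic urbanization score (a noisy
    decreasing function of distance) is attached so score-based
    classification can be exercised.
    """
    if n_urban_sites < 1 or n_rural_sites < 1:
        raise ValueError("site counts must be >= 1")
    rng = np.random.default_rng(seed)
    lat0, lon0 = urban_class.CITY_CENTER

    def grid_cells(cell_km, r_lo, r_hi):
        coords = np.arange(-60.0, 60.0, cell_km) + cell_km / 2.0
        cells = [(x, y) for x in coords for y in coords
                 if r_lo <= np.hypot(x, y) <= r_hi]
        return cells

    urban_cells = grid_cells(2.5, 0.0, 28.0)
    rural_cells = grid_cells(10.0, 32.0, 58.0)
    if n_urban_sites > len(urban_cells) or n_rural_sites > len(rural_cells):
        raise ValueError("requested more sites than grid cells available")

    rows = []
    site_no = 0

    def add_site(x_km, y_km, jitter_km):
        nonlocal site_no
        site_no += 1
        sid = f"S{site_no:03d}"
        sx = x_km + rng.uniform(-jitter_km, jitter_km)
        sy = y_km + rng.uniform(-jitter_km, jitter_km)
        n_ind = int(rng.integers(1, max_individuals_per_site + 1))
        placed: list[tuple[float, float]] = []
        while len(placed) < n_ind:
            ox, oy = rng.uniform(-0.05, 0.05, size=2)   # within ~100 m
            if all(np.hypot(ox - px, oy - py) * 1000.0 > 3.0 for px, py in placed):
                placed.append((ox, oy))
        for k, (ox, oy) in enumerate(placed):
            lat, lon = _km_offset_to_latlon(lat0, lon0, sx + ox, sy + oy)
            d = np.hypot(sx + ox, sy + oy)
            score = (30.0 - d) / 10.0 + rng.normal(0.0, 0.5)
            rows.append({"sample_id": f"{sid}_{k}", "site_id": sid,
                         "lat": lat, "lon": lon, "urban_score": score})

    for x, y in [urban_cells[i] for i in rng.choice(len(urban_cells),
                                                    n_urban_sites, replace=False)]:
        add_site(x, y, 0.9)
    for x, y in [rural_cells[i] for i in rng.choice(len(rural_cells),
                                                    n_rural_sites, replace=False)]:
        add_site(x, y, 3.5)
    if transect:
        for d in np.linspace(5, 55, 11):
            add_site(d, 0.0, 0.5)
    frame = pd.DataFrame(rows)
    return urban_class.classify_habitat(frame)


# ---------------------------------------------------------------------------
# missingness and sib planting
# ---------------------------------------------------------------------------

def add_missingness_and_sibs(g: GenotypeMatrix, miss_rate: float = 0.0,
                             n_sib_pairs: int = 0, seed: int = 1):
    """Mask genotypes uniformly and plant full-sib pairs.

    Each sib pair is Mendelian-sampled from a random parent pair and
    overwrites that same parent pair's rows (so the only planted
    relationship is the full sibship itself). Returns ``(matrix, info)``
    where info lists the planted pair ids.
    """
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    geno = g.genotypes.copy()
    info = {"sib_pairs": []}

    def gamete(parent_row):
        # transmit one allele per SNP: het -> coin flip
        out = np.where(parent_row == 1, rng.integers(0, 2, size=len(parent_row)),
                       parent_row // 2)
        return np.where(parent_row == MISSING, rng.integers(0, 2, len(parent_row)), out)

    used: set[int] = set()
    for _ in range(n_sib_pairs):
        free = [i for i in range(g.n_individuals) if i not in used]
        if len(free) < 2:
            raise ValueError("not enough individuals to plant sib pairs")
        pa, pb = rng.choice(free, size=2, replace=False)
        used.update((pa, pb))
        for child in (pa, pb):
            geno[child] = (gamete(g.genotypes[pa]) + gamete(g.genotypes[pb])).astype(np.int8)
        info["sib_pairs"].append((g.individual_ids[pa], g.individual_ids[pb]))

    if miss_rate > 0:
        mask = rng.random(geno.shape) < miss_rate
        geno[mask] = MISSING
    out = GenotypeMatrix(geno, list(g.individual_ids), g.chrom, g.pos, g.ref,
                         g.alt, g.locus_ids, g.locus_sites)
    return out, info


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
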