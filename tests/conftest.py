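import numpy as np
import pytest

from urbanpopgen.geno_io import MISSING, GenotypeMatrix

M = MISSING


def make_matrix(geno, pos=None, loci=None, locus_len=74, ids=None, chrom="1"):
    geno = np.asarray(geno, dtype=np.int8)
    n, s = geno.shape
    if pos is None:
        pos = np.arange(1, s + 1)
    if loci is None:
        loci = [f"L{j:04d}" for j in range(s)]
    if ids is None:
        ids = [f"i{k:03d}" for k in range(n)]
    sites = {lid: locus_len for lid in loci}
    return GenotypeMatrix(geno, ids, [chrom] * s, pos, ["A"] * s, ["T"] * s,
                          loci, sites)


# 20-SNP fixture with hand-enumerated filtering outcomes (8 individuals).
# Columns: (pos, locus, genotypes). Expected retained positions:
#   permissive analogue (mmaf=2/16=0.125, R=0.5, one SNP/locus):
#       50 110 205 330 490 610 722 944 1065 1175
#   strict analogue (mmaf=0.05, R=0.75, one SNP/locus):
#       50 110 220 330 490 540 610 722 833 944 1065 1175
TOY_COLUMNS = [
    (50, "L01", [1, 1, 0, 0, 0, 0, 0, 0]),
    (100, "L01", [1, 0, 0, 0, 0, 0, 0, 0]),
    (110, "L02", [2, 1, 0, 0, 0, 0, 0, 0]),
    (205, "L03", [1, M, M, M, M, 0, 0, 0]),
    (220, "L03", [1, 1, 1, 0, 0, 0, 0, 0]),
    (307, "L04", [0, 0, 0, 0, 0, 0, 0, 0]),
    (330, "L04", [1, 1, 1, 1, 0, 0, 0, 0]),
    (411, "L05", [M, M, M, M, M, 1, 0, 0]),
    (490, "L05", [0, 1, 1, 0, 0, 0, 1, 0]),
    (540, "L06", [2, 2, 2, 2, 2, 2, 2, 1]),
    (560, "L06", [2, 2, 2, 2, 2, 2, 2, 2]),
    (610, "L07", [0, 0, 1, 1, 1, 1, 0, 0]),
    (615, "L07", [1, 1, 0, 0, M, M, 0, 0]),
    (722, "L08", [M, M, 1, 1, 1, 0, 0, 0]),
    (833, "L09", [0, 0, 0, 0, 1, 0, M, M]),
    (944, "L10", [1, 0, 1, 0, 1, 0, 1, M]),
    (1055, "L11", [M, M, M, M, M, M, M, M]),
    (1065, "L11", [0, 1, 0, 0, 0, 0, 0, 1]),
    (1175, "L12", [2, 0, 2, 0, 2, 0, 2, 0]),
    (1180, "L12", [0, 0, 1, 1, 0, 0, 1, 1]),
]

TOY_EXPECTED_PERMISSIVE = [50, 110, 205, 330, 490, 610, 722, 944, 1065, 1175]
TOY_EXPECTED_STRICT = [50, 110, 220, 330, 490, 540, 610, 722, 833, 944, 1065, 1175]


@pytest.fixture
def toy20():
    pos = [c[0] for c in TOY_COLUMNS]
    loci = [c[1] for c in TOY_COLUMNS]
    geno = np.array([c[2] for c in TOY_COLUMNS], dtype=np.int8).T
    return make_matrix(geno, pos=pos, loci=loci)


@pytest.fixture(scope="session")
def small_panmictic():
    """One modest constant-Ne coalescent dataset shared across tests."""
    from urbanpopgen import simulate as sim

    scn = sim.scenario_preset("null_panmixia", n_individuals=20, n_loci=600, seed=11)
    g, truth = sim.simulate_coalescent(scn)
    return g, truth
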