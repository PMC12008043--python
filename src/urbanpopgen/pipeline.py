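"""Configuration-driven orchestration of the full analysis.

A run starts either from a VCF + metadata pair or from a named simulation
scenario, then executes: filtering into a permissive dataset (rare
variants kept; diversity and demography) and a strict dataset (structure
analyses and F_IS, mirroring the two-criteria design), habitat
classification under both schemes, diversity statistics and windowed
Tajima's D with t-tests, pairwise Hudson F_ST with group means, AMOVA /
PERMANOVA / PERMDISP, PCA + Mantel correlogram + MEM, folded-SFS Ne
reconstruction, and the breakpoint period table. Every output is a TSV or
JSON written with fixed formatting so a rerun with the same config is
byte-identical; seeds and parameters are logged to ``run.log`` (no
timestamps, for the same reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (breakpoints as bp, demography as dem, differentiation as diff,
               diversity as div, geno_io, simulate as sim, spatial, urban_class)

logger = logging.getLogger("urbanpopgen.pipeline")

FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunConfig:
    outdir: str = "results"
    seed: int = 1
    # exactly one of (vcf, scenario) must be set
    vcf: str | None = None
    metadata: str | None = None
    loci_table: str | None = None
    scenario: str | None = None
    n_loci: int = 500
    n_individuals: int = 40
    n_perm: int = 199
    n_bootstrap: int = 50
    projection: int | None = None
    k_breakpoints: int = 4
    miss_rate: float = 0.1
    mu: float = sim.DEFAULT_MU
    gen_time: float = 2.0
    run_demography: bool = True
    run_structure: bool = True

    def __post_init__(self) -> None:
        if (self.vcf is None) == (self.scenario is None):
            raise ValueError("exactly one of vcf/scenario must be given")
        if self.vcf is not None and self.metadata is None:
            raise ValueError("metadata path required with a VCF input")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a dict of the key result objects."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("urbanpopgen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {"config": dataclasses.asdict(cfg)}
    try:
        return _run(cfg, out, results)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path, results: dict) -> dict:
    logger.info("run config: %s", json.dumps(dataclasses.asdict(cfg), sort_keys=True))

    # ---- stage: input --------------------------------------------------
    if cfg.scenario is not None:
        scn = sim.scenario_preset(cfg.scenario, n_loci=cfg.n_loci,
                                  n_individuals=cfg.n_individuals,
                                  mu=cfg.mu, seed=cfg.seed)
        g, truth = sim.simulate_coalescent(scn)
        g, _ = sim.add_missingness_and_sibs(g, miss_rate=cfg.miss_rate,
                                            seed=cfg.seed + 1)
        n_sites = max(2 * cfg.n_individuals // 3, 2)
        meta = sim.simulate_landscape(
            n_urban_sites=max(n_sites // 2, 1),
            n_rural_sites=max(n_sites - n_sites // 2, 1), seed=cfg.seed + 2)
        meta = _attach_samples(meta, g, truth, cfg.seed + 3)
        geno_io.write_vcf(g, out / "simulated.vcf")
        geno_io.write_loci_table(g, out / "loci.tsv")
        sim.write_truth(truth, out / "truth.json")
    else:
        meta = geno_io.read_metadata(cfg.metadata)
        loci = geno_io.read_loci_table(cfg.loci_table) if cfg.loci_table else None
        g = geno_io.read_vcf(cfg.vcf, metadata=meta, locus_sites=loci)
        meta = urban_class.classify_habitat(meta)
    geno_io.write_metadata(meta, out / "metadata_classified.tsv")

    # ---- stage: relatedness pruning ------------------------------------
    g, prune_report = geno_io.relatedness_prune(g)
    _write(prune_report, out / "relatedness_removals.tsv")
    meta = meta[meta["sample_id"].isin(g.individual_ids)].reset_index(drop=True)

    # ---- stage: filtering (permissive + strict datasets) ---------------
    ds1, rep1 = geno_io.filter_snps(g, geno_io.FilterConfig.permissive(g.n_individuals))
    ds2, rep2 = geno_io.filter_snps(g, geno_io.FilterConfig.strict())
    _write(rep1, out / "filter_report_permissive.tsv")
    _write(rep2, out / "filter_report_strict.tsv")
    results["n_snps"] = {"input": g.n_snps, "permissive": ds1.n_snps,
                         "strict": ds2.n_snps}

    habitat = dict(zip(meta["sample_id"], meta["habitat_by_distance"]))
    site_of = dict(zip(meta["sample_id"], meta["site_id"]))
    site_habitat = dict(zip(meta["site_id"], meta["habitat_by_distance"]))

    # ---- stage: diversity (permissive dataset; F_IS from strict) -------
    tab_all = div.diversity_table(ds1)
    tab_hab = div.diversity_table(ds1, habitat)
    fis_strict = div.diversity_table(ds2, habitat)[["unit", "f_is"]]
    table1 = pd.concat([tab_all, tab_hab], ignore_index=True)
    table1 = table1.merge(fis_strict.rename(columns={"f_is": "f_is_strict"}),
                          on="unit", how="left")
    groups = geno_io.group_indices(ds1, habitat)
    dtabs = {}
    for lab, idx in groups.items():
        dtabs[lab] = div.tajimas_d_windows(ds1, idx)
        _write(dtabs[lab], out / f"tajima_windows_{lab}.tsv")
    labs = sorted(dtabs)
    if len(labs) == 2 and all(dtabs[l]["defined"].sum() >= 2 for l in labs):
        ttab = div.d_tests(dtabs[labs[0]], dtabs[labs[1]])
        _write(ttab, out / "tajima_tests.tsv")
        for lab in labs:
            d = dtabs[lab].loc[dtabs[lab]["defined"], "D"]
            table1.loc[table1["unit"] == lab, "mean_D"] = d.mean()
    _write(table1, out / "diversity_table.tsv")
    results["diversity"] = table1

    # ---- stage: differentiation & spatial (strict dataset) -------------
    if cfg.run_structure:
        fst = diff.fst_matrix(ds2, site_of, habitat=site_habitat)
        fst.matrix.to_csv(out / "fst_matrix.tsv", sep="\t", float_format=FLOAT_FMT)
        _write(pd.DataFrame(sorted(fst.group_means.items()),
                            columns=["pair", "mean_fst"]), out / "fst_group_means.tsv")
        results["fst_group_means"] = fst.group_means

        am = diff.amova(ds2, site_of, habitat, n_perm=cfg.n_perm, seed=cfg.seed + 10)
        _write(am.table, out / "amova.tsv")
        results["amova"] = am

        x = diff.imputed_allele_matrix(ds2)
        d = diff.euclidean_distance_matrix(x)
        labels = [habitat[i] for i in ds2.individual_ids]
        f_perm, p_perm = diff.permanova(d, labels, n_perm=cfg.n_perm,
                                        seed=cfg.seed + 11)
        f_disp, p_disp = diff.permdisp(d, labels, n_perm=cfg.n_perm,
                                       seed=cfg.seed + 12)
        _write(pd.DataFrame([
            {"test": "PERMANOVA", "statistic": f_perm, "p": p_perm},
            {"test": "PERMDISP", "statistic": f_disp, "p": p_disp},
        ]), out / "permutation_tests.tsv")

        scores, var_frac = spatial.pca_genotypes(ds2, n_components=5)
        pca_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
        pca_df.insert(0, "sample_id", ds2.individual_ids)
        _write(pca_df, out / "pca_scores.tsv")

        site_meta = meta.drop_duplicates("site_id")
        # one individual per site for the main spatial analysis
        first_by_site = meta.groupby("site_id")["sample_id"].first()
        keep = [i for i, iid in enumerate(ds2.individual_ids)
                if iid in set(first_by_site)]
        sub = ds2.take_individuals(np.asarray(keep, dtype=int))
        sub_sites = [site_of[i] for i in sub.individual_ids]
        coords = site_meta.set_index("site_id").loc[sub_sites, ["lat", "lon"]]
        geo = urban_class.haversine_km(coords["lat"].values[:, None],
                                       coords["lon"].values[:, None],
                                       coords["lat"].values[None, :],
                                       coords["lon"].values[None, :])
        gen_d = diff.euclidean_distance_matrix(diff.imputed_allele_matrix(sub))
        corr = spatial.mantel_correlogram(gen_d, geo, n_perm=cfg.n_perm,
                                          seed=cfg.seed + 13)
        _write(corr, out / "mantel_correlogram.tsv")
        mem = spatial.mem_analysis(sub, geo, n_perm=cfg.n_perm, seed=cfg.seed + 14)
        _write(pd.DataFrame([{"n_candidates": mem.n_candidates,
                              "n_selected": len(mem.selected),
                              "r2_adj": mem.r2_adj, "verdict": mem.verdict}]),
               out / "mem_report.tsv")
        results["mem"] = mem

    # ---- stage: demography + breakpoints (permissive dataset) ----------
    if cfg.run_demography:
        sfs = dem.build_folded_sfs(ds1, n_chrom=cfg.projection, seed=cfg.seed + 20)
        np.savetxt(out / "folded_sfs.txt", sfs.counts[None, :], fmt="%.10g",
                   header=f"n_chrom={sfs.n_chrom} L={sfs.total_sites}")
        dcfg = dem.DemographyConfig(mu=cfg.mu, gen_time=cfg.gen_time,
                                    n_bootstrap=cfg.n_bootstrap, seed=cfg.seed + 21)
        traj = dem.infer_ne_trajectory(sfs, dcfg)
        _write(traj.to_frame(), out / "ne_trajectory.tsv")
        series = bp.subsample_years(traj)
        model = bp.fit_piecewise(series, k_breakpoints=cfg.k_breakpoints)
        _write(model.to_frame(), out / "breakpoint_periods.tsv")
        results["trajectory"] = traj
        results["breakpoints"] = model

    logger.info("pipeline complete")
    return results


def _attach_samples(meta: pd.DataFrame, g, truth: dict, seed: int) -> pd.DataFrame:
    """Assign simulated individuals to landscape sampling sites.

    Two-deme simulations place deme-0 individuals at urban sites and
    deme-1 individuals at rural sites; panmictic simulations assign sites
    in order. The metadata is trimmed so each individual appears once.
    """
    rng = np.random.default_rng(seed)
    meta = meta.copy()
    # interleave habitats so panmictic individuals spread over both label
    # classes rather than filling the urban block first
    meta = (meta.assign(_rank=meta.groupby("habitat_by_distance").cumcount())
            .sort_values(["_rank", "habitat_by_distance", "site_id"])
            .drop(columns="_rank").reset_index(drop=True))
    deme_of = truth.get("deme_of")
    ids = list(g.individual_ids)
    rows = []
    if deme_of:
        pools = {"urban": [i for i in ids if deme_of[i] == "urban"],
                 "rural": [i for i in ids if deme_of[i] == "rural"]}
    else:
        pools = {"any": ids[:]}
    for _, row in meta.iterrows():
        if deme_of:
            pool = pools[row["habitat_by_distance"]]
        else:
            pool = pools["any"]
        if not pool:
            continue
        iid = pool.pop(0)
        r = row.copy()
        r["sample_id"] = iid
        rows.append(r)
    leftovers = [i for p in pools.values() for i in p]
    # park any unassigned individuals at extra copies of existing sites
    base = meta.drop_duplicates("site_id")
    while leftovers:
        row = base.iloc[int(rng.integers(0, len(base)))].copy()
        if deme_of and deme_of[leftovers[0]] != row["habitat_by_distance"]:
            continue
        row["sample_id"] = leftovers.pop(0)
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out[[c for c in out.columns]]
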