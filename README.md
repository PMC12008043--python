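# urbanpopgen

Population-genomic analysis of reduced-representation (GBS) SNP data
sampled along an urbanization gradient, built around one question: does a
plant population spanning a metropolitan area behave as one panmictic
population whose effective size (Ne) has been reshaped by human activity,
or as urban and rural fragments diverging in diversity and structure?

The package takes a VCF of biallelic SNPs plus a sample table
(site, coordinates, optional urbanization score) and provides:

- **Filtering** — MAF / completeness / one-SNP-per-locus filters in the
  two-dataset design (permissive for diversity and demography, strict for
  structure), and method-of-moments relatedness pruning (PI_HAT-style).
- **Urban/rural classification** — great-circle distance to the city
  center (urban iff <= 30 km; Toronto's center 43.6563, -79.3809 is the
  default) and, when available, an urbanization score (urban iff > 0).
- **Diversity** — nucleotide diversity pi, Watterson's theta, observed and
  expected heterozygosity, F_IS, Tajima's D in 100 kb windows with one-
  and two-sample t-tests, and site-level regressions of diversity on
  urbanization (type-II Wald chi-square).
- **Differentiation** — pairwise Hudson F_ST (ratio of averages),
  hierarchical AMOVA on Euclidean allele-count distances with
  per-component permutation tests, PERMANOVA and PERMDISP.
- **Spatial structure** — genotype PCA, Mantel correlograms with
  progressive Holm correction, and Moran-eigenvector-map (MEM) forward
  selection against genotype PC scores.
- **Demography** — folded site-frequency spectra by hypergeometric
  projection and a stairway-style composite-likelihood reconstruction of
  the Ne history (Poisson likelihood linear in per-lineage-interval Ne,
  held-out complexity selection, bootstrap percentile trajectories).
- **Breakpoints** — segmented regression (Muggeo's iterative
  linearization) of ln(Ne) against years before sampling on the
  systematic 300-year subsampling grid; per-segment slopes b convert to
  growth rates r = -(e^b - 1) with endpoint-swapped CIs, delimiting
  periods of constant exponential growth or decline.
- **Synthetic data** — coalescent-simulated GBS datasets (msprime
  genealogies, infinite-sites mutations, 74 nt loci) with known truth:
  panmixia, two-deme fragmentation/facilitation, demographic decline, a
  city-centered sampling landscape, missingness, and planted sib pairs.

The model at the core of the breakpoint analysis: under exponential
change Ne_t = Ne_0 (1+r)^t, ln(Ne_t) is linear in t with slope
b = ln(1+r); periods of constant rate are linear segments of
ln(Ne) vs. years-before-present, and the sign of r is reverted because
the axis runs backwards in time.

See `docs/methods.md` for the full model descriptions, defaults, and
numerical choices.

## Worked example

Simulate a population that collapsed 100-fold five hundred generations
ago, reconstruct its history, and locate the change points:

```python
import numpy as np
from urbanpopgen import simulate as sim, demography as dem, breakpoints as bp

scn = sim.scenario_preset("decline", n_individuals=20, n_loci=24_000, seed=7)
g, truth = sim.simulate_coalescent(scn)           # 20 diploids, 74 nt loci
sfs = dem.build_folded_sfs(g, n_chrom=40, seed=8)
traj = dem.infer_ne_trajectory(sfs, dem.DemographyConfig(n_bootstrap=50, seed=9))

recent = np.median(traj.median_at(np.arange(1, 101)))
ancient = np.median(traj.median_at(np.linspace(5000, 15000, 50)))
print(f"recent Ne ~ {recent:.0f}, ancient Ne ~ {ancient:.0f}, "
      f"ratio {ancient / recent:.0f}")

model = bp.fit_piecewise(bp.subsample_years(traj), k_breakpoints=8)
print(model.to_frame()[["start_year", "end_year", "r", "r_lo", "r_hi"]])
```

which prints

```
recent Ne ~ 808, ancient Ne ~ 99045, ratio 123
    start_year      end_year         r      r_lo      r_hi
0     1.000000   1550.983857 -0.000000 -0.000001  0.000001
...
7  2776.974294   2911.233295 -0.033350 -0.033374 -0.033326
8  2911.233295  15000.000000 -0.000000 -0.000000 -0.000000
```

The truth was Ne 1,000 today against 100,000 anciently (ratio 100): the
reconstruction recovers the two plateaus, and the period table isolates a
segment with a strongly negative growth rate (r about -0.03 per year,
CI excluding zero) where the trajectory collapses — the decline, placed
at roughly twice 500 generations x 2 years/generation by the bootstrap
median's smoothing of the transition.

The same machinery runs end-to-end from the command line:

```sh
urbanpopgen run-all --preset decline --seed 11 --out results/
```

writing the diversity table, F_ST summaries, AMOVA/PERMANOVA/PERMDISP
tables, correlogram and MEM reports, the Ne trajectory, and the
breakpoint period table as TSV files.

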