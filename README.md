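# agecoex

Differential co-expression analysis of transcriptomic aging across cohorts.

`agecoex` is a Python re-implementation of the weighted gene co-expression
workflow used to study immune aging in PBMC transcriptomes: it discovers
co-expression modules, correlates their eigengenes with donor traits such
as age and sex, screens differentially expressed genes between young and
old donors, ranks hub genes on protein–protein interaction subnetworks,
tests gene-set over-representation, locates breakpoints in eigengene–age
trajectories, and extracts the aging signature shared between two cohorts.
A synthetic cohort generator with planted ground truth makes the entire
pipeline testable without any external data download. It is aimed at
computational biologists who want a scripted, reproducible, fully tested
version of this analysis rather than a chain of interactive tools.

## The method in brief

For a genes × samples expression matrix, Pearson correlations are raised
to a soft power β (chosen so the network's connectivity distribution
approaches scale-free topology, R² > 0.8), and genes are clustered on
`1 − TOM`, where the topological overlap

```
TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),   l_ij = Σ_u a_iu a_uj
```

rewards shared network neighbourhoods. Each module is summarised by its
eigengene (first principal component); near-duplicate modules (eigengene
r > 0.8) merge. Module–trait association is Pearson correlation with
p-values from `t = r·√(n−2)/√(1−r²)`. Differentially expressed genes
satisfy `|log2FC| ≥ 0.5` at Benjamini–Hochberg FDR < 0.05. Hubs are ranked
by Maximal Clique Centrality, `MCC(v) = Σ_{C∈S(v)} (|C|−1)!`, computed in
exact integer arithmetic over the maximal cliques S(v). Over-representation
uses the hypergeometric upper tail. Eigengene–age trajectories are fitted
as continuous piecewise-linear regressions with 0–2 breakpoints selected by
BIC. See `docs/methods.md` for assumptions, defaults and design decisions.

## Worked example

Simulate a cohort of 60 donors (ages 21–93) with ten planted 50-gene
modules — one with a linear age trend, one with a slope change at 70
years — plus 500 background genes, then fit the network model:

```python
from agecoex.simulate import default_modules, generate_cohort, generate_ppi
from agecoex.network import CoexpressionNetwork
from agecoex.hubs import rank_module_hubs
from agecoex.trajectory import fit_trajectory

m, truth = generate_cohort(500, default_modules(), n_samples=60, seed=1)
results = CoexpressionNetwork(m, truth.traits).fit(beta=6)
print(results.summary().round(3).to_string(index=False))
```

```
   module  n_genes  variance_explained  age_r  age_p
    black       50               0.750  0.031  0.813
     blue       50               0.732  0.775  0.000
    brown       50               0.730 -0.181  0.167
    green       50               0.738 -0.003  0.982
  magenta       50               0.696  0.220  0.092
     pink       50               0.747  0.049  0.708
      red       50               0.725 -0.102  0.439
turquoise       50               0.739  0.963  0.000
   yellow       50               0.739 -0.242  0.063
   purple       49               0.699  0.061  0.642
```

All ten planted modules are recovered (each eigengene explains ~70–75% of
its module's variance); exactly the two age-driven modules show significant
eigengene–age correlations (turquoise r = 0.963, blue r = 0.775). Fitting
their age trajectories recovers the planted trend shapes:

```python
for mod in ("turquoise", "blue"):
    fit = fit_trajectory(results.eigengenes.eigengenes.loc[mod], truth.traits.age)
    print(mod, fit.n_breaks, fit.breakpoints, [round(s, 3) for s in fit.segment_slopes])
```

```
turquoise: 0 breakpoint(s) at [], segment slopes [0.047]
blue: 1 breakpoint(s) at [70.0], segment slopes [0.0, 0.145]
```

The linear module selects zero breakpoints; the slope-change module places
its single breakpoint exactly at the planted age of 70. Ranking hubs on
the simulated PPI subnetwork of the top age module puts the planted hub
first, with the expected exact MCC score (two 6-cliques → 2·5! = 240, plus
background-edge cliques):

```python
ppi = generate_ppi(truth, seed=1)
print(rank_module_hubs(ppi, results.module_genes("turquoise"), k=3).to_string(index=False))
```

```
    gene  mcc  log10_mcc  degree
M01_0000  242   2.383815      10
M01_0002  122   2.086360       7
M01_0007  122   2.086360       7
```

The same stages are available from the shell (`agecoex simulate`,
`preprocess`, `network`, `deg`, `hubs`, `enrich`, `trajectory`, `compare`,
`run-all`); every subcommand writes TSV tables plus a JSON run summary and
is byte-reproducible for a fixed seed and configuration.

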