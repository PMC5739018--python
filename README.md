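# oligonet

Recurrent co-occurrence modules in amplicon time series.

Temperate coastal bacterioplankton communities respond to seasonal forcing
— spring/summer phytoplankton blooms, winter-high inorganic nutrients —
with shifts that recur year after year. `oligonet` is a Python library for
asking whether the *network structure* of such a community recurs too: do
the same guilds of co-varying taxa re-assemble each year, tracking the
same environmental drivers, with the same internal correlation structure?

It implements the full pipeline for two-year, weekly 16S-style surveys:

- **`simulate`** — a seasonal two-year community generator with planted
  co-varying modules, an environment table (temperature, chl *a*,
  nutrients, salinity), compositional multinomial counts and a read
  simulator, so every stage is testable against known truth;
- **`med`** — minimum-entropy decomposition of aligned amplicons into
  oligotypes (single-nucleotide resolution units): reads are split
  recursively at the highest-Shannon-entropy alignment column, filtered by
  a minimum substantive abundance `M` and a maximum variation from the
  node representative;
- **`preprocess`** — taxonomy-based removal, prevalence filtering, year
  intersection, and broad (>75% of samples) vs narrow (<10%) prevalence
  classification, with exact bookkeeping at each step;
- **`diversity`** — Hill numbers `D_q` (q = 0, 1, 2: richness,
  exponential Shannon, inverse Simpson) and Pielou evenness
  `J = H/ln S`;
- **`sparcc`** — compositionality-robust correlation inference: basis
  correlations from log-ratio variances `T_ij = Var ln(x_i/x_j)` under a
  sparsity assumption, averaged over posterior Dirichlet draws, with
  two-sided pseudo-*p*-values from column-permutation bootstraps;
- **`modules`** — per-year unsigned topological overlap matrices (TOM),
  quantile calibration between years, consensus TOM by parallel minimum,
  dynamic-cut module detection on `1 − TOM`, clr-based module eigengenes
  (first principal component of each module's member profiles) and
  eigengene-similarity merging;
- **`envassoc`** — redundancy analysis of eigengenes on standardized
  physicochemical variables and Spearman correlations with
  Benjamini–Hochberg FDR control;
- **`conserve`** — per-module |rho| threshold scans ("trim as much as
  possible without breaking the module network apart"), graph filtration,
  cross-year Venn-style intersection, and shared-vertex/-edge percentages.

See `docs/methods.md` for the models, parameter defaults and design
choices.

## Worked example

Recovering planted guilds end-to-end (`examples/05_consensus_modules.py`):

```python
import pandas as pd
import oligonet as on

spec = on.CommunitySimSpec(seed=1)          # 200 taxa, 4 planted modules
env = on.generate_env(spec)
t1, t2, truth = on.generate_community(spec, env)

net1 = on.sparcc(t1.counts, seed=11)        # per-year basis correlations
net2 = on.sparcc(t2.counts, seed=12)
tom1 = on.tom_similarity(on.rescale_cor(net1.rho.to_numpy()))
tom2 = on.tom_similarity(on.rescale_cor(net2.rho.to_numpy()))
consensus = on.consensus_tom(tom1, on.scale_tom(tom2, tom1))

detected = on.detect_modules(consensus, ids=pd.Index(t1.counts.columns))
merged = on.merge_modules(detected, {1: on.clr_transform(t1),
                                     2: on.clr_transform(t2)})
```

Running the script prints:

```
detected 5 modules, 5 after merging
module sizes: {1: 52, 2: 43, 3: 41, 4: 41, 5: 23}
adjusted Rand index vs planted truth (module taxa): 1.000
```

The four planted guilds are recovered exactly (the fifth cluster collects
background taxa); an adjusted Rand index of 1.0 means the consensus-TOM
partition of module taxa coincides with the planted truth. The companion
scripts show each stage in isolation — e.g.
`examples/06_environment_association.py` prints each module eigengene's
strongest Spearman partner, which is its planted driver in both years
(temperature, chl *a*, DIN, salinity; all BH-adjusted p < 1e-20), and
`examples/07_module_conservation.py` shows the perturbed module dropping
to 10% shared edges while intact modules keep ~30-45%.

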