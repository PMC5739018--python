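# Methods

`oligonet` implements an analysis pipeline for multi-year, high-frequency
amplicon surveys of microbial communities: it resolves fine-scale taxonomic
units from aligned reads, characterises prevalence and diversity, infers
compositionality-robust co-occurrence networks for each year, detects
consensus modules of co-varying taxa across years, associates each module's
eigengene with environmental drivers, and quantifies how well each module's
internal correlation structure is conserved from one year to the next.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Synthetic community generator

The generator (`simulate`) exists so that every downstream stage can be
tested against known truth. It emulates a temperate coastal two-year weekly
time series:

- **Sampling grid.** Two "years" of `samples_per_year` samples (default 50)
  every 7 days starting at day 4, mirroring evenly spaced weekly sampling.
- **Environment.** Temperature is a sinusoid (mean 10 °C, amplitude 6 °C,
  peak near day 200); chlorophyll *a* is a baseline plus Gaussian
  spring/summer pulses (days 125 and 215); inorganic nutrients (DIN, SiO2,
  PO4) are winter-high sinusoids depleted proportionally to chlorophyll and
  floored at zero; salinity is a weak sinusoid. Nutrient phases and
  chlorophyll-coupling strengths deliberately differ per species
  (differential uptake and remineralisation), so the nutrients correlate
  strongly without being collinear — otherwise the planted "nutrient"
  driver would be unidentifiable in principle. Each variable carries
  Gaussian observation noise scaled to its amplitude (`env_noise_sd`,
  default 0.05).
- **Community.** Each taxon belongs to one of `n_modules` guilds (default
  4 × 40 taxa) or to a low-abundance background pool (default 40 taxa).
  The latent log-abundance is
  `lambda_it = b_i + l_i * g_m(i)(t) + e_it`
  with baseline `b_i ~ N(0, 0.5)` for module taxa and `N(-2, 0.5)` for
  background, loading `l_i ~ U(0.75, 1.25)` (0 for background), `g_m` the
  z-scored driver series of module *m* (temperature, chl a, DIN or
  salinity by default), and `e_it` stationary AR(1) noise (marginal SD
  0.3, lag-1 correlation 0.5). Relative abundances are the softmax of
  `lambda` (closure), and counts are `Multinomial(depth, p_t)` with
  default depth 5,000 reads — a desk-scale stand-in for ~90k-read
  sequencing depth; depth is a knob, optionally with a lognormal
  per-sample multiplier (`depth_cv`). Softmax closure was chosen over
  Dirichlet draws so that planted correlations are controlled directly.
- **Perturbed module.** With `perturb_module` set, that module's year-2
  loadings are re-drawn from the symmetric range `U(-l_max, l_max)`: the
  guild persists but its internal correlation structure changes sign and
  strength member-by-member, modelling a poorly conserved summer guild.
- **Reads.** `generate_reads` emits aligned reads from equal-length
  templates with independent per-base substitution errors (gaps are never
  mutated) and records each read's template of origin.

What the generator does **not** emulate: predator/phage dynamics, real
sequence evolution, primer bias, uneven or missing sampling, taxon-specific
overdispersion beyond AR(1)-plus-multinomial noise. Passing recovery tests
therefore show that the pipeline's inference is correct under its own
statistical assumptions, not that those assumptions exhaust real data.

## Entropy decomposition (`med`)

Aligned, equal-length reads over {A,C,G,T,-} are partitioned recursively at
the single highest-entropy alignment column (ties to the lowest index, for
determinism; gaps count as a fifth state; entropies are
multiplicity-weighted Shannon entropies in bits). Splitting stops when the
maximum column entropy falls below `entropy_floor` (default 0.1 bits — the
iterative stop needs a floor, and 0.1 bits corresponds to a minor-allele
frequency of ~1%, well below the abundance filter's reach). Residue classes
whose total count cannot reach the minimum substantive abundance `M`
(default 100) are routed to the outlier pool immediately; terminal nodes
whose most abundant unique sequence falls below `M` are dissolved likewise;
within surviving nodes, reads more than `max_variation` mismatches from the
node representative (default `round(L/100)`, i.e. linear in read length)
become `max-variation` outliers. Node + outlier counts always add up to the
input read count — an invariant that is asserted after every run. An
off-by-default `relocate_outliers` flag reassigns outliers to the nearest
node representative within `max_variation`. Only `d=1` (one position per
split) is supported.

Taxonomy handling is reduced to the decision rule
`(identity + coverage)/2 >= 93%` (a database "match" versus "no relative");
database search itself is out of scope.

## Diversity (`diversity`)

Empirical (plug-in) Hill numbers only: richness (q=0), exponential Shannon
(q=1) and inverse Simpson (q=2), all in effective-species units, and
Pielou's `J = H/ln(S)` with natural logarithms. A `paper_literal` mode
computes `exp(H)/ln(S)` instead — the literal reading of some published
formulations, which can exceed 1 — because the two conventions circulate;
the bounded entropy form is the default. Asymptotic
interpolation/extrapolation estimators and bootstrap intervals are out of
scope.

## Basis correlations (`sparcc`)

Proportions are compositional, so Pearson correlations between them are
distorted by closure — most visibly during low-diversity bloom periods,
when one dominant taxon drives spurious negative correlations with (and
spurious positive correlations among) everything else. The estimator infers
correlations of the unobserved absolute abundances from log-ratio
variances `T_ij = Var ln(x_i/x_j)` under a sparsity assumption: basis
variances solve `t = ((D-2) I + 11') omega`, correlations follow as
`rho_ij = (omega_i + omega_j - T_ij) / (2 sqrt(omega_i omega_j))` (clipped
to [-1, 1]), and the strongest pair above `exclusion_threshold` (default
0.1) is iteratively removed from the system and the variances re-solved,
up to `exclusion_iterations` (default 10) rounds. Components excluded from
`D-3` or more pairs, or acquiring a non-positive variance estimate, are
flagged and their correlations zeroed with a warning. Natural logarithms
throughout.

Sampling noise is integrated out by averaging the estimate over posterior
Dirichlet draws (`counts + 1` prior — a uniform prior, the reference
behaviour; default 10 draws). Significance uses column-permutation
bootstraps: each component's counts are permuted independently across
samples (destroying association, preserving marginals), the full estimator
is re-run, and the two-sided pseudo-p-value is `(1 + k)/(n_boot + 1)` with
`k` the number of null draws at least as extreme; an `add_one=False` flag
gives the plain `k/n` convention. The add-one form avoids literal zero
p-values, standard permutation practice.

## Consensus modules (`modules`)

Correlations are mapped to adjacencies `A = 0.5 (rho + 1)` and each year's
network is summarised by its unsigned topological overlap matrix
`TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)`. The
second year's TOM is power-calibrated against the first so their 0.95
off-diagonal quantiles match (`tom^beta`, `beta = ln Q_ref / ln Q`;
order-statistic quantiles so the match is exact and entry order is
preserved). The consensus TOM is the elementwise minimum: high only for
pairs strongly connected in **both** years.

Modules are branches of the average-linkage dendrogram of `1 - TOM`,
extracted with a two-phase cut (defaults `deepSplit=2`, `cutHeight=0.995`,
`minClusterSize=10`):

1. a static cut at `cutHeight`;
2. recursive root bisection of each branch. When both children hold at
   least `minClusterSize` leaves, the branch splits if the cross-children
   mean dissimilarity (exactly the merge height under average linkage)
   exceeds the looser child's internal mean by a relative margin
   `c(deepSplit)` (0.40/0.25/**0.01**/0.005/0 for deepSplit 0–4). When one
   child is a small fragment — background taxa chain onto branches one
   leaf at a time — the procedure descends into the large child and sets
   the fragment aside if substructure is found there. Set-aside leaves are
   re-attached to the cluster with the highest mean TOM affinity when that
   affinity beats their overall background mean, else left unassigned
   (label 0).

A merge-height-gap criterion was tried first and discarded: with
`0.5 (rho + 1)` adjacencies the TOM range is compressed, and true
between-module merges sit only marginally above within-module heights, so
no gap threshold separates them from noise. The contrast criterion does:
in pilot simulations true between-module splits show contrast 0.02–0.24,
background/noise splits stay at or below ~0.008, and exact ties (uniform
TOM) give exactly 0. A too-liberal cut is self-correcting here, because
over-split fragments of one guild have near-identical eigengenes and are
re-merged in the next step; an unsplit pair of guilds is unrecoverable.
This procedure approximates the dynamic hybrid tree cut; recovery of
planted structure, not replication of any particular implementation's
labels, is the contract.

Each module is summarised per year by its **eigengene**: the first
principal component of the members' clr-transformed abundance profiles
(pseudocount 1e-6 added to proportions — the magnitude only makes sense on
proportions, not counts), sign-oriented to correlate positively with the
mean member profile. Modules are merged when their eigengenes are
consistently similar: average-linkage clustering of
`d(a,b) = max_year (1 - cor(ME_a, ME_b))`, merging below `cutHeight=0.25`,
recomputing eigengenes, iterating to a fixed point. Per-year eigengenes
combined by the maximum over years are used (rather than pooled-data
eigengenes), so a pair must be similar in both years to merge.

## Environmental association (`envassoc`)

Physicochemical variables are standardized to z-scores (sample SD).
Redundancy analysis regresses the column-centered eigengene matrix on the
predictors (`Y_hat = X (X'X)^-1 X' Y`, collinear columns dropped with a
warning) and ordinates the fitted values by SVD; site scores are the
sample projections, variable scores the correlations of predictors with
the axes, and the proportion explained is `tr(Y_hat'Y_hat)/tr(Y'Y)`. This
is an indirect gradient analysis: the ordination is of eigengenes, not raw
abundances. Pairwise Spearman correlations (t-approximation p-values,
adequate at 40–70 samples; exact permutation would change little) are
corrected with Benjamini–Hochberg over the full eigengene × variable grid
as one family (per-eigengene families available via a flag).

## Conservation (`conserve`)

Each module's correlation subnetwork is extracted per year and scanned
over |rho| thresholds 0–1 (step 0.01): edges below the threshold and the
resulting isolated vertices are dropped, and the number of components plus
the largest component's share are recorded. Two share definitions are
reported: relative to surviving vertices, and relative to the module's
full vertex set (`main_fraction`). Threshold selection uses
`main_fraction`: the chosen `t*` is the largest threshold at or above the
floor (default 0.5) that keeps at least `main_fraction=0.8` of the
module's vertices in one component — i.e. maximal trimming without
breaking the module network apart. The surviving-vertex definition is
degenerate for selection (a single surviving edge is always "100%
connected"), which is why the full-vertex-set share is the selector. If no
threshold qualifies, the floor is returned with a `degraded` flag.

The two filtered yearly graphs are then intersected: shared vertices and
edges are reported as percentages of the two-year **union** (the
Venn-diagram reading; the denominator is a documented choice, and the
aggregate summary is denominator-independent when fed published per-module
percentages). Intersected edges carry both years' correlations and their
mean. `conservation_summary` reports means and ranges across modules.

Note that the component *count* is not monotone in the threshold: it rises
while the network fragments and falls again as fragments dissolve — the
familiar sharp peak in deconstruction curves. Only the largest component's
share is monotone (non-increasing), and that is the property tested.

## Problem sizes used in tests

The default simulation — 200 taxa (4 × 40 module taxa + 40 background), 50
samples per year, depth 5,000, 10 Dirichlet draws — runs the full pipeline
in well under a second, so end-to-end recovery is tested across many seeds:
adjusted Rand index against planted truth is computed on module taxa
(background taxa have no planted label to recover), driver identification
is checked in both years, and the perturbed-module conservation ranking is
evaluated over 20 seeds. Null calibration of the correlation estimator uses
50 independent log-normal components at 200 samples with 100 permutation
bootstraps. These sizes are the package's chosen desk-scale study
conditions, not limits of the method.

## Known limitations

- The dynamic-cut stand-in is tuned for recovery, not for reproducing any
  reference implementation's labels on ties.
- The sparse basis-correlation system assumes most pairs are uncorrelated;
  with dense planted structure (most taxa in strongly driven modules) the
  estimates shrink toward zero and the exclusion heuristic only partially
  compensates.
- Eigengenes are linear summaries; a guild with a strongly nonlinear
  seasonal response could correlate poorly with its own driver.
- Spearman p-values use the t-approximation; at fewer than ~10 samples use
  the exact option or permutations.
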