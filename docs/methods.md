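# Methods

This note documents the models, numerical choices, and limitations behind
`sedstrat`, in the order the pipeline runs them.

## Interstitial-space physics

A sediment layer is a three-phase mixture: pore water (volume `V_w`, mass
`M_w`), solids (`V_s`, `M_s`) and, where methane supersaturates, free gas
(`V_a`). The measurable quantities are the in-situ volumetric water content
`Moi_v = V_w / V_T` with `V_T = V_w + V_s + V_a`, the lab mass water content
`Moi_m = M_w / (M_w + M_s)`, the pore-water density `ρ_w`, and the
mixed-sediment density by the submerged method, `ρ_ws`. A point that the
formula hides: the submerged-method sample is degassed, so
`ρ_ws = (M_w + M_s)/(V_w + V_s)` — *not* mass over the gas-inclusive volume.
With that convention

    VP_a = 1 − (Moi_v · ρ_w) / (Moi_m · ρ_ws)

reduces algebraically to `V_a / V_T` (numerator of the ratio `M_w/V_T`,
denominator `M_w/(V_w+V_s)`), and `TIS = Moi_v + VP_a` is the total
interstitial space. Were ρ_ws taken as `M_T/V_T`, the expression would be
identically zero. Measurement noise can drive raw VP_a slightly negative on
saturated layers; values in `[−ε, 0)` are clamped to 0 and flagged in the
result's `warning` column, while values above 1 (impossible for positive
inputs) raise. A property test constructs `(V_w, V_s, V_a, ρ)` from first
principles and verifies VP_a recovers `V_a/V_T` to machine precision.

Age–depth models are piecewise-linear through dated anchors
(depth, calendar year), extended below the deepest anchor at the terminal
segment's constant rate; deposition rate over a depth interval is thickness
over elapsed years. With the anchor set (0 cm, 2015), (21.4 cm, 1963),
(55 cm, 1709) this yields 0.41 cm/yr above and 0.13 cm/yr below the damming
horizon.

## Community statistics

Counts are rarefied to the minimum sample total by exact multivariate-
hypergeometric subsampling before diversity statistics. Chao1 uses the
bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` so it is defined without
doubletons; Pielou is Shannon (natural log) over `ln S_obs`, reported as
missing when `S_obs ≤ 1`. Bray–Curtis operates on counts by default (a flag
switches to relative abundances); Jaccard is presence/absence. PCoA is
classical Gower double-centering with negative eigenvalues reported, not
corrected; proportions explained are computed over positive eigenvalues and
the absolute negative mass is returned alongside. UPGMA orders samples
lexicographically before linkage so ties break deterministically, and
reports ultrametric node heights (half the cophenetic merge distance).
ANOSIM uses `R = (r̄_between − r̄_within)/(M/2)` on tied ranks with
`M = n(n−1)/2` and the add-one permutation p-value, seeded. Temporal
fluctuation of one layer is Baselga's abundance-based multiple-site
dissimilarity with its balanced-variation / abundance-gradient partition;
for two timepoints it reduces exactly to pairwise Bray–Curtis (asserted to
1e−12). The bipartite connection degree counts samples where a taxon's
pooled abundance reaches 10 reads (log10 ≥ 1, boundary inclusive).

## Phylogenetic null models

βMNTD between communities is
`0.5·[Σ_s f_s1·min_{t∈c2} d(s,t) + Σ_s f_s2·min_{t∈c1} d(s,t)]` on patristic
distances, abundance-weighted by default (a flag gives the unweighted form);
a shared taxon contributes distance 0. βNTI standardizes the observed βMNTD
against nulls that shuffle taxa across **all** tips of the supplied distance
matrix (a flag restricts the pool to the pair's taxa); each null replicate
draws one permutation and applies it to both communities, preserving
shared-taxon structure. NTI uses the same null with the opposite sign so
positive values mean clustering. When a community covers every tip the null
has zero spread and the index is reported as NaN with a warning — this is a
real degeneracy of the estimator, not an error, and classification of such
pairs is "undefined".

RC_bray nulls preserve each community's observed richness and total count:
taxa are drawn without replacement with probability proportional to
metacommunity occurrence frequency, the remaining individuals are assigned
multinomially in proportion to metacommunity relative abundance among the
drawn taxa, and Bray–Curtis is computed on relative abundances. Ties count
half: `RC = 2·[(#{BC_null < BC_obs} + ½·#{BC_null = BC_obs})/n_null] − 1`.
Under the null, `RC` is approximately uniform on [−1, 1], so |RC| > 0.95 is
a 5 % event; the calibration tests assert the binomial 99 % band around
0.05 for both |βNTI| > 2 and |RC| > 0.95. Defaults are 999 (βNTI) and 9999
(RC) randomizations; tests and the acceptance script scale these down
(199/199–999) to keep desk runtimes in minutes.

The five-way partition per sample pair: βNTI > 2 → heterogeneous selection;
βNTI < −2 → homogeneous selection; otherwise RC > 0.95 → dispersal
limitation, RC < −0.95 → homogenizing dispersal, else drift. Zone-level
process fractions are computed over **all within-zone pairs** (as when a
two-zone system is defined by the UPGMA cut); the adjacent-layer profile is
a separate product reporting one βNTI/RC per boundary (per season in
snapshot mode, or after seasonal pooling in merged mode — two different
estimators whose disagreement is reported, not reconciled).

## Niche breadth

Levin's breadth `B_j = 1/Σ_i P_ij²` over the N seasonally pooled layers
ranges from 1 (single-layer specialist) to N (uniform generalist); the mean
niche breadth of a layer is the within-layer abundance-weighted mean
`MNB_i = Σ_j Q_ij·B_j`. Because every `B_j ≥ 1`, any weighted mean is ≥ 1,
so the implementation asserts `MNB ∈ [1, N]`; a nominal lower bound of 0
sometimes quoted for this index is not attainable. The depth profile is
summarised by an OLS quadratic in layer index; the fitted vertex marks the
generalist-rich transition zone.

## Random-forest damming sensitivity

Samples are labelled by the side of the damming horizon; features are
relative abundances, usually aggregated to a coarse clade rank. The screen
trains `n_forests` (default 100) independently seeded forests of `n_trees`
(default 1000) each, pools mean-decrease-Gini importances by arithmetic
mean (order-free), and averages OOB misclassification rates. scikit-learn's
impurity importances are normalized per forest; ranking and breakpoint
placement are invariant to that scale. Class imbalance is damped with
`class_weight="balanced_subsample"` (per-bootstrap reweighting), switchable
off. The descending importance curve is segmented by exact dynamic
programming over piecewise-constant fits (minimum segment length 2), with
the number of breakpoints chosen by BIC
(`n·ln(RSS/n) + (2k+1)·ln n`); taxa ranked before the first breakpoint form
the sensitive set. A piecewise-constant model was chosen over sloped
segments because the ranked importance curve is a step-like scree by
construction; the DP is verified against exhaustive enumeration for
n ≤ 12. Unsupervised validation builds a synthetic contrast class from the
product of feature marginals (independent column permutations), trains a
real-vs-synthetic forest, derives proximities as co-leaf frequencies,
embeds `1 − proximity` by classical scaling, and cuts an average-linkage
tree at k = 2.

## Synthetic-data generator

The generator emulates the processed structure of a year-round dammed-lake
survey: 11 depth layers × 6 bimonthly seasons of 5-cm intervals (optional
dropout reproduces incomplete designs), ~50,000 reads per sample, a
Kingman-coalescent tree over the taxon pool, a physics table saturated above
the horizon with ~5 % planted gas below, and anchors at the surface (2015),
the horizon (1963) and the core bottom (dated by a 0.13 cm/yr pre-damming
rate). A depth-indexed environmental variable E rises by 1 per layer and
steps by `effect_size` (default 4) at the damming horizon.

Niche structure is conserved at the **clade level**: the tree is cut into
roughly ten-tip clades and each clade draws one guild —

* *specialists* (60 %): Gaussian response centred on a random layer's E with
  tolerance `niche_width` (default 0.5), truncated to zero beyond 2.5
  tolerances, so filtering acts on presence/absence;
* *zone generalists*: centred mid-zone with 4× tolerance, present
  throughout their zone — they bound within-zone dissimilarity so the
  two-zone block structure survives the within-zone gradient;
* *ecotone generalists* (a fifth of generalist clades): very broad
  tolerance centred on the horizon step midpoint, spanning both zones —
  the mechanism that places the MNB peak at the transition.

Two modelling decisions deserve justification. First, clade-level
conservatism (rather than, e.g., Brownian optima) is deliberate: under a
Brownian trait, variance is dominated by deep splits and adjacent-layer
communities are phylogenetically indistinguishable from the tip-shuffling
null, so no fine-scale βNTI signal exists to recover; clade-assigned guilds
make a gained/lost clade a phylogenetically coherent block, which is exactly
the signal the βMNTD null detects. Second, the hard tolerance cutoff:
without it, deep sequencing resurrects every taxon's vanishing Gaussian
tail, every sample contains every tip, and the tip-shuffling null becomes
degenerate (zero spread).

Regimes per zone: *selection* uses the niche responses above;
*neutral* uses the flat lognormal species-abundance distribution
(`sad_sigma`, default 1.0); *dispersal_limited* is a compositional random
walk — each layer multiplies the previous expectation by lognormal noise
(`walk_sigma`, default 1.2) and loses a 5 % random fraction of taxa to
local extinction, producing turnover stronger than the metacommunity null
with no phylogenetic structure. Seasonal replicates apply lognormal jitter
(`seasonal_noise`, default 0.5) before a multinomial draw at the library
size. An optional `pool_mixing` mass effect blends the regional pool into
every layer; it defaults to 0 because any appreciable mixing re-seeds
universal presence and degrades both the βNTI null and Raup–Crick contrast
(see above). All randomness derives from one seed via spawned substreams,
so identical configs are bit-identical.

What the generator does **not** emulate: sequencing error and chimeras,
compositional bias of extraction/PCR, overdispersion beyond lognormal
jitter, phylogenetic signal in abundance (only presence structure is
conserved), real redox chemistry, or taxon interactions. Passing tests
therefore show the estimators recover planted regimes under a clean niche
model at desk scale (150 taxa), not that real sediment data meet the
models' assumptions. In particular, drift detection by RC_bray is sensitive
to overdispersion relative to its multinomial null: neutral-regime layers
with seasonal jitter can classify as dispersal-limited because the null
only accounts for sampling noise — a known property of the metric, not a
bug.

## Problem sizes and tolerances

The test suite and acceptance script run at 150 taxa, the 11 × 6 design,
199 βNTI and 199–999 RC randomizations, 20 recovery seeds, and reduced
forest ensembles; code defaults retain the field-standard 999/9999
randomizations and 100 × 1000-tree ensembles. Oracle equivalences are
asserted exactly (1e−12 or machine precision); calibration rates use
binomial 99 % bands; planted-regime recovery requires ≥ 70 % of 20 seeds
per zone. Degenerate inputs are contracts, not crashes: undefined indices
are NaN with warnings, empty layers and singleton groups raise with the
offending label named.
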