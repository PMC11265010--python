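# Methods

This note documents the models, decision rules and numerical choices
behind `gveco`, and what the synthetic-data generator does and does not
emulate.

## Study design the package assumes

A *polB* marker-gene survey of soil giant-virus (NCLDV) communities across
five terrestrial habitat types — farmland, forest, grassland, Gobi desert
and mine wasteland — with per-sample metadata comprising habitat, read
count and 14 environmental variables (LON, LAT, ALT, MAP, pH, EC, EX-Ca,
CaCO3, CEC, clay, TP, TK, TN, TC; geographic coordinates in decimal
degrees WGS84, MAP in mm). The pipeline consumes phylotype × sample
coverage tables (read mapping is upstream), jplace placements on a fixed
reference tree (alignment and placement are upstream), eukaryote ASV
tables (18S amplicon processing is upstream), and contig annotation tables
(marker detection is upstream).

## Dereplication

Greedy incremental clustering in decreasing length order (ties broken
lexicographically by id, for determinism): a sequence joins the earliest
founded representative it matches at identity strictly above 0.95 and
coverage of the shorter sequence strictly above 0.90, else founds a new
cluster. Identity comes from pairwise global alignment (match +1,
mismatch −1, gap −2, linear gap cost) as matches / aligned-overlap
columns, where the overlap spans from the first to the last column in
which both sequences carry a residue — terminal gaps are excluded,
matching the short-sequence coverage semantics of greedy clustering tools.
Coverage is the fraction of the shorter sequence inside that overlap.

## Placement-based taxonomy

The classifier is a pure function of (best placement edge, its
like_weight_ratio, clade map). The edge is the branch above the node
carrying its jplace edge number; the decision depends only on the set of
reference leaves below that edge:

* any outgroup leaf below, or the edge above the NCLDV/outgroup split
  (including the NCLDV-clade stem, which cannot be distinguished from the
  split) → **non-NCLDV**;
* all leaves inside one family clade with cultivated representatives,
  strictly below the family's root node → **that family**;
* all leaves in one order otherwise (family stem edges, order backbones,
  families with ≤ 1 cultivated representative) → **that order, family
  unassigned**;
* leaves spanning several NCLDV orders → NCLDV, order unassigned;
* order *Pandoravirales* → **excluded** (`pandoravirales-removed`):
  long branches and sparse references make placements in this clade
  unreliable;
* best like_weight_ratio < 0.5 → **excluded** (`low-support`).

Two conventions were genuinely open and are fixed as follows. "Basal"
means the stem edge (the branch above a clade's root): a placement on a
family's stem is order-known/family-unassigned, not a family call, because
the query may be sister to the entire family. Support filtering acts on
the placement weight (like_weight_ratio ≥ 0.5) rather than on reference
bootstrap values, which do not travel with jplace output; reference clades
whose support was judged inadequate can instead be masked via
`ReferenceCladeMap.low_confidence_families`, which degrades family calls
inside them to unassigned. Only the best (highest-weight) placement is
used; multi-placement mass is ignored.

The decoy benchmark counts a query as identified NCLDV iff its call is
NCLDV and not excluded; FPR = FP/(FP+TN). For any placement set in which
every decoy's candidates lie in outgroup clades, FPR is exactly 0 by
construction of the rule — this is the property the benchmark certifies.

## Normalization and occupancy

Normalized coverage is `raw_ij / reads_j × mean_k(reads_k)`; the
proportional table rescales each sample to 100 % (empty samples stay zero
and are flagged). Detection is coverage strictly greater than 0 — the
minimal-assumption reading, exposed as a configurable threshold
(`presence_min`) because mapping noise may warrant a positive floor.
Occupancy percentages are reported at two significant figures, the
precision used in the survey literature (e.g. 381/533 → 71 %,
5/533 → 0.94 %).

## Environmental range (SEV)

Four steps: (1) min–max standardize each environmental variable across
samples; (2) SEV(sample) = mean of the standardized variables;
(3) raw range(phylotype) = max SEV − min SEV over occupied samples;
(4) min–max standardize raw ranges across phylotypes to [0, 1].
Consequences and edge-case policy:

* the statistic is invariant to affine rescaling of any variable (units
  cancel in step 1) and monotone in the occupied-sample set;
* constant variables are dropped (their standardization is 0/0) rather
  than imputed, and logged;
* missing values are excluded from a variable's min/max and from that
  sample's SEV mean (SEV averages over available variables) — no
  imputation;
* a phylotype present in a single sample has raw range 0 and attains the
  minimum standardized range;
* step 4 is min–max across phylotypes; division by the global SEV span is
  a defensible alternative that differs only by a constant factor before
  re-standardization.

"Average abundance" divides total normalized coverage by the number of
*occupied* samples, not all samples: dividing by all samples would build a
negative abundance–occupancy correlation in by construction, which is the
effect under study. Correlations are computed on log scales; zero ranges
are offset by one tenth of the smallest positive value before the log
(the offset is recorded in the output); constant inputs yield an explicit
`undefined` flag, never a silent 0.

## Rarefaction

Sample-based accumulation: mean cumulative richness over random sample
orderings (default 100; `exact=True` evaluates the mean over all
orderings in closed form, E[S_k] = Σ_i (1 − C(n−m_i, k)/C(n, k))). The
terminal slope 100·(S̄_n − S̄_{n−1})/S̄_n expresses percent new phylotypes
contributed by the last sample.

## Permutation statistics

All permutation p-values use the +1 convention
p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm), so they are exact, never
below 1/(n_perm+1), and reproducible given the seed. Defaults: 999
permutations.

* **PERMANOVA**: one-way pseudo-F from sums of squared distances
  (SS_total = Σ d²/n over pairs; SS_within per group over within-group
  pairs divided by group size), free permutation of sample labels. The
  statistic is verified against the definitional brute-force formula over
  the full permutation orbit at n = 6 and against vegan's `adonis2`.
* **Mantel / partial Mantel**: correlation of distance triangles; the
  partial statistic is the first-order partial correlation of (A, B)
  given C. The permutation scheme permutes rows/columns of the first
  matrix jointly and recomputes the (partial) statistic — the simple
  Mantel permutation of the residual association, which differs subtly
  from residual-permutation schemes; it is documented as such rather than
  claimed identical to any particular R implementation (the observed
  statistic is checked against vegan).
* **Distance–decay**: least-squares slope of community dissimilarity on
  log10(km + 1) over sample pairs; because pairs are not independent,
  significance comes from a Mantel permutation, not the naive pair-level
  regression p. Geographic distances are great circles (haversine, Earth
  radius 6371.0088 km).
* **Variation partitioning**: the community matrix is
  Hellinger-transformed (square root of within-sample relative abundance
  — the standard transform making abundance data Euclidean-embeddable for
  RDA); every non-empty subset of the predictor blocks is fitted by
  redundancy analysis, R² is Ezekiel-adjusted using the *effective* rank
  of the centred design (so collinear block unions are fitted by
  projection rather than rejected; a singular individual block is still
  an error), and the 15 individual fractions are obtained by solving the
  inclusion–exclusion system linking subset R² to region fractions.
  Fractions can be slightly negative (a known property of adjusted R²)
  and are stored untruncated; fractions + residual sum to 1 to 1e-9.
  High-dimensional blocks (edaphic variables, eukaryotic community) are
  first reduced to principal components retaining ≥ 80 % of their
  variance (configurable).

The Kruskal–Wallis test (tie-corrected H, chi-square p) and Spearman
correlations delegate to scipy; Benjamini–Hochberg adjustment delegates to
statsmodels; both are verified against hand-computed oracles in the test
suite. The all-identical-values degenerate case returns H = 0, p = 1
explicitly.

## Co-occurrence networks

Per habitat: prevalence filter (present in ≥ ceil(0.10·n) samples, so 2 of
20 passes and 1 of 20 fails), Spearman ρ with average-rank ties for every
virus × ASV pair, raw p from the t-approximation (adequate at the habitat
sample sizes used here; a rank-permutation p is available for n < 10), BH
adjustment across all tested pairs *within the habitat* (the natural unit,
since networks are built per habitat), and retention at ρ ≥ 0.60 and
adjusted p < 0.05. Edges are positive-only by default — they are read as
putative virus–host pairings — with an absolute-value mode available.
Constant features are skipped and logged. Retention is monotone: raising
either threshold never adds edges.

## Contig screening

Accept iff length > 5000 bp (strict, configurable) and at least one of:
NCLDV-specific classifier flag, ≥ 2 of 20 NCVOG ancestral markers, or
*polB* (NCVOG0038) present. The audit table records which criteria fired
(they may co-fire); the rule is monotone in the marker evidence.

## Synthetic-data generator

The generator produces the structures the analyses assume, with recorded
ground truth sufficient to evaluate every downstream stage:

* **Occupancy**: each phylotype is a specialist (default 70 %) for one
  habitat — present in home-habitat samples with probability 0.5 and
  foreign samples with probability 0.02 — or a generalist (presence
  probability 0.35 anywhere). Every phylotype is forced to occupy at
  least one sample. These rates make single-habitat phylotypes common
  without being universal, echoing heterogeneous soil communities.
* **Abundance**: log-normal conditional on occupancy
  (meanlog = 3.0 + τ·ln(occupancy), sdlog 1.0), zeros arise from
  occupancy, not the abundance law — coverage data are strictly positive
  and right-skewed where present. τ = −0.5 by default plants the
  abundance–occupancy tradeoff; τ is a free simulation knob, not an
  estimate of any field value.
* **Depth**: per-sample read counts log-uniform over [1e7, 1e8]; raw
  coverage scales with relative depth, so the normalization stage has
  real work to undo.
* **Environment**: 14 Gaussians with habitat-specific means (deserts dry
  and alkaline, mine wasteland acidic, etc.); TN is generated from TC and
  EX-Ca from CEC so two variable pairs exceed Spearman ρ² = 0.7 by
  construction and exercise the redundancy filter.
* **Virus–host couplings**: host ASVs are monotone transforms of their
  paired virus abundances plus log-scale Gaussian noise, calibrated via
  the normal-copula identity r = 2·sin(π·ρ_s/6) so the population
  Spearman correlation hits the requested target; other ASVs are
  independent log-normals.
* **Placements**: a fixed labeled reference topology (6 NCLDV orders, 12
  families, 4 outgroup clades; ladder-shaped clades so strict-interior
  edges exist) with true queries on family-interior edges (or stems, per
  a basal fraction) and decoys strictly inside outgroup clades;
  like_weight_ratio is drawn as floor + (1−floor)·Beta(8, 2) so simulated
  placements are well supported by default.
* **Contigs**: lengths log-normal (median ≈ 8 kb), marker emissions
  Bernoulli/binomial with separate rates for NCLDV and non-NCLDV origin.

A single `numpy.random.Generator` per simulation makes identical
(parameters, seed) produce bit-identical outputs.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: sequence-level artifacts (chimeras, mapping
bias, uneven coverage along genes), compositionality of real coverage
tables, spatial autocorrelation of communities beyond habitat structure,
phylogenetic signal in abundances, and non-monotone or time-lagged
virus–host dynamics. Tests certify the correctness and calibration of the
procedures, not the field validity of their assumptions.

## Problem sizes and tolerances

The test and acceptance workloads use desk-scale sizes chosen to make the
statistical checks sharp while staying quick to run: oracle equivalence on
50 random fixtures per statistic (exhaustive permutation orbits at n = 6);
type-I-error calibration over 1000 null datasets (199 permutations for
PERMANOVA, 99 for Mantel — granularities at which the nominal 0.05 level
is attainable exactly); parameter recovery over 20 seeds (communities of
300 phylotypes × 150 samples for the tradeoff; 60 samples, 200 ASVs, 10
planted pairs at ρ = 0.7 for edge recovery). Numerical tolerances:
distance-matrix symmetry and VPA fraction closure at 1e-9; oracle
agreement at 1e-10–1e-12; Monte-Carlo assertions at the binomial
tolerances stated in the tests.

## Known limitations

* Greedy clustering is O(n·k) alignments (k clusters) and is meant for
  marker-gene sets (hundreds to thousands of sequences), not genome-scale
  dereplication.
* The classifier ignores placement mass outside the best edge; queries
  with genuinely multimodal placements are resolved by the heaviest edge
  only.
* The partial-Mantel permutation scheme is one of several in use;
  p-values from different schemes can differ in small samples.
* PCA reduction before variation partitioning discards the variance
  fraction beyond the retention target; block totals are conditional on
  that reduction.
* The t-approximation for Spearman p is inaccurate below ~10 samples; use
  the permutation option there.
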