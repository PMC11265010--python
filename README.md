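# gveco — marker-gene ecology of soil giant viruses

Giant viruses (nucleocytoplasmic large DNA viruses, NCLDVs) infect diverse
soil eukaryotes, but their biogeography is hard to study: they are profiled
not by isolation but by recovering a marker gene — the family B DNA
polymerase gene *polB* — from shotgun soil metagenomes. `gveco` implements
the downstream computational workflow for such a survey, for microbial
ecologists working with phylotype × sample coverage tables, jplace
placement files and 18S ASV tables:

* **Phylotype dereplication** — CD-HIT-style greedy incremental clustering
  of marker sequences (identity > 95 %, coverage of the shorter sequence
  > 90 %, pairwise global alignment with match +1 / mismatch −1 / gap −2).
* **Placement-based taxonomy** — queries placed on a labeled reference tree
  (pplacer/EPA-ng jplace output) are called NCLDV iff the best placement
  edge lies inside an NCLDV clade; placements strictly inside a family
  clade with cultivated representatives receive that family, placements
  basal to family clades are family-unassigned, and placements in the
  long-branched *Pandoravirales* clade are excluded. A decoy benchmark
  (eukaryote/bacteria/archaea/phage PolBs) verifies that the rule makes no
  false NCLDV calls.
* **Coverage normalization** — `norm_ij = raw_ij / reads_j × mean_k(reads_k)`,
  then a proportional table (columns sum to 100 %).
* **Occupancy and niche breadth** — habitat-occupancy tallies
  (unique/shared phylotypes), occurrence frequencies, and the
  *environmental range*: each of 14 environmental variables is min–max
  standardized across samples, the per-sample mean of the standardized
  variables (SEV) is computed, and a phylotype's range is
  max SEV − min SEV over its occupied samples, re-standardized to [0, 1]
  across phylotypes.
* **Community statistics** — richness and Shannon *H*, Kruskal–Wallis,
  Bray–Curtis dissimilarity, one-way PERMANOVA (Anderson's pseudo-F, exact
  permutation p with the +1 rule), Mantel and partial Mantel tests,
  distance–decay regression on log10(km + 1) with Mantel-style inference,
  and four-block variation partitioning (Hellinger-transformed redundancy
  analysis, Ezekiel-adjusted R², inclusion–exclusion fractions).
* **Co-occurrence networks** — per habitat, features present in ≥ 10 % of
  samples are tested pairwise (virus × ASV) by Spearman rank correlation;
  Benjamini–Hochberg adjustment across all tested pairs; edges retained at
  ρ ≥ 0.60 and adjusted p < 0.05.
* **Contig screening** — putative NCLDV contigs: length > 5 kb and
  (classifier flag OR ≥ 2 of 20 NCVOG markers OR *polB* present).
* **Synthetic data** — a first-class generator producing
  habitat-structured log-normal communities with a planted
  abundance–occupancy tradeoff, correlated environmental gradients,
  planted virus–host couplings, simulated placements and contig tables,
  all with recorded ground truth, so the whole pipeline is testable
  without sequencing data.

## Worked example

```python
import gveco as g

cov, samples, truth = g.simulate_community(
    n_phylotypes=300, n_samples_per_habitat=20, seed=1)
norm = g.normalize_coverage(cov, samples)

summary = g.occupancy_summary(norm, samples)
print(summary["counts_by_n_habitats"])   # {0: 0, 1: 49, 2: 85, 3: 54, 4: 20, 5: 92}
print(summary["pct_single_habitat"])     # 16.0

ert = g.environmental_range(norm, samples)
st = g.abundance_occupancy_stats(ert)
c = st["avg_abundance_vs_log_range"]
print(f"r={c['r']:.3f} p={c['p']:.2e}")  # r=-0.416 p=5.28e-14

d = g.bray_curtis(norm)
perm = g.permanova(d, samples.habitat, n_perm=999, seed=1)
print(f"F={perm['pseudo_F']:.2f} R2={perm['R2']:.3f} p={perm['p']:.3f}")
# F=6.71 R2=0.220 p=0.001

euk, pairs = g.simulate_eukaryotes(truth, n_asvs=150, n_planted_pairs=8,
                                   rho_target=0.8, seed=2)
edges = g.spearman_edges(norm.data, euk, list(norm.sample_ids))
print(len(edges), g.evaluate_planted_edges(edges, pairs))
# 8 {'tp': 8, 'n_detected': 8, 'n_planted': 8, 'precision': 1.0, 'recall': 1.0}
```

Reading the output: with a planted negative abundance–occupancy tradeoff
(τ = −0.5), phylotypes that occupy fewer samples are on average more
abundant where they occur, so average abundance correlates negatively
with the environmental range (r = −0.42). The five habitat types impose
real community structure, which PERMANOVA detects at the permutation
floor (p = 0.001 with 999 permutations). All eight planted virus–host
couplings at Spearman ρ = 0.8 are recovered by the network rules with no
false edges across the 100 samples.

The same stages are available as a CLI
(`gveco simulate | classify | normalize | ecology | stats | network |
screen`); every JSON output embeds the thresholds and seed used.

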