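"""Synthetic inputs with recorded ground truth.

Every generator here emulates the statistical structure the downstream
analyses assume, so the whole pipeline is testable without any sequencing
data:

* a habitat-structured community of marker-gene phylotypes whose occupancy
  follows a specialist/generalist mixture and whose abundances are
  log-normal with a mean that trades off against realized occupancy,
* correlated environmental gradients (including deliberately collinear
  pairs to exercise the redundancy filter),
* eukaryote ASV tables with planted virus-host abundance couplings,
* phylogenetic placements of true and decoy queries on a labeled
  reference tree, and
* contig annotation tables for the genome-screening rules.

All generators draw from a single ``numpy.random.Generator`` seeded from the
``seed`` argument, so identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import (
    ENV_VARIABLES,
    HABITATS,
    CoverageMatrix,
    Placement,
    PlacementSet,
    QueryPlacement,
    SampleTable,
    _parse_edge_numbered_tree,
)

# Habitat-specific baseline shifts for the environmental gradients.  MAP and
# pH separate the habitats strongly (deserts dry/alkaline, mine wasteland
# acidic), the edaphic variables more weakly; TN is generated from TC and
# EX-Ca from CEC so that two variable pairs are collinear (Spearman
# rho^2 > 0.7) by construction.
_HABITAT_ENV_MEANS = {
    #            LON   LAT  ALT   MAP   pH   EC   CEC  CaCO3 clay  TP   TK   TC
    "farmland": (113., 30., 200., 1100., 6.5, 0.30, 18., 2.0, 28., 0.9, 15., 18.),
    "forest":   (110., 27., 800., 1400., 5.8, 0.15, 22., 1.0, 32., 0.7, 12., 35.),
    "grassland": (102., 36., 1500., 450., 7.5, 0.40, 15., 5.0, 20., 0.6, 18., 20.),
    "gobi":     (95., 41., 1200., 120., 8.4, 1.20, 8., 12.0, 8., 0.4, 20., 5.),
    "mine":     (112., 25., 400., 1300., 3.8, 1.50, 10., 0.5, 24., 0.5, 10., 8.),
}
_ENV_SD = {"LON": 4.0, "LAT": 3.0, "ALT": 150.0, "MAP": 120.0, "pH": 0.4,
           "EC": 0.15, "CEC": 3.0, "CaCO3": 1.0, "clay": 5.0,
           "TP": 0.15, "TK": 3.0, "TC": 4.0}


@dataclass
class SimTruth:
    """Ground truth of a simulated community, sufficient to evaluate every
    downstream analysis without re-deriving anything from the observables."""

    seed: int
    tau: float
    niche_class: pd.Series            # phylotype -> habitat name or "generalist"
    mean_log_abundance: pd.Series     # phylotype -> meanlog of the log-normal
    occupancy: pd.Series              # phylotype -> number of occupied samples
    habitat: pd.Series                # sample -> habitat
    env: pd.DataFrame                 # sample x variable gradient values
    latent_abundance: pd.DataFrame    # depth-free abundances (phylotype x sample)
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        for virus, asv, rho in self.planted_pairs:
            if virus not in self.latent_abundance.index:
                raise ValueError(f"planted pair references unknown phylotype {virus!r}")


def _simulate_env(samples: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Habitat-shifted Gaussian gradients with two collinear pairs planted."""
    base_cols = list(_ENV_SD)
    rows = []
    for s in samples.index:
        means = dict(zip(
            ("LON", "LAT", "ALT", "MAP", "pH", "EC", "CEC", "CaCO3",
             "clay", "TP", "TK", "TC"),
            _HABITAT_ENV_MEANS[samples[s]],
        ))
        rows.append([rng.normal(means[c], _ENV_SD[c]) for c in base_cols])
    env = pd.DataFrame(rows, index=samples.index, columns=base_cols)
    env["ALT"] = env["ALT"].clip(lower=0.0)
    env["MAP"] = env["MAP"].clip(lower=10.0)
    env["CaCO3"] = env["CaCO3"].clip(lower=0.0)
    # planted collinearity: TN tracks TC, EX-Ca tracks CEC (rho^2 > 0.7)
    env["TN"] = 0.08 * env["TC"] + rng.normal(0.0, 0.08, len(env))
    env["EX-Ca"] = 0.5 * env["CEC"] + rng.normal(0.0, 0.8, len(env))
    return env[list(ENV_VARIABLES)]


def simulate_community(
    n_phylotypes: int = 300,
    n_samples_per_habitat: int = 30,
    specialist_fraction: float = 0.7,
    tau: float = -0.5,
    sigma: float = 1.0,
    p_in: float = 0.5,
    p_out: float = 0.02,
    p_generalist: float = 0.35,
    mean_log_abundance0: float = 3.0,
    read_count_range: tuple[float, float] = (1e7, 1e8),
    n_sites_per_habitat: int | None = None,
    seed: int = 0,
) -> tuple[CoverageMatrix, SampleTable, SimTruth]:
    """Simulate a habitat-structured phylotype community.

    Specialists occupy samples of their home habitat with probability
    ``p_in`` and foreign samples with probability ``p_out``; generalists
    occupy any sample with probability ``p_generalist``.  Conditional on
    occupancy, abundance is log-normal with per-phylotype mean

        meanlog_p = mean_log_abundance0 + tau * ln(n_occupied_p)

    so that ``tau < 0`` plants the abundance-occupancy tradeoff seen in
    heterogeneous soil communities.  Raw coverage scales with a per-sample
    read depth drawn log-uniformly from ``read_count_range``, which the
    normalization stage is expected to undo.
    """
    if not 0.0 <= specialist_fraction <= 1.0:
        raise ValueError(f"specialist_fraction={specialist_fraction} outside [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n_phylotypes < 1 or n_samples_per_habitat < 1:
        raise ValueError("counts must be >= 1")

    rng = np.random.default_rng(seed)
    sample_ids = [f"{hab[:2].upper()}{i+1:03d}"
                  for hab in HABITATS for i in range(n_samples_per_habitat)]
    habitat = pd.Series(
        [hab for hab in HABITATS for _ in range(n_samples_per_habitat)],
        index=sample_ids, name="habitat",
    )
    phylotypes = [f"pt{i+1:04d}" for i in range(n_phylotypes)]

    is_specialist = rng.random(n_phylotypes) < specialist_fraction
    home = rng.integers(0, len(HABITATS), n_phylotypes)
    niche = pd.Series(
        [HABITATS[home[i]] if is_specialist[i] else "generalist"
         for i in range(n_phylotypes)],
        index=phylotypes, name="niche_class",
    )

    hab_idx = np.array([HABITATS.index(h) for h in habitat])
    occ_prob = np.empty((n_phylotypes, len(sample_ids)))
    for i in range(n_phylotypes):
        if is_specialist[i]:
            occ_prob[i] = np.where(hab_idx == home[i], p_in, p_out)
        else:
            occ_prob[i] = p_generalist
    present = rng.random(occ_prob.shape) < occ_prob
    # every phylotype must occur somewhere: force one home/random sample
    for i in np.flatnonzero(~present.any(axis=1)):
        pool = np.flatnonzero(hab_idx == home[i]) if is_specialist[i] \
            else np.arange(len(sample_ids))
        present[i, rng.choice(pool)] = True

    n_occ = present.sum(axis=1)
    meanlog = mean_log_abundance0 + tau * np.log(n_occ)
    abundance = np.zeros_like(occ_prob)
    draws = rng.lognormal(mean=np.repeat(meanlog, len(sample_ids)).reshape(abundance.shape),
                          sigma=sigma)
    abundance[present] = draws[present]

    lo, hi = read_count_range
    read_counts = np.exp(rng.uniform(np.log(lo), np.log(hi), len(sample_ids)))
    read_counts = np.maximum(1, np.round(read_counts)).astype(np.int64)
    raw = abundance * (read_counts / read_counts.mean())

    env = _simulate_env(habitat, rng)
    sample_df = env.copy()
    sample_df.insert(0, "habitat", habitat)
    sample_df.insert(1, "read_count", read_counts)
    if n_sites_per_habitat is not None:
        site = [f"{habitat[s]}-site{rng.integers(1, n_sites_per_habitat + 1)}"
                for s in sample_ids]
        sample_df["site"] = site

    latent = pd.DataFrame(abundance, index=phylotypes, columns=sample_ids)
    truth = SimTruth(
        seed=seed, tau=tau,
        niche_class=niche,
        mean_log_abundance=pd.Series(meanlog, index=phylotypes, name="meanlog"),
        occupancy=pd.Series(n_occ, index=phylotypes, name="occupancy"),
        habitat=habitat, env=env, latent_abundance=latent,
    )
    cov = CoverageMatrix(pd.DataFrame(raw, index=phylotypes, columns=sample_ids),
                         stage="raw")
    return cov, SampleTable(sample_df), truth


def simulate_eukaryotes(
    truth: SimTruth,
    n_asvs: int = 200,
    n_planted_pairs: int = 10,
    rho_target: float = 0.7,
    mean_log_abundance: float = 4.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Eukaryote ASV counts with planted virus-host couplings.

    Host ASVs for the ``n_planted_pairs`` most widely occupied phylotypes are
    monotone transforms of their paired virus abundances plus Gaussian noise
    on the log scale, calibrated through the normal-copula identity
    ``r = 2 sin(pi * rho_s / 6)`` so the population Spearman correlation is
    approximately ``rho_target``.  All other ASVs are independent
    log-normals.  The planted pairs are appended to ``truth.planted_pairs``.
    """
    if not 0.0 < rho_target < 1.0:
        raise ValueError(f"rho_target={rho_target} outside (0, 1)")
    if n_planted_pairs > n_asvs:
        raise ValueError("cannot plant more pairs than ASVs")

    rng = np.random.default_rng(seed)
    samples = list(truth.latent_abundance.columns)
    n = len(samples)
    asv_ids = [f"asv{i+1:04d}" for i in range(n_asvs)]

    log_abund = rng.normal(mean_log_abundance, sigma, size=(n_asvs, n))
    counts = np.exp(log_abund)

    # latent Pearson correlation giving the requested Spearman under a
    # bivariate-normal copula
    r = 2.0 * math.sin(math.pi * rho_target / 6.0)
    hosts = truth.occupancy.sort_values(ascending=False).index[:n_planted_pairs]
    pairs: list[tuple[str, str, float]] = []
    for k, virus in enumerate(hosts):
        x = truth.latent_abundance.loc[virus].to_numpy()
        lx = np.log(x + x[x > 0].min() / 10.0 if (x > 0).any() else x + 1.0)
        z = (lx - lx.mean()) / (lx.std() or 1.0)
        host_log = mean_log_abundance + sigma * (
            r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(n))
        counts[k] = np.exp(host_log)
        pairs.append((virus, asv_ids[k], rho_target))
    truth.planted_pairs.extend(pairs)
    return pd.DataFrame(counts, index=asv_ids, columns=samples), pairs


# ---------------------------------------------------------------------------
# Reference tree and placements
# ---------------------------------------------------------------------------

#: order -> {family: (n_leaves, has_cultivated_representative)}
_DEFAULT_CLADES = {
    "Imitervirales": {"Mimiviridae": (4, True), "Allomimiviridae": (2, False)},
    "Algavirales": {"Phycodnaviridae": (3, True), "Prasinoviridae": (2, True),
                    "Coccolithoviridae": (2, True)},
    "Pimascovirales": {"Pithoviridae": (4, True), "Iridoviridae": (3, True),
                       "Marseilleviridae": (2, True), "Mininucleoviridae": (2, True)},
    "Asfuvirales": {"Asfarviridae": (3, True)},
    "Chitovirales": {"Poxviridae": (3, True)},
    "Pandoravirales": {"Pandoraviridae": (3, True)},
}
_OUTGROUPS = {"eukaryote": 3, "bacteria": 3, "archaea": 3, "phage": 2}


def make_reference_tree() -> tuple[PlacementSet, pd.DataFrame]:
    """Build the default labeled reference topology for placement simulation.

    Returns an (empty) :class:`PlacementSet` carrying the edge-numbered tree
    and a leaf table with columns ``clade``, ``is_ncldv``, ``order``,
    ``family`` and ``has_rep``.
    """
    counter = iter(range(10 ** 6))
    rows = []

    def leaf(name):
        return f"{name}:0.1{{{next(counter)}}}"

    def clade(children):
        # ladder topology so clades with > 2 members have internal edges
        node = children[0]
        for child in children[1:-1]:
            node = "(" + node + "," + child + "):0.1{%d}" % next(counter)
        if len(children) > 1:
            node = "(" + node + "," + children[-1] + ")"
        return node + ":0.1{%d}" % next(counter) if len(children) > 1 \
            else node

    order_strs = []
    for order, families in _DEFAULT_CLADES.items():
        fam_strs = []
        for fam, (n, has_rep) in families.items():
            names = [f"{fam}_{i+1}" for i in range(n)]
            for nm in names:
                rows.append((nm, fam, True, order, fam, has_rep))
            fam_strs.append(clade([leaf(nm) for nm in names]))
        order_strs.append(clade(fam_strs))
    og_strs = []
    for og, n in _OUTGROUPS.items():
        names = [f"{og}_{i+1}" for i in range(n)]
        for nm in names:
            rows.append((nm, og, False, "", "", False))
        og_strs.append(clade([leaf(nm) for nm in names]))

    newick = "((" + ",".join(order_strs) + "):0.1{%d},(" % next(counter) \
        + ",".join(og_strs) + "):0.1{%d});" % next(counter)
    tree, edge_map = _parse_edge_numbered_tree(newick)
    leaf_table = pd.DataFrame(
        rows, columns=["leaf", "clade", "is_ncldv", "order", "family", "has_rep"],
    ).set_index("leaf")
    return PlacementSet(tree=tree, edge_map=edge_map, queries=[]), leaf_table


def _leafset(node: dendropy.Node) -> frozenset[str]:
    if node.is_leaf():
        return frozenset([node.taxon.label])
    return frozenset(l.taxon.label for l in node.leaf_iter())


def simulate_placements(
    n_true: int = 100,
    n_decoy: int = 50,
    basal_fraction: float = 0.0,
    include_pandoravirales: bool = False,
    support_floor: float = 0.5,
    beta_a: float = 8.0,
    beta_b: float = 2.0,
    decoy_class_counts: dict[str, int] | None = None,
    seed: int = 0,
    reference: tuple[PlacementSet, pd.DataFrame] | None = None,
) -> tuple[PlacementSet, pd.DataFrame, pd.DataFrame]:
    """Simulate placements of true NCLDV queries and non-NCLDV decoys.

    True queries land on edges strictly inside family clades, except a
    ``basal_fraction`` share placed on family stem edges (which the
    classifier must call order-known / family-unassigned).  Decoys land
    strictly inside the eukaryote/bacteria/archaea/phage outgroup clades.
    like_weight_ratio is ``support_floor + (1 - support_floor) * Beta(a, b)``
    so placements are well supported by default.

    Returns ``(placements, leaf_table, truth)`` where ``truth`` has one row
    per query: origin class, expected decision, and expected family status.
    """
    ref, leaf_table = reference if reference is not None else make_reference_tree()
    if not (leaf_table["is_ncldv"] == False).any():  # noqa: E712
        raise ValueError("reference tree lacks outgroup clade labels")
    rng = np.random.default_rng(seed)

    # catalogue candidate edges by role
    fam_leafsets = {
        fam: frozenset(leaf_table.index[leaf_table["family"] == fam])
        for fam in leaf_table.loc[leaf_table["is_ncldv"], "family"].unique()
    }
    inside_edges: dict[str, list[int]] = {fam: [] for fam in fam_leafsets}
    stem_edges: dict[str, int] = {}
    outgroup_edges: list[int] = []
    og_leaves = frozenset(leaf_table.index[~leaf_table["is_ncldv"]])
    for edge, node in ref.edge_map.items():
        ls = _leafset(node)
        if ls <= og_leaves:
            outgroup_edges.append(edge)
            continue
        for fam, fam_ls in fam_leafsets.items():
            if ls == fam_ls:
                stem_edges[fam] = edge
            elif ls < fam_ls:
                inside_edges[fam].append(edge)
    outgroup_edges.sort()

    callable_fams = sorted(
        fam for fam, row in
        leaf_table.loc[leaf_table["is_ncldv"]].groupby("family").first().iterrows()
        if row["has_rep"] and (include_pandoravirales or row["order"] != "Pandoravirales")
    )

    queries, truth_rows = [], []

    def lwr():
        return support_floor + (1.0 - support_floor) * rng.beta(beta_a, beta_b)

    for i in range(n_true):
        fam = callable_fams[rng.integers(len(callable_fams))]
        basal = rng.random() < basal_fraction
        edge = stem_edges[fam] if basal else \
            inside_edges[fam][rng.integers(len(inside_edges[fam]))]
        name = f"true{i+1:04d}"
        order = leaf_table.loc[leaf_table["family"] == fam, "order"].iloc[0]
        queries.append(QueryPlacement(name, [Placement(edge, lwr())]))
        truth_rows.append((name, "ncldv", "NCLDV", order,
                           "unassigned" if basal else fam))
    decoy_classes = sorted(_OUTGROUPS)
    og_by_class = {
        og: [e for e in outgroup_edges
             if _leafset(ref.edge_map[e]) <= frozenset(
                 leaf_table.index[leaf_table["clade"] == og])]
        for og in decoy_classes
    }
    if decoy_class_counts is None:
        classes = [decoy_classes[rng.integers(len(decoy_classes))]
                   for _ in range(n_decoy)]
    else:
        unknown = set(decoy_class_counts) - set(decoy_classes)
        if unknown:
            raise ValueError(f"unknown decoy classes: {sorted(unknown)}")
        classes = [og for og, k in sorted(decoy_class_counts.items())
                   for _ in range(k)]
    for i, og in enumerate(classes):
        edge = og_by_class[og][rng.integers(len(og_by_class[og]))]
        name = f"decoy{i+1:04d}"
        queries.append(QueryPlacement(name, [Placement(edge, lwr())]))
        truth_rows.append((name, og, "non-NCLDV", "", ""))

    ps = PlacementSet(tree=ref.tree, edge_map=ref.edge_map, queries=queries)
    truth = pd.DataFrame(
        truth_rows,
        columns=["query", "origin", "expected_decision", "expected_order",
                 "expected_family"],
    ).set_index("query")
    return ps, leaf_table, truth


def simulate_contigs(
    n_contigs: int = 200,
    ncldv_fraction: float = 0.3,
    mean_log10_len: float = 3.9,
    sd_log10_len: float = 0.35,
    p_classifier: tuple[float, float] = (0.6, 0.02),
    p_ncvog: tuple[float, float] = (0.25, 0.01),
    p_polb: tuple[float, float] = (0.4, 0.005),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a contig annotation table for the screening rules.

    Each ``p_*`` pair gives (NCLDV, non-NCLDV) emission probabilities;
    ``ncvog_count`` is Binomial(20, p).  Returns the annotation table and a
    boolean truth Series marking NCLDV-origin contigs.
    """
    for pair in (p_classifier, p_ncvog, p_polb):
        if not all(0.0 <= p <= 1.0 for p in pair):
            raise ValueError("emission probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"contig{i+1:05d}" for i in range(n_contigs)]
    is_ncldv = rng.random(n_contigs) < ncldv_fraction
    length = np.round(10 ** rng.normal(mean_log10_len, sd_log10_len, n_contigs)
                      ).astype(int).clip(min=200)
    pick = lambda pair: np.where(is_ncldv, pair[0], pair[1])
    classifier_flag = rng.random(n_contigs) < pick(p_classifier)
    ncvog_count = rng.binomial(20, pick(p_ncvog))
    polb_flag = rng.random(n_contigs) < pick(p_polb)
    table = pd.DataFrame({
        "length": length,
        "classifier_flag": classifier_flag,
        "ncvog_count": ncvog_count,
        "polb_flag": polb_flag,
    }, index=pd.Index(ids, name="contig_id"))
    return table, pd.Series(is_ncldv, index=ids, name="is_ncldv")
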