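"""Virus-eukaryote co-occurrence networks.

Within each habitat, features present in >= 10% of the habitat's samples
are retained, every virus x ASV pair is scored by Spearman rank
correlation, p-values are Benjamini-Hochberg adjusted across all tested
pairs in that habitat, and edges with rho >= 0.60 and adjusted p < 0.05
enter the network.  Edges are interpreted as putative virus-host pairings,
hence the positive-only rho cutoff (absolute-value mode is available).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("gveco")

EDGE_COLUMNS = ["virus_id", "asv_id", "rho", "p_raw", "p_adj", "habitat"]


def prevalence_filter(m: pd.DataFrame, sample_ids: list[str],
                      min_prevalence: float = 0.10,
                      presence_min: float = 0.0) -> list[str]:
    """Features present in >= ceil(min_prevalence * n) of the given samples.

    At the 10% default a feature needs 2 of 20 samples (1 of 20 fails).
    """
    if not sample_ids:
        raise ValueError("habitat has no samples")
    needed = math.ceil(min_prevalence * len(sample_ids))
    present = (m[sample_ids] > presence_min).sum(axis=1)
    return list(m.index[present >= needed])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman_permutation_p(x: np.ndarray, y: np.ndarray, rho: float,
                            n_perm: int, rng: np.random.Generator) -> float:
    ry = sps.rankdata(y)
    rx = sps.rankdata(x)
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(rng.permutation(rx), ry)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def spearman_edges(virus: pd.DataFrame, euk: pd.DataFrame,
                   sample_ids: list[str], habitat: str = "",
                   rho_min: float = 0.60, alpha: float = 0.05,
                   min_prevalence: float = 0.10,
                   absolute: bool = False,
                   p_method: str = "t", n_perm: int = 999,
                   seed: int = 0) -> pd.DataFrame:
    """Score all virus x ASV pairs in one habitat and retain network edges.

    Both matrices are prevalence-filtered on ``sample_ids`` first.  Spearman
    rho uses average ranks for ties; raw p comes from the t-approximation
    (``p_method="t"``, adequate at the habitat sample sizes used here) or a
    rank permutation test (``p_method="permutation"``, for small n); BH
    adjustment spans every tested pair in the habitat.  Retained edges
    satisfy rho >= ``rho_min`` (|rho| if ``absolute``) and adjusted
    p < ``alpha``.  Constant features are skipped and logged.
    """
    if len(sample_ids) < 5:
        raise ValueError("need >= 5 samples for correlation")
    v_ids = prevalence_filter(virus, sample_ids, min_prevalence)
    a_ids = prevalence_filter(euk, sample_ids, min_prevalence)
    if not v_ids or not a_ids:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    vx = virus.loc[v_ids, sample_ids].to_numpy(dtype=float)
    ax = euk.loc[a_ids, sample_ids].to_numpy(dtype=float)
    const_v = [v_ids[i] for i in np.flatnonzero(vx.std(axis=1) == 0)]
    const_a = [a_ids[i] for i in np.flatnonzero(ax.std(axis=1) == 0)]
    if const_v or const_a:
        logger.info("spearman_edges[%s]: skipping constant features %s",
                    habitat, const_v + const_a)
        v_ids = [v for v in v_ids if v not in const_v]
        a_ids = [a for a in a_ids if a not in const_a]
        vx = virus.loc[v_ids, sample_ids].to_numpy(dtype=float)
        ax = euk.loc[a_ids, sample_ids].to_numpy(dtype=float)
    if not v_ids or not a_ids:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    n = len(sample_ids)
    rv = np.apply_along_axis(sps.rankdata, 1, vx)
    ra = np.apply_along_axis(sps.rankdata, 1, ax)
    rv = (rv - rv.mean(axis=1, keepdims=True)) / rv.std(axis=1, keepdims=True)
    ra = (ra - ra.mean(axis=1, keepdims=True)) / ra.std(axis=1, keepdims=True)
    rho = np.clip(rv @ ra.T / n, -1.0, 1.0)  # viruses x asvs

    if p_method == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho ** 2))
        p_raw = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
        p_raw[np.abs(rho) >= 1.0] = 0.0
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        p_raw = np.empty_like(rho)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                p_raw[i, j] = _spearman_permutation_p(
                    vx[i], ax[j], rho[i, j], n_perm, rng)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    p_adj = bh_adjust(p_raw.ravel()).reshape(p_raw.shape)
    score = np.abs(rho) if absolute else rho
    keep = (score >= rho_min) & (p_adj < alpha)
    ii, jj = np.nonzero(keep)
    edges = pd.DataFrame({
        "virus_id": [v_ids[i] for i in ii],
        "asv_id": [a_ids[j] for j in jj],
        "rho": rho[ii, jj],
        "p_raw": p_raw[ii, jj],
        "p_adj": p_adj[ii, jj],
        "habitat": habitat,
    })
    return edges[EDGE_COLUMNS]


def network_summary(edges: pd.DataFrame,
                    virus_family: pd.Series | None = None,
                    euk_group: pd.Series | None = None) -> dict:
    """Edge counts per habitat, family x host-group contingency, and node
    degrees.  Nodes without annotation fall into ``other`` with a warning."""
    if edges.empty:
        return {"n_edges": 0, "edges_per_habitat": {}, "degree": {},
                "family_by_group": {}}
    per_habitat = edges.groupby("habitat").size().to_dict()
    degree = pd.concat([edges["virus_id"], edges["asv_id"]]
                       ).value_counts().to_dict()

    def annotate(series: pd.Series | None, ids: pd.Series, kind: str) -> pd.Series:
        if series is None:
            return pd.Series("other", index=ids.index)
        ann = series.reindex(ids).reset_index(drop=True)
        ann.index = ids.index
        missing = ann.isna()
        if missing.any():
            logger.warning("network_summary: %d %s nodes unannotated -> 'other'",
                           int(missing.sum()), kind)
        return ann.fillna("other")

    fam = annotate(virus_family, edges["virus_id"], "virus")
    grp = annotate(euk_group, edges["asv_id"], "eukaryote")
    contingency = pd.crosstab(fam, grp)
    return {
        "n_edges": int(len(edges)),
        "edges_per_habitat": {k: int(v) for k, v in per_habitat.items()},
        "degree": {k: int(v) for k, v in degree.items()},
        "family_by_group": {f: {g: int(contingency.loc[f, g])
                                for g in contingency.columns}
                            for f in contingency.index},
    }


def evaluate_planted_edges(edges: pd.DataFrame,
                           planted: list[tuple[str, str, float]]) -> dict:
    """Precision/recall of detected edges against planted virus-host pairs."""
    found = set(zip(edges["virus_id"], edges["asv_id"]))
    true = {(v, a) for v, a, _ in planted}
    tp = len(found & true)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(true) if true else float("nan")
    return {"tp": tp, "n_detected": len(found), "n_planted": len(true),
            "precision": precision, "recall": recall}


def group_abundance_correlation(virus: pd.DataFrame, euk: pd.DataFrame,
                                euk_group: pd.Series,
                                sample_ids: list[str] | None = None) -> dict:
    """Pearson correlation of z-scored total virus abundance against each
    eukaryote group's z-scored total abundance across samples."""
    if sample_ids is None:
        sample_ids = [s for s in virus.columns if s in euk.columns]
    if len(sample_ids) < 3:
        raise ValueError("need >= 3 samples")
    v_tot = virus[sample_ids].sum(axis=0).to_numpy(dtype=float)
    out = {}
    for group in sorted(euk_group.dropna().unique()):
        ids = euk_group.index[euk_group == group]
        g_tot = euk.loc[euk.index.intersection(ids), sample_ids] \
            .sum(axis=0).to_numpy(dtype=float)
        if v_tot.std() == 0 or g_tot.std() == 0:
            out[group] = {"r": float("nan"), "p": float("nan"),
                          "n": len(sample_ids), "undefined": True}
            continue
        zv = (v_tot - v_tot.mean()) / v_tot.std()
        zg = (g_tot - g_tot.mean()) / g_tot.std()
        r, p = sps.pearsonr(zv, zg)
        out[group] = {"r": float(r), "p": float(p), "n": len(sample_ids),
                      "undefined": False}
    return out


def to_networkx(edges: pd.DataFrame,
                virus_family: pd.Series | None = None,
                euk_group: pd.Series | None = None):
    """Bipartite graph of retained edges (for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        v, a = row["virus_id"], row["asv_id"]
        fam = virus_family.get(v, "other") if virus_family is not None else "other"
        grp = euk_group.get(a, "other") if euk_group is not None else "other"
        g.add_node(v, kind="virus", family=str(fam))
        g.add_node(a, kind="eukaryote", group=str(grp))
        g.add_edge(v, a, rho=float(row["rho"]), p_adj=float(row["p_adj"]),
                   habitat=str(row["habitat"]))
    return g
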