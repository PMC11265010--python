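"""Coverage normalization, occupancy and niche-breadth statistics.

The niche-breadth proxy used throughout is the *environmental range*: each
of the 14 environmental variables is min-max standardized across samples,
their per-sample mean is the standardized environmental value (SEV), a
phylotype's raw range is max SEV - min SEV over the samples where it is
detected, and raw ranges are min-max standardized across phylotypes to
[0, 1].
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import HABITATS, CoverageMatrix, SampleTable

logger = logging.getLogger("gveco")


def normalize_coverage(raw: CoverageMatrix, samples: SampleTable) -> CoverageMatrix:
    """Depth-correct raw coverage: divide each sample's column by its read
    count and multiply by the mean read count over all samples."""
    missing = set(raw.sample_ids) - set(samples.sample_ids)
    if missing:
        raise ValueError(f"samples missing read counts: {sorted(missing)}")
    reads = samples.read_counts.reindex(raw.sample_ids)
    norm = raw.data / reads * reads.mean()
    return CoverageMatrix(norm, stage="normalized")


def relative_abundance(norm: CoverageMatrix) -> CoverageMatrix:
    """Proportional table: each sample column rescaled to sum to 100.

    Empty samples (all-zero columns) stay zero and are logged.
    """
    if norm.stage != "normalized":
        raise ValueError(f"expected a normalized matrix, got stage {norm.stage!r}")
    totals = norm.data.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        logger.warning("relative_abundance: empty samples left at zero: %s", empty)
    safe = totals.replace(0.0, np.nan)
    rel = (norm.data / safe * 100.0).fillna(0.0)
    return CoverageMatrix(rel, stage="relative")


def occurrence_frequency(m: CoverageMatrix, samples: SampleTable,
                         presence_min: float = 0.0) -> pd.DataFrame:
    """Percent of each habitat's samples in which each phylotype is detected."""
    present = m.presence(presence_min)
    out = {}
    for hab in HABITATS:
        ids = samples.samples_in(hab)
        ids = [s for s in ids if s in present.columns]
        if samples.habitat.eq(hab).any() and not ids:
            raise ValueError(f"habitat {hab!r} has no samples in the matrix")
        if not ids:
            continue
        out[hab] = 100.0 * present[ids].sum(axis=1) / len(ids)
    return pd.DataFrame(out)


def percent_2sf(numerator: float, denominator: float) -> float:
    """A percentage rounded to two significant figures (reporting precision
    for the occupancy summaries)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total")
    pct = 100.0 * numerator / denominator
    if pct == 0:
        return 0.0
    digits = 1 - int(math.floor(math.log10(abs(pct))))
    return round(pct, digits)


def occupancy_summary(m: CoverageMatrix, samples: SampleTable,
                      presence_min: float = 0.0) -> dict:
    """Habitat-occupancy tallies: how many phylotypes occur in 1..5 habitat
    types, which are unique to each habitat, and which are fully shared."""
    present = m.presence(presence_min)
    habitats_present = pd.DataFrame({
        hab: present[[s for s in samples.samples_in(hab) if s in present.columns]
                     ].any(axis=1)
        for hab in HABITATS
        if any(s in present.columns for s in samples.samples_in(hab))
    })
    n_habitats = habitats_present.sum(axis=1)
    total = len(m.phylotype_ids)
    counts = {k: int((n_habitats == k).sum()) for k in range(0, 6)}
    unique_sets = {
        hab: sorted(habitats_present.index[(n_habitats == 1)
                                           & habitats_present[hab]])
        for hab in habitats_present.columns
    }
    n_observed_habitats = habitats_present.shape[1]
    fully_shared = sorted(habitats_present.index[n_habitats == n_observed_habitats]) \
        if n_observed_habitats == len(HABITATS) else []
    return {
        "n_phylotypes": total,
        "counts_by_n_habitats": counts,
        "n_habitats": n_habitats,
        "unique_by_habitat": unique_sets,
        "fully_shared": fully_shared,
        "pct_single_habitat": percent_2sf(counts[1], total),
        "pct_fully_shared": percent_2sf(len(fully_shared), total),
    }


def habitat_unique_by_family(summary: dict, habitat: str,
                             family_map: pd.Series) -> dict:
    """Family composition of the phylotypes unique to one habitat.

    ``family_map`` maps phylotype id -> family name.  Returns counts per
    family and their percentage (2 s.f.) of the habitat's unique phylotypes.
    """
    unique = summary["unique_by_habitat"].get(habitat, [])
    fams = family_map.reindex(unique).fillna("unassigned")
    counts = fams.value_counts().to_dict()
    n = len(unique)
    pct = {fam: percent_2sf(c, n) for fam, c in counts.items()} if n else {}
    return {"habitat": habitat, "n_unique": n, "family_counts": counts,
            "family_pct": pct}


# ---------------------------------------------------------------------------
# Environmental range (SEV)
# ---------------------------------------------------------------------------

def sev_per_sample(samples: SampleTable,
                   variables: list[str] | None = None) -> pd.Series:
    """Per-sample mean of the min-max standardized environmental variables.

    Constant variables are dropped (their standardization is 0/0); missing
    values are excluded from both the min/max and the per-sample mean, so a
    sample's SEV averages over its available variables only.
    """
    env = samples.env(variables)
    if env.shape[1] < 1:
        raise ValueError("no environmental variables available")
    std = {}
    for v in env.columns:
        x = env[v]
        lo, hi = x.min(skipna=True), x.max(skipna=True)
        if not np.isfinite(lo) or hi == lo:
            logger.info("sev_per_sample: dropping constant/empty variable %r", v)
            continue
        std[v] = (x - lo) / (hi - lo)
    if not std:
        raise ValueError("all environmental variables are constant or missing")
    return pd.DataFrame(std).mean(axis=1, skipna=True).rename("SEV")


def environmental_range(m: CoverageMatrix, samples: SampleTable,
                        variables: list[str] | None = None,
                        presence_min: float = 0.0) -> pd.DataFrame:
    """Occupancy counts, abundance and environmental range per phylotype.

    Columns: ``n_samples_present``, ``n_sites_present``,
    ``n_habitats_present``, ``total_abundance``, ``average_abundance``
    (mean over occupied samples), ``raw_range`` (max SEV - min SEV over
    occupied samples) and ``std_range`` (raw range min-max standardized
    across phylotypes).
    """
    if len(m.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    present = m.presence(presence_min)
    if (~present.any(axis=1)).any():
        empty = present.index[~present.any(axis=1)].tolist()
        raise ValueError(f"phylotypes present in zero samples: {empty[:5]}")
    sev = sev_per_sample(samples, variables).reindex(m.sample_ids)
    habitat = samples.habitat.reindex(m.sample_ids)
    site = samples.data["site"].reindex(m.sample_ids) \
        if "site" in samples.data.columns else pd.Series(m.sample_ids,
                                                         index=m.sample_ids)

    rows = []
    for p in m.phylotype_ids:
        occ = present.loc[p]
        ids = occ.index[occ]
        vals = m.data.loc[p, ids]
        sev_occ = sev[ids]
        rows.append((
            p, len(ids), site[ids].nunique(), habitat[ids].nunique(),
            float(vals.sum()), float(vals.mean()),
            float(sev_occ.max() - sev_occ.min()),
        ))
    ert = pd.DataFrame(rows, columns=[
        "phylotype_id", "n_samples_present", "n_sites_present",
        "n_habitats_present", "total_abundance", "average_abundance",
        "raw_range"]).set_index("phylotype_id")
    lo, hi = ert["raw_range"].min(), ert["raw_range"].max()
    ert["std_range"] = 0.0 if hi == lo else (ert["raw_range"] - lo) / (hi - lo)
    return ert


def abundance_occupancy_stats(ert: pd.DataFrame) -> dict:
    """Pearson correlations linking abundance, occupancy and niche breadth.

    Abundances, site counts and ranges enter on a log scale; zero ranges are
    offset by one tenth of the smallest positive value before the log.
    Constant inputs yield ``r = nan`` flagged ``undefined``.
    """
    if len(ert) < 3:
        raise ValueError("need at least 3 phylotypes")

    def log_eps(x: pd.Series) -> tuple[np.ndarray, float]:
        x = x.astype(float)
        pos = x[x > 0]
        eps = (pos.min() / 10.0) if len(pos) else 1.0
        return np.log(x + (eps if (x <= 0).any() else 0.0)), \
            (eps if (x <= 0).any() else 0.0)

    log_avg, _ = log_eps(ert["average_abundance"])
    log_tot, _ = log_eps(ert["total_abundance"])
    log_sites, _ = log_eps(ert["n_sites_present"])
    log_range, eps_used = log_eps(ert["std_range"])

    def corr(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if np.std(x) == 0 or np.std(y) == 0:
            return {"r": float("nan"), "p": float("nan"), "n": len(x),
                    "undefined": True}
        r, p = stats.pearsonr(x, y)
        return {"r": float(r), "p": float(p), "n": len(x), "undefined": False}

    return {
        "avg_abundance_vs_n_habitats": corr(log_avg, ert["n_habitats_present"]),
        "avg_abundance_vs_log_n_sites": corr(log_avg, log_sites),
        "avg_abundance_vs_log_range": corr(log_avg, log_range),
        "total_abundance_vs_log_range": corr(log_tot, log_range),
        "n_sites_vs_log_range": corr(log_sites, log_range),
        "log_eps_for_zero_ranges": eps_used,
    }


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefaction_curve(m: CoverageMatrix, samples: SampleTable, habitat: str,
                      n_perm: int = 100, seed: int = 0,
                      presence_min: float = 0.0, exact: bool = False) -> dict:
    """Sample-based species accumulation for one habitat.

    Mean cumulative richness after k samples over ``n_perm`` random sample
    orderings, plus the terminal slope
    ``100 * (S_n - S_{n-1}) / S_n`` in percent new phylotypes per sample.
    With ``exact=True`` the mean over *all* orderings is computed in closed
    form: E[S_k] = sum_i (1 - C(n - m_i, k) / C(n, k)) with m_i the number
    of samples holding phylotype i.
    """
    ids = [s for s in samples.samples_in(habitat) if s in m.data.columns]
    if len(ids) < 2:
        raise ValueError(f"habitat {habitat!r} needs >= 2 samples")
    present = m.presence(presence_min)[ids].to_numpy()  # phylotypes x samples
    n = len(ids)
    if exact:
        m_i = present.sum(axis=1)
        mean_curve = np.array([
            np.sum(1.0 - np.array([math.comb(n - mi, k) for mi in m_i])
                   / math.comb(n, k))
            for k in range(1, n + 1)])
    else:
        rng = np.random.default_rng(seed)
        curves = np.zeros((n_perm, n))
        for r in range(n_perm):
            order = rng.permutation(n)
            seen = np.cumsum(present[:, order], axis=1) > 0
            curves[r] = seen.sum(axis=0)
        mean_curve = curves.mean(axis=0)
    slope = 100.0 * (mean_curve[-1] - mean_curve[-2]) / mean_curve[-1] \
        if mean_curve[-1] > 0 else 0.0
    return {"habitat": habitat, "k": list(range(1, n + 1)),
            "mean_richness": mean_curve.tolist(),
            "terminal_slope_pct": float(slope),
            "n_perm": n_perm, "seed": seed}


# ---------------------------------------------------------------------------
# Environmental-variable redundancy filter
# ---------------------------------------------------------------------------

def env_redundancy_filter(samples: SampleTable, rho2_max: float = 0.7,
                          variables: list[str] | None = None
                          ) -> tuple[list[str], list[str]]:
    """Drop redundant environmental variables (Spearman rho^2 > ``rho2_max``).

    While any retained pair exceeds the cutoff, the member of the worst
    pair with the larger mean absolute Spearman correlation to all other
    retained variables is removed (ties by name, for determinism).
    Returns (retained, removed) in the original column order.
    """
    env = samples.env(variables)
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    cols = list(env.columns)
    rho = pd.DataFrame(
        stats.spearmanr(env.to_numpy(), nan_policy="omit")[0]
        if len(cols) > 2 else _spearman_pair_matrix(env),
        index=cols, columns=cols,
    )
    removed: list[str] = []
    retained = list(cols)
    while True:
        sub = rho.loc[retained, retained]
        np.fill_diagonal(sub.values, 0.0)
        worst = (sub ** 2).stack()
        pair = worst.idxmax()
        if worst.max() <= rho2_max:
            break
        a, b = pair
        mean_abs = sub.abs().mean(axis=1)
        drop = a if (mean_abs[a], a) > (mean_abs[b], b) else b
        retained.remove(drop)
        removed.append(drop)
        if len(retained) < 2:
            break
    return retained, removed


def _spearman_pair_matrix(env: pd.DataFrame) -> np.ndarray:
    n = env.shape[1]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = stats.spearmanr(env.iloc[:, i], env.iloc[:, j],
                                nan_policy="omit")[0]
            out[i, j] = out[j, i] = r
    return out
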