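"""Alpha/beta diversity and permutation-based community statistics.

Permutation p-values follow the +1 convention
``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)`` so they are exact and
never smaller than ``1/(n_perm + 1)``.  All permutation draws come from a
``numpy.random.Generator`` seeded by the caller.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .io import CoverageMatrix, SampleTable

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with a metric tag."""

    sample_ids: list[str]
    matrix: np.ndarray
    metric: str  # bray-curtis | euclidean | haversine-km

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix has nonzero diagonal")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.matrix = d

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.matrix[np.ix_(idx, idx)], self.metric)


def _align(*mats: DistanceMatrix) -> list[DistanceMatrix]:
    common = set(mats[0].sample_ids)
    for m in mats[1:]:
        common &= set(m.sample_ids)
    if len(common) < 3:
        raise ValueError("matrices share fewer than 3 samples")
    order = [s for s in mats[0].sample_ids if s in common]
    return [m.reorder(order) for m in mats]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(m: CoverageMatrix, presence_min: float = 0.0) -> pd.DataFrame:
    """Per-sample richness (phylotypes detected) and Shannon H (natural log).

    Empty samples get richness 0 and Shannon NaN (flagged undefined).
    """
    present = m.presence(presence_min)
    richness = present.sum(axis=0)
    shannon = {}
    for s in m.sample_ids:
        x = m.data[s].to_numpy(dtype=float)
        x = x[x > 0]
        if x.size == 0:
            shannon[s] = float("nan")
        else:
            p = x / x.sum()
            shannon[s] = float(-(p * np.log(p)).sum())
    out = pd.DataFrame({"richness": richness.astype(int),
                        "shannon": pd.Series(shannon)})
    out["shannon_undefined"] = out["shannon"].isna()
    return out


def kruskal_wallis(groups: dict[str, np.ndarray] | list[np.ndarray]) -> dict:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (g-1 df).

    All-identical values across groups give H = 0, p = 1.
    """
    values = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(values) < 2 or any(len(v) == 0 for v in values):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(v, dtype=float) for v in values])
    if np.all(flat == flat[0]):
        return {"H": 0.0, "p": 1.0, "df": len(values) - 1}
    h, p = sps.kruskal(*values)
    return {"H": float(h), "p": float(p), "df": len(values) - 1}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def bray_curtis(m: CoverageMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    A pair of empty samples has no defined dissimilarity; it is reported
    as 0 (identical emptiness).
    """
    x = m.values.T  # samples x phylotypes
    d = squareform(pdist(x, metric="braycurtis"), checks=False)
    d = np.nan_to_num(d, nan=0.0)  # both-empty pairs
    return DistanceMatrix(m.sample_ids, d, "bray-curtis")


def euclidean_env(samples: SampleTable, variables: list[str] | None = None,
                  standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance over (z-scored) environmental variables."""
    env = samples.env(variables).dropna(axis=1, how="any")
    x = env.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"), checks=False)
    return DistanceMatrix(samples.sample_ids, d, "euclidean")


def haversine_matrix(samples: SampleTable) -> DistanceMatrix:
    """Great-circle distances (km) between sample coordinates."""
    coords = np.radians(samples.coordinates().to_numpy(dtype=float))
    lat, lon = coords[:, 0], coords[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] \
        * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples.sample_ids, d, "haversine-km")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_f(d2: np.ndarray, membership: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for one or many label permutations.

    ``membership`` is (n, P*g) column blocks of group indicators; returns F
    per permutation.  Uses the sums-of-squared-distances identities
    SS_total = sum d^2 / n and SS_within = sum_g (within-group d^2) / n_g.
    """
    n = d2.shape[0]
    g = len(sizes)
    ss_total = d2.sum() / (2.0 * n)
    prod = d2 @ membership  # n x (P*g)
    within = (membership * prod).sum(axis=0) / (2.0 * sizes[None, :].repeat(
        membership.shape[1] // g, axis=0).ravel())
    ss_within = within.reshape(-1, g).sum(axis=1)
    ss_among = ss_total - ss_within
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def permanova(d: DistanceMatrix, groups: pd.Series | dict,
              n_perm: int = 999, seed: int = 0) -> dict:
    """One-way PERMANOVA (pseudo-F, R^2, permutation p).

    Free permutation of sample labels; p includes the observed statistic
    (+1 rule).  Every group must hold >= 2 samples.
    """
    labels = pd.Series(groups).reindex(d.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    uniq, codes = np.unique(labels.to_numpy(), return_inverse=True)
    sizes = np.bincount(codes).astype(float)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (sizes < 2).any():
        small = [u for u, s in zip(uniq, sizes) if s < 2]
        raise ValueError(f"groups of size 1 not allowed: {small}")
    n, g = len(codes), len(uniq)
    d2 = d.matrix ** 2

    def membership_for(code_mat: np.ndarray) -> np.ndarray:
        # code_mat: P x n -> (n, P*g) indicator blocks
        P = code_mat.shape[0]
        memb = np.zeros((n, P * g))
        for p in range(P):
            memb[np.arange(n), p * g + code_mat[p]] = 1.0
        return memb

    f_obs = float(_permanova_f(d2, membership_for(codes[None, :]), sizes)[0])
    ss_total = d2.sum() / (2.0 * n)
    memb = membership_for(codes[None, :])
    prod = d2 @ memb
    ss_within = float(((memb * prod).sum(axis=0).reshape(-1, g)
                       @ (1.0 / (2.0 * sizes)))[0])
    r2 = 1.0 - ss_within / ss_total

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    f_perm = _permanova_f(d2, membership_for(perms), sizes)
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)
    return {"pseudo_F": f_obs, "R2": float(r2), "p": float(p),
            "n_perm": n_perm, "seed": seed, "groups": {u: int(s) for u, s
                                                       in zip(uniq, sizes)}}


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _triangle(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(dA: DistanceMatrix, dB: DistanceMatrix, method: str = "pearson",
           n_perm: int = 999, seed: int = 0) -> dict:
    """Mantel correlation between two distance matrices.

    r is the (Pearson or Spearman) correlation over the upper triangles;
    p permutes rows/columns of ``dA`` jointly (one-sided, r_perm >= r_obs,
    +1 rule).  A zero-variance triangle gives r = NaN, flagged undefined.
    """
    dA, dB = _align(dA, dB)
    a, b = dA.matrix, dB.matrix
    tb = _triangle(b)
    r_obs = _corr(_triangle(a), tb, method)
    if math.isnan(r_obs):
        return {"r": float("nan"), "p": float("nan"), "n_perm": n_perm,
                "seed": seed, "undefined": True}
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _corr(_triangle(a[np.ix_(perm, perm)]), tb, method)
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return {"r": r_obs, "p": float(p), "n_perm": n_perm, "seed": seed,
            "undefined": False, "method": method}


def partial_mantel(dA: DistanceMatrix, dB: DistanceMatrix, dC: DistanceMatrix,
                   method: str = "pearson", n_perm: int = 999,
                   seed: int = 0) -> dict:
    """Partial Mantel: correlation of A and B given C.

    First-order partial correlation of the distance triangles; the
    permutation scheme permutes ``dA`` only and recomputes the partial r
    (simple Mantel permutation of the residual association).
    """
    dA, dB, dC = _align(dA, dB, dC)
    a = dA.matrix
    tb, tc = _triangle(dB.matrix), _triangle(dC.matrix)

    def partial_r(ta: np.ndarray) -> float:
        r_ab = _corr(ta, tb, method)
        r_ac = _corr(ta, tc, method)
        r_bc = _corr(tb, tc, method)
        if any(math.isnan(v) for v in (r_ab, r_ac, r_bc)):
            return float("nan")
        den = math.sqrt((1 - r_ac ** 2) * (1 - r_bc ** 2))
        if den == 0:
            return float("nan")
        return (r_ab - r_ac * r_bc) / den

    r_obs = partial_r(_triangle(a))
    if math.isnan(r_obs):
        return {"r_partial": float("nan"), "p": float("nan"),
                "n_perm": n_perm, "seed": seed, "undefined": True}
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if partial_r(_triangle(a[np.ix_(perm, perm)])) >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return {"r_partial": float(r_obs), "p": float(p), "n_perm": n_perm,
            "seed": seed, "undefined": False, "method": method}


# ---------------------------------------------------------------------------
# Distance-decay
# ---------------------------------------------------------------------------

def distance_decay(d_comm: DistanceMatrix, d_geo: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0) -> dict:
    """Least-squares fit of community dissimilarity on log10(km + 1).

    Pairs are not independent, so significance comes from a Mantel
    permutation of the community matrix against the log-transformed
    geographic matrix, not from the naive pair-level regression p.
    """
    d_comm, d_geo = _align(d_comm, d_geo)
    if d_comm.matrix.shape[0] < 4:
        raise ValueError("need >= 4 samples")
    if np.allclose(d_geo.matrix, 0.0):
        raise ValueError("all samples are co-located")
    log_geo = np.log10(d_geo.matrix + 1.0)
    np.fill_diagonal(log_geo, 0.0)
    x = _triangle(log_geo)
    y = _triangle(d_comm.matrix)
    slope, intercept = np.polyfit(x, y, 1)
    man = mantel(d_comm, DistanceMatrix(d_comm.sample_ids, log_geo, "euclidean"),
                 method="pearson", n_perm=n_perm, seed=seed)
    return {"slope": float(slope), "intercept": float(intercept),
            "r": man["r"], "p": man["p"], "n_perm": n_perm, "seed": seed}


# ---------------------------------------------------------------------------
# Variation partitioning
# ---------------------------------------------------------------------------

def hellinger(m: CoverageMatrix) -> np.ndarray:
    """Hellinger transform: sqrt of within-sample relative abundance
    (samples x phylotypes)."""
    x = m.values.T
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.sqrt(x / totals)


def _rda_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Redundancy-analysis R^2: share of total variance of Y captured by a
    multivariate linear fit on X (with intercept)."""
    yc = y - y.mean(axis=0)
    ss_tot = (yc ** 2).sum()
    if ss_tot == 0:
        return 0.0
    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
    fitted = design @ coef
    return float((fitted ** 2).sum() / ss_tot)


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _pca_reduce(x: np.ndarray, var_target: float) -> np.ndarray:
    """Principal components of z-scored X retaining >= var_target variance."""
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    var = s ** 2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, var_target - 1e-12) + 1)
    return u[:, :k] * s[:k]


@dataclass
class VpaResult:
    """Variation partitioning over predictor blocks.

    ``fractions`` maps each non-empty block combination (sorted tuple of
    names) to its individual adjusted-R^2 fraction; ``block_totals`` gives,
    per block, the sum of all fractions containing it; ``residual`` is
    1 - adjR^2(all blocks).  Fractions can be slightly negative (adjusted
    R^2); they are stored untruncated.
    """

    fractions: dict[tuple[str, ...], float]
    block_totals: dict[str, float]
    residual: float
    subset_r2: dict[tuple[str, ...], float]
    n_samples: int

    def total_explained(self) -> float:
        return sum(self.fractions.values())


def variation_partition(m: CoverageMatrix, blocks: dict[str, pd.DataFrame],
                        pca_blocks: tuple[str, ...] = (),
                        pca_var: float = 0.8) -> VpaResult:
    """Partition community variance among predictor blocks.

    The community matrix is Hellinger-transformed; each subset of blocks is
    fitted by redundancy analysis and its R^2 adjusted (Ezekiel); the
    individual (unique and shared) fractions follow by solving the
    inclusion-exclusion system linking subset R^2 to region fractions.
    Blocks named in ``pca_blocks`` are first reduced to principal
    components retaining >= ``pca_var`` of their variance.
    """
    names = sorted(blocks)
    if not 1 <= len(names) <= 6:
        raise ValueError("need between 1 and 6 predictor blocks")
    y = hellinger(m)
    n = y.shape[0]
    xs: dict[str, np.ndarray] = {}
    for name in names:
        x = blocks[name].reindex(m.sample_ids).to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"block {name!r} has missing values")
        if name in pca_blocks:
            x = _pca_reduce(x, pca_var)
        xs[name] = x
    total_p = sum(x.shape[1] for x in xs.values())
    if n <= total_p + 1:
        raise ValueError(f"only {n} samples for {total_p} predictors after reduction")

    for name in names:
        x = xs[name]
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < x.shape[1] + 1:
            raise ValueError(f"singular design for block {name!r}")

    subsets = [tuple(c) for k in range(1, len(names) + 1)
               for c in itertools.combinations(names, k)]
    adj: dict[tuple[str, ...], float] = {}
    for sub in subsets:
        x = np.hstack([xs[nm] for nm in sub])
        # unions of blocks may be collinear (shared variation); fit by
        # projection and count effective predictors by rank
        p_eff = int(np.linalg.matrix_rank(
            x - x.mean(axis=0)))
        adj[sub] = _adjusted_r2(_rda_r2(y, x), n, p_eff)

    # Solve M f = g where g[S] = adjR2(S) and M[S, T] = 1 iff T intersects S.
    regions = subsets
    mat = np.array([[1.0 if set(t) & set(s) else 0.0 for t in regions]
                    for s in regions])
    g = np.array([adj[s] for s in regions])
    f = np.linalg.solve(mat, g)
    fractions = {t: float(v) for t, v in zip(regions, f)}
    block_totals = {nm: float(sum(v for t, v in fractions.items() if nm in t))
                    for nm in names}
    residual = 1.0 - adj[tuple(names)]
    return VpaResult(fractions=fractions, block_totals=block_totals,
                     residual=float(residual), subset_r2=adj, n_samples=n)
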