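"""Readers, writers and run configuration for the pipeline's external formats.

Tables are tab-separated UTF-8 with ``NA`` for missing values.  Phylogenetic
placements are consumed from jplace (version 3) JSON files whose tree string
carries ``{edge_num}`` annotations after each branch, the dialect emitted by
pplacer and EPA-ng.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("gveco")

#: The five terrestrial habitat types of the survey.
HABITATS = ("farmland", "forest", "grassland", "gobi", "mine")

#: The 14 environmental variables used for niche-breadth and regression
#: analyses: geography (decimal degrees / m), mean annual precipitation (mm),
#: and ten edaphic variables.
ENV_VARIABLES = (
    "LON", "LAT", "ALT", "MAP", "pH", "EC", "EX-Ca", "CaCO3",
    "CEC", "clay", "TP", "TK", "TN", "TC",
)

#: Stage tags a coverage matrix moves through.
STAGES = ("raw", "normalized", "relative")


class FormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Thresholds, permutation counts and the RNG seed for one pipeline run.

    Every serialized output embeds this record so a run can be reproduced
    from its artifacts alone.
    """

    identity_min: float = 0.95      # sequence identity for phylotype clustering
    overlap_min: float = 0.90       # alignment coverage of the shorter sequence
    support_min: float = 0.50       # like_weight_ratio below which calls are dropped
    presence_min: float = 0.0       # coverage strictly above this counts as present
    prevalence_min: float = 0.10    # habitat prevalence filter for networks
    rho_min: float = 0.60           # Spearman cutoff for network edges
    fdr_alpha: float = 0.05         # BH-adjusted significance level
    contig_min_len: int = 5000      # bp, strict lower bound for contig screening
    ncvog_min: int = 2              # marker-count criterion for contig screening
    rho2_max: float = 0.7           # Spearman rho^2 redundancy cutoff
    n_permutations: int = 999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("identity_min", "overlap_min", "support_min",
                     "prevalence_min", "rho_min", "fdr_alpha", "rho2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.contig_min_len <= 0 or self.ncvog_min < 0:
            raise ValueError("contig thresholds must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Coverage matrix
# ---------------------------------------------------------------------------

@dataclass
class CoverageMatrix:
    """Phylotype x sample abundance matrix with a processing-stage tag.

    ``data`` holds phylotypes on rows and samples on columns.  ``stage`` is
    ``raw`` (mapped-read coverage), ``normalized`` (depth-corrected coverage)
    or ``relative`` (percent per sample, columns sum to 100).
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate phylotype ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at phylotype {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at phylotype {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def phylotype_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def presence(self, threshold: float = 0.0) -> pd.DataFrame:
        """Boolean detection matrix: abundance strictly above ``threshold``."""
        return self.data > threshold

    def with_stage(self, data: pd.DataFrame, stage: str) -> "CoverageMatrix":
        return CoverageMatrix(data=data, stage=stage)


def read_coverage_matrix(path, stage: str = "raw") -> CoverageMatrix:
    """Read a phylotype x sample TSV (first column = phylotype ids).

    Zero rows (phylotypes never detected) are retained but logged.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = sorted({c for c in header if header.count(c) > 1})
    if dup_cols:
        raise FormatError(f"duplicate sample ids in header: {dup_cols}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        non_numeric = pd.to_numeric(df[col], errors="coerce")
        bad = non_numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(f"non-numeric cell at phylotype {row!r}, sample {col!r}")
        if non_numeric.isna().any():
            row = df.index[non_numeric.isna()][0]
            raise FormatError(f"missing cell at phylotype {row!r}, sample {col!r}")
        df[col] = non_numeric
    m = CoverageMatrix(data=df, stage=stage)
    zero_rows = df.index[(df == 0).all(axis=1)].tolist()
    if zero_rows:
        logger.info("coverage matrix %s: %d all-zero phylotype rows: %s",
                    path, len(zero_rows), zero_rows[:10])
    return m


def write_coverage_matrix(m: CoverageMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="phylotype_id",
                  float_format="%.6g", na_rep="NA")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample metadata: habitat, read count and environmental variables.

    ``data`` is indexed by sample id with columns ``habitat``, ``read_count``
    and the 14 environmental variables (``LON``/``LAT``/``ALT`` double as the
    geographic coordinates, decimal degrees WGS84 and metres).  Missing
    environmental values are NaN and are flagged, not imputed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids")
        required = {"habitat", "read_count", "LON", "LAT", "ALT"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        bad_hab = set(df["habitat"]) - set(HABITATS)
        if bad_hab:
            raise FormatError(
                f"unknown habitat labels {sorted(bad_hab)}; expected {HABITATS}")
        if (df["read_count"] <= 0).any() or df["read_count"].isna().any():
            raise FormatError("read_count must be a positive integer for every sample")
        lat, lon = df["LAT"], df["LON"]
        if ((lat < -90) | (lat > 90)).any():
            bad = df.index[(lat < -90) | (lat > 90)].tolist()
            raise FormatError(f"latitude outside [-90, 90] for samples {bad}")
        if ((lon < -180) | (lon > 180)).any():
            bad = df.index[(lon < -180) | (lon > 180)].tolist()
            raise FormatError(f"longitude outside [-180, 180] for samples {bad}")
        n_missing = int(df[self.env_columns].isna().sum().sum())
        if n_missing:
            logger.info("sample table: %d missing environmental values flagged", n_missing)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def habitat(self) -> pd.Series:
        return self.data["habitat"]

    @property
    def read_counts(self) -> pd.Series:
        return self.data["read_count"].astype(float)

    @property
    def env_columns(self) -> list[str]:
        return [v for v in ENV_VARIABLES if v in self.data.columns]

    def env(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Environmental variables as a numeric frame (NaN = missing)."""
        cols = list(variables) if variables is not None else self.env_columns
        unknown = set(cols) - set(self.data.columns)
        if unknown:
            raise KeyError(f"unknown environmental variables: {sorted(unknown)}")
        return self.data[cols].astype(float)

    def coordinates(self) -> pd.DataFrame:
        """(lat, lon) in decimal degrees, indexed by sample id."""
        return self.data[["LAT", "LON"]].astype(float)

    def samples_in(self, habitat: str) -> list[str]:
        if habitat not in HABITATS:
            raise ValueError(f"unknown habitat {habitat!r}")
        return list(self.data.index[self.data["habitat"] == habitat])


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return SampleTable(data=df)


def write_sample_table(t: SampleTable, path) -> None:
    t.data.to_csv(path, sep="\t", index_label="sample_id",
                  float_format="%.6g", na_rep="NA")


# ---------------------------------------------------------------------------
# jplace placements
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    """One candidate placement of a query on a reference-tree edge."""
    edge_num: int
    like_weight_ratio: float
    likelihood: float | None = None


@dataclass
class QueryPlacement:
    name: str
    placements: list[Placement]

    @property
    def best(self) -> Placement:
        """Highest like_weight_ratio candidate (first on ties)."""
        return max(self.placements, key=lambda p: p.like_weight_ratio)


@dataclass
class PlacementSet:
    """Query placements plus the edge-numbered reference tree they refer to."""
    tree: dendropy.Tree
    edge_map: dict[int, dendropy.Node]
    queries: list[QueryPlacement]

    def __len__(self) -> int:
        return len(self.queries)


_EDGE_TOKEN = re.compile(r"\{(\d+)\}")


def _parse_edge_numbered_tree(tree_str: str) -> tuple[dendropy.Tree, dict[int, dendropy.Node]]:
    """Parse a newick string with pplacer-style ``{edge_num}`` annotations.

    The edge number is moved into the node label before parsing, then
    harvested from the resulting tree.
    """
    # {N} may follow "name:len", "):len", "name" or ")"
    def _lift(match: re.Match) -> str:
        prefix, edge = match.group(1), match.group(2)
        if ":" in prefix:
            name, length = prefix.split(":", 1)
            return f"{name}__EDGE{edge}__:{length}"
        return f"{prefix}__EDGE{edge}__"

    lifted = re.sub(r"([^(),;{}]*)\{(\d+)\}", _lift, tree_str)
    leftover = _EDGE_TOKEN.search(lifted)
    if leftover or "{" in lifted or "}" in lifted:
        pos = lifted.find("{")
        raise FormatError(f"malformed edge braces in jplace tree near position {pos}")
    try:
        tree = dendropy.Tree.get(
            data=lifted, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse jplace tree: {exc}") from exc

    edge_map: dict[int, dendropy.Node] = {}
    tag = re.compile(r"^(.*)__EDGE(\d+)__$")
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if label is None:
            continue
        m = tag.match(label)
        if not m:
            continue
        name, edge = m.group(1), int(m.group(2))
        if edge in edge_map:
            raise FormatError(f"edge number {edge} appears twice in jplace tree")
        edge_map[edge] = node
        if node.taxon is not None:
            node.taxon.label = name
        else:
            node.label = name or None
    return tree, edge_map


def read_jplace(path) -> PlacementSet:
    """Read a jplace v3 file into a :class:`PlacementSet`.

    ``edge_num`` and ``like_weight_ratio`` fields are mandatory;
    ``likelihood`` is kept when present.  Every query's best placement must
    refer to an edge present in the tree.
    """
    with open(path) as fh:
        doc = json.load(fh)
    return parse_jplace(doc)


def parse_jplace(doc: Mapping) -> PlacementSet:
    for key in ("tree", "fields", "placements"):
        if key not in doc:
            raise FormatError(f"jplace document missing {key!r}")
    fields = list(doc["fields"])
    for needed in ("edge_num", "like_weight_ratio"):
        if needed not in fields:
            raise FormatError(f"jplace fields missing {needed!r}")
    i_edge = fields.index("edge_num")
    i_lwr = fields.index("like_weight_ratio")
    i_like = fields.index("likelihood") if "likelihood" in fields else None

    tree, edge_map = _parse_edge_numbered_tree(doc["tree"])

    queries: list[QueryPlacement] = []
    for entry in doc["placements"]:
        names = entry.get("n") or [nm for nm, _ in entry.get("nm", [])]
        if not names:
            raise FormatError("jplace placement entry without query name")
        placements = []
        for row in entry["p"]:
            edge = int(row[i_edge])
            if edge not in edge_map:
                raise FormatError(f"placement edge {edge} absent from jplace tree")
            placements.append(Placement(
                edge_num=edge,
                like_weight_ratio=float(row[i_lwr]),
                likelihood=float(row[i_like]) if i_like is not None else None,
            ))
        if not placements:
            raise FormatError(f"query {names[0]!r} has no placements")
        for name in names:
            queries.append(QueryPlacement(name=name, placements=placements))
    return PlacementSet(tree=tree, edge_map=edge_map, queries=queries)


def write_jplace(ps: PlacementSet, path) -> None:
    """Serialize a PlacementSet back to jplace v3."""
    doc = {
        "version": 3,
        "tree": _edge_numbered_newick(ps),
        "fields": ["edge_num", "like_weight_ratio"],
        "placements": [
            {"n": [q.name],
             "p": [[p.edge_num, round(p.like_weight_ratio, 6)] for p in q.placements]}
            for q in ps.queries
        ],
        "metadata": {"invocation": "gveco"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _edge_numbered_newick(ps: PlacementSet) -> str:
    node_to_edge = {id(node): edge for edge, node in ps.edge_map.items()}

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            base = node.taxon.label if node.taxon is not None else (node.label or "")
        else:
            base = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
            if node.label:
                base += node.label
        length = node.edge.length
        if length is not None:
            base += f":{length:g}"
        edge = node_to_edge.get(id(node))
        if edge is not None:
            base += "{%d}" % edge
        return base

    return render(ps.tree.seed_node) + ";"
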