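"""Phylotype dereplication and placement-based taxonomy.

Marker sequences are collapsed into phylotypes by greedy incremental
clustering (longest sequence founds a cluster; later sequences join the
first representative they match at >95% identity over >90% of the shorter
sequence).  Queries placed on a labeled reference tree are then classified:
a query is a giant virus (NCLDV) iff its best placement edge lies inside an
NCLDV clade; placements strictly inside a family clade with cultivated
representatives receive that family, placements basal to family clades (or
inside sparsely represented families) are family-unassigned, and
placements in the Pandoravirales clade are excluded because their long
branches make the placement unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import Align

from .io import PlacementSet, QueryPlacement

_NUC = set("ACGTUNRYSWKMBDHV")
_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass
class MarkerSequence:
    """A marker-gene sequence (nucleotide) or its protein product."""

    id: str
    seq: str
    is_protein: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        alphabet = _AA if self.is_protein else _NUC
        bad = set(self.seq) - alphabet
        if bad:
            kind = "protein" if self.is_protein else "nucleotide"
            raise ValueError(f"sequence {self.id!r}: characters {sorted(bad)} "
                             f"not valid for {kind}")

    def __len__(self) -> int:
        return len(self.seq)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def pairwise_identity(a: str, b: str,
                      aligner: Align.PairwiseAligner | None = None
                      ) -> tuple[float, float]:
    """Global-alignment identity and coverage of the shorter sequence.

    Identity is matches / aligned-overlap columns, where the overlap spans
    from the first to the last column in which both sequences have a
    residue (terminal gaps excluded, internal gaps counted).  Coverage is
    the fraction of the shorter sequence falling inside that overlap.
    """
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    both = [i for i, (x, y) in enumerate(zip(sa, sb)) if x != "-" and y != "-"]
    if not both:
        return 0.0, 0.0
    i0, i1 = both[0], both[-1]
    window_a, window_b = sa[i0:i1 + 1], sb[i0:i1 + 1]
    matches = sum(x == y and x != "-" for x, y in zip(window_a, window_b))
    overlap_cols = i1 - i0 + 1
    shorter = min(len(a), len(b))
    short_str = window_a if len(a) <= len(b) else window_b
    covered = sum(c != "-" for c in short_str)
    return matches / overlap_cols, covered / shorter


def greedy_cluster(
    seqs: list[MarkerSequence],
    identity_min: float = 0.95,
    overlap_min: float = 0.90,
) -> dict[str, list[str]]:
    """Greedy incremental clustering in length order (ties by id).

    Returns representative id -> member ids (representative included,
    members in join order).  A sequence joins the earliest-founded
    representative it matches at identity strictly above ``identity_min``
    and shorter-sequence coverage strictly above ``overlap_min``.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not (0.0 < identity_min <= 1.0 and 0.0 < overlap_min <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    aligner = _make_aligner()
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    clusters: dict[str, list[str]] = {}
    reps: list[MarkerSequence] = []
    for s in ordered:
        for rep in reps:
            ident, cov = pairwise_identity(rep.seq, s.seq, aligner)
            if ident > identity_min and cov > overlap_min:
                clusters[rep.id].append(s.id)
                break
        else:
            clusters[s.id] = [s.id]
            reps.append(s)
    return clusters


# ---------------------------------------------------------------------------
# Reference clade map and classification
# ---------------------------------------------------------------------------

@dataclass
class ReferenceCladeMap:
    """Leaf-level taxonomy of the reference tree.

    ``leaf_table`` is indexed by leaf label with columns ``clade``,
    ``is_ncldv`` (bool), ``order``, ``family`` and ``has_rep`` (whether the
    family has cultivated representatives; families without them never
    receive family-level calls).  ``low_confidence_families`` optionally
    masks family clades whose support in the reference tree was judged too
    weak; placements inside them are degraded to family-unassigned.
    """

    leaf_table: pd.DataFrame
    low_confidence_families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        required = {"is_ncldv", "order", "family", "has_rep"}
        missing = required - set(self.leaf_table.columns)
        if missing:
            raise ValueError(f"leaf table missing columns: {sorted(missing)}")
        if self.leaf_table.index.duplicated().any():
            raise ValueError("duplicate leaf labels in clade map")

    @property
    def family_leafsets(self) -> dict[str, frozenset[str]]:
        t = self.leaf_table
        return {fam: frozenset(t.index[t["family"] == fam])
                for fam in t.loc[t["is_ncldv"], "family"].unique() if fam}


def read_clade_map(path) -> ReferenceCladeMap:
    """Read a leaf -> taxonomy TSV (columns leaf, clade, is_ncldv, order,
    family, has_rep)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df["is_ncldv"] = df["is_ncldv"].astype(bool)
    df["has_rep"] = df["has_rep"].astype(bool)
    df[["order", "family"]] = df[["order", "family"]].fillna("")
    return ReferenceCladeMap(leaf_table=df)


@dataclass
class TaxonomyCall:
    """Outcome of classifying one query placement."""

    query: str
    decision: str                  # "NCLDV" | "non-NCLDV"
    order: str = ""                # "" when non-NCLDV, "unassigned" when ambiguous
    family: str = "not-applicable"  # family name | "unassigned" | "not-applicable"
    excluded: bool = False
    reason: str = ""
    support: float = float("nan")  # best like_weight_ratio

    def __post_init__(self) -> None:
        if self.decision not in ("NCLDV", "non-NCLDV"):
            raise ValueError(f"bad decision {self.decision!r}")
        if self.excluded and not self.reason:
            raise ValueError("excluded call requires a reason")
        if self.decision != "NCLDV" and self.family not in ("not-applicable",):
            raise ValueError("family set on a non-NCLDV call")

    @property
    def is_ncldv(self) -> bool:
        """True when the query counts as an identified giant virus."""
        return self.decision == "NCLDV" and not self.excluded


def _subtree_leaves(node: dendropy.Node) -> frozenset[str]:
    if node.is_leaf():
        return frozenset([node.taxon.label])
    return frozenset(l.taxon.label for l in node.leaf_iter())


def classify_placement(
    ps: PlacementSet,
    query: QueryPlacement,
    clades: ReferenceCladeMap,
    support_min: float = 0.5,
) -> TaxonomyCall:
    """Classify one query from its best (highest like_weight_ratio) placement.

    The placement edge is the branch above the node carrying its edge
    number; the decision depends only on the set of reference leaves below
    that edge:

    * any outgroup leaf below (or above the NCLDV/outgroup split) -> non-NCLDV;
    * all leaves in one family clade, strictly below the family's root, with
      cultivated representatives -> that family;
    * otherwise one order -> that order, family unassigned (covers family
      stem edges and sparsely represented families);
    * several NCLDV orders -> order unassigned;
    * order Pandoravirales -> excluded (``pandoravirales-removed``);
    * best like_weight_ratio < ``support_min`` -> excluded (``low-support``).
    """
    best = query.best
    node = ps.edge_map.get(best.edge_num)
    if node is None:
        raise KeyError(f"edge {best.edge_num} not in reference tree")
    leaves = _subtree_leaves(node)
    table = clades.leaf_table
    unknown = leaves - set(table.index)
    if unknown:
        raise ValueError(
            f"edge {best.edge_num}: leaves {sorted(unknown)[:5]} absent from clade map")
    info = table.loc[sorted(leaves)]

    all_ncldv_leaves = frozenset(table.index[table["is_ncldv"]])
    if (~info["is_ncldv"]).any() or leaves == all_ncldv_leaves:
        # outgroup content below, or the NCLDV/outgroup split edge itself
        call = TaxonomyCall(query.name, "non-NCLDV", support=best.like_weight_ratio)
    else:
        orders = set(info["order"])
        if len(orders) > 1:
            call = TaxonomyCall(query.name, "NCLDV", order="unassigned",
                                family="unassigned", support=best.like_weight_ratio)
        else:
            order = orders.pop()
            families = set(info["family"])
            family = "unassigned"
            if len(families) == 1:
                fam = families.pop()
                fam_ls = clades.family_leafsets.get(fam, frozenset())
                strictly_inside = leaves < fam_ls
                if (strictly_inside and info["has_rep"].all()
                        and fam not in clades.low_confidence_families):
                    family = fam
            call = TaxonomyCall(query.name, "NCLDV", order=order, family=family,
                                support=best.like_weight_ratio)
            if order == "Pandoravirales":
                call.excluded = True
                call.reason = "pandoravirales-removed"
    if not call.excluded and best.like_weight_ratio < support_min:
        call.excluded = True
        call.reason = "low-support"
    return call


def classify_all(ps: PlacementSet, clades: ReferenceCladeMap,
                 support_min: float = 0.5) -> list[TaxonomyCall]:
    return [classify_placement(ps, q, clades, support_min) for q in ps.queries]


def calls_to_frame(calls: list[TaxonomyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.query, c.decision, c.order, c.family, c.excluded, c.reason, c.support)
         for c in calls],
        columns=["query", "decision", "order", "family", "excluded", "reason",
                 "support"],
    ).set_index("query")


# ---------------------------------------------------------------------------
# Decoy benchmark
# ---------------------------------------------------------------------------

def benchmark_decoys(calls: list[TaxonomyCall],
                     truth: pd.Series | dict) -> dict:
    """Confusion summary against known query origins.

    ``truth`` maps query id to ``"ncldv"`` or a decoy class
    (``eukaryote``/``bacteria``/``archaea``/``phage``).  A query counts as
    identified NCLDV iff its call is NCLDV and not excluded.  Returns TP,
    FP, TN, FN, the false-positive rate FP/(FP+TN), and per-class decoy
    counts.
    """
    truth = dict(truth)
    tp = fp = tn = fn = 0
    per_class: dict[str, dict[str, int]] = {}
    for call in calls:
        if call.query not in truth:
            raise KeyError(f"query {call.query!r} has no truth label")
        label = truth[call.query]
        positive = call.is_ncldv
        if label == "ncldv":
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
            cls = per_class.setdefault(label, {"n": 0, "false_positive": 0})
            cls["n"] += 1
            cls["false_positive"] += positive
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "FPR": fpr,
            "decoy_classes": per_class}
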