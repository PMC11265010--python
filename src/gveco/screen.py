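"""Screening of assembled contigs for putative giant-virus origin.

A contig longer than 5 kb is accepted when any of three marker criteria
fires: an NCLDV-specific classifier flag, at least 2 of the 20 ancestral
NCVOG marker groups, or the presence of the polB gene (NCVOG0038).  The
module also tallies glycoside-hydrolase annotations from genome tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class ContigRecord:
    contig_id: str
    length: int
    classifier_flag: bool
    ncvog_count: int
    polb_flag: bool

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: length must be > 0")
        if not 0 <= self.ncvog_count <= 20:
            raise ValueError(f"{self.contig_id}: ncvog_count must be in 0..20")


def screen_contigs(contigs: pd.DataFrame | list[ContigRecord],
                   min_len: int = 5000, ncvog_min: int = 2) -> pd.DataFrame:
    """Apply the screening rule to a contig annotation table.

    Accept iff length > ``min_len`` (strict) AND (classifier_flag OR
    ncvog_count >= ``ncvog_min`` OR polb_flag).  Returns an audit table
    with per-criterion columns and the final ``accepted`` flag; criteria
    may co-fire.
    """
    if isinstance(contigs, list):
        contigs = pd.DataFrame(
            [(c.contig_id, c.length, c.classifier_flag, c.ncvog_count,
              c.polb_flag) for c in contigs],
            columns=["contig_id", "length", "classifier_flag", "ncvog_count",
                     "polb_flag"]).set_index("contig_id")
    audit = pd.DataFrame(index=contigs.index)
    audit["long_enough"] = contigs["length"] > min_len
    audit["by_classifier"] = audit["long_enough"] & contigs["classifier_flag"]
    audit["by_ncvog"] = audit["long_enough"] & (contigs["ncvog_count"] >= ncvog_min)
    audit["by_polb"] = audit["long_enough"] & contigs["polb_flag"]
    audit["accepted"] = audit[["by_classifier", "by_ncvog", "by_polb"]].any(axis=1)
    return audit


def accepted_ids(audit: pd.DataFrame) -> list[str]:
    return list(audit.index[audit["accepted"]])


def tally_gh_families(annotations: pd.DataFrame) -> dict:
    """Summarize glycoside-hydrolase annotations.

    ``annotations`` has columns ``genome_id``, ``gene_id``, ``gh_family``.
    Duplicate (genome, gene) rows are collapsed with a warning flag in the
    output.  Returns gene counts per GH family, the number of genomes
    carrying >= 1 GH gene, and the number of distinct families.
    """
    required = {"genome_id", "gene_id", "gh_family"}
    if annotations.empty:
        return {"n_genes": 0, "n_families": 0, "n_genomes": 0,
                "genes_per_family": {}, "n_duplicates_dropped": 0}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if (annotations["gh_family"].astype(str).str.strip() == "").any():
        raise ValueError("empty GH family label")
    before = len(annotations)
    dedup = annotations.drop_duplicates(subset=["genome_id", "gene_id"])
    return {
        "n_genes": int(len(dedup)),
        "n_families": int(dedup["gh_family"].nunique()),
        "n_genomes": int(dedup["genome_id"].nunique()),
        "genes_per_family": dedup["gh_family"].value_counts().to_dict(),
        "n_duplicates_dropped": int(before - len(dedup)),
    }
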