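"""Candidate-gene calling inside QTL physical intervals.

Genes overlapping a QTL's physical support interval are flagged as
candidates when any of their biological-process GO term names contains
(case-insensitively) one of the drought-physiology keywords: abscisic
acid, water transport, root development, leaf senescence, jasmonic acid,
heat acclimation, stomata, salicylic acid.

Coordinates are 1-based inclusive throughout, matching the
"Gm10:116991-1903082" interval notation and GFF3 conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import AnalysisWarning, InvalidInputError

__all__ = [
    "DEFAULT_KEYWORDS",
    "GeneRecord",
    "CandidateCall",
    "genes_in_interval",
    "filter_candidates",
    "read_annotation_tsv",
    "read_annotation_gff3",
    "candidate_report",
    "parse_interval",
]

DEFAULT_KEYWORDS = (
    "abscisic acid",
    "water transport",
    "root development",
    "leaf senescence",
    "jasmonic acid",
    "heat acclimation",
    "stomata",
    "salicylic acid",
)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: location plus GO term names."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    go_terms: tuple[tuple[str, str], ...] = ()  # (go_id, name)
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidInputError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class CandidateCall:
    """A candidate gene with the keywords that flagged it."""

    gene: GeneRecord
    matched_keywords: tuple[str, ...]


def genes_in_interval(
    annotation: list[GeneRecord], chromosome: str, start: int, end: int
) -> list[GeneRecord]:
    """Genes overlapping [start, end] on a chromosome by >= 1 bp, by start.

    Inclusive overlap: a gene ending exactly at ``start`` (or starting at
    ``end``) is included.  An unknown chromosome yields an empty list with
    a warning.
    """
    if start > end:
        raise InvalidInputError(f"interval start {start} > end {end}")
    on = [g for g in annotation if g.chromosome == chromosome]
    if not on and annotation:
        warnings.warn(
            f"chromosome {chromosome!r} absent from annotation",
            AnalysisWarning,
            stacklevel=2,
        )
        return []
    hits = [g for g in on if g.start <= end and g.end >= start]
    return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))


def filter_candidates(
    genes: list[GeneRecord],
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
    search_description: bool = False,
) -> list[CandidateCall]:
    """Keyword filter over GO term names (case-insensitive substring).

    Each call records every keyword that matched at least one GO term name
    (or, when ``search_description`` is on, the free-text description).
    Genes without GO terms are simply never candidates.  Output order is
    deterministic: by start coordinate then gene id.
    """
    if not keywords:
        raise InvalidInputError("keyword list must be nonempty")
    kw = [k.lower() for k in keywords]
    calls = []
    for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.end, g.gene_id)):
        haystacks = [name.lower() for _, name in g.go_terms]
        if search_description and g.description:
            haystacks.append(g.description.lower())
        matched = tuple(
            orig
            for orig, low in zip(keywords, kw)
            if any(low in h for h in haystacks)
        )
        if matched:
            calls.append(CandidateCall(gene=g, matched_keywords=matched))
    return calls


def parse_interval(text: str) -> tuple[str, int, int]:
    """Parse "Gm10:116991-1903082" into (chromosome, start, end)."""
    try:
        chrom, span = text.split(":")
        lo, hi = span.replace("–", "-").split("-")
        return chrom, int(lo), int(hi)
    except ValueError as exc:
        raise InvalidInputError(f"cannot parse interval {text!r}") from exc


def read_annotation_tsv(path) -> list[GeneRecord]:
    """Flat TSV annotation: gene_id,chromosome,start,end,go_ids,go_names,description.

    go_ids and go_names are ``|``-separated parallel lists (may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["gene_id", "chromosome", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"annotation TSV missing columns: {missing}")
    genes = []
    for _, row in df.iterrows():
        ids = [s for s in str(row.get("go_ids", "")).split("|") if s]
        names = [s for s in str(row.get("go_names", "")).split("|") if s]
        if len(ids) < len(names):
            ids += [""] * (len(names) - len(ids))
        genes.append(
            GeneRecord(
                gene_id=row["gene_id"],
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
                go_terms=tuple(zip(ids, names)),
                description=str(row.get("description", "")),
            )
        )
    return genes


def write_annotation_tsv(genes: list[GeneRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "go_ids": "|".join(i for i, _ in g.go_terms),
                "go_names": "|".join(n for _, n in g.go_terms),
                "description": g.description,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_annotation_gff3(
    path,
    go_attribute: str = "Ontology_term",
    go_name_attribute: str = "Ontology_name",
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Read gene features from a GFF3 file (in-memory gffutils database).

    GO ids are taken from ``go_attribute`` and the matching human-readable
    names from ``go_name_attribute`` (both multi-valued GFF3 attributes);
    the free-text ``description`` / ``Note`` attribute is kept if present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        ids = list(feat.attributes.get(go_attribute, []))
        names = list(feat.attributes.get(go_name_attribute, []))
        if len(ids) < len(names):
            ids += [""] * (len(names) - len(ids))
        desc = (
            feat.attributes.get("description", feat.attributes.get("Note", [""]))
        )[0]
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                go_terms=tuple(zip(ids, names)),
                description=desc,
            )
        )
    return genes


def candidate_report(calls: list[CandidateCall]) -> pd.DataFrame:
    """Flat table of candidate calls, one row per gene."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene.gene_id,
                "chromosome": c.gene.chromosome,
                "start": c.gene.start,
                "end": c.gene.end,
                "matched_keywords": "|".join(c.matched_keywords),
                "go_names": "|".join(n for _, n in c.gene.go_terms),
            }
            for c in calls
        ]
    )
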