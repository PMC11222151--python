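"""Putative auxiliary-metabolic-gene (AMG) screening.

Genes on accepted viral contigs carry viral-marker labels from the
upstream classifier: ``VV-1`` (viral hallmark, e.g. terminase or capsid),
``V*-0`` (viral non-hallmark), or host/unclassified labels. Candidate AMGs
are the non-viral-labelled genes; each is categorized by the label class of
the nearest viral-labelled gene on each side:

=========  =========================================
category   flanking context (unordered)
=========  =========================================
1          hallmark / hallmark
2          hallmark / viral non-hallmark
3          viral non-hallmark / viral non-hallmark
4          hallmark / none
5          viral non-hallmark / none
=========  =========================================

Only categories 1-3 — candidates flanked by virus-specific genes on *both*
sides — are retained. Each retained gene receives the single functional
annotation with the highest bitscore (duplicates disallowed; ties broken by
database priority KO > CAZy > Pfam, then identifier), and genes whose
annotation maps to no KEGG pathway are removed. The five-category scheme is
one natural enumeration of the flanking-context combinations; both the
scheme and the context window are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneRecord",
    "AmgCall",
    "MARKER_LABELS",
    "classify_gene_context",
    "retain_amgs",
    "best_annotation",
    "kegg_filter",
    "amg_pipeline",
    "abundance_tables",
]

HALLMARK = "VV-1"
VIRAL_NONHALLMARK = "V*-0"
MARKER_LABELS = (HALLMARK, VIRAL_NONHALLMARK, "HOST", "UNCLASSIFIED")
_DB_PRIORITY = {"KO": 0, "CAZy": 1, "Pfam": 2}

#: context pair (sorted) -> category
DEFAULT_CATEGORY_SCHEME = {
    ("hallmark", "hallmark"): 1,
    ("hallmark", "viral_nonhallmark"): 2,
    ("viral_nonhallmark", "viral_nonhallmark"): 3,
    ("hallmark", "none"): 4,
    ("none", "viral_nonhallmark"): 5,
}


@dataclass
class GeneRecord:
    gene_id: str
    contig_id: str
    index: int  # 0-based position on the contig, left to right
    start: int  # 1-based inclusive
    end: int
    strand: str
    marker_label: str
    annotations: list[tuple[str, str, float]] = field(default_factory=list)  # (db, id, bitscore)


@dataclass
class AmgCall:
    gene_id: str
    contig_id: str
    category: int
    left_context: str  # hallmark | viral_nonhallmark | none
    right_context: str
    retained: bool = False
    annotation: tuple[str, str, float] | None = None
    pathways: list[str] = field(default_factory=list)


def _context_class(label: str) -> str | None:
    if label == HALLMARK:
        return "hallmark"
    if label == VIRAL_NONHALLMARK:
        return "viral_nonhallmark"
    return None


def classify_gene_context(
    genes: list[GeneRecord],
    scheme: dict[tuple[str, str], int] | None = None,
    window: int | None = None,
) -> list[AmgCall]:
    """Assign flanking-context categories to candidate genes of one contig.

    Candidates are genes labelled host-like or unclassified; each side's
    context is the label class of the nearest viral-labelled gene on that
    side (``none`` if absent, or farther than ``window`` genes away when a
    window is set). Genes with no viral context on either side are not AMG
    candidates and are omitted. Input must be sorted by on-contig index.
    """
    scheme = scheme or DEFAULT_CATEGORY_SCHEME
    if any(b.index <= a.index for a, b in zip(genes, genes[1:])):
        raise ValueError("genes must be sorted by on-contig index")
    calls = []
    for i, gene in enumerate(genes):
        if _context_class(gene.marker_label) is not None:
            continue  # viral-labelled genes are anchors, not candidates
        left = right = "none"
        for j in range(i - 1, -1, -1):
            if window is not None and i - j > window:
                break
            ctx = _context_class(genes[j].marker_label)
            if ctx is not None:
                left = ctx
                break
        for j in range(i + 1, len(genes)):
            if window is not None and j - i > window:
                break
            ctx = _context_class(genes[j].marker_label)
            if ctx is not None:
                right = ctx
                break
        if left == "none" and right == "none":
            continue
        category = scheme[tuple(sorted((left, right)))]
        calls.append(
            AmgCall(
                gene_id=gene.gene_id,
                contig_id=gene.contig_id,
                category=category,
                left_context=left,
                right_context=right,
            )
        )
    return calls


def retain_amgs(calls: list[AmgCall]) -> list[AmgCall]:
    """Flag calls whose both flanks are virus-specific (categories 1-3)."""
    for c in calls:
        c.retained = c.left_context != "none" and c.right_context != "none"
    return calls


def best_annotation(gene: GeneRecord) -> tuple[str, str, float] | None:
    """Single best annotation by bitscore; ties by KO > CAZy > Pfam, then
    lexicographic identifier. None for unannotated genes."""
    if not gene.annotations:
        return None
    for db, ident, bits in gene.annotations:
        if bits < 0:
            raise ValueError(f"negative bitscore on {gene.gene_id}: {bits}")
        if db not in _DB_PRIORITY:
            raise ValueError(f"unknown annotation database {db!r}")
    return min(
        gene.annotations, key=lambda a: (-a[2], _DB_PRIORITY[a[0]], a[1])
    )


def kegg_filter(
    calls: list[AmgCall],
    genes: dict[str, GeneRecord],
    pathway_map: dict[str, list[str]],
) -> list[AmgCall]:
    """Final AMG set: retained calls whose best annotation maps to >= 1
    KEGG pathway, with the full pathway list attached."""
    final = []
    for c in calls:
        if not c.retained:
            continue
        ann = best_annotation(genes[c.gene_id])
        if ann is None:
            continue
        pathways = pathway_map.get(ann[1], [])
        if not pathways:
            continue
        c.annotation = ann
        c.pathways = list(pathways)
        final.append(c)
    return final


def amg_pipeline(
    genes: list[GeneRecord],
    pathway_map: dict[str, list[str]],
    scheme: dict[tuple[str, str], int] | None = None,
    window: int | None = None,
) -> tuple[list[AmgCall], list[AmgCall]]:
    """Context classification -> retention -> annotation -> KEGG filter.

    Returns ``(all_calls, final_amgs)``: every candidate call with category
    and retention flag, and the KEGG-mapped final set.
    """
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    calls: list[AmgCall] = []
    for contig_id in sorted(by_contig):
        contig_genes = sorted(by_contig[contig_id], key=lambda g: g.index)
        calls.extend(classify_gene_context(contig_genes, scheme=scheme, window=window))
    retain_amgs(calls)
    gene_index = {g.gene_id: g for g in genes}
    final = kegg_filter(calls, gene_index, pathway_map)
    return calls, final


def genes_to_frame(genes: list[GeneRecord]) -> pd.DataFrame:
    """Gene table as a TSV-ready frame; annotations packed as
    semicolon-joined ``db:identifier:bitscore`` triples."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "contig_id": g.contig_id,
                "index": g.index,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "marker_label": g.marker_label,
                "annotations": ";".join(f"{d}:{i}:{b:g}" for d, i, b in g.annotations),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "contig_id",
            "index",
            "start",
            "end",
            "strand",
            "marker_label",
            "annotations",
        ],
    )


def frame_to_genes(df: pd.DataFrame) -> list[GeneRecord]:
    genes = []
    for r in df.to_dict("records"):
        packed = r.get("annotations")
        annotations = []
        if isinstance(packed, str) and packed:
            for item in packed.split(";"):
                db, ident, bits = item.split(":")
                annotations.append((db, ident, float(bits)))
        genes.append(
            GeneRecord(
                gene_id=r["gene_id"],
                contig_id=r["contig_id"],
                index=int(r["index"]),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=r["strand"],
                marker_label=r["marker_label"],
                annotations=annotations,
            )
        )
    return genes


def calls_to_frame(calls: list[AmgCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        ann = c.annotation
        rows.append(
            {
                "gene_id": c.gene_id,
                "contig_id": c.contig_id,
                "category": c.category,
                "left_context": c.left_context,
                "right_context": c.right_context,
                "retained": c.retained,
                "annotation_db": ann[0] if ann else "",
                "annotation_id": ann[1] if ann else "",
                "annotation_bitscore": ann[2] if ann else float("nan"),
                "pathways": ";".join(c.pathways),
            }
        )
    return pd.DataFrame(rows)


def abundance_tables(
    final_calls: list[AmgCall], contig_sample: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pathway and per-annotation AMG gene-copy counts per sample."""
    path_rows: dict[tuple[str, str], int] = {}
    ann_rows: dict[tuple[str, str], int] = {}
    for c in final_calls:
        sample = contig_sample.get(c.contig_id, "unknown")
        ident = c.annotation[1] if c.annotation else "unannotated"
        ann_rows[(ident, sample)] = ann_rows.get((ident, sample), 0) + 1
        for p in c.pathways:
            path_rows[(p, sample)] = path_rows.get((p, sample), 0) + 1

    def _pivot(counts: dict[tuple[str, str], int], attr: str) -> pd.DataFrame:
        df = pd.DataFrame(
            [{attr: k, "sample_id": s, "gene_copies": v} for (k, s), v in counts.items()]
        )
        if df.empty:
            return df
        return (
            df.pivot(index=attr, columns="sample_id", values="gene_copies")
            .fillna(0)
            .astype(int)
        )

    return _pivot(path_rows, "pathway"), _pivot(ann_rows, "annotation")
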