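"""CRISPR-spacer matching and consensus host-taxon assignment.

Viral contigs are searched for protospacers — full-length, gapless
occurrences of database spacers on either strand with at most a configured
number of substitutions. Retained hits (>= 25 bp, < 2 mismatches, >= 95%
spacer coverage) vote for the source host's lineage: a contig is assigned
to the host taxon at the lowest (most specific) rank where some taxon is
supported by at least two distinct spacers representing strictly more than
70% of the distinct spacers with a defined taxon at that rank.

The search is exact by construction: the spacer is split into
``max_mismatches + 1`` blocks, one of which must match exactly (pigeonhole),
candidate offsets are then verified by Hamming count. With the gapless,
full-length contract the result equals a brute-force scan of every offset
on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import SpacerDB, reverse_complement

__all__ = [
    "SpacerHit",
    "HostAssignment",
    "RANKS_BOTTOM_UP",
    "spacer_search",
    "filter_hits",
    "assign_host",
    "assign_hosts",
    "host_summary",
]

#: Most specific rank first ("lowest" in taxonomic parlance).
RANKS_BOTTOM_UP = ("species", "genus", "family", "order", "class", "phylum", "domain")


@dataclass
class SpacerHit:
    spacer_id: str
    host_genome_id: str | None
    contig_id: str
    position: int  # 0-based, forward strand of the contig
    strand: str
    matched_length: int
    mismatches: int
    spacer_coverage: float = 1.0
    lineage: dict[str, str] = field(default_factory=dict)


@dataclass
class HostAssignment:
    contig_id: str
    taxon: str
    rank: str
    n_spacers_supporting: int
    support_fraction: float
    n_spacers_total: int


def _block_starts(length: int, n_blocks: int) -> list[tuple[int, int]]:
    size = length // n_blocks
    bounds = []
    start = 0
    for b in range(n_blocks):
        end = start + size + (1 if b < length % n_blocks else 0)
        bounds.append((start, end))
        start = end
    return bounds


def _occurrences(contig: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """(offset, mismatches) of every full-length gapless occurrence with
    <= max_mm substitutions, via pigeonhole block seeding."""
    m = len(pattern)
    n = len(contig)
    if m > n:
        return []
    candidates = set()
    for bs, be in _block_starts(m, max_mm + 1):
        block = pattern[bs:be]
        at = contig.find(block)
        while at != -1:
            off = at - bs
            if 0 <= off <= n - m:
                candidates.add(off)
            at = contig.find(block, at + 1)
    out = []
    for off in sorted(candidates):
        mm = 0
        window = contig[off : off + m]
        for a, b in zip(window, pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            out.append((off, mm))
    return out


def spacer_search(
    spacer_db: SpacerDB,
    contigs: dict[str, str],
    max_mismatches: int = 1,
    lineages: pd.DataFrame | None = None,
) -> list[SpacerHit]:
    """Find all full-length spacer occurrences on both strands.

    Positions are reported on the contig forward strand; a minus-strand hit
    means the reverse complement of the spacer occurs at that position.
    ``lineages`` (genome_id + rank columns) attaches host taxonomy to each
    hit. Spacer coverage is 1.0 by construction (full-length matcher).
    """
    lineage_of: dict[str, dict[str, str]] = {}
    if lineages is not None:
        for row in lineages.to_dict("records"):
            gid = row.pop("genome_id")
            lineage_of[gid] = {k: v for k, v in row.items() if pd.notna(v)}
    hits: list[SpacerHit] = []
    for contig_id, contig in contigs.items():
        for spacer_id, spacer in spacer_db.spacers.items():
            host = spacer_db.host_of.get(spacer_id)
            for strand, pattern in (("+", spacer), ("-", reverse_complement(spacer))):
                for off, mm in _occurrences(contig, pattern, max_mismatches):
                    hits.append(
                        SpacerHit(
                            spacer_id=spacer_id,
                            host_genome_id=host,
                            contig_id=contig_id,
                            position=off,
                            strand=strand,
                            matched_length=len(spacer),
                            mismatches=mm,
                            spacer_coverage=1.0,
                            lineage=dict(lineage_of.get(host, {})),
                        )
                    )
    return hits


def filter_hits(
    hits: list[SpacerHit],
    min_len: int = 25,
    max_mm_exclusive: int = 2,
    min_cov: float = 0.95,
) -> list[SpacerHit]:
    """Retain hits of >= ``min_len`` bp, with fewer than
    ``max_mm_exclusive`` mismatches, covering >= ``min_cov`` of the spacer."""
    return [
        h
        for h in hits
        if h.matched_length >= min_len
        and h.mismatches < max_mm_exclusive
        and h.spacer_coverage >= min_cov
    ]


def assign_host(
    contig_hits: list[SpacerHit],
    ranks: tuple[str, ...] = RANKS_BOTTOM_UP,
    min_spacers: int = 2,
    min_support: float = 0.7,
    denominator: str = "defined",
) -> HostAssignment | None:
    """Consensus host taxon for one contig from its filtered hits.

    Support is counted in *distinct spacer ids*. Walking ranks from most to
    least specific, the contig is assigned at the first rank where some
    taxon reaches >= ``min_spacers`` distinct spacers and a strict majority
    > ``min_support`` of the distinct spacers with a defined taxon at that
    rank (``denominator="total"`` divides by all distinct spacers instead).
    Returns None when no rank qualifies.
    """
    if not contig_hits:
        return None
    contig_id = contig_hits[0].contig_id
    spacer_lineage: dict[str, dict[str, str]] = {}
    for h in contig_hits:
        spacer_lineage.setdefault(h.spacer_id, h.lineage)
    total = len(spacer_lineage)
    for rank in ranks:
        taxa: dict[str, set[str]] = {}
        defined = 0
        for spacer_id, lineage in spacer_lineage.items():
            taxon = lineage.get(rank)
            if taxon is None:
                continue
            defined += 1
            taxa.setdefault(taxon, set()).add(spacer_id)
        if not taxa:
            continue
        denom = defined if denominator == "defined" else total
        taxon, supporters = max(taxa.items(), key=lambda kv: (len(kv[1]), kv[0]))
        if len(supporters) >= min_spacers and len(supporters) / denom > min_support:
            return HostAssignment(
                contig_id=contig_id,
                taxon=taxon,
                rank=rank,
                n_spacers_supporting=len(supporters),
                support_fraction=len(supporters) / denom,
                n_spacers_total=total,
            )
    return None


def assign_hosts(hits: list[SpacerHit], **kwargs) -> list[HostAssignment]:
    """Per-contig consensus assignment over a filtered hit list."""
    by_contig: dict[str, list[SpacerHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    out = []
    for contig_id in sorted(by_contig):
        a = assign_host(by_contig[contig_id], **kwargs)
        if a is not None:
            out.append(a)
    return out


def host_summary(
    assignments: list[HostAssignment],
    hits: list[SpacerHit],
    contig_sample: dict[str, str],
) -> pd.DataFrame:
    """Per-sample host-linkage table.

    Columns: number of viral contigs, contigs with >= 1 retained hit and
    their fraction, spacer-hit count and its ratio to viral contigs, number
    of unique host orders, and viral-contigs-per-host-order ratio.
    """
    samples = sorted(set(contig_sample.values()))
    contigs_per_sample: dict[str, set[str]] = {s: set() for s in samples}
    for c, s in contig_sample.items():
        contigs_per_sample[s].add(c)
    hit_contigs: dict[str, set[str]] = {s: set() for s in samples}
    n_hits: dict[str, int] = {s: 0 for s in samples}
    for h in hits:
        s = contig_sample.get(h.contig_id)
        if s is None:
            continue
        hit_contigs[s].add(h.contig_id)
        n_hits[s] += 1
    orders: dict[str, set[str]] = {s: set() for s in samples}
    assigned: dict[str, set[str]] = {s: set() for s in samples}
    order_of = {a.contig_id: a for a in assignments}
    for a in assignments:
        s = contig_sample.get(a.contig_id)
        if s is None:
            continue
        assigned[s].add(a.contig_id)
        if a.rank == "order":
            orders[s].add(a.taxon)
        else:
            # use order-rank context when available from hits of this contig
            for h in (h for h in hits if h.contig_id == a.contig_id):
                o = h.lineage.get("order")
                if o:
                    orders[s].add(o)
                    break
    rows = []
    for s in samples:
        n_contigs = len(contigs_per_sample[s])
        n_with_hit = len(hit_contigs[s])
        n_orders = len(orders[s])
        rows.append(
            {
                "sample_id": s,
                "n_viral_contigs": n_contigs,
                "n_contigs_with_hit": n_with_hit,
                "fraction_with_hit": n_with_hit / n_contigs if n_contigs else 0.0,
                "n_spacer_hits": n_hits[s],
                "hit_to_contig_ratio": n_hits[s] / n_contigs if n_contigs else 0.0,
                "n_host_orders": n_orders,
                "contigs_per_host_order": (
                    len(assigned[s]) / n_orders if n_orders else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
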