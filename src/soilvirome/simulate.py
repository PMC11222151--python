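"""Synthetic viral metagenome generation with planted ground truth.

Every input the downstream pipeline consumes can be produced here at toy
scale: viral genomes with planted ANI cluster structure and optional direct
terminal repeats (DTRs), gene tables with controlled viral-marker layouts,
CRISPR spacer databases with host lineages, implanted protospacers with an
exact number of mismatches, and attribute x sample occupancy matrices.

Mutations are point substitutions only (no indels), at distinct positions,
each changing the base — so realized ancestor-to-member identity equals the
planned identity exactly and alignment-free Hamming oracles are exact.
Randomness flows from a single integer seed, hierarchically split per
operation via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ProtospacerImplant",
    "SpacerDB",
    "make_viral_genomes",
    "make_gene_table",
    "make_host_db",
    "implant_protospacers",
    "make_occupancy",
    "reverse_complement",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Seven-rank lineage, most inclusive first (the order used in lineage tables).
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Parameters of a synthetic viral community.

    ``planted_clusters`` is a list of ``(size, within_ani, between_ani)``
    tuples (percent identities). Each member is a point-substituted copy of
    the cluster ancestor at half the divergence rate
    ``(1 - within_ani/100) / 2``, so the *pairwise* identity between any
    two members is the planned within-cluster ANI (up to the binomial sd of
    coinciding mutation positions).
    """

    seed: int
    n_genomes: int = 30
    genome_length_range: tuple[int, int] = (5_000, 20_000)
    gc_content: float = 0.5
    planted_clusters: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(5, 97.0, 85.0)] * 6
    )
    dtr_length: int = 0
    spacer_length_range: tuple[int, int] = (28, 38)
    mismatch_plan: list[int] = field(default_factory=list)
    gene_length: int = 900
    gene_spacing: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        lo, hi = self.genome_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("genome_length_range must be positive and ordered")
        slo, shi = self.spacer_length_range
        if slo <= 0 or shi < slo:
            raise ValueError("spacer_length_range must be positive and ordered")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be positive")
        if self.dtr_length < 0:
            raise ValueError("dtr_length must be non-negative")
        for size, within, between in self.planted_clusters:
            if size <= 0:
                raise ValueError("cluster size must be positive")
            if within <= between:
                raise ValueError(
                    f"within_ani ({within}) must exceed between_ani ({between})"
                )
            rate = 1.0 - within / 100.0
            if rate >= 0.75:
                raise ValueError(
                    f"substitution rate {rate:.2f} >= 0.75 saturates identity"
                )


@dataclass
class ProtospacerImplant:
    contig_id: str
    spacer_id: str
    mismatches: int
    strand: str
    position: int  # 0-based on the contig forward strand
    host_genome_id: str | None = None


@dataclass
class GroundTruth:
    """Planted truth: cluster labels, implanted protospacers, AMG categories."""

    cluster_of: dict[str, str] = field(default_factory=dict)
    implants: list[ProtospacerImplant] = field(default_factory=list)
    amg_category: dict[str, int] = field(default_factory=dict)


@dataclass
class SpacerDB:
    """CRISPR spacer sequences keyed by id, with their source host genome."""

    spacers: dict[str, str]
    host_of: dict[str, str]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions, each to a new base."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        alternatives = [b for b in BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_viral_genomes(cfg: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Generate genomes in planted ANI clusters.

    Returns ``(contigs, truth)`` where ``contigs`` maps genome id to sequence
    and ``truth.cluster_of`` maps genome id to its planted cluster label.
    Cluster ancestors are independent random draws, so between-cluster
    identity is background noise (far below any ``between_ani`` bound).
    If ``cfg.dtr_length > 0``, the first ``dtr_length`` bases of each genome
    are appended to its 3' end as a direct terminal repeat.
    """
    root = np.random.SeedSequence(cfg.seed)
    contigs: dict[str, str] = {}
    truth = GroundTruth()
    for ci, ((size, within, _between), child) in enumerate(
        zip(cfg.planted_clusters, root.spawn(len(cfg.planted_clusters)))
    ):
        rng = np.random.default_rng(child)
        length = int(rng.integers(*cfg.genome_length_range, endpoint=True))
        ancestor = _random_seq(rng, length, cfg.gc_content)
        # half the planned divergence per member: pairwise member identity
        # then equals within_ani
        n_subs = round(length * (1.0 - within / 100.0) / 2.0)
        label = f"c{ci}"
        for mi in range(size):
            seq = _mutate(rng, ancestor, n_subs) if n_subs else ancestor
            if cfg.dtr_length:
                seq = seq + seq[: cfg.dtr_length]
            gid = f"{label}_m{mi}"
            contigs[gid] = seq
            truth.cluster_of[gid] = label
    return contigs, truth


def make_gene_table(
    contigs: dict[str, str],
    layouts: dict[str, list[str]],
    gene_length: int = 900,
    gene_spacing: int = 100,
):
    """Tile marker-labelled genes along each contig.

    ``layouts`` maps contig id to an ordered list of marker labels drawn from
    {"VV-1", "V*-0", "HOST", "UNCLASSIFIED"}. Genes are ``gene_length`` bp,
    separated by ``gene_spacing`` bp, 1-based inclusive coordinates,
    alternating strand. Raises ``ValueError`` if a layout exceeds the
    contig's capacity.
    """
    from .amg import MARKER_LABELS, GeneRecord

    genes: list[GeneRecord] = []
    stride = gene_length + gene_spacing
    for contig_id, layout in layouts.items():
        clen = len(contigs[contig_id])
        for label in layout:
            if label not in MARKER_LABELS:
                raise ValueError(f"unknown marker label {label!r}")
        if layout and (len(layout) - 1) * stride + gene_length > clen:
            raise ValueError(
                f"layout of {len(layout)} genes exceeds capacity of "
                f"{clen} bp contig {contig_id!r}"
            )
        for i, label in enumerate(layout):
            start = i * stride + 1
            genes.append(
                GeneRecord(
                    gene_id=f"{contig_id}_g{i}",
                    contig_id=contig_id,
                    index=i,
                    start=start,
                    end=start + gene_length - 1,
                    strand="+" if i % 2 == 0 else "-",
                    marker_label=label,
                )
            )
    return genes


def make_host_db(
    n_hosts: int,
    spacers_per_host: int,
    cfg: SimConfig,
    hosts_per_genus: int = 2,
):
    """Generate a toy CRISPR spacer database with full host lineages.

    Hosts are grouped ``hosts_per_genus`` per genus; successive higher ranks
    coarsen by factor two, so nearby hosts share low ranks and all share the
    domain. Returns ``(SpacerDB, lineage_table)`` where the lineage table is
    a pandas DataFrame with columns ``genome_id`` + the seven ranks.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0].spawn(7)[3])
    spacers: dict[str, str] = {}
    host_of: dict[str, str] = {}
    rows = []
    for h in range(n_hosts):
        gid = f"host{h}"
        genus = h // hosts_per_genus
        fam, order = genus // 2, genus // 4
        cls, phyl = genus // 8, genus // 16
        rows.append(
            {
                "genome_id": gid,
                "domain": "Bacteria",
                "phylum": f"p{phyl}",
                "class": f"c{cls}",
                "order": f"o{order}",
                "family": f"f{fam}",
                "genus": f"g{genus}",
                "species": f"s{h}",
            }
        )
        for s in range(spacers_per_host):
            length = int(rng.integers(*cfg.spacer_length_range, endpoint=True))
            sid = f"{gid}_sp{s}"
            spacers[sid] = _random_seq(rng, length, cfg.gc_content)
            host_of[sid] = gid
    lineages = pd.DataFrame(rows, columns=["genome_id", *LINEAGE_RANKS])
    return SpacerDB(spacers=spacers, host_of=host_of), lineages


def implant_protospacers(
    contigs: dict[str, str],
    spacer_db: SpacerDB,
    plan: list[tuple[str, str, int, str, int]],
    seed: int = 0,
) -> tuple[dict[str, str], GroundTruth]:
    """Write protospacers into contigs with an exact number of mismatches.

    ``plan`` entries are ``(contig_id, spacer_id, mismatches, strand,
    position)`` with 0-based positions on the contig forward strand. The
    spacer (or its reverse complement for strand ``-``) is substituted at
    exactly ``mismatches`` distinct positions before being written. Raises
    ``ValueError`` on overlap with a previously implanted protospacer.
    """
    rng = np.random.default_rng(seed)
    out = dict(contigs)
    truth = GroundTruth()
    occupied: dict[str, list[tuple[int, int]]] = {}
    for contig_id, spacer_id, mismatches, strand, position in plan:
        spacer = spacer_db.spacers[spacer_id]
        if mismatches > 3:
            raise ValueError("mismatches must be <= 3")
        if position + len(spacer) > len(out[contig_id]):
            raise ValueError(
                f"protospacer {spacer_id} overruns contig {contig_id}"
            )
        span = (position, position + len(spacer))
        for a, b in occupied.get(contig_id, []):
            if span[0] < b and a < span[1]:
                raise ValueError(
                    f"protospacer at {span} overlaps prior implant ({a},{b}) "
                    f"on {contig_id}"
                )
        occupied.setdefault(contig_id, []).append(span)
        insert = spacer if strand == "+" else reverse_complement(spacer)
        if mismatches:
            insert = _mutate(rng, insert, mismatches)
        seq = out[contig_id]
        out[contig_id] = seq[: span[0]] + insert + seq[span[1] :]
        truth.implants.append(
            ProtospacerImplant(
                contig_id=contig_id,
                spacer_id=spacer_id,
                mismatches=mismatches,
                strand=strand,
                position=position,
                host_genome_id=spacer_db.host_of.get(spacer_id),
            )
        )
    return out, truth


def make_occupancy(
    n_samples: int,
    n_attributes: int,
    abundance_model: tuple[str, dict] = ("geometric", {"p": 0.861}),
    seed: int = 0,
):
    """Simulate an attribute x sample occupancy (count) matrix.

    The default model draws, per attribute, the number of occupied samples
    from a geometric distribution with success probability ``p`` (clipped at
    ``n_samples``), so a fraction ``1 - p`` of attributes occupy more than
    one sample — most attributes are sample-unique, as in real soil-virus
    surveys. Occupied cells receive small positive integer counts. Model
    ``("ones", {})`` fills the whole matrix with ones.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    name, params = abundance_model
    mat = np.zeros((n_attributes, n_samples), dtype=int)
    if name == "ones":
        mat[:] = 1
    elif name == "geometric":
        p = params.get("p", 0.861)
        if not 0.0 < p <= 1.0:
            raise ValueError("geometric p must lie in (0, 1]")
        ks = np.minimum(rng.geometric(p, size=n_attributes), n_samples)
        for i, k in enumerate(ks):
            cols = rng.choice(n_samples, size=k, replace=False)
            mat[i, cols] = 1 + rng.poisson(1.0, size=k)
    else:
        raise ValueError(f"unknown abundance model {name!r}")
    return pd.DataFrame(
        mat,
        index=[f"attr{i}" for i in range(n_attributes)],
        columns=[f"sample{j}" for j in range(n_samples)],
    )
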