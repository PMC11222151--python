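"""Genome clustering at species (vOTU), genus and family levels.

Species-level vOTUs follow the MIUViG criteria: genomes are nodes of a
graph with an edge wherever ANI >= 95% and the aligned fraction of the
shorter genome >= 85%, then communities are extracted with Leiden (CPM
quality at resolution 0, which coincides with connected components on the
binary threshold graph but stays usable for weighted variants).

Genus and family clusters are built from amino acid identity (AAI) graphs
— genus: AAI >= 40% and >= 20% shared genes; family: AAI >= 20% and >= 10%
shared genes — clustered with an in-house Markov Cluster (MCL) iteration
(alternating expansion and inflation of a column-stochastic matrix).
An optional hierarchy repair re-assigns fine clusters that straddle coarse
clusters so that species ⊂ genus ⊂ family nests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "MclParams",
    "ClusterSet",
    "build_votu_graph",
    "build_aai_graph",
    "leiden_cluster",
    "mcl",
    "cluster_ranks",
    "repair_hierarchy",
    "pick_representative",
]


@dataclass
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    convergence_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class ClusterSet:
    """A partition of genome ids at one taxonomic-like level."""

    level: str  # species | genus | family
    clusters: list[list[str]]
    representatives: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def labels(self) -> dict[str, int]:
        return {m: i for i, members in enumerate(self.clusters) for m in members}

    def __len__(self) -> int:
        return len(self.clusters)

    def assign_representatives(self, lengths: dict[str, int]) -> None:
        self.representatives = [pick_representative(c, lengths) for c in self.clusters]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        reps = self.representatives or [None] * len(self.clusters)
        for i, members in enumerate(self.clusters):
            for m in sorted(members):
                rows.append(
                    {
                        "member": m,
                        "cluster_id": f"{self.level}_{i}",
                        "level": self.level,
                        "is_representative": m == reps[i],
                    }
                )
        return pd.DataFrame(rows)


def build_votu_graph(
    ani_table: pd.DataFrame,
    genome_ids: list[str],
    lengths: dict[str, int],
    min_ani: float = 95.0,
    min_af: float = 85.0,
    af_mode: str = "shorter",
) -> nx.Graph:
    """Threshold graph of the species-level (MIUViG) criteria.

    An edge joins a pair iff ANI >= ``min_ani`` and the aligned fraction of
    the shorter genome >= ``min_af`` (``af_mode="both"`` requires both AFs).
    Comparisons are inclusive. Genomes without qualifying pairs remain as
    isolated nodes.
    """
    g = nx.Graph()
    g.add_nodes_from(genome_ids)
    for r in ani_table.itertuples():
        a, b = r.query_id, r.subject_id
        if a == b:
            continue
        if af_mode == "both":
            af = min(r.af_query, r.af_subject)
        else:  # aligned fraction of the shorter sequence
            if lengths[a] < lengths[b]:
                af = r.af_query
            elif lengths[b] < lengths[a]:
                af = r.af_subject
            else:
                af = max(r.af_query, r.af_subject)
        if r.ani >= min_ani and af >= min_af:
            g.add_edge(a, b, weight=1.0)
    return g


def build_aai_graph(
    aai_table: pd.DataFrame, genome_ids: list[str], min_aai: float, min_shared: float
) -> nx.Graph:
    """AAI threshold graph with edge weight = AAI."""
    g = nx.Graph()
    g.add_nodes_from(genome_ids)
    for r in aai_table.itertuples():
        if r.genome_a == r.genome_b:
            continue
        if r.aai >= min_aai and r.shared_gene_fraction >= min_shared:
            g.add_edge(r.genome_a, r.genome_b, weight=float(r.aai))
    return g


def leiden_cluster(g: nx.Graph, seed: int = 0, resolution: float = 0.0) -> ClusterSet:
    """Leiden community detection (CPM quality) on a threshold graph.

    At the default resolution 0 every connected pair prefers merging, so
    the partition equals the connected components of the graph — the
    intended reading of the binary MIUViG criteria — while remaining
    usable on weighted graphs at positive resolutions.
    """
    nodes = sorted(g.nodes)
    if not nodes:
        return ClusterSet(level="species", clusters=[])
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g.edges[u, v].get("weight", 1.0) for u, v in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges)
    part = leidenalg.find_partition(
        h,
        leidenalg.CPMVertexPartition,
        weights=weights or None,
        resolution_parameter=resolution,
        seed=seed,
    )
    clusters = [sorted(nodes[i] for i in comm) for comm in part]
    return ClusterSet(level="species", clusters=clusters)


def mcl(g: nx.Graph, params: MclParams | None = None, level: str = "genus") -> ClusterSet:
    """Markov Cluster iteration on a weighted graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1 for isolated nodes); the adjacency matrix is column
    normalized and iterated: expansion (matrix power), inflation
    (elementwise power + column renormalization), pruning of entries below
    ``prune_threshold``. Clusters are the connected components of the
    nonzero structure of the converged matrix (overlapping attractor
    systems merge). Non-convergence returns the current clustering with
    ``converged=False``.
    """
    params = params or MclParams()
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return ClusterSet(level=level, clusters=[])
    A = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="lil").astype(float)
    for i, node in enumerate(nodes):
        incident = [g.edges[node, nb].get("weight", 1.0) for nb in g.neighbors(node)]
        A[i, i] = max(incident) if incident else 1.0
    M = sp.csr_array(A)
    M = M @ sp.diags_array(1.0 / M.sum(axis=0))
    converged = False
    for _ in range(params.max_iter):
        prev = M.copy()
        E = M
        for _ in range(params.expansion - 1):
            E = E @ M
        E.data = np.power(E.data, params.inflation)
        E = E @ sp.diags_array(1.0 / E.sum(axis=0))
        E.data[E.data < params.prune_threshold] = 0.0
        E.eliminate_zeros()
        E = E @ sp.diags_array(1.0 / E.sum(axis=0))
        M = E
        diff = abs(M - prev)
        if diff.nnz == 0 or diff.max() < params.convergence_eps:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", params.max_iter)
    structure = nx.from_scipy_sparse_array(M + M.T)
    comps = [sorted(nodes[i] for i in c) for c in nx.connected_components(structure)]
    comps.sort(key=lambda c: c[0])
    return ClusterSet(level=level, clusters=comps, converged=converged)


def repair_hierarchy(
    fine: ClusterSet, coarse: ClusterSet, lengths: dict[str, int]
) -> ClusterSet:
    """Make ``coarse`` a true coarsening of ``fine``.

    Any fine cluster whose members straddle several coarse clusters is
    moved wholesale into the coarse cluster that contains the fine
    cluster's representative (longest member, ties lexicographic).
    """
    coarse_label = coarse.labels
    moved = {}
    for members in fine.clusters:
        targets = {coarse_label[m] for m in members}
        if len(targets) > 1:
            rep = pick_representative(members, lengths)
            home = coarse_label[rep]
            for m in members:
                moved[m] = home
    if not moved:
        return coarse
    new: dict[int, list[str]] = {i: [] for i in range(len(coarse.clusters))}
    for m, lab in coarse_label.items():
        new[moved.get(m, lab)].append(m)
    clusters = [sorted(ms) for ms in new.values() if ms]
    clusters.sort(key=lambda c: c[0])
    return ClusterSet(level=coarse.level, clusters=clusters, converged=coarse.converged)


def cluster_ranks(
    aai_table: pd.DataFrame,
    genome_ids: list[str],
    lengths: dict[str, int],
    genus_thresholds: tuple[float, float] = (40.0, 20.0),
    family_thresholds: tuple[float, float] = (20.0, 10.0),
    params: MclParams | None = None,
    repair: bool = True,
) -> tuple[ClusterSet, ClusterSet]:
    """Genus- and family-level clustering from an AAI table.

    Per level an AAI threshold graph (edge weight = AAI) is clustered with
    MCL; with ``repair=True`` family clusters are adjusted so every genus
    cluster lies inside one family cluster.
    """
    genus_g = build_aai_graph(aai_table, genome_ids, *genus_thresholds)
    family_g = build_aai_graph(aai_table, genome_ids, *family_thresholds)
    genus = mcl(genus_g, params, level="genus")
    family = mcl(family_g, params, level="family")
    if repair:
        family = repair_hierarchy(genus, family, lengths)
    genus.assign_representatives(lengths)
    family.assign_representatives(lengths)
    return genus, family


def pick_representative(cluster, lengths: dict[str, int]) -> str:
    """Longest member; ties broken by lexicographically smallest id."""
    members = list(cluster)
    if not members:
        raise ValueError("cluster is empty")
    return min(members, key=lambda m: (-lengths[m], m))
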