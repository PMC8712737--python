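"""Multiplex-heterogeneous network assembly and the commixture matrix.

The network has two weighted intra-layer networks (mRNA-mRNA and
miRNA-miRNA), a bipartite miRNA<->mRNA coupling, and pathway<->mRNA
membership links.  It is transformed into a single column-stochastic
transition ("commixture") matrix over the full node set: from a molecule
node the outgoing probability mass splits as lambda to pathway neighbors,
delta to bipartite coupling neighbors, and the remainder to intra-layer
neighbors, each weight-proportionally; absent edge classes have their share
renormalized over the classes that are present.  A pathway node sends all
its mass to member molecules.  Dangling nodes receive a unit self-loop so
the matrix stays stochastic without global teleportation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from pathmux.io_formats import InteractionRecord, PathwayRecord, WeightedEdge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkParams:
    """Random-walk parameters.

    restart_prob : restart probability r in (0, 1)
    delta        : probability of jumping across the bipartite coupling
    lam          : probability of jumping to a pathway neighbor
    with delta + lam < 1 so intra-layer moves keep positive share.
    """

    restart_prob: float = 0.7
    delta: float = 0.3
    lam: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.restart_prob < 1:
            raise ValueError(f"restart_prob must be in (0,1), got {self.restart_prob}")
        if not 0 <= self.delta < 1:
            raise ValueError(f"delta must be in [0,1), got {self.delta}")
        if not 0 <= self.lam < 1:
            raise ValueError(f"lambda must be in [0,1), got {self.lam}")
        if self.delta + self.lam >= 1:
            raise ValueError(
                f"delta + lambda must be < 1, got {self.delta + self.lam}")


@dataclass
class MultiplexHeterogeneousNetwork:
    """Two intra-layer networks plus couplings and pathway links.

    Node identity is (id, kind); the node_index maps ids to consecutive
    integer positions in deterministic order: sorted mRNAs, then sorted
    miRNAs, then sorted pathway ids.
    """

    mrna_nodes: list
    mirna_nodes: list
    pathway_nodes: list
    gene_edges: list          # WeightedEdge within the mRNA layer
    mirna_edges: list         # WeightedEdge within the miRNA layer
    coupling: list            # (mirna, mrna, weight) treated undirected
    pathway_links: list       # (pathway_id, molecule_id, weight)
    pathways: list            # the full PathwayRecord list, kept for overlaps
    node_index: dict = field(default_factory=dict)
    n_dropped_coupling: int = 0
    n_dropped_members: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def molecule_nodes(self) -> list:
        return self.mrna_nodes + self.mirna_nodes

    def node_kind(self, node: str) -> str:
        if node in self._mrna_set:
            return "mRNA"
        if node in self._mirna_set:
            return "miRNA"
        return "pathway"

    def __post_init__(self) -> None:
        self._mrna_set = set(self.mrna_nodes)
        self._mirna_set = set(self.mirna_nodes)


def build_network(
    gene_edges: list[WeightedEdge],
    mirna_edges: list[WeightedEdge],
    target_edges: list[InteractionRecord],
    pathways: list[PathwayRecord],
    *,
    link_mirna_pathways: bool = False,
    min_mirna_targets: int = 3,
) -> MultiplexHeterogeneousNetwork:
    """Assemble the multiplex-heterogeneous network.

    Layer node sets come from their edge lists; coupling edges with an
    unregistered endpoint are dropped (counted), and pathway members absent
    from the gene layer are dropped from the membership links while the
    pathway record itself is kept for overlap statistics.

    When ``link_mirna_pathways`` is on, a pathway also links to every miRNA
    whose coupling targets include at least ``min_mirna_targets`` members,
    reflecting that miRNAs map to pathways only through their targets.
    """
    mrna_nodes = sorted({n for e in gene_edges for n in (e.source, e.target)})
    if not mrna_nodes:
        raise ValueError("empty gene layer: no mRNA intra-layer edges")
    mirna_nodes = sorted({n for e in mirna_edges for n in (e.source, e.target)})
    mrna_set, mirna_set = set(mrna_nodes), set(mirna_nodes)

    coupling = []
    n_dropped_coupling = 0
    seen_pairs = set()
    for rec in target_edges:
        if rec.regulator_type != "miRNA" or rec.target_type != "mRNA":
            raise ValueError("coupling edges must be miRNA->mRNA interactions")
        if rec.regulator in mirna_set and rec.target in mrna_set:
            if (rec.regulator, rec.target) not in seen_pairs:
                seen_pairs.add((rec.regulator, rec.target))
                coupling.append((rec.regulator, rec.target, 1.0))
        else:
            n_dropped_coupling += 1
    if n_dropped_coupling:
        logger.info("dropped %d coupling edge(s) with unregistered endpoints",
                    n_dropped_coupling)

    targets_by_mirna: dict[str, set] = {}
    for mi, m, _w in coupling:
        targets_by_mirna.setdefault(mi, set()).add(m)

    pathway_nodes = sorted({p.pathway_id for p in pathways})
    pathway_links = []
    n_dropped_members = 0
    for p in sorted(pathways, key=lambda p: p.pathway_id):
        linkable = sorted(p.members & mrna_set)
        n_dropped_members += len(p.members) - len(linkable)
        if not linkable:
            logger.warning("pathway %s has no members in the gene layer; "
                           "node kept with a self-loop", p.pathway_id)
        for m in linkable:
            pathway_links.append((p.pathway_id, m, 1.0))
        if link_mirna_pathways:
            for mi in sorted(mirna_set):
                if len(targets_by_mirna.get(mi, set()) & p.members) >= min_mirna_targets:
                    pathway_links.append((p.pathway_id, mi, 1.0))

    node_index = {n: i for i, n in
                  enumerate(mrna_nodes + mirna_nodes + pathway_nodes)}
    return MultiplexHeterogeneousNetwork(
        mrna_nodes=mrna_nodes,
        mirna_nodes=mirna_nodes,
        pathway_nodes=pathway_nodes,
        gene_edges=list(gene_edges),
        mirna_edges=list(mirna_edges),
        coupling=coupling,
        pathway_links=pathway_links,
        pathways=list(pathways),
        node_index=node_index,
        n_dropped_coupling=n_dropped_coupling,
        n_dropped_members=n_dropped_members,
    )


@dataclass
class CommixtureMatrix:
    """Column-stochastic supra-transition matrix with its node index."""

    matrix: sp.csc_matrix
    node_index: dict
    params: WalkParams

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, matrix_path, index_path) -> None:
        """Serialize as sparse triplets (row, col, value) plus a node index."""
        coo = self.matrix.tocoo()
        with open(matrix_path, "w") as fh:
            fh.write("row\tcol\tvalue\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r}\t{c}\t{v:.17g}\n")
        with open(index_path, "w") as fh:
            fh.write("node\tposition\n")
            for node, pos in sorted(self.node_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{node}\t{pos}\n")


def to_commixture(net: MultiplexHeterogeneousNetwork,
                  params: WalkParams | None = None) -> CommixtureMatrix:
    """Transform the network into the column-stochastic commixture matrix."""
    params = params or WalkParams()
    n = net.n_nodes
    idx = net.node_index

    # per-column neighbor lists by edge class
    intra: list[list] = [[] for _ in range(n)]
    coup: list[list] = [[] for _ in range(n)]
    pathw: list[list] = [[] for _ in range(n)]
    for e in net.gene_edges + net.mirna_edges:
        i, j = idx[e.source], idx[e.target]
        intra[i].append((j, e.weight))
        intra[j].append((i, e.weight))
    for mi, m, w in net.coupling:
        i, j = idx[mi], idx[m]
        coup[i].append((j, w))
        coup[j].append((i, w))
    for pid, mol, w in net.pathway_links:
        i, j = idx[pid], idx[mol]
        # pathway column sends to members; molecule column sends to pathways
        pathw[i].append((j, w))
        pathw[j].append((i, w))

    n_pathway_start = len(net.mrna_nodes) + len(net.mirna_nodes)
    rows, cols, vals = [], [], []
    for v in range(n):
        if v >= n_pathway_start:
            # pathway node: all mass to members, weight-proportionally
            classes = [(1.0, pathw[v])] if pathw[v] else []
        else:
            classes = []
            if intra[v]:
                classes.append((1.0 - params.delta - params.lam, intra[v]))
            if coup[v]:
                classes.append((params.delta, coup[v]))
            if pathw[v]:
                classes.append((params.lam, pathw[v]))
        if not classes:
            rows.append(v)
            cols.append(v)
            vals.append(1.0)
            continue
        share_total = sum(share for share, _ in classes)
        for share, nbrs in classes:
            share /= share_total          # renormalize over present classes
            wsum = sum(w for _, w in nbrs)
            if wsum <= 0:
                raise ValueError(f"zero total edge weight at column {v}")
            for j, w in nbrs:
                rows.append(j)
                cols.append(v)
                vals.append(share * w / wsum)

    M = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    M.sum_duplicates()
    colsums = np.asarray(M.sum(axis=0)).ravel()
    dev = float(np.abs(colsums - 1.0).max()) if n else 0.0
    if dev > 1e-9:
        raise AssertionError(f"commixture columns not stochastic (max dev {dev})")
    return CommixtureMatrix(matrix=M, node_index=dict(idx), params=params)
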