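"""Prior-knowledge network assembly and global heterogeneous network construction.

The prior network is an undirected simple graph over gene identifiers,
typically merged from pathway topologies (with groups/complexes replaced by
dummy nodes) and transcription-factor–target edges.  The global network adds
one node per patient sample and one node per measured gene per datatype, with

* gene–gene edges from the prior network,
* sample–gene edges for every ``1`` in a binary dataset, and
* identity edges tying each dataset gene node to the prior-network node that
  carries the same identifier.

All edges are unweighted and undirected ("is relevant to"), so the adjacency
matrix is symmetric 0/1 with a zero diagonal.  To shrink the matrix the
expression dataset can be merged into the prior network: expression links
then attach directly to the interaction nodes and no separate expression
gene nodes exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .omics_io import BinaryOmicsDataset

__all__ = [
    "NodeKind",
    "PriorNetwork",
    "NodeRegistry",
    "GlobalNetwork",
    "expand_groups",
    "merge_networks",
    "build_global_network",
    "read_edge_list",
    "write_edge_list",
]

log = logging.getLogger(__name__)

NET = "NET"
SAMPLE = "SAMPLE"
DATASET_GENE = "DATASET_GENE"


@dataclass
class PriorNetwork:
    """Undirected simple graph over gene ids, plus dummy group/complex nodes."""

    graph: nx.Graph
    dummy_nodes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.dummy_nodes = frozenset(self.dummy_nodes)
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"prior network contains self-loops: {loops[:3]}")
        missing = self.dummy_nodes - set(self.graph.nodes)
        if missing:
            raise ValueError(f"dummy ids not present as nodes: {sorted(missing)[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], dummy_nodes: Iterable[str] = ()
    ) -> "PriorNetwork":
        return merge_networks([list(edges)], dummy_nodes=dummy_nodes)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def genes(self) -> list[str]:
        """Real gene identifiers (dummy group nodes excluded)."""
        return [n for n in self.graph.nodes if n not in self.dummy_nodes]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def expand_groups(
    topology: dict, namespace: str = ""
) -> tuple[list[tuple[str, str]], list[str]]:
    """Replace group/complex entities in a pathway topology by dummy nodes.

    ``topology`` maps ``"edges"`` to a list of id pairs and ``"groups"`` to a
    mapping of group id → member gene ids.  Each non-empty group becomes one
    dummy node connected to its members; edges that referenced the group id
    are rewired to the dummy node.  Returns the expanded edge list and the
    dummy ids created.  Empty groups are skipped with a warning (their edges
    are dropped).
    """
    edges = [tuple(e) for e in topology.get("edges", [])]
    groups: dict[str, list[str]] = dict(topology.get("groups", {}))
    dummy_of: dict[str, str] = {}
    dummies: list[str] = []
    out: list[tuple[str, str]] = []
    skipped: set[str] = set()
    for i, (gid, members) in enumerate(groups.items()):
        if not members:
            log.warning("expand_groups: group %r has no members; skipped", gid)
            skipped.add(gid)
            continue
        dummy = f"GROUP:{namespace}:{i}:{gid}" if namespace else f"GROUP:{i}:{gid}"
        dummy_of[gid] = dummy
        dummies.append(dummy)
        out.extend((dummy, m) for m in members)
    for u, v in edges:
        if u in skipped or v in skipped:
            continue
        out.append((dummy_of.get(u, u), dummy_of.get(v, v)))
    return out, dummies


def merge_networks(
    edge_lists: Sequence[Iterable[tuple[str, str]]],
    dummy_nodes: Iterable[str] = (),
    extra_nodes: Iterable[str] = (),
) -> PriorNetwork:
    """Union of edge lists with duplicates collapsed and self-loops dropped."""
    g = nx.Graph()
    g.add_nodes_from(extra_nodes)
    n_loops = 0
    for edges in edge_lists:
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            g.add_edge(str(u), str(v))
    if n_loops:
        log.warning("merge_networks: dropped %d self-loop(s)", n_loops)
    return PriorNetwork(g, frozenset(dummy_nodes))


def read_edge_list(path: str | Path) -> PriorNetwork:
    """Read a 2- or 3-column TSV edge list (middle SIF interaction column ignored)."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                edges.append((parts[0], parts[2]))
            else:
                raise ValueError(f"{path}: malformed edge line {line!r}")
    return merge_networks([edges])


def write_edge_list(net: PriorNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in net.graph.edges:
            fh.write(f"{u}\t{v}\n")


@dataclass
class NodeRegistry:
    """Ordered node table of the global network.

    Layout: the NET block first, then the SAMPLE block, then one
    DATASET_GENE block per dataset in input order — submatrix extraction is
    then plain index arithmetic.  When the expression dataset is merged into
    the prior network its genes have no block of their own;
    ``merged_expression_genes`` records which NET identifiers carry the
    expression data in that case.
    """

    kinds: list[str]
    datatypes: list[str | None]
    identifiers: list[str]
    merged_expression_genes: list[str] | None = None

    def __post_init__(self) -> None:
        keys = list(zip(self.kinds, self.datatypes, self.identifiers))
        if len(set(keys)) != len(keys):
            raise ValueError("registry records must be unique")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.kinds)

    def index_of(self, kind: str, datatype: str | None, identifier: str) -> int:
        return self._index[(kind, datatype, identifier)]

    def indices(self, kind: str, datatype: str | None = None) -> list[int]:
        return [
            i
            for i, (k, d) in enumerate(zip(self.kinds, self.datatypes))
            if k == kind and (datatype is None or d == datatype)
        ]

    def identifiers_of(self, kind: str, datatype: str | None = None) -> list[str]:
        return [self.identifiers[i] for i in self.indices(kind, datatype)]

    @property
    def sample_ids(self) -> list[str]:
        return self.identifiers_of(SAMPLE)


@dataclass
class GlobalNetwork:
    """Symmetric 0/1 adjacency over the heterogeneous node registry."""

    adjacency: sp.csr_matrix
    registry: NodeRegistry

    def __post_init__(self) -> None:
        n = len(self.registry)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency size does not match registry")
        if (self.adjacency != self.adjacency.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.registry)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def to_dense(self) -> np.ndarray:
        return self.adjacency.toarray().astype(float)


def build_global_network(
    datasets: Sequence[BinaryOmicsDataset],
    prior: PriorNetwork,
    merge_expression: bool = True,
) -> GlobalNetwork:
    """Assemble the global network from binary datasets and the prior network.

    All datasets must share the same sample set and contain only genes present
    in the prior network (apply :func:`pathrank.omics_io.filter_to_network`
    first).  Every dataset gene — even one with no links — becomes a node
    tied to its interaction node, except expression genes when
    ``merge_expression`` is on, in which case the interaction nodes
    themselves carry the expression links.
    """
    tags = [d.datatype for d in datasets]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate datatype tags: {tags}")
    sample_ids: list[str] = list(datasets[0].sample_ids) if datasets else []
    for d in datasets[1:]:
        if set(d.sample_ids) != set(sample_ids):
            raise ValueError(
                f"dataset {d.datatype!r} sample set differs from {datasets[0].datatype!r}"
            )
    net_nodes = list(prior.graph.nodes)
    prior_gene_set = set(net_nodes)
    for d in datasets:
        missing = [g for g in d.gene_ids if g not in prior_gene_set]
        if missing:
            raise ValueError(
                f"dataset {d.datatype!r} contains genes absent from the prior network "
                f"(e.g. {missing[:3]}); apply filter_to_network first"
            )

    kinds = [NET] * len(net_nodes) + [SAMPLE] * len(sample_ids)
    dtypes: list[str | None] = [None] * (len(net_nodes) + len(sample_ids))
    idents = net_nodes + sample_ids
    merged_expr: list[str] | None = None

    for d in datasets:
        if d.datatype == "expression" and merge_expression:
            merged_expr = list(d.gene_ids)
            continue
        kinds.extend([DATASET_GENE] * d.n_genes)
        dtypes.extend([d.datatype] * d.n_genes)
        idents.extend(d.gene_ids)

    registry = NodeRegistry(kinds, dtypes, idents, merged_expr)
    net_index = {g: i for i, g in enumerate(net_nodes)}
    sample_index = {s: len(net_nodes) + i for i, s in enumerate(sample_ids)}

    rows: list[int] = []
    cols: list[int] = []

    def add(i: int, j: int) -> None:
        rows.append(i)
        cols.append(j)

    for u, v in prior.graph.edges:
        add(net_index[u], net_index[v])

    offset = len(net_nodes) + len(sample_ids)
    for d in datasets:
        merged = d.datatype == "expression" and merge_expression
        if merged:
            gene_pos = [net_index[g] for g in d.gene_ids]
        else:
            gene_pos = list(range(offset, offset + d.n_genes))
            for k, g in enumerate(d.gene_ids):  # identity link to the NET node
                add(gene_pos[k], net_index[g])
            offset += d.n_genes
        gi, sj = np.nonzero(d.links)
        for k in range(gi.size):
            add(gene_pos[gi[k]], sample_index[d.sample_ids[sj[k]]])

    n = len(registry)
    data = np.ones(len(rows), dtype=np.int8)
    a = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    a = a + a.T
    a.data[:] = 1  # cap multi-edges at 1
    a.setdiag(0)
    a.eliminate_zeros()
    return GlobalNetwork(a.tocsr(), registry)


def write_global_network(g: GlobalNetwork, path: str | Path) -> None:
    """Export the global network as an annotated edge list, for debugging."""
    reg = g.registry
    coo = sp.triu(g.adjacency).tocoo()
    with open(path, "w") as fh:
        fh.write("node_a\tkind_a\tdatatype_a\tnode_b\tkind_b\tdatatype_b\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(
                f"{reg.identifiers[i]}\t{reg.kinds[i]}\t{reg.datatypes[i] or ''}\t"
                f"{reg.identifiers[j]}\t{reg.kinds[j]}\t{reg.datatypes[j] or ''}\n"
            )
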