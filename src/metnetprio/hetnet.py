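"""Heterogeneous network assembly and the column-stochastic transition model.

:func:`assemble` merges the six edge sets into one node universe with a
single symmetric sparse adjacency; :func:`build_transition` turns it into
the walk matrix.  For a node in layer X, transition mass is split between
its intra-layer neighbors and its cross-layer neighbors:

* probability ``1 - lambda_jump`` stays within the layer, spread over
  intra-layer neighbors proportional to edge weight;
* probability ``lambda_jump`` is divided equally among the cross-layer
  blocks in which the node actually has edges (k in {0, 1, 2}), within each
  block proportional to edge weight;
* if the node has no intra-layer edges, all mass goes cross-layer (split
  over the available blocks); if it has no cross-layer edges, all mass
  stays intra-layer; a node with no edges at all is dangling (its column is
  zero and its probability is teleported to the restart vector during the
  walk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .edges import EdgeSet, PART_LAYERS, LAYERS

LAYER_INDEX = {layer: i for i, layer in enumerate(LAYERS)}


class NetworkError(ValueError):
    """Inconsistent node layers or invalid transition parameters."""


@dataclass(frozen=True)
class HeteroNetwork:
    """Unified node index over three layers plus symmetric sparse adjacency.

    ``node_ids`` is ordered (genes, then metabolites, then phenotypes, each
    sorted); ``layers`` gives each node's layer; ``adjacency`` stores every
    undirected edge in both triangles.
    """

    node_ids: tuple[str, ...]
    layers: np.ndarray  # int8 codes into LAYERS, aligned with node_ids
    adjacency: sp.csr_matrix  # symmetric, weights in (0, 1]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        """Undirected edge count (each unordered pair counted once)."""
        return self.adjacency.nnz // 2

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise NetworkError(f"unknown node ID {node_id!r}")

    @property
    def _index(self) -> dict[str, int]:
        # built lazily; cached on the instance despite frozen dataclass
        cache = self.__dict__.get("_index_cache")
        if cache is None:
            cache = {nid: i for i, nid in enumerate(self.node_ids)}
            object.__setattr__(self, "_index_cache", cache)
        return cache

    def layer_of(self, node_id: str) -> str:
        return LAYERS[self.layers[self.index_of(node_id)]]

    def nodes_in_layer(self, layer: str) -> list[str]:
        code = LAYER_INDEX[layer]
        return [nid for nid, c in zip(self.node_ids, self.layers) if c == code]

    def layer_mask(self, layer: str) -> np.ndarray:
        return self.layers == LAYER_INDEX[layer]

    def write_node_table(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("node_id\tlayer\n")
            for nid, c in zip(self.node_ids, self.layers):
                fh.write(f"{nid}\t{LAYERS[c]}\n")


@dataclass(frozen=True)
class TransitionModel:
    """Column-stochastic walk matrix with dangling-node bookkeeping."""

    W: sp.csr_matrix  # column-stochastic except dangling columns (all-zero)
    lambda_jump: float
    dangling: np.ndarray  # boolean mask over nodes, True = no edges at all


def assemble(edge_sets: dict[str, EdgeSet] | list[EdgeSet]) -> HeteroNetwork:
    """Merge edge sets into one heterogeneous network.

    The node universe is the union of all endpoint IDs, with each node's
    layer inferred from the part tags it appears under.  An ID claimed by
    two different layers is a hard error naming the ID.
    """
    if isinstance(edge_sets, dict):
        parts = list(edge_sets.values())
    else:
        parts = list(edge_sets)
    seen = set()
    for es in parts:
        if es.part in seen:
            raise NetworkError(f"duplicate edge set for part {es.part!r}")
        seen.add(es.part)

    layer_of: dict[str, str] = {}
    for es in parts:
        la, lb = PART_LAYERS[es.part]
        for a, b, _ in es.edges:
            for nid, layer in ((a, la), (b, lb)):
                prev = layer_of.setdefault(nid, layer)
                if prev != layer:
                    raise NetworkError(
                        f"node ID {nid!r} appears in both layer {prev!r} and {layer!r}"
                    )

    node_ids = tuple(
        sorted(layer_of, key=lambda n: (LAYER_INDEX[layer_of[n]], n))
    )
    index = {nid: i for i, nid in enumerate(node_ids)}
    layers = np.array([LAYER_INDEX[layer_of[n]] for n in node_ids], dtype=np.int8)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for es in parts:
        for a, b, w in es.edges:
            i, j = index[a], index[b]
            rows.extend((i, j))
            cols.extend((j, i))
            vals.extend((w, w))
    n = len(node_ids)
    adj = sp.csr_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(n, n)
    )
    # duplicate (i,j) entries across parts would be summed by CSR conversion;
    # parts live on disjoint blocks so each pair occurs once per direction
    net = HeteroNetwork(node_ids=node_ids, layers=layers, adjacency=adj)
    return net


def build_transition(net: HeteroNetwork, lambda_jump: float = 0.5) -> TransitionModel:
    """Derive the column-stochastic transition matrix of the walk.

    See the module docstring for the intra/cross mass-splitting rule.
    Every non-dangling column of the result sums to 1 (up to float round-off);
    dangling columns are identically zero.
    """
    if not 0.0 <= lambda_jump <= 1.0:
        raise NetworkError(f"lambda_jump must be in [0, 1], got {lambda_jump}")
    A = net.adjacency.tocoo()
    n = net.n_nodes
    lcodes = np.asarray(net.layers, dtype=np.int64)

    # block_sum[l, j] = total weight from column j into row-layer l
    block_sum = np.zeros((len(LAYERS), n))
    np.add.at(block_sum, (lcodes[A.row], A.col), A.data)

    intra_sum = block_sum[lcodes, np.arange(n)]
    cross_mask = block_sum > 0
    cross_mask[lcodes, np.arange(n)] = False
    k_cross = cross_mask.sum(axis=0)  # available cross-layer blocks per column

    # factor[l, j]: multiply A[i, j] (i in layer l) to get W[i, j]
    factor = np.zeros((len(LAYERS), n))
    has_intra = intra_sum > 0
    has_cross = k_cross > 0

    cols = np.arange(n)
    # intra-layer share
    intra_share = np.where(has_cross, 1.0 - lambda_jump, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor[lcodes, cols] = np.where(has_intra, intra_share / np.where(has_intra, intra_sum, 1.0), 0.0)
        # cross-layer share, split equally over available blocks
        cross_share = np.where(has_intra, lambda_jump, 1.0) / np.where(has_cross, k_cross, 1)
        for l in range(len(LAYERS)):
            is_cross = cross_mask[l]
            factor[l, is_cross] = cross_share[is_cross] / block_sum[l, is_cross]

    data = A.data * factor[lcodes[A.row], A.col]
    W = sp.csr_matrix((data, (A.row, A.col)), shape=(n, n))
    W.eliminate_zeros()
    dangling = ~(has_intra | has_cross)
    return TransitionModel(W=W, lambda_jump=float(lambda_jump), dangling=dangling)
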