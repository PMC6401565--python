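"""Turn walk scores into deliverables: metabolite ranking, subnetwork,
co-expressed genes and degree tables.

"Co-expressed genes" are operationalized as gene-layer nodes adjacent
(through gene-metabolite edges) to at least one ranked metabolite, ordered
by their walk score.  Degrees are unweighted incident-edge counts on the
induced subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hetnet import HeteroNetwork, NetworkError
from .rwr import SeedSet


@dataclass(frozen=True)
class MetaboliteRanking:
    """Ranked metabolites: rows of (rank, metabolite_id, score), score-descending."""

    rows: tuple[tuple[int, str, float], ...]

    def ids(self) -> list[str]:
        return [m for _, m, _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("rank\tmetabolite_id\tscore\n")
            for rank, mid, score in self.rows:
                fh.write(f"{rank}\t{mid}\t{score!r}\n")


@dataclass(frozen=True)
class Subnetwork:
    """Induced subgraph: kept node set plus the surviving edges."""

    node_ids: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]

    def write_edges(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b, w in self.edges:
                fh.write(f"{a}\t{b}\t{w!r}\n")


def rank_metabolites(
    scores: np.ndarray,
    net: HeteroNetwork,
    k: int = 50,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> MetaboliteRanking:
    """Top-k metabolite-layer nodes by walk score.

    ``exclude`` removes seed metabolites from the candidate pool.  Ties
    break by ID ascending; raw scores are reported without renormalization.
    """
    if k < 1:
        raise NetworkError("k must be >= 1")
    mask = net.layer_mask("metabolite")
    candidates = [
        (float(scores[i]), net.node_ids[i])
        for i in np.nonzero(mask)[0]
        if net.node_ids[i] not in exclude
    ]
    if not candidates and not mask.any():
        raise NetworkError("network has no metabolite nodes")
    candidates.sort(key=lambda t: (-t[0], t[1]))
    rows = tuple(
        (rank, mid, score)
        for rank, (score, mid) in enumerate(candidates[:k], start=1)
    )
    return MetaboliteRanking(rows=rows)


def top_coexpressed_genes(
    scores: np.ndarray,
    net: HeteroNetwork,
    top_mets: MetaboliteRanking,
    n: int = 100,
) -> list[tuple[str, float]]:
    """Genes adjacent (gm edges) to any ranked metabolite, by walk score.

    Returns up to ``n`` (gene_id, score) pairs, score-descending with ID
    tiebreak; an empty candidate set returns an empty list.
    """
    if n < 1:
        raise NetworkError("n must be >= 1")
    gene_mask = net.layer_mask("gene")
    adj = net.adjacency
    candidate_idx: set[int] = set()
    for mid in top_mets.ids():
        j = net.index_of(mid)
        row = adj.indices[adj.indptr[j]: adj.indptr[j + 1]]
        candidate_idx.update(int(i) for i in row if gene_mask[i])
    ranked = sorted(
        ((net.node_ids[i], float(scores[i])) for i in candidate_idx),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:n]


def extract_subnetwork(net: HeteroNetwork, keep: set[str]) -> Subnetwork:
    """Induced subgraph of the composite network on the ``keep`` node set."""
    for nid in sorted(keep):
        if nid not in net._index:
            raise NetworkError(f"unknown node ID {nid!r} in keep set")
    keep_idx = np.zeros(net.n_nodes, dtype=bool)
    for nid in keep:
        keep_idx[net.index_of(nid)] = True
    coo = net.adjacency.tocoo()
    edges = []
    for i, j, w in zip(coo.row, coo.col, coo.data):
        if i < j and keep_idx[i] and keep_idx[j]:
            edges.append((net.node_ids[i], net.node_ids[j], float(w)))
    edges.sort()
    return Subnetwork(node_ids=tuple(sorted(keep)), edges=tuple(edges))


def degree_table(sub: Subnetwork) -> list[tuple[str, int]]:
    """Unweighted degree per node, sorted degree-descending with ID tiebreak."""
    deg = {nid: 0 for nid in sub.node_ids}
    for a, b, _ in sub.edges:
        deg[a] += 1
        deg[b] += 1
    return sorted(deg.items(), key=lambda t: (-t[1], t[0]))


def score_threshold_report(
    ranking: MetaboliteRanking, threshold: float
) -> tuple[int, list[str]]:
    """Metabolites whose score strictly exceeds ``threshold``."""
    if threshold < 0:
        raise NetworkError("threshold must be >= 0")
    ids = [mid for _, mid, score in ranking.rows if score > threshold]
    return len(ids), ids


def reporting_node_set(
    ranking: MetaboliteRanking, seeds: SeedSet
) -> set[str]:
    """Node set of the headline subnetwork: ranked metabolites plus seed
    genes and seed phenotypes."""
    return set(ranking.ids()) | set(seeds.seed_genes) | set(seeds.seed_phenotypes)


def write_degree_table(rows: list[tuple[str, int]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\tdegree\n")
        for nid, d in rows:
            fh.write(f"{nid}\t{d}\n")
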