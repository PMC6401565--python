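"""Random walk with restart over the heterogeneous transition model.

The walk iterates ``p <- (1 - beta) * W @ p + beta * p0`` plus a
teleport-on-dangling correction: probability mass sitting on nodes with no
edges is redirected to the restart vector so total probability is conserved
exactly at every step.  ``rwr_solve_oracle`` solves the same fixed point
directly (dense linear algebra) and exists purely as an independent check
on the power iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hetnet import HeteroNetwork, TransitionModel, NetworkError


class SeedError(ValueError):
    """Invalid seed configuration."""


@dataclass(frozen=True)
class SeedSet:
    """Disease seeds: genes, phenotypes and (optionally) known metabolites.

    ``eta_phenotype`` is the fraction of restart mass assigned to the
    phenotype seeds; the remainder is split equally over the gene and
    metabolite seeds together.  If either category is empty its mass is
    reassigned to the other.
    """

    seed_genes: frozenset[str] = frozenset()
    seed_phenotypes: frozenset[str] = frozenset()
    seed_metabolites: frozenset[str] = frozenset()
    eta_phenotype: float = 0.5

    def __post_init__(self) -> None:
        if not (self.seed_genes or self.seed_phenotypes or self.seed_metabolites):
            raise SeedError("at least one seed is required")
        if not 0.0 <= self.eta_phenotype <= 1.0:
            raise SeedError("eta_phenotype must be in [0, 1]")

    @classmethod
    def from_tsv(cls, path, eta_phenotype: float = 0.5) -> "SeedSet":
        """Read a two-column TSV of (kind, node_id) with kind in
        gene/phenotype/metabolite."""
        genes: set[str] = set()
        phenos: set[str] = set()
        mets: set[str] = set()
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise SeedError(f"{path}:{lineno}: expected 2 fields")
                kind, nid = fields
                if kind == "gene":
                    genes.add(nid)
                elif kind == "phenotype":
                    phenos.add(nid)
                elif kind == "metabolite":
                    mets.add(nid)
                else:
                    raise SeedError(f"{path}:{lineno}: unknown seed kind {kind!r}")
        return cls(frozenset(genes), frozenset(phenos), frozenset(mets), eta_phenotype)


@dataclass(frozen=True)
class RWRParams:
    """Restart probability and convergence control for the power iteration."""

    beta: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise NetworkError("beta must be in (0, 1]")
        if self.tol <= 0:
            raise NetworkError("tol must be > 0")
        if self.max_iter < 1:
            raise NetworkError("max_iter must be >= 1")


def build_restart_vector(net: HeteroNetwork, seeds: SeedSet) -> np.ndarray:
    """Restart distribution over network nodes; sums to exactly 1.

    Phenotype seeds share mass ``eta_phenotype`` equally; gene and
    metabolite seeds together share ``1 - eta_phenotype`` equally.  An empty
    category's mass goes to the other.  Unknown seed IDs raise, naming the
    offender.
    """
    for nid in sorted(seeds.seed_genes | seeds.seed_phenotypes | seeds.seed_metabolites):
        if nid not in net._index:
            raise SeedError(f"seed node {nid!r} not present in the network")
        # layer sanity: a gene seed must live in the gene layer, etc.
    for nid in seeds.seed_genes:
        if net.layer_of(nid) != "gene":
            raise SeedError(f"seed gene {nid!r} is a {net.layer_of(nid)} node")
    for nid in seeds.seed_phenotypes:
        if net.layer_of(nid) != "phenotype":
            raise SeedError(f"seed phenotype {nid!r} is a {net.layer_of(nid)} node")
    for nid in seeds.seed_metabolites:
        if net.layer_of(nid) != "metabolite":
            raise SeedError(f"seed metabolite {nid!r} is a {net.layer_of(nid)} node")

    pheno = sorted(seeds.seed_phenotypes)
    other = sorted(seeds.seed_genes | seeds.seed_metabolites)
    eta = seeds.eta_phenotype
    if not pheno:
        eta = 0.0
    if not other:
        eta = 1.0

    p0 = np.zeros(net.n_nodes)
    if pheno:
        for nid in pheno:
            p0[net.index_of(nid)] = eta / len(pheno)
    if other:
        for nid in other:
            p0[net.index_of(nid)] = (1.0 - eta) / len(other)
    return p0


def rwr_power(
    model: TransitionModel,
    p0: np.ndarray,
    params: RWRParams = RWRParams(),
) -> tuple[np.ndarray, int, bool]:
    """Power iteration for the restart fixed point.

    Iterates ``p <- (1-beta) * (W @ p + dangling_mass(p) * p0) + beta * p0``
    until the L1 change drops below ``tol`` or ``max_iter`` is reached.
    Returns ``(scores, n_iter, converged)``; non-convergence warns rather
    than raises.
    """
    beta = params.beta
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (model.W.shape[0],):
        raise NetworkError("restart vector length mismatch")
    if not np.isclose(p0.sum(), 1.0):
        raise NetworkError("restart vector must sum to 1")
    if beta == 1.0:
        return p0.copy(), 1, True
    p = p0.copy()
    for it in range(1, params.max_iter + 1):
        dangling_mass = p[model.dangling].sum()
        p_next = (1.0 - beta) * (model.W @ p + dangling_mass * p0) + beta * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < params.tol:
            return p, it, True
    warnings.warn(
        f"RWR did not converge in {params.max_iter} iterations (L1 residual {delta:.3e})",
        RuntimeWarning,
    )
    return p, params.max_iter, False


_ORACLE_MAX_NODES = 2000


def rwr_solve_oracle(
    model: TransitionModel, p0: np.ndarray, beta: float
) -> np.ndarray:
    """Direct dense solve of the restart fixed point (verification oracle).

    Solves ``(I - (1-beta) * (W + p0 d^T)) p = beta * p0`` where ``d`` is
    the dangling-column indicator — identical dangling handling to
    :func:`rwr_power` — then normalizes.  Guarded to <= 2000 nodes.
    """
    n = model.W.shape[0]
    if n > _ORACLE_MAX_NODES:
        raise NetworkError(f"oracle limited to {_ORACLE_MAX_NODES} nodes, got {n}")
    if not 0.0 < beta <= 1.0:
        raise NetworkError("beta must be in (0, 1]")
    p0 = np.asarray(p0, dtype=float)
    if beta == 1.0:
        return p0.copy()
    M = model.W.toarray() + np.outer(p0, model.dangling.astype(float))
    A = np.eye(n) - (1.0 - beta) * M
    p = np.linalg.solve(A, beta * p0)
    return p / p.sum()


def write_scores(
    net: HeteroNetwork, scores: np.ndarray, path
) -> None:
    """Write per-node scores as TSV: node_id, layer, score, rank-within-layer."""
    from .hetnet import LAYERS

    order = {}
    for layer in LAYERS:
        mask = net.layer_mask(layer)
        idx = np.nonzero(mask)[0]
        ranked = idx[np.lexsort((np.array(net.node_ids, dtype=object)[idx], -scores[idx]))]
        for r, i in enumerate(ranked, start=1):
            order[i] = r
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\tlayer\tscore\trank_in_layer\n")
        for i, nid in enumerate(net.node_ids):
            fh.write(f"{nid}\t{LAYERS[net.layers[i]]}\t{float(scores[i])!r}\t{order[i]}\n")
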