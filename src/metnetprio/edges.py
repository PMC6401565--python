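"""Uniform weighted edge sets for the six parts of the composite network.

The composite network is built from six parts, identified by two-letter
tags over the layers gene (g), metabolite (m) and phenotype (p):

========  =======================  ==========
part tag  layers (node_a, node_b)  kind
========  =======================  ==========
``gg``    gene, gene               intra-layer
``mm``    metabolite, metabolite   intra-layer
``pp``    phenotype, phenotype     intra-layer
``gm``    gene, metabolite         bipartite
``gp``    gene, phenotype          bipartite
``mp``    metabolite, phenotype    bipartite
========  =======================  ==========

Every part is stored as an :class:`EdgeSet`: an undirected, deduplicated
list of ``(node_a, node_b, weight)`` with weights in ``(0, 1]``.  Intra-layer
edges are canonicalized with ``node_a <= node_b``; bipartite edges keep
``node_a`` in the first declared layer.  Duplicated pairs collapse to the
maximum weight and self-loops are dropped (counted in the log).

On disk an EdgeSet is a UTF-8 TSV whose first line is ``#part=<tag>``
followed by ``node_a<TAB>node_b<TAB>weight`` rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: part tag -> (layer of node_a, layer of node_b)
PART_LAYERS: dict[str, tuple[str, str]] = {
    "gg": ("gene", "gene"),
    "mm": ("metabolite", "metabolite"),
    "pp": ("phenotype", "phenotype"),
    "gm": ("gene", "metabolite"),
    "gp": ("gene", "phenotype"),
    "mp": ("metabolite", "phenotype"),
}

INTRA_PARTS = frozenset({"gg", "mm", "pp"})
BIPARTITE_PARTS = frozenset({"gm", "gp", "mp"})
LAYERS = ("gene", "metabolite", "phenotype")


class EdgeSetError(ValueError):
    """Malformed edge input (bad part tag, weight, or file row)."""


def _validate_part(part: str) -> None:
    if part not in PART_LAYERS:
        raise EdgeSetError(f"unknown part tag {part!r}; expected one of {sorted(PART_LAYERS)}")


@dataclass(frozen=True)
class EdgeSet:
    """Deduplicated undirected weighted edge list for one network part.

    Construct via :meth:`from_pairs` (which canonicalizes, deduplicates and
    drops self-loops) rather than directly, unless the input is already
    canonical.
    """

    part: str
    edges: tuple[tuple[str, str, float], ...]

    @classmethod
    def from_pairs(
        cls, part: str, pairs: Iterable[tuple[str, str, float]]
    ) -> "EdgeSet":
        """Build a canonical EdgeSet from raw (a, b, weight) triples.

        Self-loops are dropped (count logged), duplicate unordered pairs
        collapse keeping the maximum weight, and edges are sorted for
        deterministic output.  Weights must lie in (0, 1].
        """
        _validate_part(part)
        intra = part in INTRA_PARTS
        best: dict[tuple[str, str], float] = {}
        n_loops = 0
        for a, b, w in pairs:
            if not (isinstance(w, (int, float)) and math.isfinite(w)):
                raise EdgeSetError(f"non-finite weight {w!r} on edge ({a}, {b})")
            if not 0.0 < w <= 1.0:
                raise EdgeSetError(f"weight {w} outside (0, 1] on edge ({a}, {b})")
            if a == b:
                n_loops += 1
                continue
            key = (min(a, b), max(a, b)) if intra else (a, b)
            prev = best.get(key)
            if prev is None or w > prev:
                best[key] = w
        if n_loops:
            logger.info("part %s: dropped %d self-loop(s)", part, n_loops)
        edges = tuple(sorted((a, b, w) for (a, b), w in best.items()))
        return cls(part=part, edges=edges)

    # -- introspection -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.edges)

    def nodes_a(self) -> set[str]:
        """IDs appearing on the node_a side (both sides for intra parts)."""
        if self.part in INTRA_PARTS:
            return self.node_ids()
        return {a for a, _, _ in self.edges}

    def nodes_b(self) -> set[str]:
        if self.part in INTRA_PARTS:
            return self.node_ids()
        return {b for _, b, _ in self.edges}

    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out

    # -- serialization -----------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write as TSV: ``#part=<tag>`` header then node_a/node_b/weight rows."""
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"#part={self.part}\n")
            for a, b, w in self.edges:
                fh.write(f"{a}\t{b}\t{w!r}\n")

    @classmethod
    def read(cls, path: str | Path) -> "EdgeSet":
        """Read an EdgeSet TSV written by :meth:`write` (lossless round trip)."""
        path = Path(path)
        part: str | None = None
        pairs: list[tuple[str, str, float]] = []
        with path.open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#part="):
                        part = line[len("#part="):].strip()
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise EdgeSetError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}")
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise EdgeSetError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
                pairs.append((fields[0], fields[1], w))
        if part is None:
            raise EdgeSetError(f"{path}: missing '#part=<tag>' header line")
        return cls.from_pairs(part, pairs)


# ---------------------------------------------------------------------------
# readers for the source dialects
# ---------------------------------------------------------------------------

def read_scored_edges(
    path: str | Path,
    part: str,
    min_score: float = 0.0,
    score_scale: float = 1.0,
) -> EdgeSet:
    """Read a scored 3-column TSV (node_a, node_b, score) into an EdgeSet.

    ``score_scale`` converts file score units to [0, 1] — e.g. 1000 for
    0-1000 integer confidence scores, 1 for already-normalized scores.
    Edges with ``score / score_scale >= min_score`` are retained with
    ``weight = score / score_scale``; the boundary is inclusive.  Zero-score
    edges are always dropped (weights must be positive).

    Raises :class:`EdgeSetError` with the line number for malformed rows or
    scores outside ``[0, score_scale]``.
    """
    _validate_part(part)
    if score_scale <= 0:
        raise EdgeSetError(f"score_scale must be positive, got {score_scale}")
    path = Path(path)
    pairs: list[tuple[str, str, float]] = []
    n_zero = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeSetError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}")
            try:
                score = float(fields[2])
            except ValueError:
                if lineno == 1:  # tolerate a column-header first row
                    continue
                raise EdgeSetError(f"{path}:{lineno}: bad score {fields[2]!r}")
            if not 0.0 <= score <= score_scale:
                raise EdgeSetError(f"{path}:{lineno}: score {score} outside [0, {score_scale}]")
            w = score / score_scale
            if w == 0.0:
                n_zero += 1
                continue
            if w >= min_score:
                pairs.append((fields[0], fields[1], w))
    if n_zero:
        logger.info("%s: dropped %d zero-score edge(s)", path, n_zero)
    return EdgeSet.from_pairs(part, pairs)


def read_unit_edges(path: str | Path, part: str) -> EdgeSet:
    """Read a 2-column TSV of ID pairs; every association gets weight 1.0.

    Used for the unweighted phenotype-gene and phenotype-metabolite
    association files.  ``part`` must be a bipartite tag; column order must
    match the part's declared (layer_a, layer_b).
    """
    _validate_part(part)
    if part not in BIPARTITE_PARTS:
        raise EdgeSetError(f"read_unit_edges expects a bipartite part, got {part!r}")
    path = Path(path)
    pairs: list[tuple[str, str, float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise EdgeSetError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            pairs.append((fields[0], fields[1], 1.0))
    return EdgeSet.from_pairs(part, pairs)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def map_node_ids(
    edges: EdgeSet,
    mapping: dict[str, str],
    sides: str = "both",
) -> tuple[EdgeSet, set[str]]:
    """Translate node IDs through ``mapping`` (e.g. protein -> gene symbol).

    ``sides`` selects which endpoint(s) the mapping applies to ("a", "b" or
    "both").  IDs on a mapped side that are absent from the mapping are
    collected into the returned unmapped set and their edges dropped.  Edges
    whose endpoints become identical collapse to self-loops and are removed;
    duplicates re-collapse by maximum weight.
    """
    if sides not in {"a", "b", "both"}:
        raise EdgeSetError(f"sides must be 'a', 'b' or 'both', got {sides!r}")
    map_a = sides in {"a", "both"}
    map_b = sides in {"b", "both"}
    unmapped: set[str] = set()
    pairs: list[tuple[str, str, float]] = []
    for a, b, w in edges.edges:
        ok = True
        if map_a:
            if a in mapping:
                a = mapping[a]
            else:
                unmapped.add(a)
                ok = False
        if map_b:
            if b in mapping:
                b = mapping[b]
            else:
                unmapped.add(b)
                ok = False
        if ok:
            pairs.append((a, b, w))
    return EdgeSet.from_pairs(edges.part, pairs), unmapped


def restrict_to_genes(edges: EdgeSet, keep: set[str]) -> EdgeSet:
    """Keep only gene-gene edges whose both endpoints lie in ``keep``.

    Used with ``keep`` = the differential-gene set to reduce the background
    interaction network to the informative gene network.
    """
    if edges.part != "gg":
        raise EdgeSetError(f"restrict_to_genes expects part 'gg', got {edges.part!r}")
    kept = tuple(e for e in edges.edges if e[0] in keep and e[1] in keep)
    return EdgeSet(part="gg", edges=kept)


def cross_filter(
    bipartite: EdgeSet,
    layer_a_nodes: set[str],
    layer_b_nodes: set[str],
) -> EdgeSet:
    """Keep bipartite edges whose endpoints both exist in their layer's node set."""
    if bipartite.part not in BIPARTITE_PARTS:
        raise EdgeSetError(f"cross_filter expects a bipartite part, got {bipartite.part!r}")
    kept = tuple(
        e for e in bipartite.edges if e[0] in layer_a_nodes and e[1] in layer_b_nodes
    )
    return EdgeSet(part=bipartite.part, edges=kept)


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column source-ID -> target-ID TSV mapping file."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise EdgeSetError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            mapping[fields[0]] = fields[1]
    return mapping
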