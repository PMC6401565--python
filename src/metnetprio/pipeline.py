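"""End-to-end orchestration: simulate, DEG stage, network build, walk, report.

``run_full`` executes the whole chain on file inputs and writes every
deliverable plus a JSON manifest (parameters, input checksums, iteration
count, convergence flag) sufficient to reproduce the run bit-for-bit.
``run_simulate`` emits a complete runnable input bundle from the synthetic
generators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import deg as deg_mod
from . import edges as edges_mod
from . import prioritize as prio
from .edges import EdgeSet
from .hetnet import assemble, build_transition
from .rwr import RWRParams, SeedSet, build_restart_vector, rwr_power, write_scores
from .synthetic import (
    SyntheticExprConfig,
    SyntheticNetConfig,
    generate_expression,
    generate_hetnet,
    write_expression,
    write_labels,
)

logger = logging.getLogger(__name__)

EDGE_FILES = {
    "gg": "edges_gg.tsv",
    "mm": "edges_mm.tsv",
    "pp": "edges_pp.tsv",
    "gm": "edges_gm.tsv",
    "gp": "edges_gp.tsv",
    "mp": "edges_mp.tsv",
}


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """File paths and parameters of a full run.

    Paths may be None for optional stages (expression/labels skip the DEG
    stage; id_mapping skips protein-to-gene translation of the gg part).
    """

    # inputs
    edges_gg: str | None = None
    edges_mm: str | None = None
    edges_pp: str | None = None
    edges_gm: str | None = None
    edges_gp: str | None = None
    edges_mp: str | None = None
    expression: str | None = None
    labels: str | None = None
    seeds: str | None = None
    id_mapping: str | None = None
    out_dir: str = "results"
    # parameters
    alpha: float = 0.05
    pooled_ttest: bool = False
    min_combine_score: float = 0.8
    min_stitch_score: float = 0.0
    gg_score_scale: float = 1.0
    restrict_gg_to_degs: bool = True
    cross_filter_bipartite: bool = True
    lambda_jump: float = 0.5
    beta: float = 0.7
    eta_phenotype: float = 0.5
    top_k_metabolites: int = 50
    top_n_genes: int = 100
    score_threshold: float = 0.009
    tol: float = 1e-10
    max_iter: int = 1000
    rng_seed: int = 0

    _BOOL_FIELDS = {"pooled_ttest", "restrict_gg_to_degs", "cross_filter_bipartite"}
    _INT_FIELDS = {"top_k_metabolites", "top_n_genes", "max_iter", "rng_seed"}
    _FLOAT_FIELDS = {
        "alpha", "min_combine_score", "min_stitch_score", "gg_score_scale",
        "lambda_jump", "beta", "eta_phenotype", "score_threshold", "tol",
    }

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Read a flat ``key = value`` config file, then apply overrides."""
        raw: dict[str, str] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise PipelineError(f"config:{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                raw[key] = val
        kwargs: dict = {}
        valid = set(cls.__dataclass_fields__)
        for key, val in raw.items():
            if key not in valid:
                raise PipelineError(f"config: unknown key {key!r}")
            if key in cls._BOOL_FIELDS:
                kwargs[key] = val.lower() in {"1", "true", "yes"}
            elif key in cls._INT_FIELDS:
                kwargs[key] = int(val)
            elif key in cls._FLOAT_FIELDS:
                kwargs[key] = float(val)
            else:
                kwargs[key] = val or None
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _is_native_edgeset(path: str | Path) -> bool:
    with open(path, "r", encoding="utf-8") as fh:
        return fh.readline().startswith("#part=")


def _load_edges(
    path: str | Path,
    part: str,
    min_score: float = 0.0,
    score_scale: float = 1.0,
    unit: bool = False,
) -> EdgeSet:
    """Read one part, accepting either the native EdgeSet TSV (``#part=``
    header) or the raw source dialect (scored 3-column / pair 2-column)."""
    if _is_native_edgeset(path):
        es = EdgeSet.read(path)
        if es.part != part:
            raise PipelineError(f"{path}: expected part {part!r}, found {es.part!r}")
        if min_score > 0.0:
            es = EdgeSet(part=part, edges=tuple(
                e for e in es.edges if e[2] >= min_score))
        return es
    if unit:
        return edges_mod.read_unit_edges(path, part)
    return edges_mod.read_scored_edges(
        path, part, min_score=min_score, score_scale=score_scale)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, dt)
            return False

    return _Ctx()


def run_full(config: PipelineConfig) -> dict:
    """Execute deg -> network build -> hetnet -> rwr -> prioritize.

    Writes all deliverables under ``config.out_dir`` and returns the run
    manifest (also written as ``manifest.json``).  Deterministic given the
    same inputs and configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.to_dict()
    params.pop("out_dir")  # not part of the result identity
    # record input files by basename; content identity is the checksum below
    for name in ("edges_gg", "edges_mm", "edges_pp", "edges_gm", "edges_gp",
                 "edges_mp", "expression", "labels", "seeds", "id_mapping"):
        if params.get(name):
            params[name] = Path(params[name]).name
    manifest: dict = {"parameters": params, "inputs": {}, "counts": {}}

    input_paths = {
        name: getattr(config, name)
        for name in (
            "edges_gg", "edges_mm", "edges_pp", "edges_gm", "edges_gp",
            "edges_mp", "expression", "labels", "seeds", "id_mapping",
        )
        if getattr(config, name)
    }
    for name, path in input_paths.items():
        if not Path(path).exists():
            raise PipelineError(f"stage 'inputs' failed: missing file {path!r} ({name})")
        manifest["inputs"][name] = _sha256(path)
    if config.seeds is None:
        raise PipelineError("stage 'inputs' failed: a seeds file is required")

    # ---- DEG stage -------------------------------------------------------
    deg_ids: set[str] | None = None
    if config.expression and config.labels:
        with _stage("deg"):
            matrix = deg_mod.ExpressionMatrix.from_tsv(config.expression, config.labels)
            table = deg_mod.call_degs(matrix, alpha=config.alpha, pooled=config.pooled_ttest)
            deg_mod.write_deg_table(table, out / "degs.tsv")
            deg_ids = set(table.index[table["is_deg"]])
            manifest["counts"]["n_genes_tested"] = int(len(table))
            manifest["counts"]["n_degs"] = int(len(deg_ids))
            logger.info("deg: %d/%d genes significant at FDR < %g",
                        len(deg_ids), len(table), config.alpha)

    # ---- network build ---------------------------------------------------
    with _stage("network_build"):
        gg = _load_edges(
            config.edges_gg, "gg",
            min_score=config.min_combine_score, score_scale=config.gg_score_scale,
        )
        if config.id_mapping:
            mapping = edges_mod.read_id_mapping(config.id_mapping)
            gg, unmapped = edges_mod.map_node_ids(gg, mapping)
            manifest["counts"]["n_unmapped_gg_ids"] = len(unmapped)
        background_genes = gg.node_ids()
        if deg_ids is not None and config.restrict_gg_to_degs:
            gg = edges_mod.restrict_to_genes(gg, deg_ids)
        mm = _load_edges(config.edges_mm, "mm", min_score=config.min_stitch_score)
        pp = _load_edges(config.edges_pp, "pp")
        gm = _load_edges(config.edges_gm, "gm", min_score=config.min_stitch_score)
        gp = _load_edges(config.edges_gp, "gp", unit=True)
        mp = _load_edges(config.edges_mp, "mp", unit=True)
        if config.cross_filter_bipartite:
            met_nodes = mm.node_ids()
            pheno_nodes = pp.node_ids()
            gm = edges_mod.cross_filter(gm, background_genes, met_nodes)
            gp = edges_mod.cross_filter(gp, background_genes, pheno_nodes)
            mp = edges_mod.cross_filter(mp, met_nodes, pheno_nodes)
        edge_sets = {"gg": gg, "mm": mm, "pp": pp, "gm": gm, "gp": gp, "mp": mp}
        for part, es in edge_sets.items():
            manifest["counts"][f"n_edges_{part}"] = len(es)
        if sum(len(es) for es in edge_sets.values()) == 0:
            raise ValueError("no edges survive filtering; nothing to walk on")

    # ---- hetnet + transition --------------------------------------------
    with _stage("hetnet"):
        net = assemble(edge_sets)
        net.write_node_table(out / "nodes.tsv")
        model = build_transition(net, lambda_jump=config.lambda_jump)
        manifest["counts"]["n_nodes"] = net.n_nodes
        manifest["counts"]["n_edges_total"] = net.n_edges
        manifest["counts"]["n_dangling"] = int(model.dangling.sum())
        logger.info("hetnet: %d nodes, %d edges", net.n_nodes, net.n_edges)

    # ---- rwr -------------------------------------------------------------
    with _stage("rwr"):
        seeds = SeedSet.from_tsv(config.seeds, eta_phenotype=config.eta_phenotype)
        # seeds may drop out of the network during filtering (e.g. a curated
        # gene absent from the interaction data); keep the ones present
        present = set(net.node_ids)
        dropped = sorted(
            (seeds.seed_genes | seeds.seed_phenotypes | seeds.seed_metabolites)
            - present
        )
        if dropped:
            logger.warning("dropping %d seed(s) absent from the network: %s",
                           len(dropped), ", ".join(dropped))
            seeds = SeedSet(
                seed_genes=frozenset(seeds.seed_genes & present),
                seed_phenotypes=frozenset(seeds.seed_phenotypes & present),
                seed_metabolites=frozenset(seeds.seed_metabolites & present),
                eta_phenotype=seeds.eta_phenotype,
            )
        manifest["counts"]["n_seeds_dropped"] = len(dropped)
        p0 = build_restart_vector(net, seeds)
        params = RWRParams(beta=config.beta, tol=config.tol, max_iter=config.max_iter)
        scores, n_iter, converged = rwr_power(model, p0, params)
        write_scores(net, scores, out / "scores.tsv")
        manifest["rwr"] = {"n_iter": n_iter, "converged": bool(converged)}
        logger.info("rwr: converged=%s after %d iterations", converged, n_iter)

    # ---- prioritize ------------------------------------------------------
    with _stage("prioritize"):
        ranking = prio.rank_metabolites(
            scores, net, k=config.top_k_metabolites,
            exclude=seeds.seed_metabolites,
        )
        ranking.write(out / "metabolite_ranking.tsv")
        coexpr = prio.top_coexpressed_genes(scores, net, ranking, n=config.top_n_genes)
        with (out / "coexpressed_genes.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("rank\tgene_id\tscore\n")
            for rank, (gid, s) in enumerate(coexpr, start=1):
                fh.write(f"{rank}\t{gid}\t{s!r}\n")

        sub_nodes = prio.reporting_node_set(ranking, seeds)
        sub = prio.extract_subnetwork(net, sub_nodes)
        sub.write_edges(out / "subnetwork_edges.tsv")
        prio.write_degree_table(prio.degree_table(sub), out / "subnetwork_degrees.tsv")

        coexpr_nodes = sub_nodes | {gid for gid, _ in coexpr}
        coexpr_sub = prio.extract_subnetwork(net, coexpr_nodes)
        coexpr_sub.write_edges(out / "coexpressed_network_edges.tsv")
        prio.write_degree_table(
            prio.degree_table(coexpr_sub), out / "coexpressed_network_degrees.tsv")

        n_above, above_ids = prio.score_threshold_report(ranking, config.score_threshold)
        manifest["counts"]["n_metabolites_ranked"] = len(ranking)
        manifest["counts"]["n_coexpressed_genes"] = len(coexpr)
        manifest["counts"]["n_above_threshold"] = n_above
        manifest["above_threshold_metabolites"] = above_ids

    with (out / "manifest.json").open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_simulate(
    net_config: SyntheticNetConfig,
    expr_config: SyntheticExprConfig | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit a complete runnable input bundle from the synthetic generators.

    Writes the six edge TSVs, seeds.tsv, truth.tsv and (when an expression
    config is given) expression.tsv + labels.tsv.  Returns the file map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edge_sets, truth = generate_hetnet(net_config)
    files: dict[str, Path] = {}
    for part, es in edge_sets.items():
        path = out / EDGE_FILES[part]
        es.write(path)
        files[f"edges_{part}"] = path

    truth_path = out / "truth.tsv"
    truth.write(truth_path)
    files["truth"] = truth_path

    seeds_path = out / "seeds.tsv"
    with seeds_path.open("w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(truth.seed_genes):
            fh.write(f"gene\t{g}\n")
        fh.write(f"phenotype\t{truth.disease_phenotype}\n")
    files["seeds"] = seeds_path

    if expr_config is not None:
        matrix, labels, planted = generate_expression(expr_config)
        write_expression(matrix, out / "expression.tsv")
        write_labels(labels, out / "labels.tsv")
        with (out / "planted_de_genes.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            for g in sorted(planted):
                fh.write(f"{g}\n")
        files["expression"] = out / "expression.tsv"
        files["labels"] = out / "labels.tsv"
        files["planted_de"] = out / "planted_de_genes.tsv"
    return files
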