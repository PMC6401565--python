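"""Synthetic heterogeneous networks and expression matrices with planted truth.

Every downstream stage of the pipeline is testable offline: this module
draws a three-layer network (genes / metabolites / phenotypes) from an
independent-edge (Erdos-Renyi per block) model, plants a "disease
neighborhood" that wires seed genes to a disease phenotype and to a set of
true-positive metabolites, and draws two-group expression matrices with a
known set of shifted genes.

IDs are layer-prefixed ("G0001", "M0001", "P0001") so layer membership is
checkable from the ID alone.  All generation is driven by a single
``numpy`` Generator seeded from the config, so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import EdgeSet

PART_ORDER = ("gg", "mm", "pp", "gm", "gp", "mp")


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class SyntheticNetConfig:
    """Parameters of the planted three-layer random network.

    Densities are independent per-pair edge probabilities within each block.
    ``planted_boost`` multiplies the weight of gene-metabolite edges inside
    the planted neighborhood (capped at 1); planted gene-phenotype edges get
    weight exactly 1, mirroring unit-weighted curated associations.
    """

    n_genes: int = 1000
    n_metabolites: int = 400
    n_phenotypes: int = 100
    intra_density_g: float = 0.01
    intra_density_m: float = 0.02
    intra_density_p: float = 0.05
    cross_density_gm: float = 0.005
    cross_density_gp: float = 0.002
    cross_density_mp: float = 0.01
    n_seed_genes: int = 6
    n_true_metabolites: int = 10
    planted_boost: float = 5.0
    weight_low: float = 0.2
    weight_high: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_metabolites", "n_phenotypes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "intra_density_g", "intra_density_m", "intra_density_p",
            "cross_density_gm", "cross_density_gp", "cross_density_mp",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.n_seed_genes <= self.n_genes:
            raise ConfigError("n_seed_genes must be in [0, n_genes]")
        if not 0 <= self.n_true_metabolites <= self.n_metabolites:
            raise ConfigError("n_true_metabolites must be in [0, n_metabolites]")
        if self.planted_boost < 1.0:
            raise ConfigError("planted_boost must be >= 1")
        if not 0.0 < self.weight_low <= self.weight_high <= 1.0:
            raise ConfigError("need 0 < weight_low <= weight_high <= 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels of the planted disease neighborhood."""

    seed_genes: frozenset[str]
    true_metabolites: frozenset[str]
    disease_phenotype: str

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            for g in sorted(self.seed_genes):
                fh.write(f"seed_gene\t{g}\n")
            for m in sorted(self.true_metabolites):
                fh.write(f"true_metabolite\t{m}\n")
            fh.write(f"disease_phenotype\t{self.disease_phenotype}\n")

    @classmethod
    def read(cls, path: str | Path) -> "PlantedTruth":
        seed_genes: set[str] = set()
        true_mets: set[str] = set()
        pheno = ""
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                kind, node = line.split("\t")
                if kind == "seed_gene":
                    seed_genes.add(node)
                elif kind == "true_metabolite":
                    true_mets.add(node)
                elif kind == "disease_phenotype":
                    pheno = node
        return cls(frozenset(seed_genes), frozenset(true_mets), pheno)


@dataclass(frozen=True)
class SyntheticExprConfig:
    """Parameters of the planted two-group expression matrix.

    The first ``n_de`` genes get a ``+effect_size * noise_sd`` mean shift in
    the case group; everything else is i.i.d. Gaussian noise.
    """

    n_genes: int = 1000
    n_case: int = 13
    n_control: int = 21
    n_de: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("need >= 2 samples per group for a t-test")
        if not 0 <= self.n_de <= self.n_genes:
            raise ConfigError("n_de must be in [0, n_genes]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")


def _bernoulli_block(
    rng: np.random.Generator,
    ids_a: list[str],
    ids_b: list[str] | None,
    density: float,
    weight_low: float,
    weight_high: float,
) -> list[tuple[str, str, float]]:
    """Draw independent edges for one block; ids_b=None means intra-layer."""
    if density == 0.0:
        return []
    if ids_b is None:
        na = len(ids_a)
        iu, ju = np.triu_indices(na, k=1)
        mask = rng.random(iu.size) < density
        iu, ju = iu[mask], ju[mask]
        weights = rng.uniform(weight_low, weight_high, iu.size)
        return [(ids_a[i], ids_a[j], float(w)) for i, j, w in zip(iu, ju, weights)]
    na, nb = len(ids_a), len(ids_b)
    mask = rng.random(na * nb) < density
    idx = np.nonzero(mask)[0]
    weights = rng.uniform(weight_low, weight_high, idx.size)
    return [
        (ids_a[k // nb], ids_b[k % nb], float(w)) for k, w in zip(idx, weights)
    ]


def generate_hetnet(
    config: SyntheticNetConfig,
) -> tuple[dict[str, EdgeSet], PlantedTruth]:
    """Draw the six edge sets plus the planted disease neighborhood.

    Returns a dict keyed by part tag ("gg", "mm", "pp", "gm", "gp", "mp")
    and the :class:`PlantedTruth`.  Guarantees: every seed gene carries a
    weight-1 gp edge to the disease phenotype, and every true metabolite
    carries >= 1 gm edge to a seed gene whose weight is a uniform draw
    multiplied by ``planted_boost`` and capped at 1.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = _ids("G", config.n_genes)
    mets = _ids("M", config.n_metabolites)
    phenos = _ids("P", config.n_phenotypes)

    seed_genes = sorted(rng.choice(genes, size=config.n_seed_genes, replace=False).tolist())
    true_mets = sorted(rng.choice(mets, size=config.n_true_metabolites, replace=False).tolist())
    disease_pheno = str(rng.choice(phenos))
    truth = PlantedTruth(frozenset(seed_genes), frozenset(true_mets), disease_pheno)

    lo, hi = config.weight_low, config.weight_high
    blocks: dict[str, list[tuple[str, str, float]]] = {
        "gg": _bernoulli_block(rng, genes, None, config.intra_density_g, lo, hi),
        "mm": _bernoulli_block(rng, mets, None, config.intra_density_m, lo, hi),
        "pp": _bernoulli_block(rng, phenos, None, config.intra_density_p, lo, hi),
        "gm": _bernoulli_block(rng, genes, mets, config.cross_density_gm, lo, hi),
        "gp": _bernoulli_block(rng, genes, phenos, config.cross_density_gp, lo, hi),
        "mp": _bernoulli_block(rng, mets, phenos, config.cross_density_mp, lo, hi),
    }

    # planted neighborhood: seed genes -> disease phenotype at weight 1
    for g in seed_genes:
        blocks["gp"].append((g, disease_pheno, 1.0))
    # every true metabolite -> one seed gene, boosted weight capped at 1
    for m in true_mets:
        g = str(rng.choice(seed_genes)) if seed_genes else None
        if g is None:
            break
        w = min(1.0, float(rng.uniform(lo, hi)) * config.planted_boost)
        blocks["gm"].append((g, m, w))

    edge_sets = {part: EdgeSet.from_pairs(part, blocks[part]) for part in PART_ORDER}
    return edge_sets, truth


def generate_expression(
    config: SyntheticExprConfig,
) -> tuple[pd.DataFrame, dict[str, str], set[str]]:
    """Draw a genes x samples Gaussian matrix with planted differential genes.

    Returns ``(matrix, labels, planted_de)`` where ``matrix`` is indexed by
    gene ID with sample-ID columns, ``labels`` maps sample ID to
    "case"/"control", and ``planted_de`` is the set of shifted gene IDs
    (the first ``n_de`` genes).
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = _ids("G", config.n_genes)
    case_ids = [f"S{i:03d}_case" for i in range(1, config.n_case + 1)]
    ctrl_ids = [f"S{i:03d}_ctrl" for i in range(1, config.n_control + 1)]
    n_samples = config.n_case + config.n_control

    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    shift = config.effect_size * config.noise_sd
    values[: config.n_de, : config.n_case] += shift

    matrix = pd.DataFrame(values, index=genes, columns=case_ids + ctrl_ids)
    matrix.index.name = "gene_id"
    labels = {s: "case" for s in case_ids}
    labels.update({s: "control" for s in ctrl_ids})
    planted = set(genes[: config.n_de])
    return matrix, labels, planted


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    """Write a two-column sample_id / group TSV."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the expression matrix as TSV, gene IDs in column 1."""
    matrix.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")
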