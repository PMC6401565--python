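"""Differential-expression calling: per-gene two-sample t-test + BH FDR.

The input is an already-normalized genes x samples matrix with a binary
case/control labeling; upstream array preprocessing is out of scope.  The
default test is Welch's (unequal-variance) t; the pooled-variance Student
form is available behind a flag.  Multiple testing uses Benjamini-Hochberg
step-up, and a gene is called differential iff its adjusted value is
strictly below ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class ExpressionError(ValueError):
    """Invalid expression matrix or labels."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with case/control labels."""

    values: pd.DataFrame  # index = gene IDs, columns = sample IDs
    labels: dict[str, str]  # sample ID -> "case" | "control"

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise ExpressionError("duplicate gene IDs in expression matrix")
        if df.columns.duplicated().any():
            raise ExpressionError("duplicate sample IDs in expression matrix")
        unlabeled = [s for s in df.columns if s not in self.labels]
        if unlabeled:
            raise ExpressionError(f"unlabeled samples: {unlabeled[:5]}")
        bad = {g for g in self.labels.values()} - {"case", "control"}
        if bad:
            raise ExpressionError(f"labels must be 'case'/'control', got {sorted(bad)}")
        if not np.isfinite(df.to_numpy()).all():
            raise ExpressionError("expression values must be finite")
        if len(self.case_samples()) < 2 or len(self.control_samples()) < 2:
            raise ExpressionError("need >= 2 samples per group")

    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == "case"]

    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == "control"]

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, labels_path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        lab = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "group"])
        labels = dict(zip(lab["sample"].astype(str), lab["group"].astype(str)))
        return cls(values=df, labels=labels)


def t_test_two_sample(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    pooled: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch by default, pooled if requested.

    Degenerate variances are handled explicitly: two constant equal samples
    give (t=0, p=1); two constant unequal samples give p=0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ExpressionError("each sample needs >= 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ExpressionError("samples must be finite")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("degenerate variances with unequal means; p=0", RuntimeWarning)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return sign * np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=pooled)
    return float(t), float(p)


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ExpressionError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene t-test with joint BH adjustment over all genes.

    Returns a DataFrame indexed by gene ID with columns ``t``, ``p``,
    ``fdr`` and ``is_deg`` (strictly ``fdr < alpha``).  Vectorized over
    genes; degenerate zero-variance genes fall back to the scalar rules of
    :func:`t_test_two_sample`.
    """
    case = matrix.values[matrix.case_samples()].to_numpy()
    ctrl = matrix.values[matrix.control_samples()].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=pooled)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    # degenerate genes: both groups constant
    vx = case.var(axis=1, ddof=1)
    vy = ctrl.var(axis=1, ddof=1)
    degen = (vx == 0.0) & (vy == 0.0)
    if degen.any():
        equal = degen & (case.mean(axis=1) == ctrl.mean(axis=1))
        unequal = degen & ~equal
        t[equal], p[equal] = 0.0, 1.0
        if unequal.any():
            warnings.warn(
                f"{int(unequal.sum())} gene(s) with degenerate variances and "
                "unequal means; p set to 0",
                RuntimeWarning,
            )
            t[unequal] = np.where(case.mean(axis=1)[unequal] > ctrl.mean(axis=1)[unequal], np.inf, -np.inf)
            p[unequal] = 0.0

    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {"t": t, "p": p, "fdr": fdr, "is_deg": fdr < alpha},
        index=matrix.values.index,
    )
    out.index.name = "gene_id"
    return out


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the DEG table as TSV (gene_id, t, p, fdr, is_deg)."""
    table.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
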