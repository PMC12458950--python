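"""Copy-number burden scoring from an inferred-CNV matrix.

Single-cell CNV inference tools emit a cells x genes matrix of smoothed
relative copy-number values centered at 1 (diploid). The per-cell CNV score
is the fraction of genes whose value falls strictly outside a neutral band
(default 0.9–1.1) — a simple burden statistic that separates genomically
quiet cells from aneuploid ones. Rank correlation between CNV and expression
asks whether a clone's expression program tracks its copy-number changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CNVBand", "cnv_score", "cnv_scores", "spearman_rho", "group_cnv_expression"]


@dataclass(frozen=True)
class CNVBand:
    """The copy-number-neutral band; values strictly outside it count as deviating."""

    lower: float = 0.9
    upper: float = 1.1

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError("need 0 < lower < upper")


def cnv_score(values, band: CNVBand | None = None) -> float:
    """Fraction of genes whose inferred CNV lies strictly outside the band.

    Boundary values (exactly at ``lower`` or ``upper``) do not count: the
    definition is (1/N) Σ I(x_i < lower or x_i > upper).
    """
    band = band or CNVBand()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty CNV vector")
    return float(((x < band.lower) | (x > band.upper)).mean())


def cnv_scores(matrix: pd.DataFrame, band: CNVBand | None = None) -> pd.Series:
    """Per-cell CNV score over a cells x genes inferred-CNV frame."""
    band = band or CNVBand()
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] == 0:
        raise ValueError("matrix has no genes")
    out = ((x < band.lower) | (x > band.upper)).mean(axis=1)
    return pd.Series(out, index=matrix.index, name="cnv_score")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (ties get mean ranks).

    Thin, validating wrapper: rejects constant inputs explicitly ("zero rank
    variance") instead of returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance: constant input")
    return float(stats.spearmanr(x, y).statistic)


def group_cnv_expression(
    cnv: pd.DataFrame,
    expression: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell CNV-vs-expression rank correlation, summarized per clone group.

    Both frames are cells x genes; only cells and genes present in both are
    used (no imputation). For each shared cell, Spearman's rho is computed
    across the shared genes; cells whose CNV or expression vector is constant
    are dropped with a warning. Returns (per-cell frame with columns
    ``group`` and ``rho``, per-group median rho). Groups with no usable cells
    are omitted with a warning.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    cells = cnv.index.intersection(expression.index).intersection(groups.index)
    genes = cnv.columns.intersection(expression.columns)
    if len(cells) == 0 or len(genes) == 0:
        raise ValueError("no shared cells or genes between CNV and expression")
    rows = []
    for cell in cells:
        xv = cnv.loc[cell, genes].to_numpy(dtype=float)
        yv = expression.loc[cell, genes].to_numpy(dtype=float)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            warnings.warn(f"cell {cell!r}: constant vector, skipped")
            continue
        rows.append((cell, groups[cell], spearman_rho(xv, yv)))
    per_cell = pd.DataFrame(rows, columns=["cell", "group", "rho"]).set_index("cell")
    empty = set(groups.unique()) - set(per_cell["group"].unique())
    if empty:
        warnings.warn(f"groups with no usable cells omitted: {sorted(empty)}")
    medians = per_cell.groupby("group")["rho"].median()
    return per_cell, medians
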