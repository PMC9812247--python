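"""Per-gene Spearman association between expression and activation.

The central exchange object is the :class:`CorrelationTable`: one Spearman
rho per gene against the activation profile of one compartment at one
granularity (region or voxel), sorted by descending rho with a deterministic
gene-id tie-break, plus an optional spatially corrected p-value column
filled in by the surrogate machinery.

Spearman (rank) correlation is used throughout because regional expression
values are partly non-symmetric and contain outliers; it is the Pearson
correlation of mid-ranks (average ranks on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AlignmentError, ParameterError, UndefinedCorrelationError
from .io import SpatialProfile

__all__ = [
    "CorrelationTable",
    "spearman",
    "correlate_genes",
    "threshold_correlations",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationTable:
    """Ranked per-gene correlation records for one compartment/granularity.

    ``data`` columns: gene_id, rho, p_spatial, rank. Sorted by descending
    rho; ranks are 1-based. ``excluded_genes`` lists genes dropped for
    having a constant expression profile (their rho is undefined).
    """

    data: pd.DataFrame
    compartment: str
    granularity: str
    n_units: int
    excluded_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_units <= 2:
            raise ParameterError("need more than 2 spatial units")
        required = {"gene_id", "rho", "p_spatial", "rank"}
        if not required <= set(self.data.columns):
            raise ParameterError(f"table needs columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.data["gene_id"].to_numpy()

    def rho_series(self) -> pd.Series:
        """rho indexed by gene_id (the per-gene ranking metric)."""
        return self.data.set_index("gene_id")["rho"]

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        out = self.data.copy()
        out.insert(1, "compartment", self.compartment)
        out.insert(2, "granularity", self.granularity)
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _midranks(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Raises :class:`UndefinedCorrelationError` on a constant input rather
    than silently returning 0, and :class:`ParameterError` for length
    mismatch, n < 3 or non-finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ParameterError(f"need n >= 3, got n = {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant input")
    rx = _midranks(x)
    ry = _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
    return float(np.clip(rho, -1.0, 1.0))


def rank_rows(values: np.ndarray) -> np.ndarray:
    """Mid-rank every row of a 2-D array (vectorized rankdata)."""
    return rankdata(values, method="average", axis=1)


def spearman_matrix(profiles: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of ``profiles`` against ``target``.

    Rows with zero rank variance (constant profiles) yield NaN.
    """
    rx = rank_rows(profiles)
    ry = _midranks(target)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry @ ry))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    return np.clip(rho, -1.0, 1.0)


def correlate_genes(
    expression: pd.DataFrame, activation: SpatialProfile
) -> CorrelationTable:
    """Spearman rho of every gene's profile against the activation profile.

    Expression columns and activation unit ids must contain the same units;
    columns are reordered to the activation's order before correlating.
    Genes with a constant profile are excluded from the ranking (logged).
    The result is sorted by descending rho, ties broken by gene_id.
    """
    expr_units = set(expression.columns)
    act_units = set(activation.unit_ids.tolist())
    if expr_units != act_units:
        raise AlignmentError(
            f"unit-id mismatch: {len(expr_units - act_units)} only in expression, "
            f"{len(act_units - expr_units)} only in activation"
        )
    expr = expression.loc[:, list(activation.unit_ids)]
    rho = spearman_matrix(expr.to_numpy(dtype=float), activation.values)

    constant = np.isnan(rho)
    if constant.any():
        logger.info(
            "excluded %d constant-profile gene(s) from ranking", int(constant.sum())
        )
    df = pd.DataFrame(
        {"gene_id": expr.index[~constant], "rho": rho[~constant]}
    )
    df = df.sort_values(
        ["rho", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["p_spatial"] = np.nan
    df["rank"] = np.arange(1, len(df) + 1)
    return CorrelationTable(
        df[["gene_id", "rho", "p_spatial", "rank"]],
        compartment=activation.compartment,
        granularity=activation.granularity,
        n_units=len(activation),
        excluded_genes=tuple(expr.index[constant]),
    )


def threshold_correlations(
    table: CorrelationTable, rho_min: float = 0.5
) -> tuple[set[str], set[str]]:
    """Split a ranked table into large-effect positive / negative gene sets.

    Strict inequalities: positive = {rho > rho_min}, negative =
    {rho < -rho_min}; a gene at exactly the threshold is excluded. The
    default 0.5 retains only correlations with a large effect size.
    """
    if not 0.0 < rho_min < 1.0:
        raise ParameterError(f"rho_min must be in (0, 1), got {rho_min}")
    rho = table.rho_series()
    positive = set(rho.index[rho > rho_min])
    negative = set(rho.index[rho < -rho_min])
    if not positive and not negative:
        logger.info("no gene exceeds |rho| > %.3f", rho_min)
    return positive, negative
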