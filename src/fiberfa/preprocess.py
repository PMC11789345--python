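"""Quality filtering and log2(RPM + 1) normalization.

Cells are removed when their total count reaches the count cutoff
(boundary inclusive, >= 5000 by default) or their mitochondrial fraction
reaches the mito cutoff (>= 10%).  Retained counts are converted to
reads-per-million and log2-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["ExprMatrix", "QCReport", "qc_filter", "normalize_log_rpm"]


class EmptyMatrixError(RuntimeError):
    """All cells were removed by QC; the configuration needs review."""


@dataclass
class QCReport:
    """Per-cell QC record: totals, mito fraction, kept flag and reason."""

    frame: pd.DataFrame  # cell, total, mito_frac, kept, reason
    count_cutoff: float
    mito_cutoff: float

    @property
    def kept_fraction(self) -> float:
        return float(self.frame["kept"].mean()) if len(self.frame) else float("nan")


@dataclass
class ExprMatrix:
    """log2(RPM + 1) expression, cells x genes."""

    cells: list[str]
    genes: list[str]
    values: np.ndarray
    condition: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.genes)

    def subset_genes(self, genes: list[str]) -> pd.DataFrame:
        missing = [g for g in genes if g not in self.genes]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        ix = [self.genes.index(g) for g in genes]
        return pd.DataFrame(self.values[:, ix], index=self.cells, columns=genes)


def qc_filter(counts: CountMatrix, count_cutoff: float = 5000,
              mito_cutoff: float = 0.10,
              count_filter: str = "ge_removes") -> tuple[CountMatrix, QCReport]:
    """Remove cells failing the count or mitochondrial-fraction rule.

    With the default ``count_filter="ge_removes"`` a cell is removed when
    its total count is >= ``count_cutoff`` or its mitochondrial fraction
    is >= ``mito_cutoff`` (both boundaries inclusive on the removal
    side).  ``"lt_removes"`` inverts the count rule for reanalyses that
    want a lower bound instead.  Zero-total cells are always removed.
    """
    if count_filter not in ("ge_removes", "lt_removes"):
        raise ValueError(f"unknown count_filter {count_filter!r}")
    totals = counts.totals()
    mito = counts.mito_fraction()
    if count_filter == "ge_removes":
        bad_count = totals >= count_cutoff
    else:
        bad_count = totals < count_cutoff
    bad_mito = mito >= mito_cutoff
    zero = totals == 0

    reason = np.full(counts.n_cells, "", dtype=object)
    reason[bad_mito] = "high_mito"
    reason[bad_count] = "count_cutoff"
    reason[bad_count & bad_mito] = "count_cutoff+high_mito"
    reason[zero] = "zero_total"
    kept = ~(bad_count | bad_mito | zero)

    report = QCReport(
        frame=pd.DataFrame({
            "cell": counts.cells,
            "total": totals,
            "mito_frac": mito,
            "kept": kept,
            "reason": np.where(kept, "kept", reason),
        }),
        count_cutoff=count_cutoff,
        mito_cutoff=mito_cutoff,
    )
    if counts.n_cells and not kept.any():
        raise EmptyMatrixError(
            "QC removed every cell; review count_cutoff/mito_cutoff against "
            "the data's depth")
    return counts.subset_cells(kept), report


def normalize_log_rpm(counts: CountMatrix) -> ExprMatrix:
    """Convert counts to log2(RPM + 1); RPM = count / cell total * 1e6."""
    totals = counts.totals().astype(float)
    if np.any(totals <= 0):
        bad = counts.cells[int(np.flatnonzero(totals <= 0)[0])]
        raise ValueError(
            f"cell {bad!r} has zero total counts; run qc_filter first")
    rpm = counts.counts / totals[:, None] * 1e6
    return ExprMatrix(
        cells=list(counts.cells),
        genes=list(counts.genes),
        values=np.log2(rpm + 1.0),
        condition=list(counts.condition) if counts.condition is not None else None,
    )
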