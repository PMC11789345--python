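"""Four-way fiber classification from the two factor scores.

A cell is fast-positive when its fast-factor score reaches tau_fast and
slow-positive when its slow score reaches tau_slow (boundaries
inclusive), giving the four classes double_negative / fast / slow /
double_positive.  Thresholds are normally read off the score histograms
by eye; ``propose_thresholds`` automates that reading by locating the
density valley between the two main modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSet", "FiberClassAssignment", "propose_thresholds",
           "classify_cells", "CLASS_LABELS"]

CLASS_LABELS = ("double_negative", "fast", "slow", "double_positive")


@dataclass(frozen=True)
class ThresholdSet:
    tau_fast: float
    tau_slow: float
    provenance: str = "auto"  # "manual" when supplied by the analyst

    def __post_init__(self):
        if not (np.isfinite(self.tau_fast) and np.isfinite(self.tau_slow)):
            raise ValueError("thresholds must be finite")


@dataclass
class FiberClassAssignment:
    frame: pd.DataFrame  # cell, F_fast, F_slow, label
    thresholds: ThresholdSet

    def counts(self) -> pd.Series:
        return self.frame["label"].value_counts()


def _valley_threshold(values: np.ndarray, grid_size: int = 512
                      ) -> tuple[float, bool]:
    """KDE-valley threshold; returns (threshold, used_fallback)."""
    kde = scipy.stats.gaussian_kde(values)
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    peaks, props = scipy.signal.find_peaks(dens, prominence=0.05 * dens.max())
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(dens[peaks])[::-1][:2]]
        left, right = sorted(top2)
        valley = grid[left + int(np.argmin(dens[left:right + 1]))]
        return float(valley), False
    # unimodal density: fall back to the 1-D 2-means midpoint
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
        values.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    return float(centers.mean()), True


def propose_thresholds(scores: pd.DataFrame, method: str = "valley",
                       tau_fast: float | None = None,
                       tau_slow: float | None = None) -> ThresholdSet:
    """Thresholds for the fast and slow factor scores.

    Manual values, when given, are returned verbatim with provenance
    "manual".  Otherwise each score's kernel-density estimate is scanned
    for its two largest modes and the threshold placed at the density
    minimum between them, falling back (with a warning) to the 1-D
    2-means midpoint when the density is unimodal.
    """
    if tau_fast is not None and tau_slow is not None:
        return ThresholdSet(float(tau_fast), float(tau_slow),
                            provenance="manual")
    if method != "valley":
        raise ValueError(f"unknown threshold method {method!r}")
    if len(scores) < 20:
        raise ValueError(
            f"only {len(scores)} cells; too few for automatic thresholds -- "
            "supply tau_fast/tau_slow manually")
    taus = {}
    for key, col in (("fast", "F_fast"), ("slow", "F_slow")):
        vals = scores[col].to_numpy(dtype=float)
        tau, fell_back = _valley_threshold(vals)
        if fell_back:
            logger.warning(
                "%s score density is unimodal; threshold from 2-means "
                "midpoint at %.3f", key, tau)
        taus[key] = tau
    return ThresholdSet(taus["fast"], taus["slow"], provenance="auto")


def classify_cells(scores: pd.DataFrame,
                   thresholds: ThresholdSet) -> FiberClassAssignment:
    """Assign each cell to one of the four fiber classes.

    fast-positive = F_fast >= tau_fast, slow-positive = F_slow >=
    tau_slow (boundaries inclusive); the two bits select the class.
    """
    for col in ("F_fast", "F_slow"):
        if col not in scores.columns:
            raise KeyError(f"scores missing column {col!r}")
        bad = scores.index[scores[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col} score for cell {bad[0]!r}")
    fast_pos = scores["F_fast"] >= thresholds.tau_fast
    slow_pos = scores["F_slow"] >= thresholds.tau_slow
    label = np.select(
        [fast_pos & slow_pos, fast_pos, slow_pos],
        ["double_positive", "fast", "slow"],
        default="double_negative",
    )
    frame = pd.DataFrame({
        "cell": scores.index,
        "F_fast": scores["F_fast"].to_numpy(),
        "F_slow": scores["F_slow"].to_numpy(),
        "label": label,
    })
    return FiberClassAssignment(frame=frame, thresholds=thresholds)
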