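"""Threshold-based rejection of spurious frames and ROC threshold selection.

A frame is rejected as spurious when its class-conditional log-density is
below a threshold Th for *every* state, i.e. when the rejection statistic
max_i log p(x | S_i) falls below Th. The threshold is picked from the
sensitivity/specificity curve computed on training data where the truly
spurious frames are known: moving along the grid, sensitivity (spurious
frames rejected) rises while specificity (genuine frames retained) falls,
and the selected threshold is the last point at which specificity still
(slightly) exceeds sensitivity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RejectionConfig",
    "RocCurve",
    "rejection_statistic",
    "rejection_mask",
    "roc_curve",
    "select_threshold",
    "plot_roc",
]


@dataclass
class RejectionConfig:
    """Threshold on the max-over-states log class-conditional density."""

    threshold: float


@dataclass
class RocCurve:
    """Se/Sp per threshold; Se non-decreasing, Sp non-increasing in Th."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def rejection_statistic(log_densities) -> np.ndarray:
    """max over states of log p(x | S_i), one value per frame."""
    logd = np.atleast_2d(np.asarray(log_densities, dtype=float))
    return logd.max(axis=1)


def rejection_mask(log_densities, cfg: RejectionConfig | float) -> np.ndarray:
    """True where the frame is spurious: every state's density below Th."""
    th = cfg.threshold if isinstance(cfg, RejectionConfig) else float(cfg)
    return rejection_statistic(log_densities) < th


def roc_curve(log_densities, true_spurious_flags) -> RocCurve:
    """Se/Sp over the sorted unique statistic values (plus +inf).

    Se = fraction of truly spurious frames rejected at Th;
    Sp = fraction of genuine frames retained at Th.
    """
    stat = rejection_statistic(log_densities)
    flags = np.asarray(true_spurious_flags, dtype=bool)
    if flags.shape[0] != stat.shape[0]:
        raise ValueError("one flag per frame required")
    if flags.all() or not flags.any():
        raise ValueError("both spurious and genuine frames are required")
    grid = np.append(np.unique(stat), np.inf)
    spurious = stat[flags]
    genuine = stat[~flags]
    se = np.array([(spurious < th).mean() for th in grid])
    sp = np.array([(genuine >= th).mean() for th in grid])
    return RocCurve(grid, se, sp)


def select_threshold(roc: RocCurve) -> float:
    """Largest grid threshold with Sp >= Se (specificity slightly greater).

    Along the grid Se rises from 0 and Sp falls from 1, so this is the point
    just before the Se/Sp crossing. If Sp >= Se everywhere the largest grid
    threshold is returned.
    """
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    ok = np.flatnonzero(roc.specificity >= roc.sensitivity)
    if ok.size == 0:
        return float(roc.thresholds[0])
    return float(roc.thresholds[ok[-1]])


def plot_roc(roc: RocCurve, path=None, ax=None):
    """Plot Se and 1-Sp against the threshold grid (optional figure export)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    finite = np.isfinite(roc.thresholds)
    ax.plot(roc.thresholds[finite], roc.sensitivity[finite], label="sensitivity")
    ax.plot(roc.thresholds[finite], roc.specificity[finite], label="specificity")
    ax.set_xlabel("threshold Th (log density)")
    ax.set_ylabel("rate")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120)
    return ax
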