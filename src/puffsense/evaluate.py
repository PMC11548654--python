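"""Per-bin evaluation statistics for predicted size-binned PM masses.

For each size bin, with targets M_k and predictions Mhat_k over n puffs:

    MSE = (1/n) sum (M_k - Mhat_k)^2          [mg^2]
    MRE = (1/n) sum |(M_k - Mhat_k) / M_k|    [fraction]
    MBE = (1/n) sum (M_k - Mhat_k)            [mg]

Residuals follow the target-minus-prediction convention, so a positive MBE
means the model underpredicts.  Accuracy is reported as 100 * (1 - MRE)
percent, and the bias ratio as 100 * MBE / mean(M).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationReport",
    "evaluate_predictions",
    "mbe_ratio",
    "accuracy_percent",
    "report_table",
    "plot_target_vs_predicted",
]

BIN_LABELS = ("M1 (100-300 nm)", "M2 (300-600 nm)", "M3 (600-1000 nm)")


@dataclass(frozen=True)
class EvaluationReport:
    """Per-bin arrays ordered (M1, M2, M3)."""

    mse: np.ndarray  # mg^2
    mre: np.ndarray  # fraction
    mbe: np.ndarray  # mg, target - prediction
    mean_target: np.ndarray  # mg
    mbe_ratio: np.ndarray  # percent
    n: int
    n_zero_targets_excluded: int = 0

    def accuracy(self) -> np.ndarray:
        return accuracy_percent(self.mre)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mse_mg2": self.mse.tolist(),
            "mre": self.mre.tolist(),
            "accuracy_percent": self.accuracy().tolist(),
            "mbe_mg": self.mbe.tolist(),
            "mean_target_mg": self.mean_target.tolist(),
            "mbe_ratio_percent": self.mbe_ratio.tolist(),
            "n_zero_targets_excluded": self.n_zero_targets_excluded,
        }

    def summary(self) -> str:
        lines = [f"{'bin':<18}{'MSE/mg^2':>12}{'MRE':>9}{'acc/%':>8}{'MBE/mg':>10}{'MBE ratio/%':>13}"]
        for i, label in enumerate(BIN_LABELS):
            lines.append(
                f"{label:<18}{self.mse[i]:>12.5g}{self.mre[i]:>9.3f}"
                f"{self.accuracy()[i]:>8.1f}{self.mbe[i]:>10.4g}{self.mbe_ratio[i]:>13.2f}"
            )
        return "\n".join(lines)


def _to_matrix(values) -> np.ndarray:
    arr = np.asarray(
        [v.as_array() if hasattr(v, "as_array") else v for v in values], dtype=float
    )
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected n x 3 size-binned masses")
    return arr


def evaluate_predictions(targets, predictions) -> EvaluationReport:
    """Per-bin MSE/MRE/MBE and bias ratios from paired target/prediction lists."""
    t = _to_matrix(targets)
    p = _to_matrix(predictions)
    if t.shape != p.shape:
        raise ValueError("targets and predictions must have equal lengths")
    n = t.shape[0]
    if n < 1:
        raise ValueError("at least one sample is required")
    resid = t - p
    mse = np.mean(resid**2, axis=0)
    mbe = np.mean(resid, axis=0)
    mean_target = np.mean(t, axis=0)

    zero = t == 0
    n_excluded = int(np.any(zero, axis=1).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sample(s) with zero target excluded from MRE",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(zero, np.nan, np.abs(resid) / t)
    mre = np.nanmean(rel, axis=0)

    if np.any(mean_target <= 0):
        ratio = np.full(3, np.nan)
    else:
        ratio = np.array([mbe_ratio(b, m) for b, m in zip(mbe, mean_target)])
    return EvaluationReport(mse, mre, mbe, mean_target, ratio, n, n_excluded)


def mbe_ratio(mbe: float, mean_target: float) -> float:
    """Bias as a percentage of the mean target mass: 100 * MBE / mean."""
    if mean_target <= 0:
        raise ValueError("mean_target must be > 0")
    return 100.0 * mbe / mean_target


def accuracy_percent(mre) -> np.ndarray:
    """Accuracy bookkeeping: 100 * (1 - MRE) percent."""
    return 100.0 * (1.0 - np.asarray(mre, dtype=float))


REPORT_COLUMNS = [
    "model_ref",
    "inputs",
    "layer_size",
    "epochs",
    "train_mse_m1",
    "train_mse_m2",
    "train_mse_m3",
    "test_mse_m1",
    "test_mse_m2",
    "test_mse_m3",
]


def report_table(configs) -> pd.DataFrame:
    """Ablation-style table: one row per trained configuration."""
    return pd.DataFrame(list(configs), columns=REPORT_COLUMNS)


def plot_target_vs_predicted(targets, predictions, path=None):
    """Three-panel scatter of target vs predicted mass, one panel per bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, p = _to_matrix(targets), _to_matrix(predictions)
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.2))
    for i, (ax, label) in enumerate(zip(axes, BIN_LABELS)):
        ax.scatter(t[:, i], p[:, i], s=18)
        lim = max(t[:, i].max(), p[:, i].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("target mass / mg")
        ax.set_ylabel("predicted mass / mg")
        ax.set_title(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
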