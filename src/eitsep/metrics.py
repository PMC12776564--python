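"""Segmentation metrics: Dice similarity coefficient and percent MAE.

Dice is computed on 0.5-binarized maps, MAE on the continuous probability
maps (reported in percent); both are averaged per-sample over the test
set.  Relative improvements are reported in percentage points against the
classical U-Net baseline: model - baseline for Dice (higher is better),
baseline - model for MAE (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel = 1 iff value >= threshold (ties count as foreground)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def mae(pred_map: np.ndarray, target_map: np.ndarray) -> float:
    """100 x mean absolute per-pixel difference (percent)."""
    p = np.asarray(pred_map, dtype=float)
    t = np.asarray(target_map, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(100.0 * np.mean(np.abs(p - t)))


def relative_improvement(model_value: float, baseline_value: float,
                         orientation: str) -> float:
    """Improvement in percentage points over the baseline."""
    if orientation == "higher_better":
        return model_value - baseline_value
    if orientation == "lower_better":
        return baseline_value - model_value
    raise ValueError(f"unknown orientation {orientation!r}")


@dataclass
class MetricsRecord:
    """One row of the weight-ratio comparison table."""

    label: str                      # "wc=1.8" or "baseline"
    wc: float | None
    dice_heart: float               # percent
    mae_heart: float                # percent
    dice_lung: float                # percent
    mae_lung: float                 # percent
    improvement_dice: float | None = None   # pp vs baseline
    improvement_mae: float | None = None    # pp vs baseline

    def with_baseline(self, baseline: "MetricsRecord") -> "MetricsRecord":
        return MetricsRecord(
            self.label, self.wc, self.dice_heart, self.mae_heart,
            self.dice_lung, self.mae_lung,
            relative_improvement(self.dice_heart, baseline.dice_heart,
                                 "higher_better"),
            relative_improvement(self.mae_heart, baseline.mae_heart,
                                 "lower_better"),
        )


def evaluate(model, test_X: np.ndarray, test_y: np.ndarray,
             threshold: float = 0.5, label: str = "",
             wc: float | None = None) -> MetricsRecord:
    """Per-sample-averaged heart and lung Dice/MAE of a fitted estimator."""
    if test_X.shape[0] == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(test_X)
    masks = binarize(proba, threshold)
    d_l, d_h, m_l, m_h = [], [], [], []
    for i in range(test_X.shape[0]):
        d_l.append(dice(masks[i, 0], test_y[i, 0] >= 0.5))
        d_h.append(dice(masks[i, 1], test_y[i, 1] >= 0.5))
        m_l.append(mae(proba[i, 0], test_y[i, 0]))
        m_h.append(mae(proba[i, 1], test_y[i, 1]))
    return MetricsRecord(
        label=label, wc=wc,
        dice_heart=100.0 * float(np.mean(d_h)),
        mae_heart=float(np.mean(m_h)),
        dice_lung=100.0 * float(np.mean(d_l)),
        mae_lung=float(np.mean(m_l)),
    )


def records_to_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def export_csv(records: Iterable[MetricsRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def plot_wc_curves(records: Iterable[MetricsRecord], path) -> None:
    """Heart Dice and MAE versus the weight ratio Wc (trend curves)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = [r for r in records if r.wc is not None]
    recs.sort(key=lambda r: r.wc)
    wcs = [r.wc for r in recs]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    ax1.plot(wcs, [r.dice_heart for r in recs], "o-")
    ax1.set_xlabel("Wc"); ax1.set_ylabel("heart Dice (%)")
    ax2.plot(wcs, [r.mae_heart for r in recs], "o-", color="tab:red")
    ax2.set_xlabel("Wc"); ax2.set_ylabel("heart MAE (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_history(history: dict, path) -> None:
    """Per-epoch training/validation curves of one run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    ax1.plot(history["epoch"], history["train_loss"], label="train")
    if np.isfinite(history["val_loss"]).any():
        ax1.plot(history["epoch"], history["val_loss"], label="validation")
    ax1.set_xlabel("epoch"); ax1.set_ylabel("loss"); ax1.legend()
    if np.isfinite(history["val_dice_heart"]).any():
        ax2.plot(history["epoch"], history["val_dice_heart"], label="heart")
        ax2.plot(history["epoch"], history["val_dice_lung"], label="lung")
    ax2.set_xlabel("epoch"); ax2.set_ylabel("validation Dice"); ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
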