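"""Training orchestration: fixed-split training runs and the Wc grid search.

The grid search trains one semi-Siamese network per heart-weight ratio
Wc (W_lung fixed at 1, W_heart = Wc) plus one classical U-Net baseline
with unit weights, evaluates each once on the fixed independent test set,
and tabulates heart Dice/MAE with relative improvements over the
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DatasetSplit
from .losses import EPS_DEFAULT, LossWeights
from .metrics import MetricsRecord, evaluate
from .models import ClassicalUNet, SemiSiameseUNet

WC_GRID_DEFAULT = (1.0, 1.5, 1.8, 2.0)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run (Adam throughout)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 60
    patience: int = 10
    base_channels: int = 16
    depth: int = 4
    head_bias: float = -2.0
    clip_eps: float = EPS_DEFAULT
    seed: int = 0
    wc_grid: tuple[float, ...] = WC_GRID_DEFAULT

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.wc_grid):
            raise ValueError("grid values must be positive")
        if not 0 < self.clip_eps < 0.5:
            raise ValueError("clipping epsilon must be in (0, 0.5)")


def _estimator(config: TrainingConfig, weights: LossWeights, seed: int,
               baseline: bool = False):
    cls = ClassicalUNet if baseline else SemiSiameseUNet
    return cls(
        base_channels=config.base_channels, depth=config.depth,
        w_lung=weights.w_lung, w_heart=weights.w_heart,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        epochs=config.epochs, patience=config.patience,
        clip_eps=config.clip_eps, head_bias=config.head_bias,
        random_state=seed,
    )


def train_model(model, X: np.ndarray, y: np.ndarray, split: DatasetSplit,
                ):
    """Fit an estimator on the train part of ``split``, validating on the rest.

    Returns ``(fitted model, history dict)``.
    """
    if len(split.train_indices) == 0 or len(split.val_indices) == 0:
        raise ValueError("split has an empty train or validation part")
    model.fit(
        X[split.train_indices], y[split.train_indices],
        validation_data=(X[split.val_indices], y[split.val_indices]),
    )
    return model, model.history_


def grid_search_wc(X: np.ndarray, y: np.ndarray, split: DatasetSplit,
                   test_X: np.ndarray, test_y: np.ndarray,
                   config: TrainingConfig | None = None,
                   grid: tuple[float, ...] | None = None,
                   include_baseline: bool = True,
                   ) -> list[MetricsRecord]:
    """One independently seeded run per grid point, plus the baseline row.

    Records are returned in input grid order followed by the baseline;
    every record's relative-improvement columns are filled against the
    baseline when it is included.
    """
    config = config or TrainingConfig()
    grid = tuple(grid if grid is not None else config.wc_grid)
    if not grid:
        raise ValueError("empty Wc grid")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(grid) + 1)
    records = []
    for wc, seed in zip(grid, seeds[:-1]):
        w = LossWeights(1.0, wc)
        model = _estimator(config, w, int(seed) % 2**31)
        train_model(model, X, y, split)
        records.append(
            evaluate(model, test_X, test_y, label=f"wc={wc:g}", wc=wc)
        )
    if include_baseline:
        base_model = _estimator(config, LossWeights(1.0, 1.0),
                                int(seeds[-1]) % 2**31, baseline=True)
        train_model(base_model, X, y, split)
        baseline = evaluate(base_model, test_X, test_y, label="baseline")
        records = [r.with_baseline(baseline) for r in records] + [baseline]
    return records
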