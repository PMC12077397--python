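"""Bootstrapped learning-curve estimation and tangent extrapolation.

Cross-validated performance estimates at a single sample size are noisy,
especially early in data acquisition.  The learning curve is therefore
estimated by repeatedly subsampling the acquired data *without replacement*
at each grid size, scoring each subsample with nested cross-validation, and
aggregating: the mean is the curve value, the 2.5/97.5 bootstrap
percentiles the interval.

The expected full-budget performance is forecast from the curve's tangent
at the current size — assuming the latest growth rate persists for the
remaining observations.  For concave (saturating) learning curves this is
an optimistic forecast, which makes it a useful upper bound on achievable
performance: when even the upper bound shows no relevant gain, discovery
can stop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import rng_from, spawn_seeds
from .dataset import Dataset
from .models import SCORERS, ModelSpec, cv_predict, min_feasible_size

__all__ = [
    "LearningCurve",
    "default_grid",
    "bootstrap_learning_curve",
    "actual_score",
    "extrapolate_tangent",
]


@dataclass(frozen=True)
class LearningCurve:
    """Bootstrapped CV score as a function of training sample size."""

    sizes: np.ndarray
    scores: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    scorer_id: str

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=int)
        if not (len(sizes) == len(self.scores) == len(self.ci_low) == len(self.ci_high)):
            raise ValueError("curve arrays must have equal length")
        if len(sizes) == 0:
            raise ValueError("empty learning curve")
        if np.any(np.diff(sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")
        object.__setattr__(self, "sizes", sizes)

    @property
    def n_act(self) -> int:
        return int(self.sizes[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "score": self.scores,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_dict(self) -> dict:
        return {
            "sizes": [int(s) for s in self.sizes],
            "scores": [float(s) for s in self.scores],
            "ci_low": [float(s) for s in self.ci_low],
            "ci_high": [float(s) for s in self.ci_high],
            "n_boot": self.n_boot,
            "scorer_id": self.scorer_id,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> str:
        return self.to_dataframe().to_string(index=False)


def default_grid(dataset: Dataset, spec: ModelSpec, n_points: int | None = None) -> list[int]:
    """Evenly spaced sample-size grid from the smallest feasible CV size
    (never below 12) up to the acquired size, 4-10 points."""
    lo = max(12, min_feasible_size(dataset, spec))
    hi = dataset.n
    if lo >= hi:
        return [hi]
    if n_points is None:
        n_points = int(np.clip(4 + (hi - lo) // 40, 4, 10))
    grid = np.unique(np.round(np.linspace(lo, hi, n_points)).astype(int))
    return [int(g) for g in grid]


def _stratified_subsample(dataset: Dataset, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m rows without replacement; classification draws preserve the
    class ratio to within one observation."""
    if dataset.task != "classification":
        return rng.choice(dataset.n, size=m, replace=False)
    labels = dataset.target
    classes, counts = np.unique(labels, return_counts=True)
    take = np.floor(m * counts / dataset.n).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = m * counts / dataset.n - take
    for i in np.argsort(-frac)[: m - take.sum()]:
        take[i] += 1
    idx = []
    for cls, t in zip(classes, take):
        cls_idx = np.flatnonzero(labels == cls)
        idx.append(rng.choice(cls_idx, size=t, replace=False))
    return np.concatenate(idx)


def bootstrap_learning_curve(
    dataset: Dataset,
    spec: ModelSpec,
    grid: list[int] | None = None,
    n_boot: int = 50,
    seed: int = 0,
) -> LearningCurve:
    """Estimate the learning curve on the acquired data.

    For each grid size ``m``, ``n_boot`` subsamples of size ``m`` are drawn
    without replacement (stratified for classification) and scored via
    nested CV; the mean is the curve value and the 2.5/97.5 percentiles the
    interval.  The draws are organized as nested chains — each bootstrap
    replicate subsamples the smaller grid sizes from within the larger
    ones — which leaves the per-size marginal distribution unchanged but
    strongly reduces the variance of the curve's finite differences, on
    which the tangent forecast depends.  Deterministic given ``seed``.
    """
    if grid is None:
        grid = default_grid(dataset, spec)
    grid = sorted(int(g) for g in grid)
    if grid[-1] > dataset.n:
        raise ValueError("grid exceeds acquired sample")
    if grid[0] < min_feasible_size(dataset, spec):
        raise ValueError("insufficient sample for cross-validation")
    boot_seeds = spawn_seeds(seed, n_boot)
    values = np.empty((n_boot, len(grid)))
    for b, b_seed in enumerate(boot_seeds):
        draw_rng = rng_from(b_seed)
        cv_seeds = spawn_seeds(b_seed, len(grid))
        # nested subsample chain, largest size first: each smaller grid
        # size is drawn from within the next larger one, so per-draw
        # increments estimate the gain of the added rows and the curve's
        # finite differences are far less noisy than with independent
        # draws per size
        sub = dataset
        for k in range(len(grid) - 1, -1, -1):
            m = grid[k]
            if m < sub.n:
                sub = sub.subset(_stratified_subsample(sub, m, draw_rng))
            values[b, k] = cv_predict(sub, spec, cv_seeds[k]).score()
    means = values.mean(axis=0)
    lows = np.percentile(values, 2.5, axis=0)
    highs = np.percentile(values, 97.5, axis=0)
    return LearningCurve(
        sizes=np.asarray(grid),
        scores=np.asarray(means),
        ci_low=np.asarray(lows),
        ci_high=np.asarray(highs),
        n_boot=n_boot,
        scorer_id=spec.scorer_id,
    )


def actual_score(curve: LearningCurve) -> float:
    """The curve value at the largest grid size: the current bootstrapped
    performance estimate s_act."""
    return float(curve.scores[-1])


def extrapolate_tangent(curve: LearningCurve, n_total: int) -> float:
    """Forecast performance at the full budget by extending the curve's
    latest growth rate linearly.

    slope = (scores[-1] - scores[-2]) / (sizes[-1] - sizes[-2]);
    forecast = s_act + slope * (n_total - n_act), clipped at the scorer's
    attainable upper bound.  A negative slope is retained so that a
    declining curve can trigger the performance rule even at a smallest
    effect of interest of 0.
    """
    if len(curve.sizes) < 2:
        raise ValueError("cannot extrapolate")
    if n_total < curve.n_act:
        raise ValueError("n_total must be >= the last grid size")
    slope = (curve.scores[-1] - curve.scores[-2]) / (
        curve.sizes[-1] - curve.sizes[-2]
    )
    s_hat = actual_score(curve) + slope * (n_total - curve.n_act)
    upper = SCORERS[curve.scorer_id].upper
    return float(min(s_hat, upper))
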