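"""Permutation test of predictive performance and validation power.

Machine-learning predictions are often non-normally distributed, so the
significance of a performance score is assessed non-parametrically: the
observed score is compared with its distribution under random permutations
of the truth vector.  Building on that test, the power of a *future*
external validation of a given size is estimated by bootstrapping: resample
(truth, prediction) pairs from the discovery phase's out-of-fold
predictions at the candidate validation size, run the permutation test on
each resample, and count rejections.  Evaluating this over a range of
candidate sizes traces the validation power curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd

from ._seeds import rng_from, spawn_seeds
from .models import SCORERS, PredictionSample, Scorer, score

__all__ = [
    "PowerCurve",
    "permutation_test",
    "estimate_power",
    "compute_power_curve",
    "EXHAUSTIVE_LIMIT",
]

# enumerate all permutations exactly when n! is at most this (n <= 7)
EXHAUSTIVE_LIMIT = 5040


@dataclass(frozen=True)
class PowerCurve:
    """Estimated rejection probability of the external validation's
    permutation test as a function of validation sample size."""

    n_grid: np.ndarray
    power: np.ndarray
    alpha: float
    n_boot: int
    n_perm: int

    def __post_init__(self) -> None:
        if len(self.n_grid) != len(self.power):
            raise ValueError("grid and power must have equal length")
        if np.any((np.asarray(self.power) < 0) | (np.asarray(self.power) > 1)):
            raise ValueError("power values must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_grid, "power": self.power})

    def to_dict(self) -> dict:
        return {
            "n_grid": [int(n) for n in self.n_grid],
            "power": [float(p) for p in self.power],
            "alpha": self.alpha,
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> str:
        return self.to_dataframe().to_string(index=False)


def _permuted_scores(
    truth: np.ndarray, prediction: np.ndarray, scorer: Scorer, perms: np.ndarray
) -> np.ndarray:
    """Scores of prediction against each row-permuted truth (vectorized for
    the built-in scorers)."""
    permuted = truth[perms]  # (n_perm, n)
    if scorer.id == "accuracy":
        return (permuted == prediction).mean(axis=1)
    if scorer.id == "neg_mean_absolute_error":
        return -np.abs(permuted - prediction).mean(axis=1)
    if scorer.id == "explained_variance":
        resid = permuted - prediction
        return 1.0 - resid.var(axis=1) / truth.var()
    return np.array([score(row, prediction, scorer) for row in permuted])


def permutation_test(
    truth,
    prediction,
    scorer: Scorer | str,
    n_perm: int = 5000,
    seed: int = 0,
    exhaustive: str | bool = "auto",
) -> float:
    """Permutation p-value of the observed performance score.

    The null distribution is generated by permuting the truth vector.  The
    add-one convention p = (1 + #{s_perm >= s_obs}) / (n_perm + 1) keeps
    p strictly positive; ties count toward the null (conservative).  For
    n! <= 5040 all permutations are enumerated instead of sampled.
    """
    if isinstance(scorer, str):
        scorer = SCORERS[scorer]
    truth = np.asarray(truth, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    n = truth.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scorer.id == "explained_variance" and truth.var() == 0:
        raise ValueError("zero-variance target")
    s_obs = score(truth, prediction, scorer)
    if exhaustive == "auto":
        exhaustive = math.factorial(n) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        perms = np.array(list(_iter_permutations(range(n))), dtype=int)
    else:
        rng = rng_from(seed)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
    s_perm = _permuted_scores(truth, prediction, scorer, perms)
    exceed = int(np.count_nonzero(s_perm >= s_obs - 1e-12))
    return (1 + exceed) / (len(perms) + 1)


def estimate_power(
    sample: PredictionSample,
    n_val: int,
    alpha: float = 0.05,
    n_boot: int = 100,
    n_perm: int = 500,
    seed: int = 0,
) -> float:
    """Bootstrapped power of a permutation test at validation size n_val.

    Resamples ``n_boot`` sets of ``n_val`` (truth, prediction) pairs with
    replacement from the discovery out-of-fold predictions, runs the
    permutation test on each, and returns the fraction rejecting at
    ``alpha``.  Returns 0 for n_val < 3 (no testable sample).
    """
    if not (0 < alpha < 1):
        raise ValueError("invalid alpha")
    if sample.n == 0:
        raise ValueError("empty prediction sample")
    if n_val < 0:
        raise ValueError("n_val must be >= 0")
    if n_val < 3:
        return 0.0
    rng = rng_from(seed)
    perm_seeds = spawn_seeds(seed, n_boot)
    rejections = 0
    for b in range(n_boot):
        idx = rng.integers(0, sample.n, size=n_val)
        truth = sample.truth[idx]
        pred = sample.prediction[idx]
        try:
            p = permutation_test(
                truth, pred, sample.scorer_id, n_perm=n_perm, seed=perm_seeds[b]
            )
        except ValueError:
            # e.g. zero-variance resampled truth: the test cannot reject
            continue
        if p < alpha:
            rejections += 1
    return rejections / n_boot


def compute_power_curve(
    sample: PredictionSample,
    n_max: int,
    alpha: float = 0.05,
    n_boot: int = 100,
    n_perm: int = 500,
    seed: int = 0,
    n_grid: list[int] | None = None,
) -> PowerCurve:
    """Validation power over a grid of candidate sizes 1..n_max.

    The grid is thinned to at most 20 points by default; each grid point
    gets its own child seed so the curve is reproducible point by point.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if n_grid is None:
        n_points = min(20, n_max)
        n_grid = [int(v) for v in np.unique(np.round(np.linspace(1, n_max, n_points)))]
    seeds = spawn_seeds(seed, len(n_grid))
    power = [
        estimate_power(sample, n, alpha, n_boot=n_boot, n_perm=n_perm, seed=s)
        for n, s in zip(n_grid, seeds)
    ]
    return PowerCurve(
        n_grid=np.asarray(n_grid, dtype=int),
        power=np.asarray(power),
        alpha=alpha,
        n_boot=n_boot,
        n_perm=n_perm,
    )
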