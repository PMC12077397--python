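"""The tabular dataset container consumed by every stage of the pipeline.

A :class:`Dataset` is a plain (features, target, task) triple: an
``n x p`` numeric feature matrix, a length-``n`` target vector (real-valued
for regression, two distinct labels for classification), and the task kind.
Missing values are rejected up front so downstream cross-validation and
permutation machinery can assume clean numeric arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dataset", "TASKS"]

TASKS = ("classification", "regression")


@dataclass(frozen=True)
class Dataset:
    """Feature matrix + prediction target + task kind.

    Parameters
    ----------
    features : ndarray of shape (n, p)
        Numeric feature matrix, no missing values.
    target : ndarray of shape (n,)
        Real-valued for regression; exactly two distinct labels for
        classification.
    task : {"classification", "regression"}
    """

    features: np.ndarray
    target: np.ndarray
    task: str
    feature_names: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.target)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("need at least one observation and one feature")
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ValueError("target length must match number of observations")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not np.isfinite(X).all():
            raise ValueError("missing data not supported")
        y = y.astype(float)
        if not np.isfinite(y).all():
            raise ValueError("missing data not supported")
        if self.task == "classification" and np.unique(y).size != 2:
            raise ValueError("degenerate target: classification needs exactly 2 labels")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "target", y)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray | None:
        """Sorted class labels (classification) or None."""
        if self.task != "classification":
            return None
        return np.unique(self.target)

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row subset preserving task and column names."""
        return Dataset(
            self.features[idx], self.target[idx], self.task, self.feature_names
        )

    def chance_level(self) -> float:
        """Score of an uninformed predictor: majority-class rate for
        classification, 0 for regression scorers referenced to it."""
        if self.task == "classification":
            _, counts = np.unique(self.target, return_counts=True)
            return float(counts.max() / self.n)
        return 0.0
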