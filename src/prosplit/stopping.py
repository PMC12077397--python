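"""The adaptive stopping rule and its auditable decision record.

The discovery phase of a prospective predictive-modeling study ends when
the stopping rule fires.  The rule composes four sub-rules:

* Min-rule:          n_act >= t_min                (discovery floor)
* Max-rule:          n_act >= n_total - v_min      (validation floor)
* Performance-rule:  s_hat_total - s_act <= s_min  (no relevant gain left)
* Power-rule:        POW_alpha(s_act, n_val) <= v_pow
                     (waiting longer would under-power validation)

and stops iff::

    Min-rule AND (Max-rule OR Performance-rule OR Power-rule)

With t_min + v_min = n_total the rule degenerates to a fixed split.  Every
evaluation returns a :class:`StopDecision` recording each sub-rule verdict
and the intermediate quantities (learning curve, current score, tangent
forecast, power at the remaining budget), serializable to JSON for
preregistration audit trails.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._seeds import spawn_seeds
from .dataset import Dataset
from .learning_curve import (
    LearningCurve,
    actual_score,
    bootstrap_learning_curve,
    default_grid,
    extrapolate_tangent,
)
from .models import ModelSpec, cv_predict, min_feasible_size
from .power import estimate_power

__all__ = [
    "RuleParams",
    "AcquisitionState",
    "StopDecision",
    "min_rule",
    "max_rule",
    "performance_rule",
    "power_rule",
    "combine_rules",
    "evaluate_stopping",
]


@dataclass(frozen=True)
class RuleParams:
    """Stopping-rule configuration Phi = <t_min, v_min, s_min, v_pow, alpha>.

    t_min : minimum discovery sample size.
    v_min : minimum external validation sample size.
    s_min : smallest predictive performance gain of interest (0 effectively
            disables the performance rule on rising curves).
    v_pow : target statistical power of the external validation.
    alpha : significance level of the validation permutation test.
    """

    t_min: int = 0
    v_min: int = 12
    s_min: float = 0.0
    v_pow: float = 0.8
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.t_min < 0 or self.v_min < 0:
            raise ValueError("t_min and v_min must be >= 0")
        if not (0 < self.v_pow < 1):
            raise ValueError("v_pow must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("invalid alpha")

    @classmethod
    def defaults_for_budget(cls, n_total: int, **overrides) -> "RuleParams":
        """Default configuration used throughout the evaluation protocol:
        t_min = ceil(n_total / 3), v_min = 12, s_min = 0, v_pow = 0.8,
        alpha = 0.05."""
        kwargs = dict(t_min=math.ceil(n_total / 3), v_min=12, s_min=0.0,
                      v_pow=0.8, alpha=0.05)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class AcquisitionState:
    """Where the study stands: n_act observations acquired out of a total
    sample-size budget n_total."""

    n_act: int
    n_total: int

    def __post_init__(self) -> None:
        if not (self.n_total >= self.n_act > 0):
            raise ValueError("need n_total >= n_act > 0")

    @property
    def n_val(self) -> int:
        """Validation size if stopping now."""
        return self.n_total - self.n_act


@dataclass(frozen=True)
class StopDecision:
    """One evaluation of the stopping rule, with full audit trail."""

    stop: bool
    min_rule: bool
    max_rule: bool
    performance_rule: bool
    power_rule: bool
    s_act: float
    s_hat_total: float
    power_at_remaining: float
    n_act: int
    n_total: int
    params: RuleParams
    seed: int
    flag: str | None = None
    curve: LearningCurve | None = field(default=None, compare=False)

    @property
    def n_val_if_stop(self) -> int:
        return self.n_total - self.n_act

    def to_dict(self) -> dict:
        d = {
            "stop": self.stop,
            "min_rule": self.min_rule,
            "max_rule": self.max_rule,
            "performance_rule": self.performance_rule,
            "power_rule": self.power_rule,
            "s_act": self.s_act,
            "s_hat_total": self.s_hat_total,
            "power_at_remaining": self.power_at_remaining,
            "n_act": self.n_act,
            "n_total": self.n_total,
            "n_val_if_stop": self.n_val_if_stop,
            "params": vars(self.params).copy(),
            "seed": self.seed,
            "flag": self.flag,
        }
        if self.curve is not None:
            d["learning_curve"] = self.curve.to_dict()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# sub-rules (pure predicates)


def min_rule(state: AcquisitionState, params: RuleParams) -> bool:
    """Discovery floor: enough data acquired to consider stopping."""
    return state.n_act >= params.t_min


def max_rule(state: AcquisitionState, params: RuleParams) -> bool:
    """Validation floor: acquiring more would leave fewer than v_min
    observations for external validation."""
    return state.n_act >= state.n_total - params.v_min


def performance_rule(s_hat_total: float, s_act: float, params: RuleParams) -> bool:
    """No relevant gain expected from the remaining budget."""
    return (s_hat_total - s_act) <= params.s_min


def power_rule(power_at_remaining: float, params: RuleParams) -> bool:
    """Estimated power of validating with the remaining budget has fallen
    to (or below) the target."""
    if not (0 <= power_at_remaining <= 1):
        raise ValueError("power must lie in [0, 1]")
    return power_at_remaining <= params.v_pow


def combine_rules(min_r: bool, max_r: bool, perf_r: bool, pow_r: bool) -> bool:
    """The composition: Min AND (Max OR Performance OR Power)."""
    return bool(min_r and (max_r or perf_r or pow_r))


# ---------------------------------------------------------------------------


def evaluate_stopping(
    dataset_act: Dataset,
    spec: ModelSpec,
    state: AcquisitionState,
    params: RuleParams,
    seed: int,
    *,
    curve_boot: int = 50,
    power_boot: int = 100,
    n_perm: int = 500,
    grid: list[int] | None = None,
    grid_points: int | None = None,
) -> StopDecision:
    """Evaluate the full stopping rule on the data acquired so far.

    Computes the bootstrapped learning curve, the current score s_act, the
    tangent forecast at the full budget, and the bootstrapped power of a
    validation sample of the remaining size, then combines the four
    sub-rules.  ``curve_boot``, ``power_boot`` and ``n_perm`` trade
    Monte-Carlo precision against runtime.

    If the acquired sample is too small to cross-validate, the decision is
    ``stop=False`` with flag ``"below minimum evaluable size"``.
    """
    if dataset_act.n != state.n_act:
        raise ValueError("dataset size must equal state.n_act")
    min_r = min_rule(state, params)
    max_r = max_rule(state, params)
    if dataset_act.n < min_feasible_size(dataset_act, spec):
        return StopDecision(
            stop=False,
            min_rule=min_r,
            max_rule=max_r,
            performance_rule=False,
            power_rule=False,
            s_act=float("nan"),
            s_hat_total=float("nan"),
            power_at_remaining=float("nan"),
            n_act=state.n_act,
            n_total=state.n_total,
            params=params,
            seed=seed,
            flag="below minimum evaluable size",
        )

    curve_seed, sample_seed, power_seed = spawn_seeds(seed, 3)
    if grid is None:
        grid = default_grid(dataset_act, spec, n_points=grid_points)
    curve = bootstrap_learning_curve(
        dataset_act, spec, grid=grid, n_boot=curve_boot, seed=curve_seed
    )
    s_act = actual_score(curve)
    if len(curve.sizes) >= 2:
        s_hat = extrapolate_tangent(curve, state.n_total)
        perf_r = performance_rule(s_hat, s_act, params)
    else:
        # a single-point curve cannot be extrapolated; never stop on it
        s_hat = float("nan")
        perf_r = False

    sample = cv_predict(dataset_act, spec, sample_seed)
    pow_remaining = estimate_power(
        sample,
        n_val=state.n_val,
        alpha=params.alpha,
        n_boot=power_boot,
        n_perm=n_perm,
        seed=power_seed,
    )
    pow_r = power_rule(pow_remaining, params)

    return StopDecision(
        stop=combine_rules(min_r, max_r, perf_r, pow_r),
        min_rule=min_r,
        max_rule=max_r,
        performance_rule=perf_r,
        power_rule=pow_r,
        s_act=s_act,
        s_hat_total=s_hat,
        power_at_remaining=pow_remaining,
        n_act=state.n_act,
        n_total=state.n_total,
        params=params,
        seed=seed,
        curve=curve,
    )
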