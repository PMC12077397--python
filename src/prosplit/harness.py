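"""Replay engine: prospective acquisition on a finite dataset.

Given a dataset that is larger than (or equal to) a chosen sample-size
budget, the harness simulates a prospective study: rows are drawn without
replacement into an acquisition order, the acquired prefix grows along a
schedule (default: start at 10% of the budget, grow in 5% increments), and
the stopping rule is evaluated at every step.  When it fires, the model is
finalized on the discovery prefix and externally validated on the
remaining rows with a permutation test.  Fixed splits (50:50, Pareto
80:20, 90:10, ...) run through the same machinery for paired comparison,
and :func:`compare_strategies` aggregates over repetitions and budgets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import seed_to_int
from .dataset import Dataset
from .models import FittedModel, ModelSpec, Scorer, fit_tuned, predict, score
from .power import permutation_test
from .stopping import AcquisitionState, RuleParams, StopDecision, evaluate_stopping

__all__ = [
    "AcquisitionSchedule",
    "SplitOutcome",
    "StrategySummary",
    "acquisition_steps",
    "replay_adaptive",
    "run_fixed",
    "external_validate",
    "compare_strategies",
]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Evaluation schedule: start at ``start_fraction`` of the budget and
    re-evaluate every ``step_fraction`` of the budget."""

    start_fraction: float = 0.10
    step_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.start_fraction <= 1):
            raise ValueError("start_fraction must lie in (0, 1]")
        if not (0 < self.step_fraction <= 1):
            raise ValueError("step_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SplitOutcome:
    """End-to-end result of one replayed study."""

    strategy: str
    n_total: int
    n_discovery: int
    n_validation: int
    external_score: float
    external_p: float
    seed: int
    trajectory: tuple[StopDecision, ...] = field(default=(), compare=False)
    forced_stop: bool = False

    @property
    def discovery_fraction(self) -> float:
        return self.n_discovery / self.n_total

    def to_dict(self, include_trajectory: bool = False) -> dict:
        d = {
            "strategy": self.strategy,
            "n_total": self.n_total,
            "n_discovery": self.n_discovery,
            "n_validation": self.n_validation,
            "discovery_fraction": self.discovery_fraction,
            "external_score": self.external_score,
            "external_p": self.external_p,
            "seed": self.seed,
            "forced_stop": self.forced_stop,
        }
        if include_trajectory:
            d["trajectory"] = [t.to_dict() for t in self.trajectory]
        return d


def acquisition_steps(
    n_total: int, schedule: AcquisitionSchedule, v_min: int
) -> list[int]:
    """The n_act values at which the rule is evaluated: from
    ceil(start * n_total) in steps of ceil(step * n_total), rounded up and
    clipped to the discovery cap n_total - v_min (always included last)."""
    cap = max(1, n_total - v_min)
    start = math.ceil(schedule.start_fraction * n_total)
    step = max(1, math.ceil(schedule.step_fraction * n_total))
    steps = list(range(min(start, cap), cap, step))
    steps.append(cap)
    return steps


def _split_seeds(seed: int) -> tuple[int, int, int, np.random.SeedSequence]:
    """Shared seed tree for adaptive and fixed replays so that paired runs
    draw the same rows and fit/validate with the same child seeds."""
    draw_ss, fit_ss, val_ss, steps_ss = np.random.SeedSequence(int(seed)).spawn(4)
    return seed_to_int(draw_ss), seed_to_int(fit_ss), seed_to_int(val_ss), steps_ss


def _draw_budget(dataset: Dataset, n_total: int, draw_seed: int) -> Dataset:
    if n_total > dataset.n:
        raise ValueError("budget exceeds available data")
    order = np.random.default_rng(draw_seed).permutation(dataset.n)[:n_total]
    return dataset.subset(order)


def external_validate(
    model: FittedModel,
    validation: Dataset,
    scorer: Scorer | str,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Score a frozen model on held-out data and test its significance
    with a permutation test (default 5,000 permutations)."""
    if validation.n == 0:
        raise ValueError("empty validation set")
    preds = predict(model, validation.features)
    s = score(validation.target, preds, scorer)
    p = permutation_test(validation.target, preds, scorer, n_perm=n_perm, seed=seed)
    return s, p


def _finalize(
    drawn: Dataset,
    n_disc: int,
    spec: ModelSpec,
    fit_seed: int,
    val_seed: int,
    n_perm: int,
) -> tuple[FittedModel, float, float]:
    discovery = drawn.subset(np.arange(n_disc))
    validation = drawn.subset(np.arange(n_disc, drawn.n))
    model = fit_tuned(discovery, spec, fit_seed)
    s, p = external_validate(model, validation, spec.scorer, n_perm=n_perm, seed=val_seed)
    return model, s, p


def replay_adaptive(
    dataset: Dataset,
    n_total: int,
    params: RuleParams,
    spec: ModelSpec,
    schedule: AcquisitionSchedule | None = None,
    seed: int = 0,
    *,
    curve_boot: int = 50,
    power_boot: int = 100,
    n_perm_power: int = 500,
    n_perm_final: int = 5000,
    grid_points: int | None = None,
) -> SplitOutcome:
    """Replay one adaptively split prospective study.

    Rows are drawn without replacement into an acquisition order; the
    stopping rule is evaluated at each schedule step on the acquired
    prefix.  On stop, the model is fit on the discovery prefix and
    externally validated on the remaining budget.  If the rule never fires
    (possible only with inconsistent floors), the stop is forced at the
    discovery cap n_total - v_min so the replay always terminates.
    """
    schedule = schedule or AcquisitionSchedule()
    draw_seed, fit_seed, val_seed, steps_ss = _split_seeds(seed)
    drawn = _draw_budget(dataset, n_total, draw_seed)
    steps = acquisition_steps(n_total, schedule, params.v_min)
    step_seeds = [seed_to_int(s) for s in steps_ss.spawn(len(steps))]

    trajectory: list[StopDecision] = []
    n_disc = steps[-1]
    forced = True
    for n_act, step_seed in zip(steps, step_seeds):
        state = AcquisitionState(n_act=n_act, n_total=n_total)
        if n_act < params.t_min and n_act < steps[-1]:
            # the Min-rule gates stopping: skip the expensive diagnostics
            trajectory.append(
                StopDecision(
                    stop=False, min_rule=False,
                    max_rule=n_act >= n_total - params.v_min,
                    performance_rule=False, power_rule=False,
                    s_act=float("nan"), s_hat_total=float("nan"),
                    power_at_remaining=float("nan"),
                    n_act=n_act, n_total=n_total, params=params,
                    seed=step_seed, flag="below discovery floor; diagnostics skipped",
                )
            )
            continue
        decision = evaluate_stopping(
            drawn.subset(np.arange(n_act)),
            spec,
            state,
            params,
            step_seed,
            curve_boot=curve_boot,
            power_boot=power_boot,
            n_perm=n_perm_power,
            grid_points=grid_points,
        )
        trajectory.append(decision)
        if decision.stop:
            n_disc, forced = n_act, False
            break

    model, s, p = _finalize(drawn, n_disc, spec, fit_seed, val_seed, n_perm_final)
    assert n_disc + (n_total - n_disc) == n_total
    return SplitOutcome(
        strategy="adaptive",
        n_total=n_total,
        n_discovery=n_disc,
        n_validation=n_total - n_disc,
        external_score=s,
        external_p=p,
        seed=seed,
        trajectory=tuple(trajectory),
        forced_stop=forced,
    )


def run_fixed(
    dataset: Dataset,
    n_total: int,
    ratio: float,
    spec: ModelSpec,
    seed: int = 0,
    n_perm_final: int = 5000,
) -> SplitOutcome:
    """Replay one fixed-ratio split: the first ceil(ratio * n_total) drawn
    rows form the discovery set, the rest the validation set.  Shares the
    seed tree with :func:`replay_adaptive`, so the same seed draws the same
    rows (paired-comparison contract)."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    draw_seed, fit_seed, val_seed, _ = _split_seeds(seed)
    drawn = _draw_budget(dataset, n_total, draw_seed)
    n_disc = min(math.ceil(ratio * n_total), n_total - 1)
    model, s, p = _finalize(drawn, n_disc, spec, fit_seed, val_seed, n_perm_final)
    return SplitOutcome(
        strategy=f"fixed({ratio:g})",
        n_total=n_total,
        n_discovery=n_disc,
        n_validation=n_total - n_disc,
        external_score=s,
        external_p=p,
        seed=seed,
    )


@dataclass(frozen=True)
class StrategySummary:
    """Aggregated replay results per (budget, strategy) cell."""

    runs: pd.DataFrame  # one row per (budget, strategy, repetition)
    table: pd.DataFrame  # aggregated summary
    reps: int
    alpha: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "reps": self.reps,
            "alpha": self.alpha,
            "seed": self.seed,
            "summary": self.table.to_dict(orient="records"),
            "runs": self.runs.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> str:
        return self.table.to_string(index=False)


def compare_strategies(
    dataset: Dataset,
    budgets: list[int],
    strategies: list,
    reps: int,
    params: RuleParams | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
    schedule: AcquisitionSchedule | None = None,
    *,
    curve_boot: int = 50,
    power_boot: int = 100,
    n_perm_power: int = 500,
    n_perm_final: int = 5000,
    grid_points: int | None = None,
) -> StrategySummary:
    """Run every (budget, strategy, repetition) cell and aggregate.

    ``strategies`` mixes the string ``"adaptive"`` with fixed discovery
    ratios (floats).  Each repetition gets one child seed shared across
    strategies, so comparisons are paired; each budget-repetition draws its
    rows independently.  The summary reports mean and 2.5/97.5 percentile
    interval of the external score, mean external p, mean discovery
    fraction, and the count of conclusive validations (p < alpha).
    """
    spec = spec or ModelSpec(dataset.task)
    rows = []
    budget_sss = np.random.SeedSequence(int(seed)).spawn(len(budgets))
    for budget, budget_ss in zip(budgets, budget_sss):
        rule = params or RuleParams.defaults_for_budget(budget)
        rep_seeds = [seed_to_int(s) for s in budget_ss.spawn(reps)]
        for rep, rep_seed in enumerate(rep_seeds):
            for strat in strategies:
                if strat == "adaptive":
                    out = replay_adaptive(
                        dataset, budget, rule, spec, schedule, rep_seed,
                        curve_boot=curve_boot, power_boot=power_boot,
                        n_perm_power=n_perm_power, n_perm_final=n_perm_final,
                        grid_points=grid_points,
                    )
                else:
                    out = run_fixed(
                        dataset, budget, float(strat), spec, rep_seed,
                        n_perm_final=n_perm_final,
                    )
                row = out.to_dict()
                row["budget"] = budget
                row["rep"] = rep
                rows.append(row)
    runs = pd.DataFrame(rows)
    alpha = (params.alpha if params is not None else 0.05)

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "mean_external_score": g["external_score"].mean(),
                "score_ci_low": g["external_score"].quantile(0.025),
                "score_ci_high": g["external_score"].quantile(0.975),
                "mean_external_p": g["external_p"].mean(),
                "mean_discovery_fraction": g["discovery_fraction"].mean(),
                "conclusive": int((g["external_p"] < alpha).sum()),
                "n_runs": len(g),
            }
        )

    table = (
        runs.groupby(["budget", "strategy"])[
            ["external_score", "external_p", "discovery_fraction"]
        ]
        .apply(_agg)
        .reset_index()
    )
    return StrategySummary(runs=runs, table=table, reps=reps, alpha=alpha, seed=seed)
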