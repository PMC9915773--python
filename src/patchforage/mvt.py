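"""Marginal Value Theorem optimality benchmarks for the patch depletion task.

The optimal policy maximizes the cumulative rate of return from a patch —
total volume collected divided by total time including the changeover delay
(travel cost). Under geometric depletion the rate as a function of the number
of rewards taken is unimodal, so the optimum is found by enumeration.

Two rejection-volume conventions coexist in this task and are both exposed:
the *optimal rejection volume* is the scheduled volume at the rate-maximizing
position n* (the printed convention: 120 µL at a 6-s COD), while the
*observed* rejection volume of an agent that leaves after n rewards is the
next scheduled volume, position n+1. An optimal agent's observed rejection
volume is therefore ``scheduled_volume(n* + 1)``, carried here as
``optimal_observed_rejection`` and used as the reference when scoring
deviation from optimality. The two conventions differ by exactly one
position on the schedule; neither is folded into the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .config import TaskConfig
from .task_model import scheduled_volume


@dataclass(frozen=True)
class MVTBenchmark:
    """Per-COD optimal policy summary."""

    cod_s: float
    n_star: int
    optimal_rejection_volume: float
    optimal_observed_rejection: float
    optimal_time_in_patch: float
    optimal_overall_rate: float


def _cumulative_volume(n: int, config: TaskConfig) -> float:
    # geometric series: A (1 - d^n) / (1 - d)
    d = config.decay_fraction
    return config.initial_volume * (1 - d**n) / (1 - d)


def cumulative_rate(cod_s: float, n: int, config: TaskConfig | None = None) -> float:
    """Cumulative rate of return (µL/s) after ``n`` rewards in a patch.

    Total volume of the first ``n`` rewards divided by the travel time plus
    the ``n - 1`` inter-reward intervals: at a 6-s COD this gives 25, 27 and
    ~26.14 µL/s for n = 1, 2, 3 under the default schedule. The degenerate
    COD 0, n = 1 case (a free immediate reward) returns ``inf``.
    """
    if config is None:
        config = TaskConfig()
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if cod_s < 0:
        raise ValueError("cod_s must be >= 0")
    denom = cod_s + config.inter_reward_interval * (n - 1)
    if denom == 0:
        return math.inf
    return _cumulative_volume(n, config) / denom


def optimal_n(cod_s: float, config: TaskConfig | None = None, n_max: int = 200) -> int:
    """Rate-maximizing number of rewards per patch (ties go to fewer rewards).

    COD 0 returns 1: the first reward is instantaneous, so its rate is
    unbounded and the limiting optimal policy is leave-after-first-reward.
    """
    if config is None:
        config = TaskConfig()
    if cod_s == 0:
        return 1
    rates = [cumulative_rate(cod_s, n, config) for n in range(1, n_max + 1)]
    if rates[-1] >= rates[-2]:
        raise AssertionError(
            f"cumulative rate still rising at n_max={n_max}; raise n_max"
        )
    best = max(range(n_max), key=lambda i: (rates[i], -i))
    return best + 1


def mvt_benchmark(cod_s: float, config: TaskConfig | None = None) -> MVTBenchmark:
    """Full optimality summary for one changeover delay."""
    if config is None:
        config = TaskConfig()
    n_star = optimal_n(cod_s, config)
    return MVTBenchmark(
        cod_s=cod_s,
        n_star=n_star,
        optimal_rejection_volume=scheduled_volume(n_star, config),
        optimal_observed_rejection=scheduled_volume(n_star + 1, config),
        optimal_time_in_patch=config.inter_reward_interval * (n_star - 1),
        optimal_overall_rate=cumulative_rate(cod_s, n_star, config),
    )


def benchmark_table(
    cods: Sequence[float], config: TaskConfig | None = None
) -> pd.DataFrame:
    """One row of optimality benchmarks per COD, in input order."""
    rows = []
    for cod in cods:
        b = mvt_benchmark(cod, config)
        rows.append(
            {
                "cod_s": b.cod_s,
                "n_star": b.n_star,
                "optimal_rejection_volume_ul": b.optimal_rejection_volume,
                "optimal_observed_rejection_ul": b.optimal_observed_rejection,
                "optimal_time_in_patch_s": b.optimal_time_in_patch,
                "optimal_overall_rate_ul_per_s": b.optimal_overall_rate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cod_s",
            "n_star",
            "optimal_rejection_volume_ul",
            "optimal_observed_rejection_ul",
            "optimal_time_in_patch_s",
            "optimal_overall_rate_ul_per_s",
        ],
    )
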