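"""Synthetic cohorts for the patch depletion task.

The generative agent is a myopic indifference-threshold forager obtained by
inverting the hyperbolic discounting model: a subject with bias b and
discount rate k values the fresh-patch reward A delayed by the changeover
delay D at v*(D) = bA / (1 + kD), and leaves the current patch as soon as the
next scheduled reward no longer exceeds that threshold. Its observed
rejection volume (the forgone next reward) is thus the hyperbolic
indifference point, quantized to the geometric volume grid — which makes the
downstream discounting fit the matched estimator and parameter recovery
well-posed. Optional logistic choice noise (temperature in µL) and
exponential response latencies add trial-level variability; both default on
for cohort generation and off for deterministic analyses.

The rate-maximizing MVT agent is provided separately as the optimal
reference policy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import CohortSpec, ConfigError, TaskConfig
from .mvt import optimal_n
from .task_model import Decision, Policy, SessionRecord, simulate_session

_TOL = 1e-9


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str
    sex: str
    k_true: float  # hyperbolic discount rate, 1/s
    b_true: float  # bias at zero delay, in (0, 1]
    noise_temp: float  # logistic choice-noise temperature, µL
    latency_mean: float  # mean exponential response latency, s

    def __post_init__(self) -> None:
        if self.k_true < 0:
            raise ConfigError("k_true must be >= 0")
        if not 0 < self.b_true <= 1:
            raise ConfigError("b_true must lie in (0, 1]")
        if self.noise_temp < 0:
            raise ConfigError("noise_temp must be >= 0")


def subject_seed_sequence(spec_seed: int, subject_id: str) -> np.random.SeedSequence:
    """Per-subject random substream, stable under iteration order.

    The cohort seed is combined with a CRC32 of the subject label, so adding
    or reordering subjects never perturbs another subject's draws.
    """
    return np.random.SeedSequence([spec_seed, zlib.crc32(subject_id.encode())])


def make_subject(
    sex: str, spec: CohortSpec, rng: np.random.Generator, subject_id: str = "S0"
) -> SubjectParams:
    """Draw one subject's generative parameters for the given sex.

    k is lognormal (exp of a normal with mean log(median), sd log(gsd));
    b is normal truncated to (0, 1] by resampling. Deterministic given the
    rng state.
    """
    p = spec.sex_params(sex)
    k = p.k_median * np.exp(np.log(p.k_gsd) * rng.standard_normal())
    if p.b_sd == 0:
        b = p.b_mean
    else:
        while True:
            b = p.b_mean + p.b_sd * rng.standard_normal()
            if 0 < b <= 1:
                break
    return SubjectParams(
        subject_id=subject_id,
        sex=sex,
        k_true=float(k),
        b_true=float(b),
        noise_temp=spec.noise_temp,
        latency_mean=spec.latency_mean,
    )


def indifference_threshold(subject: SubjectParams, cod_s: float, A: float) -> float:
    """The subject's hyperbolic indifference point v*(D) = bA / (1 + kD)."""
    return subject.b_true * A / (1.0 + subject.k_true * cod_s)


def threshold_policy(
    subject: SubjectParams, cod_s: float, config: TaskConfig | None = None
) -> Policy:
    """Stay/leave rule of the indifference-threshold agent at one COD.

    Leaves when the next scheduled volume no longer exceeds v*(D) (so the
    observed rejection volume equals the indifference point whenever v* lies
    on the volume grid). With noise temperature tau > 0 the rule softens to
    P(leave) = logistic((v* - v_next) / tau), which tends to a fair coin as
    tau grows.
    """
    if config is None:
        config = TaskConfig()
    v_star = indifference_threshold(subject, cod_s, config.initial_volume)
    tau = subject.noise_temp

    def policy(ctx: Decision, rng=None) -> str:
        if tau == 0:
            return "leave" if ctx.next_volume <= v_star + _TOL else "stay"
        # numerically safe logistic
        x = (v_star - ctx.next_volume) / tau
        p_leave = 1.0 / (1.0 + np.exp(-x))
        return "leave" if rng.random() < p_leave else "stay"

    return policy


def mvt_policy(config: TaskConfig, cod_s: float) -> Policy:
    """The rate-maximizing reference rule: leave after exactly n*(COD) rewards."""
    n_star = optimal_n(cod_s, config)

    def policy(ctx: Decision, rng=None) -> str:
        return "leave" if ctx.rewards_in_visit >= n_star else "stay"

    return policy


#: maps a (subject, cod) pair to a decision rule
PolicyFactory = Callable[[SubjectParams, float], Policy]


def simulate_subject_sessions(
    subject: SubjectParams,
    config: TaskConfig,
    seed_seq: np.random.SeedSequence,
    policy_factory: PolicyFactory | None = None,
) -> list[SessionRecord]:
    """Run a subject through the full session schedule (n_cycles x cod_cycle)."""
    rng = np.random.default_rng(seed_seq)
    if policy_factory is None:
        policy_factory = lambda s, cod: threshold_policy(s, cod, config)
    if subject.latency_mean > 0:
        latency = lambda: int(round(rng.exponential(subject.latency_mean) * 1000))
    else:
        latency = None
    records = []
    for idx in range(config.n_sessions):
        cod = config.cod_cycle[idx % len(config.cod_cycle)]
        records.append(
            simulate_session(
                policy_factory(subject, cod),
                config,
                cod,
                rng,
                subject_id=subject.subject_id,
                sex=subject.sex,
                session_index=idx,
                latency_ms=latency,
            )
        )
    return records


def generate_cohort(
    spec: CohortSpec,
    config: TaskConfig | None = None,
    policy_factory: PolicyFactory | None = None,
    subjects: Sequence[SubjectParams] | None = None,
) -> tuple[list[SessionRecord], pd.DataFrame]:
    """Simulate a full study dataset for a two-sex cohort.

    Returns all session records (``n_subjects * n_cycles * len(cod_cycle)``
    of them, in schedule order per subject) together with a ground-truth
    roster of the generative parameters, for recovery tests. Pass
    ``subjects`` to override the random parameter draws (e.g. a k grid), or
    ``policy_factory`` to swap in a different decision rule such as
    :func:`mvt_policy`.
    """
    if config is None:
        config = TaskConfig()
    if subjects is None:
        subjects = []
        for sex in ("M", "F"):
            for i in range(spec.n_per_sex):
                sid = f"{sex}{i + 1:03d}"
                rng = np.random.default_rng(subject_seed_sequence(spec.seed, sid))
                subjects.append(make_subject(sex, spec, rng, subject_id=sid))

    records: list[SessionRecord] = []
    roster_rows = []
    for subject in subjects:
        seed_seq = subject_seed_sequence(spec.seed, subject.subject_id + ":sessions")
        records.extend(
            simulate_subject_sessions(subject, config, seed_seq, policy_factory)
        )
        roster_rows.append(
            {
                "subject_id": subject.subject_id,
                "sex": subject.sex,
                "k_true": subject.k_true,
                "b_true": subject.b_true,
                "noise_temp": subject.noise_temp,
                "latency_mean": subject.latency_mean,
                "seed": spec.seed,
            }
        )
    roster = pd.DataFrame(roster_rows)
    return records, roster
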