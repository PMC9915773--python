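"""Configuration objects for the task environment, synthetic cohorts, and pipeline runs.

The task constants mirror the operant procedure: two water patches, a
geometrically depleting reward schedule (150 µL entry reward, 20% reduction
per successive reward, 4 s between rewards), a changeover delay (COD) imposed
on every patch switch, and sessions capped at 10 min or 5 ml of cumulative
water. The COD varies across the six sessions of a weekly cycle
(0, 0, 6, 12, 18, 24 s), repeated over four cycles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented constraints."""


@dataclass(frozen=True)
class TaskConfig:
    """Environment constants of the sequential patch depletion procedure.

    Parameters
    ----------
    initial_volume:
        Volume (µL) of the entry reward in a fresh patch. Default 150.
    decay_fraction:
        Multiplicative retention per successive reward; 0.8 means each
        stay reward is 20% smaller than the previous one.
    inter_reward_interval:
        Seconds between successive rewards while staying in a patch.
    session_max_duration:
        Session time cap in seconds (10 min).
    session_volume_cap:
        Cumulative water cap in µL (5 ml); reaching it ends the session.
    cod_cycle:
        Ordered per-session changeover delays within one cycle (seconds).
    n_cycles:
        Number of times the cycle is repeated.
    exclude_first_session_of_cycle:
        Drop each cycle's first session (the warm-up 0-s session) from
        analysis.
    """

    initial_volume: float = 150.0
    decay_fraction: float = 0.8
    inter_reward_interval: float = 4.0
    session_max_duration: float = 600.0
    session_volume_cap: float = 5000.0
    cod_cycle: tuple[float, ...] = (0.0, 0.0, 6.0, 12.0, 18.0, 24.0)
    n_cycles: int = 4
    exclude_first_session_of_cycle: bool = True

    def __post_init__(self) -> None:
        if self.initial_volume <= 0:
            raise ConfigError("initial_volume must be > 0")
        if not 0 < self.decay_fraction < 1:
            raise ConfigError("decay_fraction must lie in (0, 1)")
        if self.inter_reward_interval <= 0:
            raise ConfigError("inter_reward_interval must be > 0")
        if self.session_max_duration <= 0:
            raise ConfigError("session_max_duration must be > 0")
        if self.session_volume_cap <= 0:
            raise ConfigError("session_volume_cap must be > 0")
        if any(c < 0 for c in self.cod_cycle):
            raise ConfigError("changeover delays must be >= 0")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        object.__setattr__(self, "cod_cycle", tuple(float(c) for c in self.cod_cycle))

    @property
    def delays(self) -> tuple[float, ...]:
        """Distinct CODs in first-appearance order (the tested delays)."""
        seen: list[float] = []
        for c in self.cod_cycle:
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    @property
    def n_sessions(self) -> int:
        return self.n_cycles * len(self.cod_cycle)


@dataclass(frozen=True)
class SexParams:
    """Generative population parameters for one sex.

    k is drawn lognormally (median, geometric SD); b from a normal
    (mean, sd) truncated to (0, 1].
    """

    k_median: float = 0.06
    k_gsd: float = 2.0
    b_mean: float = 0.8
    b_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.k_median <= 0:
            raise ConfigError("k_median must be > 0")
        if self.k_gsd < 1:
            raise ConfigError("k_gsd must be >= 1")
        if not 0 < self.b_mean <= 1:
            raise ConfigError("b_mean must lie in (0, 1]")
        if self.b_sd < 0:
            raise ConfigError("b_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-sex cohort.

    Defaults emulate a modest sex effect in the direction reported for the
    task (the higher-k sex stays longer, changes patches less, and earns
    water at a lower rate): female median k is 1.5x the male median.
    noise_temp is the logistic choice-noise temperature in µL (0 =
    deterministic threshold rule); latency_mean is the mean of the
    exponential per-response latency in seconds (0 = instantaneous
    responding).
    """

    n_per_sex: int = 100
    male: SexParams = field(default_factory=lambda: SexParams(k_median=0.06))
    female: SexParams = field(default_factory=lambda: SexParams(k_median=0.09))
    noise_temp: float = 5.0
    latency_mean: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_sex < 1:
            raise ConfigError("n_per_sex must be >= 1")
        if self.noise_temp < 0:
            raise ConfigError("noise_temp must be >= 0")
        if self.latency_mean < 0:
            raise ConfigError("latency_mean must be >= 0")

    def sex_params(self, sex: str) -> SexParams:
        if sex == "M":
            return self.male
        if sex == "F":
            return self.female
        raise ConfigError(f"unknown sex label {sex!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs.

    Analysis toggles:

    * ``rate_includes_cod`` — include interior changeover delays in the
      denominator of the water reinforcement rate (overall-intake-rate
      convention) or count in-patch time only.
    * ``auc_normalize_by`` — normalize indifference points by the fresh-patch
      amount ``"A"`` or by the subject's own 0-s point ``"v0"`` when
      computing the normalized AUC.
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    rate_includes_cod: bool = True
    auc_normalize_by: str = "A"
    out_dir: str = "patchforage_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.auc_normalize_by not in ("A", "v0"):
            raise ConfigError("auc_normalize_by must be 'A' or 'v0'")
        if not isinstance(self.rate_includes_cod, bool):
            raise ConfigError("rate_includes_cod must be a boolean")


def _build(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run configuration.

    Top-level keys ``task:``, ``cohort:`` (with optional nested ``male:`` /
    ``female:`` blocks) and ``analysis:`` mirror the dataclass field names;
    ``seed``, ``out_dir`` and ``log_level`` sit at the top level.
    """
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    task = _build(TaskConfig, dict(data.get("task", {})))
    cohort_data = dict(data.get("cohort", {}))
    for sex_key in ("male", "female"):
        if sex_key in cohort_data:
            cohort_data[sex_key] = _build(SexParams, dict(cohort_data[sex_key]))
    cohort = _build(CohortSpec, cohort_data)
    analysis = dict(data.get("analysis", {}))
    extra = {k: data[k] for k in ("out_dir", "seed", "log_level") if k in data}
    return _build(RunConfig, {"task": task, "cohort": cohort, **analysis, **extra})


def config_to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def save_config(config: RunConfig, path: str | Path) -> None:
    d = config_to_dict(config)
    task = d.pop("task")
    cohort = d.pop("cohort")
    analysis = {
        "rate_includes_cod": d.pop("rate_includes_cod"),
        "auc_normalize_by": d.pop("auc_normalize_by"),
    }
    out = {"task": task, "cohort": cohort, "analysis": analysis, **d}
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False), encoding="utf-8")


def config_hash(config: RunConfig) -> str:
    """Stable hash of a run configuration, for run manifests."""
    import hashlib

    blob = json.dumps(config_to_dict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()
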