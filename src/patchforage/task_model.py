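"""The sequential patch depletion environment.

Two water patches; entering a patch delivers an initial reward immediately and
each successive "stay" choice delivers a geometrically smaller reward after a
fixed inter-reward interval. "Leave" switches to the alternative patch after a
changeover delay (COD, the travel cost) and resets the abandoned patch's
schedule. Sessions end at a time cap or a cumulative-volume cap, whichever
comes first.

The simulator runs an arbitrary stay/leave decision policy and emits a
complete, validated :class:`SessionRecord`. Time is tracked internally in
integer milliseconds (the apparatus resolution), so event logs written with
millisecond precision round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .config import TaskConfig

PATCH_IDS = ("A", "B")

#: termination reasons
TIME_CAP = "time_cap"
VOLUME_CAP = "volume_cap"

_REL_TOL = 1e-9


class ProtocolError(RuntimeError):
    """A policy returned something other than 'stay' or 'leave'."""


def scheduled_volume(position: int, config: TaskConfig | None = None) -> float:
    """Volume (µL) scheduled at the given within-patch reward position.

    Position 1 is the entry reward. The schedule is pure geometric decay:
    ``initial_volume * decay_fraction**(position - 1)``, continuous µL with
    no rounding (150, 120, 96, 76.8, ... under the defaults).
    """
    if config is None:
        config = TaskConfig()
    if position < 1:
        raise ValueError(f"reward position must be >= 1, got {position}")
    return config.initial_volume * config.decay_fraction ** (position - 1)


@dataclass
class Decision:
    """Context handed to a policy at each stay/leave decision point."""

    cod_s: float
    next_position: int
    next_volume: float
    elapsed_s: float
    rewards_in_visit: int
    visit_index: int


#: A policy maps a decision context (and an rng, for stochastic rules) to
#: "stay" or "leave".
Policy = Callable[[Decision, object], str]


@dataclass
class PatchVisit:
    """One uninterrupted stay at a patch."""

    patch_id: str
    entry_time: float
    reward_volumes: list[float] = field(default_factory=list)
    reward_times: list[float] = field(default_factory=list)
    exit_time: Optional[float] = None  # None if session ends in-patch
    preceded_by_cod: bool = False

    @property
    def n_rewards(self) -> int:
        return len(self.reward_volumes)

    @property
    def duration(self) -> Optional[float]:
        if self.exit_time is None:
            return None
        return self.exit_time - self.entry_time


@dataclass
class SessionRecord:
    """A complete subject-session: ordered patch visits plus totals."""

    subject_id: str
    sex: str
    session_index: int
    cod_s: float
    visits: list[PatchVisit]
    termination: str
    total_volume: float
    total_time: float


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _REL_TOL * max(1.0, abs(a), abs(b))


def simulate_session(
    policy: Policy,
    config: TaskConfig,
    cod_s: float,
    rng=None,
    *,
    subject_id: str = "S0",
    sex: str = "M",
    session_index: int = 0,
    latency_ms: Callable[[], int] | None = None,
) -> SessionRecord:
    """Run one session of the task under the given decision policy.

    The event loop: the session starts with entry into patch A (no COD before
    the first visit). Each patch entry delivers the entry reward immediately;
    after every reward the policy chooses "stay" (next reward one
    inter-reward interval later, at the next scheduled volume) or "leave"
    (a COD of ``cod_s`` with no reward anywhere, then entry into the
    alternative patch with a reset schedule). The session terminates the
    instant the time cap is reached, or the instant cumulative volume reaches
    the volume cap — the final reward is truncated to exactly fill the cap.

    ``latency_ms`` optionally returns a nonnegative response latency in
    integer milliseconds, drawn before every poke (patch entry, stay, leave);
    omitted, all responses are instantaneous and within-visit rewards are
    spaced exactly one inter-reward interval apart.
    """
    if cod_s < 0:
        raise ValueError("cod_s must be >= 0")
    lat = latency_ms if latency_ms is not None else (lambda: 0)

    iri = round(config.inter_reward_interval * 1000)
    cod = round(cod_s * 1000)
    tmax = round(config.session_max_duration * 1000)
    cap = config.session_volume_cap

    visits: list[PatchVisit] = []
    total = 0.0
    t = 0  # ms
    patch = 0
    preceded = False
    termination: str | None = None

    while termination is None:
        entry_t = t + lat()
        if entry_t >= tmax:
            t = tmax
            termination = TIME_CAP
            break
        t = entry_t
        visit = PatchVisit(
            patch_id=PATCH_IDS[patch],
            entry_time=t / 1000.0,
            preceded_by_cod=preceded,
        )
        visits.append(visit)
        position = 1
        while True:
            volume = scheduled_volume(position, config)
            if total + volume >= cap:
                volume = cap - total
                total = cap
                visit.reward_volumes.append(volume)
                visit.reward_times.append(t / 1000.0)
                termination = VOLUME_CAP
                break
            total += volume
            visit.reward_volumes.append(volume)
            visit.reward_times.append(t / 1000.0)

            decision = policy(
                Decision(
                    cod_s=cod_s,
                    next_position=position + 1,
                    next_volume=scheduled_volume(position + 1, config),
                    elapsed_s=t / 1000.0,
                    rewards_in_visit=position,
                    visit_index=len(visits) - 1,
                ),
                rng,
            )
            if decision == "stay":
                next_t = t + iri + lat()
                if next_t >= tmax:
                    t = tmax
                    termination = TIME_CAP
                    break
                t = next_t
                position += 1
            elif decision == "leave":
                leave_t = t + lat()
                if leave_t >= tmax:
                    t = tmax
                    termination = TIME_CAP
                    break
                visit.exit_time = leave_t / 1000.0
                t = leave_t + cod
                if t >= tmax:
                    t = tmax
                    termination = TIME_CAP  # cap hit during the COD
                    break
                patch = 1 - patch
                preceded = True
                break
            else:
                raise ProtocolError(
                    f"policy returned {decision!r}; expected 'stay' or 'leave'"
                )

    return SessionRecord(
        subject_id=subject_id,
        sex=sex,
        session_index=session_index,
        cod_s=cod_s,
        visits=visits,
        termination=termination,
        total_volume=total,
        total_time=t / 1000.0,
    )


def validate_session(record: SessionRecord, config: TaskConfig) -> list[str]:
    """Check a session record against the task's structural invariants.

    Returns an empty list iff the record is internally consistent; otherwise
    one human-readable description per violation, each naming the field and
    the rule broken. The final reward of a volume-capped session is allowed
    to be truncated below its scheduled volume.
    """
    v: list[str] = []
    if record.termination not in (TIME_CAP, VOLUME_CAP):
        v.append(f"termination: unknown reason {record.termination!r}")
    if not record.visits:
        v.append("visits: session has no visits")
        return v

    cap_truncated = record.termination == VOLUME_CAP
    running = 0.0
    for i, visit in enumerate(record.visits):
        last_of_session = i == len(record.visits) - 1
        if visit.patch_id not in PATCH_IDS:
            v.append(f"visits[{i}].patch_id: unknown patch {visit.patch_id!r}")
        if i > 0 and visit.patch_id == record.visits[i - 1].patch_id:
            v.append(f"visits[{i}].patch_id: consecutive visits must alternate patches")
        if i == 0 and visit.preceded_by_cod:
            v.append("visits[0].preceded_by_cod: first visit cannot follow a changeover")
        if not visit.reward_volumes:
            v.append(f"visits[{i}].reward_volumes: visit delivered no reward")
            continue
        for k, vol in enumerate(visit.reward_volumes):
            expected = scheduled_volume(k + 1, config)
            truncation_slot = cap_truncated and last_of_session and k == visit.n_rewards - 1
            if truncation_slot:
                if vol > expected * (1 + _REL_TOL):
                    v.append(
                        f"visits[{i}].reward_volumes[{k}]: truncated reward {vol} "
                        f"exceeds scheduled {expected}"
                    )
            elif not _close(vol, expected):
                v.append(
                    f"visits[{i}].reward_volumes[{k}]: {vol} breaks the geometric "
                    f"decay rule (expected {expected})"
                )
        if visit.exit_time is not None and visit.exit_time < visit.entry_time:
            v.append(f"visits[{i}].exit_time: exit {visit.exit_time} precedes entry")
        if visit.exit_time is None and not last_of_session:
            v.append(f"visits[{i}].exit_time: missing on a non-final visit")
        if i > 0:
            prev_exit = record.visits[i - 1].exit_time
            if prev_exit is not None:
                gap = visit.entry_time - prev_exit
                if gap < record.cod_s - 1e-9:
                    v.append(
                        f"visits[{i}].entry_time: inter-visit gap {gap:.3f} s shorter "
                        f"than the {record.cod_s} s changeover delay"
                    )
        running += sum(visit.reward_volumes)

    if not _close(running, record.total_volume):
        v.append(
            f"total_volume: recorded {record.total_volume} != summed rewards {running}"
        )
    if record.total_volume > config.session_volume_cap * (1 + _REL_TOL):
        v.append(
            f"total_volume: {record.total_volume} exceeds the "
            f"{config.session_volume_cap} µL session cap"
        )
    if record.total_time > config.session_max_duration + 1e-9:
        v.append(
            f"total_time: {record.total_time} exceeds the "
            f"{config.session_max_duration} s session cap"
        )
    return v


def fixed_n_policy(n: int) -> Policy:
    """Deterministic rule: leave every patch after exactly ``n`` rewards."""
    if n < 1:
        raise ValueError("n must be >= 1")

    def policy(ctx: Decision, rng=None) -> str:
        return "leave" if ctx.rewards_in_visit >= n else "stay"

    return policy


def never_leave_policy() -> Policy:
    """Degenerate rule that exhausts a single patch for the whole session."""

    def policy(ctx: Decision, rng=None) -> str:
        return "stay"

    return policy
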