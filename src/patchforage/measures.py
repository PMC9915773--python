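"""Behavioral dependent measures extracted from session records.

Five primary measures per subject and changeover delay: rate of water
reinforcement (µL/min), number of patch changes, mean time in patch (s),
mean rejection volume (µL; the indifference point — the next scheduled
volume forgone at each leave), and percent deviations from the
rate-maximizing benchmark (volume and time). Exclusion and averaging rules:
the first and final patch visits of every session are dropped, each cycle's
first session is excluded, and per-COD values are averaged over the last two
cycles.

Sign conventions for the deviations: positive percent *volume* deviation
means the subject overharvested (stayed until the forgone volume fell below
the optimum); positive percent *time* deviation means the subject spent
less time in the patch than optimal (underharvested on the time axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import TaskConfig
from .mvt import MVTBenchmark
from .task_model import PatchVisit, SessionRecord, scheduled_volume

#: session-level fields averaged into per-COD measures
MEASURE_FIELDS = (
    "water_rate",
    "n_patch_changes",
    "time_in_patch",
    "rejection_volume",
    "pct_time_deviation",
    "pct_volume_deviation",
)


def included_visits(session: SessionRecord) -> list[PatchVisit]:
    """Visits retained for analysis: all but the first and final patch.

    The first patch is dropped because the subject has not yet paid a
    changeover delay; the final patch is dropped because session termination,
    not choice, ends it. Sessions with two or fewer visits therefore
    contribute nothing.
    """
    if len(session.visits) <= 2:
        return []
    return session.visits[1:-1]


def pct_volume_deviation(observed: float, optimal: float) -> float:
    """Percent deviation from the optimal rejection volume.

    (optimal - observed) / optimal x 100; positive = overharvesting (the
    subject stayed past the rate-maximizing leaving point), negative =
    underharvesting.
    """
    if optimal <= 0:
        raise ValueError("optimal rejection volume must be > 0")
    return (optimal - observed) / optimal * 100.0


def pct_time_deviation(observed: float, optimal: float) -> float:
    """Percent deviation from the optimal time in patch.

    Same form as the volume deviation but with the opposite behavioral
    reading: negative values mean the observed stay was *longer* than
    optimal. An optimal time of zero (COD 0, where the optimal policy leaves
    after the instantaneous entry reward) makes the measure undefined and
    returns NaN rather than raising.
    """
    if optimal <= 0:
        return math.nan
    return (optimal - observed) / optimal * 100.0


def session_measures(
    session: SessionRecord,
    benchmark: MVTBenchmark,
    config: TaskConfig,
    rate_includes_cod: bool = True,
) -> dict:
    """All dependent measures for one session.

    Over the included visits: the reinforcement rate divides total volume by
    the span from the first included entry to the last included exit
    (interior changeover delays included, matching the overall-intake-rate
    framing; set ``rate_includes_cod=False`` to count in-patch time only);
    the rejection volume of a visit with n rewards is the scheduled volume
    at position n + 1. Deviations are scored against the benchmark's
    observed-convention optimum. An empty included set yields NaN measures.
    """
    if benchmark.cod_s != session.cod_s:
        raise ValueError(
            f"benchmark COD {benchmark.cod_s} does not match session COD {session.cod_s}"
        )
    visits = included_visits(session)
    out = {
        "subject_id": session.subject_id,
        "sex": session.sex,
        "session_index": session.session_index,
        "cod_s": session.cod_s,
    }
    if not visits:
        out.update({f: math.nan for f in MEASURE_FIELDS})
        return out

    total_volume = sum(sum(v.reward_volumes) for v in visits)
    if rate_includes_cod:
        span = visits[-1].exit_time - visits[0].entry_time
    else:
        span = sum(v.exit_time - v.entry_time for v in visits)
    water_rate = total_volume / span * 60.0 if span > 0 else math.nan

    time_in_patch = float(np.mean([v.exit_time - v.entry_time for v in visits]))
    rejection = float(
        np.mean([scheduled_volume(v.n_rewards + 1, config) for v in visits])
    )
    out.update(
        water_rate=water_rate,
        n_patch_changes=float(len(visits)),
        time_in_patch=time_in_patch,
        rejection_volume=rejection,
        pct_time_deviation=pct_time_deviation(
            time_in_patch, benchmark.optimal_time_in_patch
        ),
        pct_volume_deviation=pct_volume_deviation(
            rejection, benchmark.optimal_observed_rejection
        ),
    )
    return out


def _analysis_sessions(config: TaskConfig) -> set[int]:
    """Session indices entering the per-COD averages (last two cycles,
    cycle-initial sessions excluded)."""
    cycle_len = len(config.cod_cycle)
    first_cycle = max(0, config.n_cycles - 2)
    keep = set()
    for idx in range(config.n_sessions):
        cycle, pos = divmod(idx, cycle_len)
        if cycle < first_cycle:
            continue
        if config.exclude_first_session_of_cycle and pos == 0:
            continue
        keep.add(idx)
    return keep


def subject_delay_measures(
    records: Sequence[SessionRecord],
    benchmarks: Mapping[float, MVTBenchmark],
    config: TaskConfig,
    rate_includes_cod: bool = True,
) -> pd.DataFrame:
    """Per-COD dependent measures for one subject.

    Averages session-level measures over the analysis sessions of each COD
    (two sessions per COD under the default 4-cycle schedule). Missing
    session-level values propagate: nothing is imputed, the average is NaN.
    Raises if the records do not cover the full schedule.
    """
    if not records:
        raise ValueError("no session records supplied")
    subject_ids = {r.subject_id for r in records}
    if len(subject_ids) != 1:
        raise ValueError(f"records span multiple subjects: {sorted(subject_ids)}")
    indices = {r.session_index for r in records}
    expected = set(range(config.n_sessions))
    if not expected <= indices:
        raise ValueError(
            f"records do not cover the full schedule; missing sessions "
            f"{sorted(expected - indices)}"
        )

    keep = _analysis_sessions(config)
    rows = [
        session_measures(r, benchmarks[r.cod_s], config, rate_includes_cod)
        for r in records
        if r.session_index in keep
    ]
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby("cod_s", sort=True)[list(MEASURE_FIELDS)]
        .mean()  # NaN propagates: skipna would silently impute
        .reset_index()
    )
    grouped.insert(0, "subject_id", records[0].subject_id)
    grouped.insert(1, "sex", records[0].sex)
    return grouped


def cohort_delay_measures(
    records: Sequence[SessionRecord],
    benchmarks: Mapping[float, MVTBenchmark],
    config: TaskConfig,
    rate_includes_cod: bool = True,
) -> pd.DataFrame:
    """Per-subject x COD measures table for a whole cohort."""
    by_subject: dict[str, list[SessionRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    tables = [
        subject_delay_measures(recs, benchmarks, config, rate_includes_cod)
        for recs in by_subject.values()
    ]
    return pd.concat(tables, ignore_index=True)


def harvest_class(pct_vol_dev: float, tol: float = 1e-9) -> str:
    """Classify a volume deviation: 'over', 'optimal' (exactly zero), 'under'."""
    if math.isnan(pct_vol_dev):
        return "missing"
    if pct_vol_dev > tol:
        return "over"
    if pct_vol_dev < -tol:
        return "under"
    return "optimal"


def harvest_distribution(measures: pd.DataFrame) -> pd.DataFrame:
    """Percent of subjects over-/optimally-/under-harvesting at each COD.

    Subjects with missing volume deviation at a COD are excluded from that
    COD's denominator; the three percentages sum to 100 wherever any subject
    is classifiable.
    """
    rows = []
    for cod, grp in measures.groupby("cod_s", sort=True):
        classes = grp["pct_volume_deviation"].map(harvest_class)
        classified = classes[classes != "missing"]
        n = len(classified)
        row = {"cod_s": cod, "n": n}
        for label in ("over", "optimal", "under"):
            row[f"pct_{label}"] = (
                (classified == label).sum() / n * 100.0 if n else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
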