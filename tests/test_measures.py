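"""Dependent measures: exclusions, averaging, deviations, harvest classes."""

import math

import numpy as np
import pandas as pd
import pytest

from patchforage import CohortSpec, TaskConfig
from patchforage.cohort import (
    SubjectParams,
    generate_cohort,
    mvt_policy,
    simulate_subject_sessions,
    subject_seed_sequence,
    threshold_policy,
)
from patchforage.measures import (
    cohort_delay_measures,
    harvest_class,
    harvest_distribution,
    included_visits,
    pct_time_deviation,
    pct_volume_deviation,
    session_measures,
    subject_delay_measures,
)
from patchforage.task_model import fixed_n_policy, simulate_session


def test_included_visits_drops_first_and_last(config):
    rec = simulate_session(mvt_policy(config, 6.0), config, 6.0)
    assert len(rec.visits) == 19
    inner = included_visits(rec)
    assert len(inner) == 17
    assert all(v.n_rewards == 2 for v in inner)
    assert inner[0] is rec.visits[1] and inner[-1] is rec.visits[-2]


def test_included_visits_boundary(config):
    rec = simulate_session(fixed_n_policy(2), config, 6.0)
    rec.visits = rec.visits[:2]
    assert included_visits(rec) == []


@pytest.mark.parametrize(
    "observed,optimal,expected",
    [(120.0, 120.0, 0.0), (96.0, 120.0, 20.0), (144.0, 120.0, -20.0)],
)
def test_pct_volume_deviation_sign_convention(observed, optimal, expected):
    assert pct_volume_deviation(observed, optimal) == pytest.approx(expected)


def test_pct_volume_deviation_requires_positive_optimum():
    with pytest.raises(ValueError):
        pct_volume_deviation(96.0, 0.0)


@pytest.mark.parametrize(
    "observed,optimal,expected", [(4.0, 4.0, 0.0), (8.0, 4.0, -100.0), (2.0, 4.0, 50.0)]
)
def test_pct_time_deviation_sign_convention(observed, optimal, expected):
    assert pct_time_deviation(observed, optimal) == pytest.approx(expected)


def test_pct_time_deviation_undefined_at_zero_optimum():
    assert math.isnan(pct_time_deviation(4.0, 0.0))


def test_session_measures_of_mvt_agent(config, benchmarks):
    """A two-reward visit forgoes the 96-µL third reward; the optimal agent's
    time in patch is one inter-reward interval."""
    rec = simulate_session(mvt_policy(config, 6.0), config, 6.0)
    m = session_measures(rec, benchmarks[6.0], config)
    assert m["rejection_volume"] == pytest.approx(96.0)
    assert m["time_in_patch"] == pytest.approx(4.0)
    assert m["pct_volume_deviation"] == pytest.approx(0.0)
    assert m["pct_time_deviation"] == pytest.approx(0.0)
    assert m["n_patch_changes"] == 17
    # rate over the included span: 17 visits of 270 µL over 164 s
    assert m["water_rate"] == pytest.approx(17 * 270 / 164.0 * 60)


def test_session_measures_rate_toggle(config, benchmarks):
    rec = simulate_session(mvt_policy(config, 6.0), config, 6.0)
    m = session_measures(rec, benchmarks[6.0], config, rate_includes_cod=False)
    # in-patch time only: 17 visits x 4 s
    assert m["water_rate"] == pytest.approx(17 * 270 / 68.0 * 60)


def test_session_measures_benchmark_mismatch(config, benchmarks):
    rec = simulate_session(mvt_policy(config, 6.0), config, 6.0)
    with pytest.raises(ValueError):
        session_measures(rec, benchmarks[12.0], config)


def test_short_session_yields_missing_measures(config, benchmarks):
    rec = simulate_session(fixed_n_policy(2), config, 6.0)
    rec.visits = rec.visits[:2]
    m = session_measures(rec, benchmarks[6.0], config)
    assert math.isnan(m["water_rate"]) and math.isnan(m["rejection_volume"])


def test_subject_measures_average_last_two_cycles(config, benchmarks):
    """Noiseless agents repeat themselves exactly, so the per-COD average
    equals any single analysis session; COD 0 keeps only the cycle's second
    session, and the worked threshold example lands on the 8th grid volume."""
    sub = SubjectParams("t", "M", 0.1, 0.8, 0.0, 0.0)
    recs = simulate_subject_sessions(sub, config, subject_seed_sequence(0, "t"))
    dm = subject_delay_measures(recs, benchmarks, config).set_index("cod_s")
    assert dm.loc[24.0, "rejection_volume"] == pytest.approx(31.45728)
    assert dm.loc[0.0, "rejection_volume"] == pytest.approx(120.0)
    single = session_measures(
        next(r for r in recs if r.session_index == 21), benchmarks[12.0], config
    )
    assert dm.loc[12.0, "rejection_volume"] == pytest.approx(single["rejection_volume"])


def test_subject_measures_require_full_schedule(config, benchmarks):
    sub = SubjectParams("t", "M", 0.1, 0.8, 0.0, 0.0)
    recs = simulate_subject_sessions(sub, config, subject_seed_sequence(0, "t"))
    with pytest.raises(ValueError, match="missing sessions"):
        subject_delay_measures(recs[:-1], benchmarks, config)


def test_harvest_class_boundaries():
    assert harvest_class(5.0) == "over"
    assert harvest_class(-5.0) == "under"
    assert harvest_class(0.0) == "optimal"
    assert harvest_class(math.nan) == "missing"


def test_harvest_distribution_sums_to_100(config, benchmarks):
    spec = CohortSpec(n_per_sex=5, seed=2)
    records, _ = generate_cohort(spec, config)
    measures = cohort_delay_measures(records, benchmarks, config)
    dist = harvest_distribution(measures)
    totals = dist[["pct_over", "pct_optimal", "pct_under"]].sum(axis=1)
    assert np.allclose(totals, 100.0)


def test_all_optimal_cohort_classified_optimal(config, benchmarks):
    subs = [SubjectParams(f"S{i}", "M", 0.0, 1.0, 0.0, 0.0) for i in range(3)]
    records, _ = generate_cohort(
        CohortSpec(n_per_sex=3, seed=0),
        config,
        policy_factory=lambda s, cod: mvt_policy(config, cod),
        subjects=subs,
    )
    measures = cohort_delay_measures(records, benchmarks, config)
    dist = harvest_distribution(measures).set_index("cod_s")
    for cod in (6.0, 12.0, 18.0, 24.0):
        assert dist.loc[cod, "pct_optimal"] == pytest.approx(100.0)


def test_overharvest_fraction_shrinks_with_delay(config, benchmarks):
    """Low-k noiseless agents overharvest at short delays (their threshold
    sits below the optimal leaving volume) but approach the optimum as travel
    costs depress it; the overharvesting fraction cannot rise with delay."""
    ks = np.geomspace(0.005, 0.05, 12)
    subs = [SubjectParams(f"S{i}", "M", float(k), 0.8, 0.0, 0.0) for i, k in enumerate(ks)]
    records, _ = generate_cohort(
        CohortSpec(n_per_sex=1, seed=0), config, subjects=subs
    )
    measures = cohort_delay_measures(records, benchmarks, config)
    dist = harvest_distribution(measures).sort_values("cod_s")
    over = dist[dist.cod_s > 0].pct_over.to_numpy()
    assert all(b <= a + 1e-9 for a, b in zip(over, over[1:]))


def test_threshold_measures_track_delay_direction(config, benchmarks):
    """Noiseless threshold forager: fewer patch changes, longer stays, and
    lower rejection volumes as the travel cost grows."""
    sub = SubjectParams("t", "M", 0.08, 0.8, 0.0, 0.0)
    recs = simulate_subject_sessions(sub, config, subject_seed_sequence(0, "t"))
    dm = subject_delay_measures(recs, benchmarks, config).sort_values("cod_s")
    pc = dm.n_patch_changes.to_numpy()
    tip = dm.time_in_patch.to_numpy()
    rej = dm.rejection_volume.to_numpy()
    assert all(b <= a + 1e-9 for a, b in zip(pc, pc[1:]))
    assert all(b >= a - 1e-9 for a, b in zip(tip, tip[1:]))
    assert all(b <= a + 1e-9 for a, b in zip(rej, rej[1:]))
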