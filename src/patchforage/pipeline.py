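"""End-to-end pipeline: simulate or ingest, validate, measure, fit, correlate.

Outputs (all CSV plus a JSON manifest) land in the configured directory:

* ``events.csv``, ``visits.csv``, ``roster.csv`` — simulated raw data
* ``benchmarks.csv`` — MVT optimality benchmarks per tested delay
* ``measures.csv`` — per subject x COD dependent measures
* ``fits.csv`` — per-subject hyperbolic fits and normalized AUC
* ``composites.csv`` — delay-summed composite scores
* ``correlations_<sex>.csv`` / ``correlation_p_<sex>.csv`` — Pearson matrices
* ``comparisons.csv`` — dependent-correlation z-tests
* ``harvest.csv`` — over/optimal/under harvesting percentages per COD
* ``manifest.json`` — seed, config hash, package and library versions

A run is deterministic given its config (the cohort seed drives every random
draw), so re-running with the same config reproduces every output file
byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash, config_to_dict
from .cohort import generate_cohort, mvt_policy
from .corrstats import comparison_table, composite_scores, pearson_matrix
from .discounting import FitError, fit_profile
from .io import visit_table, write_csv, write_event_log
from .measures import cohort_delay_measures, harvest_distribution
from .mvt import benchmark_table, mvt_benchmark
from .task_model import SessionRecord, validate_session

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def fit_cohort(
    measures: pd.DataFrame, A: float, auc_normalize_by: str = "A"
) -> pd.DataFrame:
    """Hyperbolic fit + AUC per subject from the measures table.

    A subject's indifference points are the per-COD rejection volumes;
    subjects whose profile cannot be fit (a missing delay, an out-of-range
    point) are reported with NaN fit fields rather than silently dropped.
    """
    rows = []
    for sid, grp in measures.groupby("subject_id"):
        grp = grp.sort_values("cod_s")
        delays = grp["cod_s"].to_numpy(dtype=float)
        points = grp["rejection_volume"].to_numpy(dtype=float)
        row = {"subject_id": sid, "sex": grp["sex"].iloc[0]}
        try:
            if np.any(~np.isfinite(points)):
                raise FitError("missing rejection volume at one or more delays")
            fit = fit_profile(
                points, delays, A, subject_id=sid, auc_normalize_by=auc_normalize_by
            )
            row.update(
                b=fit.b, k=fit.k, auc=fit.auc, sse=fit.sse, converged=fit.converged
            )
        except FitError as e:
            logger.warning("discounting fit failed for %s: %s", sid, e)
            row.update(b=np.nan, k=np.nan, auc=np.nan, sse=np.nan, converged=False)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_records(
    records: Sequence[SessionRecord], config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Run the analysis stages on session records; returns all result tables."""
    task = config.task
    delays = sorted({r.cod_s for r in records})
    benchmarks = {d: mvt_benchmark(d, task) for d in delays}

    measures = cohort_delay_measures(
        records, benchmarks, task, rate_includes_cod=config.rate_includes_cod
    )
    fits = fit_cohort(measures, task.initial_volume, config.auc_normalize_by)
    composites = composite_scores(measures, fits.dropna(subset=["k", "auc"]))
    out: dict[str, pd.DataFrame] = {
        "benchmarks": benchmark_table(delays, task),
        "measures": measures,
        "fits": fits,
        "composites": composites,
        "harvest": harvest_distribution(measures),
    }
    sexes = composites["sex"].value_counts()
    if len(sexes) >= 1 and (sexes >= 4).all():
        matrices = pearson_matrix(composites, by_sex=True)
        for sex, (r, p) in matrices.items():
            out[f"correlations_{sex}"] = r.rename_axis("variable").reset_index()
            out[f"correlation_p_{sex}"] = p.rename_axis("variable").reset_index()
        out["comparisons"] = comparison_table(composites)
    else:
        logger.warning("too few subjects per sex for correlation tables; skipped")
    return out


def run_pipeline(
    config: RunConfig,
    records: Sequence[SessionRecord] | None = None,
    policy: str = "threshold",
) -> dict[str, pd.DataFrame]:
    """Simulate (or ingest) a cohort and write the full report bundle.

    ``policy`` selects the generative agent when simulating: ``"threshold"``
    (the hyperbolic indifference-threshold forager) or ``"mvt"`` (the
    rate-maximizing reference, noiseless and instantaneous — the pipeline's
    null configuration). Any stage failure removes files written by this run
    and raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out_dir / f"{name}.csv"
        write_csv(df, p)
        written.append(p)

    stage = "simulate"
    try:
        if records is None:
            if policy == "threshold":
                records, roster = generate_cohort(config.cohort, config.task)
            elif policy == "mvt":
                subjects = _mvt_subjects(config)
                records, roster = generate_cohort(
                    config.cohort,
                    config.task,
                    policy_factory=lambda s, cod: mvt_policy(config.task, cod),
                    subjects=subjects,
                )
            else:
                raise PipelineError(f"unknown policy {policy!r}")
            write_event_log(records, out_dir / "events.csv")
            written.append(out_dir / "events.csv")
            emit("roster", roster)
            emit("visits", visit_table(records, config.task))

        stage = "validate"
        for rec in records:
            violations = validate_session(rec, config.task)
            if violations:
                raise PipelineError(
                    f"session {rec.subject_id}/{rec.session_index} invalid: "
                    + "; ".join(violations)
                )

        stage = "analyze"
        tables = analyze_records(records, config)
        for name, df in tables.items():
            emit(name, df)

        stage = "manifest"
        manifest = {
            "seed": config.cohort.seed,
            "config_sha256": config_hash(config),
            "config": config_to_dict(config),
            "policy": policy,
            "versions": {
                "patchforage": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, default=list) + "\n", encoding="utf-8"
        )
        written.append(manifest_path)
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    return tables


def _mvt_subjects(config: RunConfig):
    """Idealized noiseless, zero-latency subjects for the MVT null cohort."""
    from .cohort import SubjectParams

    subjects = []
    for sex in ("M", "F"):
        for i in range(config.cohort.n_per_sex):
            subjects.append(
                SubjectParams(
                    subject_id=f"{sex}{i + 1:03d}",
                    sex=sex,
                    k_true=0.0,
                    b_true=1.0,
                    noise_temp=0.0,
                    latency_mean=0.0,
                )
            )
    return subjects
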