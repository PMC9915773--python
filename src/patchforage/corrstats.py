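"""Composite scores, correlation matrices, and dependent-correlation z-tests.

Each subject's delay-varying measures are summed across the tested delays
into composite scores; Pearson correlation matrices over the seven composite
variables (k, AUC, volume deviation, time deviation, time in patch, patch
changes, water rate) are computed per sex; and the relative strength of
overlapping correlations sharing a common variable is compared with the
Meng–Rosenthal–Rubin z-test on Fisher-transformed coefficients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: composite-table column -> short label used in the correlation outputs
VARIABLES = {
    "k": "k",
    "auc": "AUC",
    "volume_deviation": "VD",
    "time_deviation": "TD",
    "time_in_patch": "TIP",
    "n_patch_changes": "PC",
    "water_rate": "WR",
}

#: delay-varying measures summed into composites
_SUMMED = {
    "volume_deviation": "pct_volume_deviation",
    "time_deviation": "pct_time_deviation",
    "time_in_patch": "time_in_patch",
    "n_patch_changes": "n_patch_changes",
    "water_rate": "water_rate",
}

DD_VARIABLES = ("k", "AUC")
RM_VARIABLES = ("VD", "TD")
PATCH_VARIABLES = ("TIP", "PC", "WR")


@dataclass(frozen=True)
class CorrelationComparison:
    """One dependent-correlation contrast: corr(common, var1) vs corr(common, var2)."""

    sex: str
    common_variable: str
    variable_1: str
    variable_2: str
    r_common_1: float
    r_common_2: float
    r_12: float
    N: int
    z: float
    p: float


def composite_scores(measures: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Per-subject composite table: delay-summed measures plus b/k/AUC.

    Summing requires a value at every tested delay; the one structural
    exception is the time deviation, undefined at COD 0 (optimal time in
    patch is zero there), which is summed over the positive delays only.
    Subjects with any other missing value are dropped with a log line.
    """
    delays = sorted(measures["cod_s"].unique())
    pos_delays = [d for d in delays if d > 0]
    rows = []
    fits_idx = fits.set_index("subject_id")
    for sid, grp in measures.groupby("subject_id"):
        grp = grp.set_index("cod_s")
        if sid not in fits_idx.index:
            logger.warning("composite_scores: no discounting fit for %s; dropped", sid)
            continue
        row = {"subject_id": sid, "sex": grp["sex"].iloc[0]}
        ok = True
        for comp, col in _SUMMED.items():
            wanted = pos_delays if comp == "time_deviation" else delays
            vals = grp[col].reindex(wanted)
            if vals.isna().any():
                logger.warning(
                    "composite_scores: %s missing %s at COD(s) %s; subject dropped",
                    sid,
                    col,
                    list(vals.index[vals.isna()]),
                )
                ok = False
                break
            row[comp] = float(vals.sum())
        if not ok:
            continue
        frow = fits_idx.loc[sid]
        row["b"] = float(frow["b"])
        row["k"] = float(frow["k"])
        row["auc"] = float(frow["auc"])
        rows.append(row)
    cols = ["subject_id", "sex", "b", "k", "auc", *(_SUMMED)]
    return pd.DataFrame(rows, columns=cols)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_matrix(
    table: pd.DataFrame, by_sex: bool = True
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Pearson r and two-tailed p matrices over the seven composite variables.

    Returned as ``{group: (r, p)}`` with groups per sex (or a single "all"
    group). Zero-variance columns give NaN entries. Requires at least four
    subjects per group.
    """
    groups = table.groupby("sex") if by_sex else [("all", table)]
    out = {}
    labels = list(VARIABLES.values())
    for name, grp in groups:
        if len(grp) < 4:
            raise ValueError(f"group {name!r} has fewer than 4 subjects")
        r = pd.DataFrame(index=labels, columns=labels, dtype=float)
        p = pd.DataFrame(index=labels, columns=labels, dtype=float)
        cols = {lab: grp[col].to_numpy(dtype=float) for col, lab in VARIABLES.items()}
        for i, li in enumerate(labels):
            for lj in labels[i:]:
                if li == lj:
                    r.loc[li, lj], p.loc[li, lj] = 1.0, 0.0
                    continue
                rij, pij = _pearson_with_p(cols[li], cols[lj])
                r.loc[li, lj] = r.loc[lj, li] = rij
                p.loc[li, lj] = p.loc[lj, li] = pij
        out[str(name)] = (r, p)
    return out


def fisher_z(r: float) -> float:
    """Fisher r-to-z transform, arctanh(r); odd and strictly increasing."""
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def meng_z_test(r_y1: float, r_y2: float, r_12: float, N: int) -> tuple[float, float]:
    """Meng–Rosenthal–Rubin z-test for two overlapping dependent correlations.

    Compares corr(y, x1) = ``r_y1`` against corr(y, x2) = ``r_y2`` given the
    correlation ``r_12`` between x1 and x2, all estimated on the same N
    subjects:

        rbar2 = (r_y1^2 + r_y2^2) / 2
        f     = min(1, (1 - r_12) / (2 (1 - rbar2)))      (capped at 1)
        h     = (1 - f rbar2) / (1 - rbar2)
        z     = (z(r_y1) - z(r_y2)) sqrt((N - 3) / (2 (1 - r_12) h))

    with a two-tailed normal p. Positive z means the first correlation is
    the stronger (in the signed, Fisher-transformed sense).
    """
    if N <= 3:
        raise ValueError("N must exceed 3")
    for r in (r_y1, r_y2, r_12):
        if abs(r) >= 1:
            raise ValueError(f"correlations must satisfy |r| < 1, got {r}")
    if 1 - r_12 <= 0:
        raise ValueError("r_12 = 1 makes the comparison degenerate")
    rbar2 = (r_y1**2 + r_y2**2) / 2.0
    f = min(1.0, (1.0 - r_12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (fisher_z(r_y1) - fisher_z(r_y2)) * math.sqrt(
        (N - 3) / (2.0 * (1.0 - r_12) * h)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def comparison_table(table: pd.DataFrame) -> pd.DataFrame:
    """All dependent-correlation contrasts of discounting vs reward maximization.

    For each sex and each patch-utilization variable (TIP, PC, WR) as the
    common variable, the correlation with each discounting index (k, AUC) is
    tested against the correlation with each deviation measure (VD, TD):
    2 x 2 x 3 = 12 contrasts per sex. Positive z means the discounting
    correlation is the (signed-)stronger one.
    """
    label_to_col = {lab: col for col, lab in VARIABLES.items()}
    rows = []
    for sex, grp in table.groupby("sex"):
        n = len(grp)
        get = lambda lab: grp[label_to_col[lab]].to_numpy(dtype=float)
        for common in PATCH_VARIABLES:
            for dd in DD_VARIABLES:
                for rm in RM_VARIABLES:
                    r1, _ = _pearson_with_p(get(common), get(dd))
                    r2, _ = _pearson_with_p(get(common), get(rm))
                    r12, _ = _pearson_with_p(get(dd), get(rm))
                    z, p = meng_z_test(r1, r2, r12, n)
                    rows.append(
                        CorrelationComparison(
                            sex=str(sex),
                            common_variable=common,
                            variable_1=dd,
                            variable_2=rm,
                            r_common_1=r1,
                            r_common_2=r2,
                            r_12=r12,
                            N=n,
                            z=z,
                            p=p,
                        )
                    )
    return pd.DataFrame([vars(c) for c in rows])
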