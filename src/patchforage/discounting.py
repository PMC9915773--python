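"""Hyperbolic delay discounting fits and normalized AUC.

The subjective value of the fresh-patch amount A delayed by D is modeled as
V = bA / (1 + kD) (Mazur's hyperbola with a zero-delay bias b). Per subject,
b is fixed from the 0-s indifference point (b = v0 / A) and the discount
rate k is estimated by bounded least squares on the remaining delays. The
normalized area under the indifference-point curve (delays scaled by the
longest delay, volumes by A or by v0) gives the model-free companion index;
smaller AUC means steeper discounting / more overharvesting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar


class FitError(ValueError):
    """Raised when indifference-point data cannot support a fit."""


@dataclass(frozen=True)
class DiscountFit:
    subject_id: str
    b: float
    k: float  # 1/s
    auc: float
    sse: float  # µL^2
    converged: bool


def bias_parameter(v0: float, A: float) -> float:
    """Zero-delay bias b such that bA equals the 0-s indifference point."""
    if A <= 0:
        raise ValueError("A must be > 0")
    if not 0 < v0 <= A:
        raise ValueError(f"0-s indifference point must lie in (0, A], got {v0}")
    return v0 / A


def hyperbolic_value(D: float, b: float, k: float, A: float):
    """V = bA / (1 + kD), the discounted value of amount A at delay D."""
    return b * A / (1.0 + k * np.asarray(D, dtype=float))


def _validate_profile(points, delays):
    points = np.asarray(points, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if points.shape != delays.shape or points.ndim != 1:
        raise FitError("points and delays must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(points)) and np.all(np.isfinite(delays))):
        raise FitError("non-finite indifference points or delays")
    if np.any(np.diff(delays) <= 0):
        raise FitError("delays must be sorted strictly ascending")
    return points, delays


K_BOUNDS = (0.0, 100.0)


def fit_k(
    indifference_points: Sequence[float],
    delays: Sequence[float],
    A: float,
    subject_id: str = "",
) -> DiscountFit:
    """Fit the hyperbola to one subject's indifference points.

    Requires at least three delays including 0; the 0-s point pins b and the
    rest are fit by least squares over k in [0, 100] s^-1 (log-spaced coarse
    grid followed by bounded scalar refinement to 1e-10, robust to the flat
    objectives short profiles can produce). Exactly flat profiles return
    k = 0. The AUC field is NaN here; use :func:`fit_profile` for the
    combined fit-plus-AUC record.
    """
    points, dels = _validate_profile(indifference_points, delays)
    if len(dels) < 3:
        raise FitError("need at least 3 delays to fit")
    zero = np.flatnonzero(dels == 0)
    if len(zero) != 1:
        raise FitError("profile must contain exactly one 0-s delay")
    v0 = points[zero[0]]
    if np.any(points <= 0) or np.any(points > A * (1 + 1e-12)):
        raise FitError("indifference points must lie in (0, A]")
    b = bias_parameter(v0, A)

    mask = dels > 0
    d_pos, p_pos = dels[mask], points[mask]

    def sse(k: float) -> float:
        resid = p_pos - hyperbolic_value(d_pos, b, k, A)
        return float(resid @ resid)

    grid = np.concatenate([[0.0], np.geomspace(1e-4, K_BOUNDS[1], 80)])
    k0 = grid[int(np.argmin([sse(k) for k in grid]))]
    lo = max(K_BOUNDS[0], k0 / 10 if k0 > 0 else 0.0)
    hi = min(K_BOUNDS[1], max(k0 * 10, 1e-3))
    res = minimize_scalar(
        sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    k_hat, converged = float(res.x), bool(res.success)
    if sse(0.0) <= sse(k_hat):
        k_hat = 0.0
    return DiscountFit(
        subject_id=subject_id,
        b=b,
        k=k_hat,
        auc=math.nan,
        sse=sse(k_hat),
        converged=converged,
    )


def auc_normalized(
    indifference_points: Sequence[float],
    delays: Sequence[float],
    A: float,
    normalize_by: str = "A",
) -> float:
    """Normalized trapezoidal area under the indifference-point curve.

    Delays are scaled by the maximum delay and volumes by A (default) or by
    the subject's own 0-s point (``normalize_by='v0'``); a profile constant
    at the normalizer integrates to exactly 1.
    """
    points, dels = _validate_profile(indifference_points, delays)
    if dels[-1] <= 0:
        raise FitError("maximum delay must be > 0")
    if normalize_by == "A":
        norm = A
    elif normalize_by == "v0":
        zero = np.flatnonzero(dels == 0)
        if len(zero) != 1:
            raise FitError("normalize_by='v0' requires a 0-s delay point")
        norm = points[zero[0]]
    else:
        raise ValueError("normalize_by must be 'A' or 'v0'")
    if norm <= 0:
        raise FitError("AUC normalizer must be > 0")
    return float(np.trapezoid(points / norm, dels / dels[-1]))


def fit_profile(
    indifference_points: Sequence[float],
    delays: Sequence[float],
    A: float,
    subject_id: str = "",
    auc_normalize_by: str = "A",
) -> DiscountFit:
    """Hyperbolic fit plus normalized AUC for one subject's profile."""
    fit = fit_k(indifference_points, delays, A, subject_id=subject_id)
    auc = auc_normalized(indifference_points, delays, A, auc_normalize_by)
    return DiscountFit(
        subject_id=fit.subject_id,
        b=fit.b,
        k=fit.k,
        auc=auc,
        sse=fit.sse,
        converged=fit.converged,
    )
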