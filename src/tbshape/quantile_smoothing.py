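"""Penalized additive quantile-regression smoothing over time.

Fits a τ-quantile curve f(t) in a cubic B-spline space by minimizing

    Σ_i ρ_τ(tb_i − f(t_i)) + λ · Σ_j |Δ² c_j|

where ρ_τ is the pinball (check) loss and Δ²c are second differences of
the basis coefficients (P-spline flavor, L1 roughness). Both terms are
linear-programmable, so the fit is solved as an exact LP (HiGHS); no
iteratively-reweighted approximation is involved.

Knots are deliberately sparse: the default interior-knot spacing of 72 h
(floor 48 h = twice the circadian period) guarantees the smooth tracks
slow drift in the level of the temperature cycle and cannot absorb the
daily cycle itself. Splitting readings at the fitted 45th/55th quantile
band is only meaningful under that constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import linprog

from tbshape.errors import EvaluationRangeError, FitError, ValidationError
from tbshape.trace_io import TbTrace

#: Interior knots may never be closer than twice the circadian period.
DEFAULT_MIN_KNOT_SPACING_H = 48.0
DEFAULT_KNOT_SPACING_H = 72.0
DEFAULT_LAMBDA = 1.0
DEFAULT_MIN_FIT_DURATION_H = 72.0


def pinball_loss(residual, tau: float):
    """Check loss ρ_τ(u) = u·(τ − 1{u<0}); nonnegative, zero iff u = 0."""
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    u = np.asarray(residual, dtype=float)
    out = u * (tau - (u < 0))
    return float(out) if np.isscalar(residual) else out


@dataclass(frozen=True)
class QuantileCurve:
    """A fitted penalized τ-quantile spline over one trace segment."""

    tau: float
    knots_h: np.ndarray  # interior knot positions, hours
    degree: int
    coefficients: np.ndarray  # basis weights, °C
    lam: float
    objective: float  # achieved penalized pinball objective, °C units
    span_h: tuple[float, float]  # fitted time span

    @property
    def full_knots(self) -> np.ndarray:
        t0, t1 = self.span_h
        k = self.degree
        return np.r_[[t0] * (k + 1), self.knots_h, [t1] * (k + 1)]

    def __call__(self, times) -> np.ndarray:
        return evaluate_curve(self, times)


def _full_knots(t0: float, t1: float, interior: np.ndarray, degree: int) -> np.ndarray:
    return np.r_[[t0] * (degree + 1), interior, [t1] * (degree + 1)]


def _design_matrix(times: np.ndarray, knots: np.ndarray, degree: int):
    return BSpline.design_matrix(times, knots, degree, extrapolate=False)


def _second_difference(p: int) -> sparse.csr_matrix:
    """(p-2) x p second-difference operator; empty for p < 3."""
    if p < 3:
        return sparse.csr_matrix((0, p))
    data = np.tile([1.0, -2.0, 1.0], (p - 2, 1))
    offsets = np.arange(p - 2)
    rows = np.repeat(offsets, 3)
    cols = (offsets[:, None] + np.array([0, 1, 2])).ravel()
    return sparse.csr_matrix((data.ravel(), (rows, cols)), shape=(p - 2, p))


def penalized_objective(
    times: np.ndarray,
    values: np.ndarray,
    curve: QuantileCurve,
) -> float:
    """Recompute Σρ_τ(residual) + λ·Σ|Δ²c| for a fitted curve (oracle check)."""
    fitted = evaluate_curve(curve, times)
    loss = float(np.sum(pinball_loss(values - fitted, curve.tau)))
    rough = float(np.abs(_second_difference(curve.coefficients.size) @ curve.coefficients).sum())
    return loss + curve.lam * rough


def fit_quantile_spline(
    times: np.ndarray,
    values: np.ndarray,
    tau: float,
    interior_knots,
    degree: int = 3,
    lam: float = DEFAULT_LAMBDA,
    span: tuple[float, float] | None = None,
) -> QuantileCurve:
    """Exact LP fit of a penalized quantile spline (low-level; no duration guards).

    Variables are (coefficients c, positive/negative residual parts u/v,
    roughness slacks w >= |Δ²c|); the LP minimizes
    τ·Σu + (1−τ)·Σv + λ·Σw subject to Bc + u − v = y.
    """
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = times.size
    t0, t1 = span if span is not None else (float(times[0]), float(times[-1]))
    interior = np.asarray(interior_knots, dtype=float)
    knots = _full_knots(t0, t1, interior, degree)
    p = knots.size - degree - 1
    if n < p:
        raise FitError(f"degenerate design: {n} points for {p} coefficients")
    B = _design_matrix(times, knots, degree)
    D = _second_difference(p)
    m = D.shape[0]

    # column order: c (p) | u (n) | v (n) | w (m)
    c_cost = np.concatenate(
        [np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau), np.full(m, lam)]
    )
    I_n = sparse.eye(n, format="csr")
    A_eq = sparse.hstack([B, I_n, -I_n, sparse.csr_matrix((n, m))], format="csr")
    b_eq = values
    if m:
        Z = sparse.csr_matrix((m, 2 * n))
        I_m = sparse.eye(m, format="csr")
        A_ub = sparse.vstack(
            [sparse.hstack([D, Z, -I_m]), sparse.hstack([-D, Z, -I_m])], format="csr"
        )
        b_ub = np.zeros(2 * m)
    else:
        A_ub, b_ub = None, None
    bounds = [(None, None)] * p + [(0, None)] * (2 * n + m)
    res = linprog(
        c_cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise FitError(f"LP solver failed (status {res.status}): {res.message}")
    coef = res.x[:p]
    curve = QuantileCurve(
        tau=tau,
        knots_h=interior,
        degree=degree,
        coefficients=coef,
        lam=lam,
        objective=0.0,
        span_h=(t0, t1),
    )
    achieved = penalized_objective(times, values, curve)
    if abs(achieved - res.fun) > 1e-6 * max(1.0, abs(res.fun)):
        raise FitError(
            f"LP objective {res.fun:.8g} disagrees with recomputed objective "
            f"{achieved:.8g}"
        )
    object.__setattr__(curve, "objective", achieved)
    return curve


def _interior_knots(t0: float, t1: float, spacing_h: float) -> np.ndarray:
    k = np.arange(t0 + spacing_h, t1, spacing_h)
    # avoid an interior knot indistinguishable from the right boundary
    return k[k < t1 - 1e-9 * max(1.0, abs(t1))]


def fit_quantile_curve(
    trace: TbTrace,
    tau: float,
    knot_spacing_h: float = DEFAULT_KNOT_SPACING_H,
    lam: float = DEFAULT_LAMBDA,
    degree: int = 3,
    min_fit_duration_h: float = DEFAULT_MIN_FIT_DURATION_H,
    min_knot_spacing_h: float = DEFAULT_MIN_KNOT_SPACING_H,
) -> QuantileCurve:
    """Fit the τ-quantile smooth to one trace segment.

    ``knot_spacing_h`` must stay at or above ``min_knot_spacing_h``
    (default 48 h, twice the circadian period) so the smooth cannot track
    the daily cycle; segments shorter than ``min_fit_duration_h`` are
    refused.
    """
    if knot_spacing_h < min_knot_spacing_h:
        raise ValidationError(
            f"knot_spacing_h={knot_spacing_h:g} h below the floor of "
            f"{min_knot_spacing_h:g} h; the smooth would absorb the daily cycle"
        )
    if trace.duration_h < min_fit_duration_h:
        raise FitError(
            f"segment of {trace.duration_h:.1f} h shorter than the minimum "
            f"fit duration {min_fit_duration_h:g} h"
        )
    t0, t1 = float(trace.time_h[0]), float(trace.time_h[-1])
    interior = _interior_knots(t0, t1, knot_spacing_h)
    # The pinball term is a sum over readings (°C·readings) while the
    # roughness term is °C, so the raw LP weight must scale with sampling
    # density: lam is per reading-per-knot-interval, making the default
    # invariant to the logger's sampling rate.
    dt_h = float(np.median(np.diff(trace.time_h)))
    lam_eff = lam * knot_spacing_h / dt_h
    return fit_quantile_spline(
        trace.time_h, trace.tb_c, tau, interior, degree=degree, lam=lam_eff,
        span=(t0, t1),
    )


def evaluate_curve(curve: QuantileCurve, times) -> np.ndarray:
    """Evaluate a fitted curve; extrapolation outside the fitted span is refused."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    t0, t1 = curve.span_h
    tol = 1e-9 * max(1.0, abs(t0), abs(t1))
    if np.any(times < t0 - tol) or np.any(times > t1 + tol):
        bad = times[(times < t0 - tol) | (times > t1 + tol)][0]
        raise EvaluationRangeError(
            f"time {bad:g} h outside fitted span [{t0:g}, {t1:g}] h"
        )
    times = np.clip(times, t0, t1)
    spl = BSpline(curve.full_knots, curve.coefficients, curve.degree,
                  extrapolate=False)
    out = spl(times)
    # right-closed span: BSpline treats t1 as outside the last interval
    if np.any(np.isnan(out)):
        out = np.where(np.isnan(out), spl(np.nextafter(times, t0)), out)
    return out


def rearrange_noncrossing(
    lower: QuantileCurve, upper: QuantileCurve, times
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (min, max) of two evaluated quantile curves.

    Restores lower <= upper wherever the independently fitted curves
    cross; returns the inputs unchanged elsewhere.
    """
    if not lower.tau < upper.tau:
        raise ValidationError(
            f"lower.tau ({lower.tau}) must be < upper.tau ({upper.tau})"
        )
    if not np.allclose(lower.span_h, upper.span_h):
        raise ValidationError(
            f"curves fitted on different spans {lower.span_h} vs {upper.span_h}"
        )
    lo = evaluate_curve(lower, times)
    hi = evaluate_curve(upper, times)
    return np.minimum(lo, hi), np.maximum(lo, hi)


def select_lambda(
    trace: TbTrace,
    tau: float,
    lambdas=(0.01, 0.1, 1.0, 10.0, 100.0),
    knot_spacing_h: float = DEFAULT_KNOT_SPACING_H,
    degree: int = 3,
    n_folds: int = 5,
) -> float:
    """Pick λ by blocked (contiguous-in-time) cross-validation.

    Folds are contiguous blocks because readings are autocorrelated;
    random folds would leak the circadian cycle across the split. The λ
    minimizing mean held-out pinball loss wins; ties go to the larger
    (smoother) λ.
    """
    n = len(trace)
    t0, t1 = float(trace.time_h[0]), float(trace.time_h[-1])
    interior = _interior_knots(t0, t1, knot_spacing_h)
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    best_lam, best_score = None, np.inf
    for lam in sorted(lambdas, reverse=True):
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            keep = np.ones(n, dtype=bool)
            keep[a:b] = False
            curve = fit_quantile_spline(
                trace.time_h[keep], trace.tb_c[keep], tau, interior,
                degree=degree, lam=lam, span=(t0, t1),
            )
            pred = evaluate_curve(curve, trace.time_h[a:b])
            total += float(np.sum(pinball_loss(trace.tb_c[a:b] - pred, tau)))
        if total < best_score:
            best_lam, best_score = lam, total
    return float(best_lam)
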