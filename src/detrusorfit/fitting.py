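"""Nonlinear least-squares estimation of the frequency-response models.

Each fit is a bounded least-squares problem solved from multiple
deterministic, data-driven starting points with a trust-region reflective
solver (the bounded analogue of Levenberg-Marquardt damping); the best
solution by sum of squared residuals wins.  The two-component search is
additionally seeded at the one-component optimum with a zero
high-frequency amplitude, which guarantees the nested-model SSE ordering
sse(two-component) <= sse(one-component) on any data set.

Model selection between the nested one- and two-component fits uses the
extra-sum-of-squares F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from .errors import (
    IncompatibleFitsError,
    InsufficientDataError,
    InvalidInputError,
)
from .models import (
    OneComponentParams,
    ReductionParams,
    TwoComponentParams,
    eval_one_component,
    eval_reduction_curve,
    eval_two_component,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "ModelComparison",
    "fit_one_component",
    "fit_two_component",
    "fit_two_component_paired",
    "fit_reduction_curve",
    "compare_models",
]

_M_GRID = (0.5, 1.0, 2.0, 4.0)  # exponent starting values


def _f_half_upper(f: np.ndarray, options: "FitOptions") -> float:
    """Effective upper bound for half-frequencies: the highest stimulated
    frequency (or the absolute cap if lower).  The stimulation protocol is
    designed to reach the response plateau, so a component whose own
    half-maximum lies beyond the tested range is pure extrapolation and
    makes the derived T_max and f_1/2 uncontrolled."""
    return float(min(options.f_half_bounds[1], np.max(f)))


@dataclass(frozen=True)
class FitOptions:
    """Tunable knobs of the multi-start bounded least-squares search.

    ``n_starts`` caps the number of starting points (a deterministic
    heuristic grid, padded with seeded random draws if the grid is
    smaller).  Amplitude bounds are [0, amplitude_factor * max(|value|)];
    half-frequencies are confined to ``f_half_bounds`` Hz (further capped
    at the highest stimulated frequency, beyond which the asymptote is
    pure extrapolation) and the steepness exponent to ``m_bounds``.

    ``component_split_hz`` separates the two components of the
    two-component fit: the low-frequency (purinergic) half-frequency must
    lie below it and the high-frequency (cholinergic) one above it.  The
    4 Hz default is the frequency divide between ATP-dominated and
    ACh-dominated responses; without the split the two components are
    free to merge under measurement noise, which makes the derived
    overall f_1/2 unstable.
    """

    n_starts: int = 20
    amplitude_factor: float = 10.0
    f_half_bounds: tuple[float, float] = (0.05, 400.0)
    m_bounds: tuple[float, float] = (0.2, 10.0)
    component_split_hz: float = 4.0
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-14
    max_nfev: int = 10_000
    seed: int = 0


ParamsT = Union[TwoComponentParams, OneComponentParams, ReductionParams]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit.

    ``at_bounds`` marks a solution pinned at a half-frequency or exponent
    bound; derived quantities (T_max, overall f_1/2) from such a fit are
    extrapolations and should be treated as unreliable.
    """

    params: ParamsT
    sse: float
    n_points: int
    n_params: int
    converged: bool
    residuals: np.ndarray = field(repr=False)
    n_starts_used: int
    degenerate: bool = False
    at_bounds: bool = False


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares F-test between nested one-/two-component fits."""

    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    preferred: Literal["one_component", "two_component"]


def _validate_xy(freqs, values, min_distinct: int, n_params: int):
    f = np.asarray(freqs, dtype=float)
    v = np.asarray(values, dtype=float)
    if f.shape != v.shape or f.ndim != 1:
        raise InvalidInputError("freqs and values must be 1-D sequences of equal length")
    if not np.all(np.isfinite(f)) or not np.all(np.isfinite(v)):
        raise InvalidInputError("freqs and values must be finite (no NaN/inf)")
    if np.any(f <= 0):
        raise InvalidInputError("fit frequencies must be strictly positive")
    if len(np.unique(f)) < min_distinct or len(f) <= n_params:
        raise InsufficientDataError(
            f"need >= {min_distinct} distinct frequencies and more points than "
            f"parameters ({n_params}) to fit; got {len(np.unique(f))} distinct"
        )
    return f, v


def _run_starts(residual, starts, lower, upper, options: FitOptions):
    """Solve from each start, return (best_x, best_sse, converged, n_used)."""
    best_x, best_sse, best_conv = None, np.inf, False
    n_used = 0
    for x0 in starts[: options.n_starts]:
        x0 = np.clip(x0, lower, upper)
        n_used += 1
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(lower, upper),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                gtol=options.gtol,
                max_nfev=options.max_nfev,
            )
        except Exception:  # singular Jacobian from a pathological start
            continue
        sse = float(2.0 * sol.cost)
        if sse < best_sse:  # strict: ties keep the earlier (deterministic) start
            best_x, best_sse, best_conv = sol.x, sse, bool(sol.success)
    return best_x, best_sse, best_conv, n_used


def _pad_random_starts(starts, n_wanted, lower, upper, seed):
    """Top up a heuristic start grid with seeded draws inside the bounds."""
    if len(starts) >= n_wanted:
        return starts
    rng = np.random.default_rng(seed)
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    hi = np.where(np.isfinite(hi), hi, np.abs(lo) + 100.0)
    lo = np.where(np.isfinite(lo), lo, -hi)
    extra = [lo + rng.random(len(lo)) * (hi - lo) for _ in range(n_wanted - len(starts))]
    return list(starts) + extra


def _freq_percentiles(f: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.percentile(np.unique(f), q)) for q in (25, 50, 75))


def _pinned(x, lower, upper, checks) -> bool:
    """True when a shape parameter sits at a bound that invalidates the
    derived curve summaries: a low-frequency half-frequency at the
    component split (components merged), a high-frequency one at the
    extrapolation cap (asymptote unresolved), or the exponent at either
    end.  ``checks`` is a sequence of (index, side) with side in
    {"lower", "upper", "both"}."""
    x = np.asarray(x, dtype=float)
    tol = 1e-3
    for i, side in checks:
        span = upper[i] - lower[i]
        lo_hit = x[i] <= lower[i] + tol * span
        hi_hit = x[i] >= upper[i] - tol * span
        if (side in ("lower", "both") and lo_hit) or (side in ("upper", "both") and hi_hit):
            return True
    return False


def fit_one_component(
    freqs: Sequence[float], values: Sequence[float], options: FitOptions | None = None
) -> FitResult:
    """Fit the single Hill component (y_max, f_half, m) to release data."""
    options = options or FitOptions()
    f, v = _validate_xy(freqs, values, min_distinct=4, n_params=3)
    if np.all(v == 0):
        params = OneComponentParams(0.0, float(np.median(f)), 1.0)
        return FitResult(params, 0.0, len(f), 3, True, np.zeros_like(v), 0, degenerate=True)

    vmax = float(np.max(np.abs(v)))
    f_hi = _f_half_upper(f, options)
    lower = np.array([0.0, options.f_half_bounds[0], options.m_bounds[0]])
    upper = np.array([options.amplitude_factor * vmax, f_hi, options.m_bounds[1]])
    p25, p50, p75 = _freq_percentiles(f)
    starts = [np.array([max(vmax, 1e-12), fh, m]) for fh in (p25, p50, p75) for m in _M_GRID]
    starts = _pad_random_starts(starts, options.n_starts, lower, upper, options.seed)

    def residual(x):
        return x[0] * _hill_vec(f, x[1], x[2]) - v

    x, sse, conv, n_used = _run_starts(residual, starts, lower, upper, options)
    params = OneComponentParams(float(x[0]), float(x[1]), float(x[2]))
    res = eval_one_component(params, f) - v
    return FitResult(params, sse, len(f), 3, conv, res, n_used)


def fit_two_component(
    freqs: Sequence[float], values: Sequence[float], options: FitOptions | None = None
) -> FitResult:
    """Fit the two-component curve (y_lf_max, f_star_lf, y_hf_max, f_star_hf, m).

    Components are relabelled after the fit so that f_star_lf <= f_star_hf.
    """
    options = options or FitOptions()
    f, v = _validate_xy(freqs, values, min_distinct=6, n_params=5)
    if np.all(v == 0):
        fh = float(np.median(f))
        params = TwoComponentParams(0.0, fh, 0.0, 2.0 * fh, 1.0)
        return FitResult(params, 0.0, len(f), 5, True, np.zeros_like(v), 0, degenerate=True)

    vmax = float(np.max(np.abs(v)))
    fb, mb = options.f_half_bounds, options.m_bounds
    f_hi = _f_half_upper(f, options)
    split = float(np.clip(options.component_split_hz, fb[0], f_hi))
    lower = np.array([0.0, fb[0], 0.0, split, mb[0]])
    upper = np.array([options.amplitude_factor * vmax, split,
                      options.amplitude_factor * vmax, f_hi, mb[1]])

    one = fit_one_component(f, v, options)
    op = one.params
    # nested start: the one-component optimum with zero hf amplitude has
    # exactly the one-component SSE, so the final SSE can only be lower.
    # Whichever side of the split its half-frequency falls on, the other
    # component starts at zero amplitude, preserving that SSE.
    if op.f_half <= split:
        nested = np.array([op.y_max, op.f_half, 0.0, min(4.0 * op.f_half, f_hi), op.m])
    else:
        nested = np.array([0.0, 0.5 * split, op.y_max, op.f_half, op.m])
    p25, _, p75 = _freq_percentiles(f)
    starts = [nested]
    for m in _M_GRID:
        starts.append(np.array([0.7 * vmax, 0.5 * split, 0.7 * vmax, max(p75, split), m]))
        starts.append(np.array([0.5 * vmax, 0.25 * split, 0.5 * vmax, min(2 * p75, f_hi), m]))
    starts = _pad_random_starts(starts, options.n_starts, lower, upper, options.seed)

    def residual(x):
        return x[0] * _hill_vec(f, x[1], x[4]) + x[2] * _hill_vec(f, x[3], x[4]) - v

    x, sse, conv, n_used = _run_starts(residual, starts, lower, upper, options)
    params = TwoComponentParams(
        float(x[0]), float(x[1]), float(x[2]), float(x[3]), float(x[4])
    ).sorted_by_half_frequency()
    res = eval_two_component(params, f) - v
    pinned = _pinned(x, lower, upper, [(1, "upper"), (3, "upper"), (4, "both")])
    return FitResult(params, sse, len(f), 5, conv, res, n_used, at_bounds=pinned)


def fit_two_component_paired(
    freqs: Sequence[float],
    values_ref: Sequence[float],
    values_test: Sequence[float],
    options: FitOptions | None = None,
) -> tuple[FitResult, FitResult]:
    """Jointly fit two paired conditions with shared curve shape.

    In a paired design the half-frequencies and steepness are properties
    of the preparation's innervation and muscle, while interventions act
    on the component amplitudes.  Both curves are therefore fitted
    together with common (f_star_lf, f_star_hf, m) and per-condition
    amplitudes — the shared-parameter "global fit" of pharmacological
    curve analysis — which determines the paired change of the derived
    T_max and f_1/2 far more precisely than two independent fits.

    Returns one ``FitResult`` per condition (reference first).  Both
    carry the shared shape; ``sse``/``residuals`` are per condition.
    """
    options = options or FitOptions()
    f, va = _validate_xy(freqs, values_ref, min_distinct=6, n_params=5)
    f2, vb = _validate_xy(freqs, values_test, min_distinct=6, n_params=5)
    if np.all(va == 0) and np.all(vb == 0):
        fh = float(np.median(f))
        params = TwoComponentParams(0.0, fh, 0.0, 2.0 * fh, 1.0)
        zero = FitResult(params, 0.0, len(f), 5, True, np.zeros_like(va), 0, degenerate=True)
        return zero, zero

    vmax = float(max(np.max(np.abs(va)), np.max(np.abs(vb))))
    fb, mb = options.f_half_bounds, options.m_bounds
    f_hi = _f_half_upper(f, options)
    split = float(np.clip(options.component_split_hz, fb[0], f_hi))
    amp_hi = options.amplitude_factor * vmax
    # x = (f_star_lf, f_star_hf, m, ylf_ref, yhf_ref, ylf_test, yhf_test)
    lower = np.array([fb[0], split, mb[0], 0.0, 0.0, 0.0, 0.0])
    upper = np.array([split, f_hi, mb[1], amp_hi, amp_hi, amp_hi, amp_hi])

    one = fit_one_component(f, 0.5 * (va + vb), options)
    op = one.params
    _, _, p75 = _freq_percentiles(f)
    if op.f_half <= split:
        shape0 = [op.f_half, max(p75, split), op.m]
    else:
        shape0 = [0.5 * split, min(op.f_half, f_hi), op.m]
    starts = [np.array(shape0 + [0.5 * vmax] * 4)]
    for m in _M_GRID:
        starts.append(np.array([0.5 * split, max(p75, split), m] + [0.5 * vmax] * 4))
        starts.append(np.array([0.25 * split, min(2 * p75, f_hi), m] + [0.4 * vmax] * 4))
    starts = _pad_random_starts(starts, options.n_starts, lower, upper, options.seed)

    def residual(x):
        hl = _hill_vec(f, x[0], x[2])
        hh = _hill_vec(f, x[1], x[2])
        return np.concatenate([x[3] * hl + x[4] * hh - va, x[5] * hl + x[6] * hh - vb])

    x, _, conv, n_used = _run_starts(residual, starts, lower, upper, options)
    pinned = _pinned(x, lower, upper, [(0, "upper"), (1, "upper"), (2, "both")])
    out = []
    for ylf, yhf, v in ((x[3], x[4], va), (x[5], x[6], vb)):
        params = TwoComponentParams(float(ylf), float(x[0]), float(yhf), float(x[1]), float(x[2]))
        res = eval_two_component(params, f) - v
        out.append(FitResult(params, float(np.sum(res**2)), len(f), 5, conv, res,
                             n_used, at_bounds=pinned))
    return out[0], out[1]


def fit_reduction_curve(
    freqs: Sequence[float], reductions: Sequence[float], options: FitOptions | None = None
) -> FitResult:
    """Fit the percent-reduction curve (t_lf, t_hf, k, m).

    Plateaus are unconstrained in sign (negative reduction = enhancement);
    k and m stay inside the usual frequency/exponent bounds.
    """
    options = options or FitOptions()
    f, v = _validate_xy(freqs, reductions, min_distinct=5, n_params=4)

    span = float(np.max(np.abs(v))) + 1.0
    fb, mb = options.f_half_bounds, options.m_bounds
    f_hi = _f_half_upper(f, options)
    lower = np.array([-10.0 * span, -10.0 * span, fb[0], mb[0]])
    upper = np.array([10.0 * span, 10.0 * span, f_hi, mb[1]])
    order = np.argsort(f)
    lo_val = float(np.mean(v[order[:2]]))
    hi_val = float(np.mean(v[order[-2:]]))
    p25, p50, p75 = _freq_percentiles(f)
    starts = [np.array([lo_val, hi_val, k, m]) for k in (p25, p50, p75) for m in _M_GRID]
    starts = _pad_random_starts(starts, options.n_starts, lower, upper, options.seed)

    def residual(x):
        return x[0] - (x[0] - x[1]) * _hill_vec(f, x[2], x[3]) - v

    x, sse, conv, n_used = _run_starts(residual, starts, lower, upper, options)
    params = ReductionParams(float(x[0]), float(x[1]), float(x[2]), float(x[3]))
    res = eval_reduction_curve(params, f) - v
    return FitResult(params, sse, len(f), 4, conv, res, n_used)


def compare_models(
    one_fit: FitResult, two_fit: FitResult, alpha: float = 0.05
) -> ModelComparison:
    """Extra-sum-of-squares F-test of the two- vs the nested one-component fit.

    F = ((sse1 - sse2)/(p2 - p1)) / (sse2/(n - p2)); the two-component
    model is preferred when p < alpha.
    """
    if one_fit.n_points != two_fit.n_points:
        raise IncompatibleFitsError("fits use different numbers of data points")
    if two_fit.n_params <= one_fit.n_params:
        raise IncompatibleFitsError("two-component fit must have more parameters")
    n = one_fit.n_points
    df_num = two_fit.n_params - one_fit.n_params
    df_den = n - two_fit.n_params
    if df_den <= 0:
        raise IncompatibleFitsError("no residual degrees of freedom for comparison")
    extra = max(one_fit.sse - two_fit.sse, 0.0)  # clip tiny numerical inversions
    if two_fit.sse <= 0.0:
        f_stat = np.inf if extra > 0 else 0.0
    else:
        f_stat = (extra / df_num) / (two_fit.sse / df_den)
    p = float(sps.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
    preferred = "two_component" if p < alpha else "one_component"
    return ModelComparison(float(f_stat), df_num, df_den, p, preferred)


def _hill_vec(f: np.ndarray, f_half: float, m: float) -> np.ndarray:
    # local copy of the Hill ratio kept inline for residual speed
    r = (f_half / f) ** m
    return 1.0 / (1.0 + r)
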