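"""Frequency-response curve models for nerve-mediated detrusor responses.

Nerve-mediated contraction of detrusor smooth muscle is driven by two
cotransmitters released from parasympathetic terminals: ATP (purinergic,
dominant at low stimulation frequencies) and acetylcholine (cholinergic,
dominant at high frequencies).  Tension- and ATP-release-versus-frequency
data are described by the sum of two saturating Hill-type components; ACh
release by a single component; and the percentage reduction of tension by
an intervention by a sigmoid interpolating between a low- and a
high-frequency plateau.

All evaluation functions accept scalar or array frequencies (in Hz) and
are pure: no fitting, no I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, UndefinedResultError

__all__ = [
    "TwoComponentParams",
    "OneComponentParams",
    "ReductionParams",
    "DerivedSummary",
    "eval_two_component",
    "eval_one_component",
    "eval_reduction_curve",
    "derive_t_max",
    "solve_f_half",
    "component_fraction_lf",
]

#: Bracket used when inverting the two-component curve for its overall
#: half-maximal frequency.  Monotonicity guarantees a unique root inside.
_F_HALF_BRACKET = (1e-3, 1e4)


def _hill(f: np.ndarray, f_half: float, m: float) -> np.ndarray:
    """Saturating Hill term f^m / (f_half^m + f^m); equals 0 at f=0, 1/2 at f_half."""
    f = np.asarray(f, dtype=float)
    out = np.zeros_like(f)
    pos = f > 0
    # ratio form avoids overflow of f^m; an overflowing ratio itself
    # (f << f_half with large m) correctly saturates to 0
    with np.errstate(over="ignore"):
        r = (f_half / f[pos]) ** m
        out[pos] = 1.0 / (1.0 + r)
    return out


def _check_freq(f) -> np.ndarray:
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise DomainError("stimulation frequency must be finite and >= 0 Hz")
    return arr


@dataclass(frozen=True)
class TwoComponentParams:
    """Parameters of the two-component (purinergic + cholinergic) curve.

    ``y_lf_max`` and ``y_hf_max`` are the maximal amplitudes of the low-
    and high-frequency components (mN·mg⁻¹ for tension, fmol·µL⁻¹·mg⁻¹
    for ATP release); ``f_star_lf`` / ``f_star_hf`` are the frequencies at
    which each component reaches half its own maximum; ``m`` is a shared
    dimensionless steepness exponent.  By convention ``f_star_lf <=
    f_star_hf`` after fitting.
    """

    y_lf_max: float
    f_star_lf: float
    y_hf_max: float
    f_star_hf: float
    m: float

    def __post_init__(self):
        if self.y_lf_max < 0 or self.y_hf_max < 0:
            raise DomainError("component amplitudes must be >= 0")
        if self.f_star_lf <= 0 or self.f_star_hf <= 0:
            raise DomainError("component half-frequencies must be > 0 Hz")
        if self.m <= 0:
            raise DomainError("exponent m must be > 0")

    def sorted_by_half_frequency(self) -> "TwoComponentParams":
        """Return an equivalent parameter set with f_star_lf <= f_star_hf."""
        if self.f_star_lf <= self.f_star_hf:
            return self
        return TwoComponentParams(
            y_lf_max=self.y_hf_max,
            f_star_lf=self.f_star_hf,
            y_hf_max=self.y_lf_max,
            f_star_hf=self.f_star_lf,
            m=self.m,
        )


@dataclass(frozen=True)
class OneComponentParams:
    """Single Hill-component curve used for ACh release-frequency data."""

    y_max: float
    f_half: float
    m: float

    def __post_init__(self):
        if self.y_max < 0:
            raise DomainError("y_max must be >= 0")
        if self.f_half <= 0:
            raise DomainError("f_half must be > 0 Hz")
        if self.m <= 0:
            raise DomainError("exponent m must be > 0")


@dataclass(frozen=True)
class ReductionParams:
    """Percentage-reduction-versus-frequency curve for an intervention.

    ``t_lf`` and ``t_hf`` are the reduction plateaus (percent, sign free —
    negative values encode enhancement) at low and high frequency; ``k``
    is the frequency of half-transition between them and ``m`` the
    steepness.  The curve interpolates t_lf → t_hf and passes through
    their midpoint exactly at f = k for any m.
    """

    t_lf: float
    t_hf: float
    k: float
    m: float

    def __post_init__(self):
        if self.k <= 0:
            raise DomainError("half-transition frequency k must be > 0 Hz")
        if self.m <= 0:
            raise DomainError("exponent m must be > 0")


@dataclass(frozen=True)
class DerivedSummary:
    """Composite parameters of a two-component fit: T_max and overall f_1/2."""

    t_max: float
    f_half_overall: float


def eval_two_component(params: TwoComponentParams, f):
    """Evaluate the two-component curve at frequency ``f`` (Hz, scalar or array).

    Y(f) = y_lf_max·f^m/(f_star_lf^m + f^m) + y_hf_max·f^m/(f_star_hf^m + f^m)
    """
    arr = _check_freq(f)
    y = params.y_lf_max * _hill(arr, params.f_star_lf, params.m) + (
        params.y_hf_max * _hill(arr, params.f_star_hf, params.m)
    )
    return y if arr.ndim else float(y)


def eval_one_component(params: OneComponentParams, f):
    """Evaluate the one-component curve: y_max·f^m/(f_half^m + f^m)."""
    arr = _check_freq(f)
    y = params.y_max * _hill(arr, params.f_half, params.m)
    return y if arr.ndim else float(y)


def eval_reduction_curve(params: ReductionParams, f):
    """Evaluate the percent-reduction curve.

    T(f) = t_lf − (t_lf − t_hf)·f^m/(k^m + f^m)

    equals t_lf at f=0 and tends to t_hf as f→∞.
    """
    arr = _check_freq(f)
    y = params.t_lf - (params.t_lf - params.t_hf) * _hill(arr, params.k, params.m)
    return y if arr.ndim else float(y)


def derive_t_max(params: TwoComponentParams) -> float:
    """Maximal response T_max: the sum of the two component amplitudes."""
    return params.y_lf_max + params.y_hf_max


def solve_f_half(params: TwoComponentParams, tolerance: float = 1e-6) -> float:
    """Frequency f_1/2 at which the two-component curve reaches T_max/2.

    The curve is strictly increasing in f, so the root is unique; it is
    bracketed on [1e-3, 1e4] Hz and solved to relative tolerance
    ``tolerance`` (default 1e-6).
    """
    total = derive_t_max(params)
    if total <= 0:
        raise UndefinedResultError("f_1/2 undefined for zero total amplitude")
    target = total / 2.0

    def g(f):
        return eval_two_component(params, f) - target

    lo, hi = _F_HALF_BRACKET
    if g(lo) > 0 or g(hi) < 0:  # pragma: no cover - bracket spans all valid params
        raise UndefinedResultError("f_1/2 not bracketed in [1e-3, 1e4] Hz")
    return float(brentq(g, lo, hi, rtol=tolerance))


def component_fraction_lf(params: TwoComponentParams, f) -> float:
    """Share of the total response carried by the low-frequency component at f."""
    total = eval_two_component(params, f)
    if np.any(np.asarray(total) <= 0):
        raise UndefinedResultError("component fraction undefined at zero total response")
    lf = params.y_lf_max * _hill(np.asarray(f, dtype=float), params.f_star_lf, params.m)
    out = lf / total
    return out if np.asarray(f).ndim else float(out)
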