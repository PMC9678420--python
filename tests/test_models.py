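"""Unit and property tests for the frequency-response curve models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detrusorfit import (
    OneComponentParams,
    ReductionParams,
    TwoComponentParams,
    component_fraction_lf,
    derive_t_max,
    eval_one_component,
    eval_reduction_curve,
    eval_two_component,
    solve_f_half,
)
from detrusorfit.errors import DomainError, UndefinedResultError

amplitudes = st.floats(0.01, 50.0)
half_freqs = st.floats(0.1, 50.0)
exponents = st.floats(0.3, 5.0)


def two_component_strategy():
    return st.builds(TwoComponentParams, amplitudes, half_freqs, amplitudes, half_freqs, exponents)


@pytest.mark.parametrize(
    "params, f, expected",
    [
        # half-maximum of a lone component falls exactly at its own f*
        (TwoComponentParams(1, 0.7, 0, 10, 1), 0.7, 0.5),
        (TwoComponentParams(1.5, 2, 0.7, 15, 2), 0.0, 0.0),
        # hand arithmetic: 4/6 + 4/12
        (TwoComponentParams(1, 2, 1, 8, 1), 4.0, 1.0),
    ],
)
def test_two_component_values(params, f, expected):
    assert eval_two_component(params, f) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "params, f, expected",
    [
        (OneComponentParams(140, 8, 2), 8.0, 70.0),  # half-maximum at f_half
        (OneComponentParams(140, 8, 2), 0.0, 0.0),
        (OneComponentParams(1, 4, 1), 12.0, 0.75),  # 12/16
    ],
)
def test_one_component_values(params, f, expected):
    assert eval_one_component(params, f) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "params, f, expected",
    [
        (ReductionParams(31.8, 0, 6.7, 2), 0.0, 31.8),  # low-frequency plateau
        (ReductionParams(31.8, 0, 6.7, 2), 6.7, 15.9),  # midpoint at f = k
        (ReductionParams(12.5, 12.5, 3.0, 1.7), 17.0, 12.5),  # flat curve
    ],
)
def test_reduction_curve_values(params, f, expected):
    assert eval_reduction_curve(params, f) == pytest.approx(expected, abs=1e-12)


def test_negative_frequency_rejected():
    p2 = TwoComponentParams(1, 1, 1, 5, 1)
    with pytest.raises(DomainError):
        eval_two_component(p2, -1.0)
    with pytest.raises(DomainError):
        eval_one_component(OneComponentParams(1, 1, 1), -0.5)
    with pytest.raises(DomainError):
        eval_reduction_curve(ReductionParams(10, 0, 1, 1), -2.0)


def test_invalid_parameters_rejected():
    with pytest.raises(DomainError):
        TwoComponentParams(-1, 1, 1, 5, 1)
    with pytest.raises(DomainError):
        OneComponentParams(1, 0, 1)
    with pytest.raises(DomainError):
        ReductionParams(10, 0, 1, -1)


@pytest.mark.parametrize(
    "params, expected",
    [
        (TwoComponentParams(1.5, 2, 0.7, 15, 2), 2.2),
        (TwoComponentParams(0, 3, 0, 3, 1), 0.0),
    ],
)
def test_t_max_is_sum_of_amplitudes(params, expected):
    assert derive_t_max(params) == pytest.approx(expected)


@settings(max_examples=60, deadline=None)
@given(st.builds(TwoComponentParams, amplitudes, half_freqs, amplitudes, half_freqs,
                 st.floats(0.6, 5.0)))
def test_t_max_equals_high_frequency_limit(params):
    # convergence to the asymptote goes as (f*/f)^m, so the 0.1% band at
    # f = 1e6 * max(f*) applies to exponents above ~0.5
    limit_f = 1e6 * max(params.f_star_lf, params.f_star_hf)
    limit = eval_two_component(params, limit_f)
    assert limit == pytest.approx(derive_t_max(params), rel=1e-3)


@settings(max_examples=60, deadline=None)
@given(two_component_strategy(), st.floats(0.0, 100.0), st.floats(0.0, 100.0))
def test_two_component_monotone_nondecreasing(params, f1, f2):
    lo, hi = sorted((f1, f2))
    assert eval_two_component(params, lo) <= eval_two_component(params, hi) + 1e-12


@settings(max_examples=60, deadline=None)
@given(st.builds(OneComponentParams, amplitudes, half_freqs, exponents), st.floats(0.1, 200.0))
def test_two_component_collapses_to_one_component(one, f):
    """With zero high-frequency amplitude the two-component curve is the
    one-component curve of its low-frequency limb."""
    two = TwoComponentParams(one.y_max, one.f_half, 0.0, 2 * one.f_half, one.m)
    assert eval_two_component(two, f) == pytest.approx(eval_one_component(one, f), rel=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.floats(-50, 80), st.floats(-50, 80), half_freqs, exponents)
def test_reduction_midpoint_identity(t_lf, t_hf, k, m):
    """The reduction curve passes through (t_lf + t_hf)/2 at f = k for any m."""
    params = ReductionParams(t_lf, t_hf, k, m)
    assert eval_reduction_curve(params, k) == pytest.approx((t_lf + t_hf) / 2, abs=1e-9)


class TestSolveFHalf:
    def test_equal_half_frequencies_collapse(self):
        for m in (0.5, 1.0, 2.0, 4.0):
            assert solve_f_half(TwoComponentParams(1, 3, 1, 3, m)) == pytest.approx(3.0, rel=1e-6)

    def test_closed_form_equal_amplitudes_m1(self):
        # for equal maxima and m=1 the root satisfies f^2 = f*_lf * f*_hf
        assert solve_f_half(TwoComponentParams(1, 2, 1, 8, 1)) == pytest.approx(4.0, rel=1e-6)

    def test_single_component(self):
        assert solve_f_half(TwoComponentParams(1, 0.7, 0, 10, 1)) == pytest.approx(0.7, rel=1e-6)

    def test_zero_amplitude_undefined(self):
        with pytest.raises(UndefinedResultError):
            solve_f_half(TwoComponentParams(0, 1, 0, 5, 1))

    def test_agrees_with_grid_bisection_oracle(self, rng):
        """Independent oracle: bisection on a dense frequency grid."""
        for _ in range(30):
            params = TwoComponentParams(
                rng.uniform(0.1, 5), rng.uniform(0.2, 5),
                rng.uniform(0.1, 5), rng.uniform(5, 40), rng.uniform(0.5, 4),
            )
            target = derive_t_max(params) / 2
            fgrid = np.logspace(-3, 4, 10**6)
            idx = np.searchsorted(eval_two_component(params, fgrid), target)
            oracle = fgrid[min(idx, len(fgrid) - 1)]
            assert solve_f_half(params) == pytest.approx(oracle, rel=1e-4)


@pytest.mark.parametrize(
    "params, f, expected",
    [
        (TwoComponentParams(1, 0.7, 0, 10, 1), 2.0, 1.0),
        (TwoComponentParams(0, 0.7, 1, 10, 1), 2.0, 0.0),
        (TwoComponentParams(1, 2, 1, 8, 1), 4.0, 2 / 3),
    ],
)
def test_component_fraction_lf(params, f, expected):
    assert component_fraction_lf(params, f) == pytest.approx(expected, abs=1e-9)


def test_component_fraction_undefined_at_zero_response():
    with pytest.raises(UndefinedResultError):
        component_fraction_lf(TwoComponentParams(1, 1, 1, 5, 1), 0.0)
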