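"""Tests for the paired-cohort simulator."""

import numpy as np
import pandas as pd
import pytest

from detrusorfit import (
    InterventionPreset,
    default_presets,
    derive_t_max,
    draw_cohort,
    eval_one_component,
    eval_two_component,
    expected_low_freq_reduction,
    population_truth,
    solve_f_half,
)
from detrusorfit.errors import DesignError
from detrusorfit.pipeline import net_release_table
from detrusorfit.synthetic import DEFAULT_GRID


def test_population_anchors():
    """The population curves hit the cohort-level anchor values: T_max
    2.2 mN/mg with f_1/2 5.1 Hz, ATP ~73.6 fmol/uL/mg at 8 Hz, ACh ~140
    at 20 Hz and negligible at 2 Hz."""
    pop = population_truth()
    assert derive_t_max(pop.tension_params) == pytest.approx(2.2, rel=1e-6)
    assert solve_f_half(pop.tension_params) == pytest.approx(5.1, abs=0.01)
    assert pop.tension_params.f_star_lf == pytest.approx(0.7)
    assert eval_two_component(pop.atp_params, 8.0) == pytest.approx(73.6, abs=1.0)
    assert eval_one_component(pop.ach_params, 20.0) == pytest.approx(140.0, abs=1.0)
    ach_2hz = eval_one_component(pop.ach_params, 2.0)
    assert ach_2hz < 0.05 * pop.ach_params.y_max


class TestPresets:
    def test_names_and_no_effect_scales(self):
        presets = default_presets()
        for name in ("control", "adenosine", "cpa", "neca", "dpcpx",
                     "dpcpx_adenosine", "camps_rp", "forskolin", "ttx"):
            assert name in presets
        assert presets["adenosine"].ach_scale == 1.0  # no effect on ACh release
        assert presets["dpcpx_adenosine"].tension_lf_scale == 1.0  # A1 blocked
        assert presets["dpcpx"].atp_scale == 1.0
        assert presets["adenosine"].tension_lf_scale == pytest.approx(0.70)
        assert presets["adenosine"].atp_scale == pytest.approx(0.66)

    def test_interventions_conserve_t_max(self):
        """Suppression of the purinergic limb redistributes amplitude so
        the population T_max is unchanged (the cholinergic ceiling)."""
        presets = default_presets()
        pop = population_truth()
        t0 = derive_t_max(pop.tension_params)
        for name in ("adenosine", "cpa", "neca", "camps_rp", "forskolin"):
            p = presets[name]
            t1 = (p.tension_lf_scale * pop.tension_params.y_lf_max
                  + p.tension_hf_scale * pop.tension_params.y_hf_max)
            assert t1 == pytest.approx(t0, rel=1e-9)

    def test_control_noiseless_roundtrip(self):
        """Simulate -> average -> derive under the control preset with no
        noise reproduces the generating T_max within 1%."""
        preset = InterventionPreset("control", noise_cv=0.0, between_prep_cv=0.0)
        tabs = draw_cohort(preset, n=3, seed=0)
        t = tabs.tension.assign(norm=lambda d: d.tension_mN / d.weight_mg)
        pop = population_truth()
        for (_, cond), g in t.groupby(["prep_id", "condition"]):
            ser = g.set_index("frequency_hz")["norm"].sort_index()
            expected = eval_two_component(pop.tension_params, ser.index.values)
            assert np.allclose(ser.values, expected, atol=1e-10)


class TestDrawCohort:
    def test_seed_reproducibility(self):
        a = draw_cohort(default_presets()["adenosine"], n=4, seed=11)
        b = draw_cohort(default_presets()["adenosine"], n=4, seed=11)
        pd.testing.assert_frame_equal(a.tension, b.tension)
        pd.testing.assert_frame_equal(a.release, b.release)

    def test_cohorts_share_first_preparations(self):
        small = draw_cohort(default_presets()["control"], n=3, seed=5)
        large = draw_cohort(default_presets()["control"], n=6, seed=5)
        small_prep1 = small.tension[small.tension.prep_id == "prep01"].reset_index(drop=True)
        large_prep1 = large.tension[large.tension.prep_id == "prep01"].reset_index(drop=True)
        pd.testing.assert_frame_equal(small_prep1, large_prep1)

    def test_minimum_cohort_size(self):
        with pytest.raises(DesignError):
            draw_cohort(default_presets()["control"], n=1, seed=0)

    def test_deterministic_limit_reduction(self):
        """With no noise and no dispersion, every preparation's tension
        reduction at f << f*_hf equals the generating percentage."""
        presets = default_presets()
        preset = InterventionPreset(
            "adenosine",
            tension_lf_scale=presets["adenosine"].tension_lf_scale,
            tension_hf_scale=presets["adenosine"].tension_hf_scale,
            atp_scale=presets["adenosine"].atp_scale,
            noise_cv=0.0,
            between_prep_cv=0.0,
        )
        tabs = draw_cohort(preset, n=2, seed=0)
        t = tabs.tension.assign(norm=lambda d: d.tension_mN / d.weight_mg)
        wide = t.pivot_table(index=["prep_id", "frequency_hz"], columns="condition",
                             values="norm").reset_index()
        low = wide[wide.frequency_hz <= 2.0]
        reductions = 100 * (1 - low["adenosine"] / low["control"])
        expected = expected_low_freq_reduction(preset, freqs=(1.0,))
        at_1hz = reductions[low.frequency_hz == 1.0]
        assert np.allclose(at_1hz, expected, atol=1e-9)

    def test_ttx_abolishes_release_and_tension(self):
        tabs = draw_cohort(default_presets()["ttx"], n=3, seed=2)
        net = net_release_table(tabs.release)
        ttx_rows = net[net.condition == "ttx"]
        assert np.allclose(ttx_rows["net"], 0.0)
        ttx_tension = tabs.tension[tabs.tension.condition == "ttx"]
        assert np.allclose(ttx_tension["tension_mN"], 0.0)

    def test_ach_no_systematic_effect_under_adenosine(self):
        """Mean ACh difference at 20 Hz stays within the noise envelope."""
        preset = default_presets()["adenosine"]
        tabs = draw_cohort(preset, n=12, seed=3)
        net = net_release_table(tabs.release)
        ach = net[(net.analyte == "ACh") & (net.frequency_hz == 20.0)]
        wide = ach.pivot(index="prep_id", columns="condition", values="net")
        diff = (wide["adenosine"] - wide["control"]).mean()
        envelope = 3 * preset.noise_cv * 140.0 / np.sqrt(len(wide))
        assert abs(diff) < envelope


def test_noiseless_grid_matches_curves_everywhere():
    preset = InterventionPreset("control", noise_cv=0.0, between_prep_cv=0.0)
    tabs = draw_cohort(preset, n=2, seed=9)
    pop = population_truth()
    net = net_release_table(tabs.release)
    atp = net[(net.analyte == "ATP") & (net.condition == "control")]
    for f in DEFAULT_GRID:
        expected = eval_two_component(pop.atp_params, f)
        got = atp[atp.frequency_hz == f]["net"]
        assert np.allclose(got, expected, atol=1e-9)
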