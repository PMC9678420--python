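"""Synthetic paired cohorts emulating the detrusor cotransmission study design.

Each simulated preparation is a bladder strip with its own wet weight and
its own true frequency-response curves: a two-component tension curve, a
two-component ATP-release curve and a one-component ACh-release curve,
drawn log-normally around population means.  An intervention preset
rescales component amplitudes multiplicatively (half-frequencies are
never touched) and the same preparation is "measured" under control and
intervention conditions at every grid frequency, with additive Gaussian
noise proportional to the true signal.

Population means are anchored to the cohort summaries the analysis is
meant to recover: control T_max ~ 2.2 mN·mg⁻¹ with overall f_1/2 ~ 5.1 Hz
and a purinergic half-frequency of 0.7 Hz; ATP release ~ 73.6
fmol·µL⁻¹·mg⁻¹ at 8 Hz; ACh release ~ 140 fmol·µL⁻¹·mg⁻¹ at 20 Hz and
negligible (< 5% of maximum) below 2 Hz.  Interventions that suppress
the purinergic limb redistribute amplitude into the cholinergic limb so
that total T_max is conserved — the cholinergic ceiling seen in tissue,
where high-frequency contractions are unaffected even when low-frequency
ones fall by a third.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DesignError
from .models import (
    OneComponentParams,
    TwoComponentParams,
    eval_one_component,
    eval_two_component,
)

__all__ = [
    "DEFAULT_GRID",
    "PreparationTruth",
    "InterventionPreset",
    "CohortTables",
    "population_truth",
    "default_presets",
    "draw_cohort",
    "expected_low_freq_reduction",
]

#: Default EFS frequency grid (Hz): the experimental 1-40 Hz range with
#: intermediate points dense enough to identify a 5-parameter fit.
DEFAULT_GRID: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 40.0)

# Population-mean curves (units: mN·mg⁻¹ for tension, fmol·µL⁻¹·mg⁻¹ for release).
# Tension: T_max 2.2, purinergic half-frequency 0.7 Hz, and f_star_hf solved so
# the overall half-maximum falls at 5.1 Hz on the rising cholinergic limb —
# a half-crossing flat enough to be consistent with the narrow cohort spread
# of f_1/2 would not be possible on an inter-limb plateau.
_TENSION_POP = TwoComponentParams(y_lf_max=0.8, f_star_lf=0.7, y_hf_max=1.4, f_star_hf=9.469, m=2.0)
_ATP_POP = TwoComponentParams(y_lf_max=60.0, f_star_lf=0.7, y_hf_max=41.5, f_star_hf=10.0, m=1.0)
_ACH_POP = OneComponentParams(y_max=154.2, f_half=8.0, m=2.5)

_WEIGHT_MEAN_MG = 10.0  # bladder-strip wet weight
_WEIGHT_CV = 0.20
_ATP_BASELINE = 2.0  # pre-EFS bath [ATP], fmol/uL
_CHOLINE_BASELINE = 50.0  # free-choline background, fmol/uL
_BASELINE_CV = 0.10


@dataclass(frozen=True)
class PreparationTruth:
    """The generating curves and weight of one simulated preparation."""

    prep_id: str
    weight: float
    tension_params: TwoComponentParams
    atp_params: TwoComponentParams
    ach_params: OneComponentParams


@dataclass(frozen=True)
class InterventionPreset:
    """Multiplicative intervention effect plus cohort noise structure.

    Scales of 1 encode "no effect"; ``atp_scale`` multiplies both ATP
    components uniformly (the proportional suppression seen at all
    frequencies), while tension scales act per component.  ``noise_cv``
    is the measurement coefficient of variation and ``between_prep_cv``
    the log-normal CV of per-preparation parameter draws.
    """

    name: str
    tension_lf_scale: float = 1.0
    tension_hf_scale: float = 1.0
    atp_scale: float = 1.0
    ach_scale: float = 1.0
    noise_cv: float = 0.10
    between_prep_cv: float = 0.30

    def __post_init__(self):
        for s in (self.tension_lf_scale, self.tension_hf_scale, self.atp_scale, self.ach_scale):
            if s < 0:
                raise DesignError("intervention scales must be >= 0")


class CohortTables(NamedTuple):
    tension: pd.DataFrame
    release: pd.DataFrame
    truths: list[PreparationTruth]


def population_truth() -> PreparationTruth:
    """The population-mean preparation (weight at the cohort mean)."""
    return PreparationTruth("population", _WEIGHT_MEAN_MG, _TENSION_POP, _ATP_POP, _ACH_POP)


def _conserving_hf_scale(lf_scale: float) -> float:
    """Cholinergic-limb scale that conserves population T_max when the
    purinergic limb is scaled by ``lf_scale``."""
    return 1.0 + (1.0 - lf_scale) * _TENSION_POP.y_lf_max / _TENSION_POP.y_hf_max


def default_presets() -> dict[str, InterventionPreset]:
    """Named intervention presets anchored to the cohort-level effect sizes.

    Tension low-frequency scales encode the mean 1-2 Hz contraction
    reductions (adenosine ~30%, CPA ~51%, NECA ~69%, the PKA inhibitor
    cAMPS-Rp ~46%, forskolin ~62%); ATP scales encode the uniform release
    reductions (34%, 44%, 52%, 36%; forskolin none); ACh is never
    affected except by nerve block.  The A1 antagonist DPCPX alone, or
    adenosine in its presence, has no effect; TTX abolishes everything.
    """
    def preset(name, tension_lf=1.0, atp=1.0, ach=1.0, **kw):
        hf = kw.pop("tension_hf", _conserving_hf_scale(tension_lf) if tension_lf != 1.0 else 1.0)
        return InterventionPreset(
            name, tension_lf_scale=tension_lf, tension_hf_scale=hf,
            atp_scale=atp, ach_scale=ach, **kw,
        )

    return {
        "control": preset("control"),
        "adenosine": preset("adenosine", tension_lf=0.70, atp=0.66),
        "cpa": preset("cpa", tension_lf=0.493, atp=0.559),
        "neca": preset("neca", tension_lf=0.308, atp=0.482),
        "dpcpx": preset("dpcpx"),
        "dpcpx_adenosine": preset("dpcpx_adenosine"),
        "camps_rp": preset("camps_rp", tension_lf=0.536, atp=0.645),
        "forskolin": preset("forskolin", tension_lf=0.384, atp=1.0),
        "ttx": preset("ttx", tension_lf=0.0, tension_hf=0.0, atp=0.0, ach=0.0),
    }


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean log-normal multiplier(s) with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# Secondary between-preparation dispersions.  The dominant variation is a
# common responsiveness factor per curve (CV = preset.between_prep_cv)
# scaling both component amplitudes together, as whole-tissue excitability
# does; component-ratio jitter and half-frequency jitter are smaller, so
# that the across-preparation spread of T_max (~30%) stays much larger
# than that of f_1/2 (~25%), as the cohort summaries show.
_RATIO_CV = 0.10
_F_HALF_CV = 0.20


def _draw_truth(rng: np.random.Generator, prep_id: str, cv: float) -> PreparationTruth:
    weight = _WEIGHT_MEAN_MG * _lognormal_factor(rng, _WEIGHT_CV)
    t, a, c = _TENSION_POP, _ATP_POP, _ACH_POP
    ratio_cv = min(_RATIO_CV, cv)
    fh_cv = min(_F_HALF_CV, cv)

    def draw_two(p: TwoComponentParams) -> TwoComponentParams:
        scale = _lognormal_factor(rng, cv)
        amp = _lognormal_factor(rng, ratio_cv, 2)
        fh = _lognormal_factor(rng, fh_cv, 2)
        return TwoComponentParams(p.y_lf_max * scale * amp[0], p.f_star_lf * fh[0],
                                  p.y_hf_max * scale * amp[1], p.f_star_hf * fh[1], p.m)

    tension = draw_two(t)
    atp = draw_two(a)
    ach = OneComponentParams(c.y_max * _lognormal_factor(rng, cv),
                             c.f_half * _lognormal_factor(rng, fh_cv), c.m)
    return PreparationTruth(prep_id, float(weight), tension, atp, ach)


def _apply_preset(truth: PreparationTruth, p: InterventionPreset) -> PreparationTruth:
    t = truth.tension_params
    tension = replace(t, y_lf_max=t.y_lf_max * p.tension_lf_scale,
                      y_hf_max=t.y_hf_max * p.tension_hf_scale)
    a = truth.atp_params
    atp = replace(a, y_lf_max=a.y_lf_max * p.atp_scale, y_hf_max=a.y_hf_max * p.atp_scale)
    ach = replace(truth.ach_params, y_max=truth.ach_params.y_max * p.ach_scale)
    return replace(truth, tension_params=tension, atp_params=atp, ach_params=ach)


def _noisy(rng: np.random.Generator, value: np.ndarray, cv: float) -> np.ndarray:
    """Additive Gaussian noise with SD proportional to the true value, so a
    zero signal (nerve block) stays exactly zero."""
    return value + rng.standard_normal(value.shape) * cv * value


def draw_cohort(
    preset: InterventionPreset,
    n: int,
    grid: tuple[float, ...] = DEFAULT_GRID,
    seed: int = 0,
) -> CohortTables:
    """Simulate a paired control/intervention cohort of ``n`` preparations.

    Returns tidy tension and release tables in the schemas the analysis
    consumes, plus the generating per-preparation truths.  One global
    seed drives a per-preparation substream, so cohorts of different
    sizes share their first preparations; identical seeds give
    bit-identical tables.
    """
    if n < 2:
        raise DesignError("a paired cohort needs n >= 2 preparations")
    freqs = np.asarray(grid, dtype=float)
    cond_label = preset.name if preset.name != "control" else "sham"
    children = np.random.SeedSequence(seed).spawn(n)

    tension_rows, release_rows, truths = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        truth = _draw_truth(rng, f"prep{i + 1:02d}", preset.between_prep_cv)
        truths.append(truth)
        w = truth.weight
        for cond, params_src in (("control", truth), (cond_label, _apply_preset(truth, preset))):
            tension = _noisy(rng, eval_two_component(params_src.tension_params, freqs), preset.noise_cv)
            atp_net = _noisy(rng, eval_two_component(params_src.atp_params, freqs), preset.noise_cv)
            ach_net = _noisy(rng, eval_one_component(params_src.ach_params, freqs), preset.noise_cv)
            atp_pre = _ATP_BASELINE * _lognormal_factor(rng, _BASELINE_CV, len(freqs))
            choline = _CHOLINE_BASELINE * _lognormal_factor(rng, _BASELINE_CV, len(freqs))
            for j, f in enumerate(freqs):
                tension_rows.append((truth.prep_id, cond, f, tension[j] * w, w))
                release_rows.extend([
                    (truth.prep_id, cond, "ATP", f, "pre_efs", atp_pre[j], w),
                    (truth.prep_id, cond, "ATP", f, "during_efs", atp_pre[j] + atp_net[j] * w, w),
                    (truth.prep_id, cond, "ACh_free_choline", f, "pre_efs", choline[j], w),
                    (truth.prep_id, cond, "ACh_free_choline", f, "during_efs", choline[j], w),
                    (truth.prep_id, cond, "ACh_total_choline", f, "pre_efs", choline[j], w),
                    (truth.prep_id, cond, "ACh_total_choline", f, "during_efs",
                     choline[j] + ach_net[j] * w, w),
                ])

    tension_df = pd.DataFrame(
        tension_rows, columns=["prep_id", "condition", "frequency_hz", "tension_mN", "weight_mg"]
    )
    release_df = pd.DataFrame(
        release_rows,
        columns=["prep_id", "condition", "analyte", "frequency_hz", "phase", "value", "weight_mg"],
    )
    return CohortTables(tension_df, release_df, truths)


def expected_low_freq_reduction(preset: InterventionPreset, freqs=(1.0, 2.0)) -> float:
    """Generating tension reduction (%) at the low-frequency report points,
    evaluated on the noiseless population curves and averaged over ``freqs``."""
    ctrl = population_truth()
    interv = _apply_preset(ctrl, preset)
    f = np.asarray(freqs, dtype=float)
    c = eval_two_component(ctrl.tension_params, f)
    v = eval_two_component(interv.tension_params, f)
    return float(np.mean(100.0 * (1.0 - v / c)))
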