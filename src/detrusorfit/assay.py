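"""Calibration and arithmetic for nerve-mediated transmitter-release assays.

ATP is assayed by luciferin-luciferase luminescence, calibrated by a
straight line on a log10-log10 plot of signal against standard
concentration (the log-log transform linearises the curve over the wide
100 fM - 1 uM working range); the detection limit is 100 fM.  ACh is
quantified as the difference between total choline (sample +
acetylcholinesterase) and free choline (no enzyme), with a plain linear
fluorescence calibration over 0-250 pM choline.  Nerve-mediated release
is the during-EFS minus pre-EFS concentration difference, normalised to
preparation wet weight.

Concentrations are handled in fmol per microlitre (1 fmol/uL = 1 nM)
unless a caller supplies standards in other units, in which case
everything downstream simply inherits those units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .errors import CalibrationError, DomainError, UndefinedResultError

__all__ = [
    "ATP_DETECTION_LIMIT_FMOL_PER_UL",
    "CalibrationModel",
    "ReleaseRecord",
    "ConcentrationResult",
    "build_calibration",
    "signal_to_concentration",
    "ach_from_choline",
    "net_release",
    "percent_reduction",
]

#: 100 fM expressed in fmol/uL (1 fmol/uL = 1 nM, so 100 fM = 1e-4 fmol/uL).
ATP_DETECTION_LIMIT_FMOL_PER_UL = 1e-4


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted signal-vs-concentration line.

    For ``kind='loglog_linear'`` the line is log10(signal) = slope *
    log10(concentration) + intercept; for ``kind='linear'`` it is signal =
    slope * concentration + intercept.  ``valid_range`` is the
    concentration span of the standards; inversions outside it are
    flagged rather than rejected.
    """

    kind: Literal["loglog_linear", "linear"]
    slope: float
    intercept: float
    valid_range: tuple[float, float]
    detection_limit: float = 0.0


@dataclass(frozen=True)
class ReleaseRecord:
    """One assay observation before differencing/normalisation."""

    prep_id: str
    analyte: Literal["ATP", "ACh_total_choline", "ACh_free_choline"]
    frequency: float
    phase: Literal["pre_efs", "during_efs"]
    concentration: float
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise DomainError("preparation weight must be > 0 mg")


class ConcentrationResult(NamedTuple):
    concentration: float
    below_detection: bool
    out_of_range: bool


def build_calibration(
    standards: Sequence[tuple[float, float]],
    kind: Literal["loglog_linear", "linear"],
    detection_limit: float = 0.0,
) -> CalibrationModel:
    """Least-squares calibration line from (concentration, signal) standards.

    Fitted in log10-log10 space for ``loglog_linear`` (ATP) and in plain
    linear space for ``linear`` (choline).  Requires >= 2 distinct
    standard concentrations; log-log standards must be strictly positive.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise CalibrationError("need >= 2 (concentration, signal) standards")
    conc, sig = arr[:, 0], arr[:, 1]
    if len(np.unique(conc)) < 2:
        raise CalibrationError("standards must span >= 2 distinct concentrations")
    if kind == "loglog_linear":
        if np.any(conc <= 0) or np.any(sig <= 0):
            raise DomainError("log-log calibration requires positive concentrations and signals")
        slope, intercept = np.polyfit(np.log10(conc), np.log10(sig), 1)
        if slope <= 0:
            raise CalibrationError("log-log calibration slope must be positive")
    elif kind == "linear":
        slope, intercept = np.polyfit(conc, sig, 1)
        if slope == 0:
            raise CalibrationError("calibration slope is zero; signal does not track concentration")
    else:
        raise ValueError(f"unknown calibration kind {kind!r}")
    return CalibrationModel(
        kind=kind,
        slope=float(slope),
        intercept=float(intercept),
        valid_range=(float(np.min(conc)), float(np.max(conc))),
        detection_limit=float(detection_limit),
    )


def signal_to_concentration(model: CalibrationModel, signal: float) -> ConcentrationResult:
    """Invert the calibration line for one raw signal.

    Concentrations implied below the detection limit are floored at the
    limit and flagged ``below_detection``; values outside the standard
    range are returned with ``out_of_range`` set.
    """
    if model.kind == "loglog_linear":
        if signal <= 0:
            raise DomainError("log-log calibration cannot invert a non-positive signal")
        conc = 10.0 ** ((np.log10(signal) - model.intercept) / model.slope)
    else:
        conc = (signal - model.intercept) / model.slope
    conc = float(conc)
    below = conc < model.detection_limit
    if below:
        conc = model.detection_limit
    lo, hi = model.valid_range
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)  # numerical slack at the range edges
    out_of_range = not (lo - tol <= conc <= hi + tol)
    return ConcentrationResult(conc, below, out_of_range)


class AchResult(NamedTuple):
    concentration: float
    negative_estimate: bool


def ach_from_choline(total: float, free: float) -> AchResult:
    """ACh concentration as total minus free choline.

    Negative differences (assay noise) are retained and flagged, never
    clamped, so that averaging across preparations stays unbiased.
    """
    if total < 0 or free < 0:
        raise DomainError("choline concentrations must be >= 0")
    diff = total - free
    return AchResult(float(diff), diff < 0)


class NetReleaseResult(NamedTuple):
    value: float
    negative: bool


def net_release(pre: float, during: float, weight: float) -> NetReleaseResult:
    """Nerve-mediated release: (during-EFS − pre-EFS) / preparation weight.

    Sign is preserved; a negative net release is flagged.  Units follow
    the inputs (fmol/uL and mg give fmol·uL⁻¹·mg⁻¹).
    """
    if weight <= 0:
        raise DomainError("preparation weight must be > 0 mg")
    value = (during - pre) / weight
    return NetReleaseResult(float(value), value < 0)


def percent_reduction(control: float, intervention: float) -> float:
    """Percent reduction of ``intervention`` relative to ``control``.

    100·(1 − intervention/control); negative values mean enhancement.
    Computed per preparation — cohort summaries average these
    per-preparation percentages, not the ratio of cohort means.
    """
    if control == 0:
        raise UndefinedResultError("percent reduction undefined for zero control value")
    return 100.0 * (1.0 - intervention / control)
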