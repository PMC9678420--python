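"""Cohort analysis: per-preparation fits to aggregate intervention tables.

The orchestration mirrors how the experiments are summarised: each
preparation's tension and ATP frequency-response data are fitted with the
two-component model and ACh with the one-component model; composite
parameters T_max and f_1/2 are derived per preparation; intervention
effects are expressed as per-preparation percentage reductions (tension
and ATP averaged over the 1 and 2 Hz points, ACh taken at 20 Hz) and then
aggregated as mean ± SD with paired comparisons against the reference
(control, or the immediately preceding condition when conditions are
chained).  Pooling several interventions yields the tension-vs-ATP
reduction correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import assay
from .errors import (
    DegenerateTestError,
    InsufficientDataError,
    MissingColumnError,
    PairingError,
)
from .fitting import (
    FitOptions,
    FitResult,
    fit_one_component,
    fit_reduction_curve,
    fit_two_component_paired,
)
from .models import derive_t_max, solve_f_half
from .stats import paired_t, pearson, rm_anova_oneway

__all__ = [
    "RunConfig",
    "Table2Row",
    "Table3Row",
    "CohortResult",
    "analyze_cohort",
    "fit_reduction_profile",
    "pooled_correlation",
    "LOW_FREQ_REPORT_HZ",
    "ACH_REPORT_HZ",
]

#: Report points: tension/ATP reductions averaged over these frequencies,
#: ACh change taken at the single high-frequency point.
LOW_FREQ_REPORT_HZ: tuple[float, float] = (1.0, 2.0)
ACH_REPORT_HZ: float = 20.0

_TENSION_COLS = ["prep_id", "condition", "frequency_hz", "tension_mN", "weight_mg"]
_RELEASE_COLS = ["prep_id", "condition", "analyte", "frequency_hz", "phase", "value", "weight_mg"]


class RunConfig(BaseModel):
    """Validated run configuration; logged verbatim into the run record."""

    tension_path: str | None = None
    release_path: str | None = None
    calibration_path: str | None = None
    output_dir: str = "results"
    preset: str = "adenosine"
    n: int = Field(default=12, ge=2)
    seed: int = 0
    grid: list[float] = Field(default_factory=lambda: [1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 40.0])
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_starts: int = Field(default=20, ge=1)
    reference_condition: str = "control"
    condition_order: list[str] | None = None


@dataclass(frozen=True)
class Table2Row:
    """Force-frequency curve parameters for one intervention condition.

    ``n`` is the cohort size; ``n_used`` the preparations entering the
    derived-parameter comparison (pairs whose joint fit pinned at a shape
    bound are excluded as unreliable extrapolations).
    """

    intervention: str
    reference: str
    n: int
    n_used: int
    t_max_mean: float
    t_max_sd: float
    t_max_p: float
    f_half_mean: float
    f_half_sd: float
    f_half_p: float


@dataclass(frozen=True)
class Table3Row:
    """Percentage reductions of contraction and transmitter release."""

    intervention: str
    reference: str
    n: int
    tension_redn_mean: float
    tension_redn_sd: float
    tension_p: float
    atp_redn_mean: float
    atp_redn_sd: float
    atp_p: float
    ach_redn_mean: float = math.nan
    ach_redn_sd: float = math.nan
    ach_p: float = math.nan
    ach_recorded: bool = False


@dataclass
class CohortResult:
    """Per-preparation fits plus Table 2/3-style aggregates."""

    fits: pd.DataFrame
    table2: list[Table2Row]
    table3: list[Table3Row]
    correlation: dict | None = None
    anova: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def table2_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.table2])

    def table3_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.table3])


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str):
    for c in cols:
        if c not in df.columns:
            raise MissingColumnError(c, table)


def _condition_order(df: pd.DataFrame, config: RunConfig) -> list[str]:
    if config.condition_order:
        return list(config.condition_order)
    seen = list(dict.fromkeys(df["condition"]))
    ref = config.reference_condition
    if ref in seen:
        seen.remove(ref)
        return [ref] + seen
    return seen


def net_release_table(release: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw pre/during release records to weight-normalised net release.

    Returns one row per (prep_id, condition, analyte ATP/ACh, frequency)
    with ``net`` in fmol·µL⁻¹·mg⁻¹.
    """
    _require_columns(release, _RELEASE_COLS, "release")
    wide = release.pivot_table(
        index=["prep_id", "condition", "frequency_hz", "weight_mg"],
        columns=["analyte", "phase"],
        values="value",
        aggfunc="first",
    )
    rows = []
    for (prep, cond, f, w), r in wide.iterrows():
        if ("ATP", "pre_efs") in r.index and not pd.isna(r[("ATP", "pre_efs")]):
            net = assay.net_release(r[("ATP", "pre_efs")], r[("ATP", "during_efs")], w)
            rows.append((prep, cond, "ATP", f, net.value))
        if ("ACh_total_choline", "pre_efs") in r.index and not pd.isna(
            r.get(("ACh_total_choline", "pre_efs"), np.nan)
        ):
            ach_pre = assay.ach_from_choline(
                r[("ACh_total_choline", "pre_efs")], r[("ACh_free_choline", "pre_efs")]
            )
            ach_dur = assay.ach_from_choline(
                r[("ACh_total_choline", "during_efs")], r[("ACh_free_choline", "during_efs")]
            )
            net = assay.net_release(ach_pre.concentration, ach_dur.concentration, w)
            rows.append((prep, cond, "ACh", f, net.value))
    return pd.DataFrame(rows, columns=["prep_id", "condition", "analyte", "frequency_hz", "net"])


def _fit_record(prep: str, cond: str, measure: str, fit: FitResult) -> dict:
    rec = {
        "prep_id": prep,
        "condition": cond,
        "measure": measure,
        "sse": fit.sse,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "at_bounds": fit.at_bounds,
    }
    p = fit.params
    if measure == "ach":
        rec.update(model="one_component", y_max=p.y_max, f_half=p.f_half, m=p.m)
    else:
        t_max = derive_t_max(p)
        rec.update(
            model="two_component",
            y_lf_max=p.y_lf_max,
            f_star_lf=p.f_star_lf,
            y_hf_max=p.y_hf_max,
            f_star_hf=p.f_star_hf,
            m=p.m,
            t_max=t_max,
            f_half_overall=solve_f_half(p) if t_max > 0 else math.nan,
        )
    return rec


def _paired_p(x, y, warnings: list[str], label: str) -> float:
    try:
        return paired_t(x, y).p_value
    except DegenerateTestError:
        warnings.append(f"degenerate paired test for {label} (zero variance); p undefined")
        return math.nan


def analyze_cohort(
    tension: pd.DataFrame,
    release: pd.DataFrame | None,
    config: RunConfig | None = None,
    measures: tuple[str, ...] = ("tension", "atp", "ach"),
) -> CohortResult:
    """Run the full per-preparation fitting and aggregation for one cohort.

    ``tension`` and ``release`` are tidy tables in the documented input
    schemas with a shared set of preparations measured under every
    condition.  Fits use the two-component model for tension and ATP and
    the one-component model for ACh; reductions are per-preparation
    percentages referenced to the immediately preceding condition.
    """
    config = config or RunConfig()
    _require_columns(tension, _TENSION_COLS, "tension")
    order = _condition_order(tension, config)
    if len(order) < 2:
        raise PairingError("need a reference and at least one intervention condition")
    opts = FitOptions(n_starts=config.n_starts)
    warnings: list[str] = []

    preps = sorted(tension["prep_id"].unique())
    for cond in order:
        have = set(tension.loc[tension["condition"] == cond, "prep_id"])
        if set(preps) - have:
            raise PairingError(f"preparations missing condition {cond!r}: {sorted(set(preps) - have)}")

    tension = tension.assign(norm=tension["tension_mN"] / tension["weight_mg"])
    net = net_release_table(release) if release is not None else None

    # measured values used for reductions: {(measure, prep, cond): freq -> value}
    measured: dict[tuple[str, str, str], pd.Series] = {}
    for prep in preps:
        for cond in order:
            if "tension" in measures:
                sub = tension[(tension["prep_id"] == prep) & (tension["condition"] == cond)]
                measured[("tension", prep, cond)] = sub.set_index("frequency_hz")["norm"].sort_index()
            if net is not None:
                for analyte, measure in (("ATP", "atp"), ("ACh", "ach")):
                    if measure not in measures:
                        continue
                    sub = net[(net["prep_id"] == prep) & (net["condition"] == cond)
                              & (net["analyte"] == analyte)]
                    if not sub.empty:
                        measured[(measure, prep, cond)] = sub.set_index("frequency_hz")["net"].sort_index()

    # Two-component measures are fitted jointly per consecutive condition
    # pair with shared curve shape (see fit_two_component_paired); ACh uses
    # independent one-component fits.
    fit_rows = []
    pair_fits: dict[tuple[str, str, int], tuple[FitResult, FitResult]] = {}
    for measure in ("tension", "atp"):
        if measure not in measures:
            continue
        for i, cond in enumerate(order[1:], start=1):
            ref = order[i - 1]
            for prep in preps:
                ref_ser = measured.get((measure, prep, ref))
                test_ser = measured.get((measure, prep, cond))
                if ref_ser is None or test_ser is None:
                    continue
                common = ref_ser.index.intersection(test_ser.index)
                pair = fit_two_component_paired(
                    common.values, ref_ser.loc[common].values, test_ser.loc[common].values, opts
                )
                pair_fits[(measure, prep, i)] = pair
                if i == 1:
                    fit_rows.append(_fit_record(prep, ref, measure, pair[0]))
                fit_rows.append(_fit_record(prep, cond, measure, pair[1]))
    if "ach" in measures:
        for prep in preps:
            for cond in order:
                ser = measured.get(("ach", prep, cond))
                if ser is not None:
                    fit_rows.append(_fit_record(prep, cond, "ach",
                                                fit_one_component(ser.index, ser.values, opts)))
    fits = pd.DataFrame(fit_rows)

    table2: list[Table2Row] = []
    table3: list[Table3Row] = []
    for i, cond in enumerate(order[1:], start=1):
        ref = order[i - 1]
        if "tension" in measures:
            # derived-parameter comparison excludes pairs whose joint fit
            # pinned at a shape bound (extrapolated T_max / f_1/2)
            rows = [pair_fits[("tension", p, i)] for p in preps if ("tension", p, i) in pair_fits]
            usable = [(r, t) for r, t in rows if not (r.at_bounds or t.at_bounds or r.degenerate)]
            if usable:
                tmax_ref = np.array([derive_t_max(r.params) for r, _ in usable])
                tmax_test = np.array([derive_t_max(t.params) for _, t in usable])
                fh_ref = np.array([solve_f_half(r.params) for r, _ in usable])
                fh_test = np.array([solve_f_half(t.params) for _, t in usable])
                if len(usable) < len(rows):
                    warnings.append(
                        f"{cond}: {len(rows) - len(usable)} preparation(s) excluded from "
                        "derived-parameter comparison (fit pinned at shape bounds)"
                    )
                table2.append(Table2Row(
                    intervention=cond,
                    reference=ref,
                    n=len(preps),
                    n_used=len(usable),
                    t_max_mean=float(tmax_test.mean()),
                    t_max_sd=float(tmax_test.std(ddof=1)) if len(usable) > 1 else math.nan,
                    t_max_p=_paired_p(tmax_test, tmax_ref, warnings, f"T_max {cond}"),
                    f_half_mean=float(fh_test.mean()),
                    f_half_sd=float(fh_test.std(ddof=1)) if len(usable) > 1 else math.nan,
                    f_half_p=_paired_p(fh_test, fh_ref, warnings, f"f_1/2 {cond}"),
                ))

        def _low_freq_values(measure: str, condition: str) -> np.ndarray | None:
            vals = []
            for prep in preps:
                ser = measured.get((measure, prep, condition))
                if ser is None or not all(f in ser.index for f in LOW_FREQ_REPORT_HZ):
                    return None
                vals.append(float(ser.loc[list(LOW_FREQ_REPORT_HZ)].mean()))
            return np.asarray(vals)

        def _reductions(measure: str) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
            """Per-prep reductions at 1-2 Hz, plus the raw paired values."""
            reds, refs_v, cond_v = [], [], []
            for prep in preps:
                rser = measured.get((measure, prep, ref))
                cser = measured.get((measure, prep, cond))
                if rser is None or cser is None:
                    return None
                if not all(f in rser.index and f in cser.index for f in LOW_FREQ_REPORT_HZ):
                    return None
                per_freq = [assay.percent_reduction(rser[f], cser[f]) for f in LOW_FREQ_REPORT_HZ]
                reds.append(float(np.mean(per_freq)))
                refs_v.append(float(rser.loc[list(LOW_FREQ_REPORT_HZ)].mean()))
                cond_v.append(float(cser.loc[list(LOW_FREQ_REPORT_HZ)].mean()))
            return np.asarray(reds), np.asarray(refs_v), np.asarray(cond_v)

        tension_red = _reductions("tension") if "tension" in measures else None
        atp_red = _reductions("atp") if "atp" in measures else None
        if tension_red is not None and atp_red is not None:
            t_reds, t_ref, t_cond = tension_red
            a_reds, a_ref, a_cond = atp_red
            row = Table3Row(
                intervention=cond,
                reference=ref,
                n=len(preps),
                tension_redn_mean=float(np.mean(t_reds)),
                tension_redn_sd=float(np.std(t_reds, ddof=1)),
                tension_p=_paired_p(t_ref, t_cond, warnings, f"tension reduction {cond}"),
                atp_redn_mean=float(np.mean(a_reds)),
                atp_redn_sd=float(np.std(a_reds, ddof=1)),
                atp_p=_paired_p(a_ref, a_cond, warnings, f"ATP reduction {cond}"),
            )
            # ACh reported at 20 Hz when recorded; "not recorded" otherwise
            ach_ok = all(
                measured.get(("ach", p, c)) is not None
                and ACH_REPORT_HZ in measured[("ach", p, c)].index
                for p in preps for c in (ref, cond)
            ) if "ach" in measures else False
            if ach_ok:
                ach_ref = np.array([measured[("ach", p, ref)][ACH_REPORT_HZ] for p in preps])
                ach_cond = np.array([measured[("ach", p, cond)][ACH_REPORT_HZ] for p in preps])
                reds = np.array([assay.percent_reduction(r, c) for r, c in zip(ach_ref, ach_cond)])
                row = Table3Row(
                    **{**vars(row),
                       "ach_redn_mean": float(np.mean(reds)),
                       "ach_redn_sd": float(np.std(reds, ddof=1)),
                       "ach_p": _paired_p(ach_ref, ach_cond, warnings, f"ACh {cond}"),
                       "ach_recorded": True}
                )
            table3.append(row)

    correlation = None
    if len(table3) >= 3:
        correlation = pooled_correlation(table3)

    anova = None
    if len(order) >= 3 and "tension" in measures:
        tmax = fits[fits["measure"] == "tension"].pivot(
            index="prep_id", columns="condition", values="t_max"
        )[order]
        res = rm_anova_oneway(tmax, reference=order[0])
        anova = {
            "measure": "t_max",
            "f_statistic": res.f_statistic,
            "df": [res.df_between, res.df_error],
            "p_value": res.p_value,
            "posthoc": res.posthoc.to_dict(orient="records"),
        }

    return CohortResult(fits=fits, table2=table2, table3=table3,
                        correlation=correlation, anova=anova, warnings=warnings)


def fit_reduction_profile(
    freqs: Sequence[float], mean_reductions: Sequence[float], options: FitOptions | None = None
) -> FitResult:
    """Fit the reduction curve to an across-preparation mean reduction profile."""
    if len(np.unique(np.asarray(freqs, dtype=float))) < 5:
        raise InsufficientDataError("reduction profile needs >= 5 distinct frequencies")
    return fit_reduction_curve(freqs, mean_reductions, options)


def pooled_correlation(rows: Sequence[Table3Row]) -> dict:
    """Pearson correlation of low-frequency tension vs ATP reductions across
    interventions (one point per Table3Row)."""
    x = [r.tension_redn_mean for r in rows]
    y = [r.atp_redn_mean for r in rows]
    r, p = pearson(x, y)
    return {
        "r": r,
        "p_value": p,
        "n_interventions": len(rows),
        "interventions": [row.intervention for row in rows],
        "tension_reductions": x,
        "atp_reductions": y,
    }
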