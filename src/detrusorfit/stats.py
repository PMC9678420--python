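"""Paired statistics applied to fitted curve parameters and reductions.

Implements the paired Student t-test, within-subject (repeated-measures)
one-way ANOVA with Holm-adjusted paired-t post hocs, the Pearson
correlation with its t-transform p-value, and the sample-size iteration
for a paired design at given power.  All statistics are computed from
first-principles sums of squares / closed forms; only distribution
functions come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, IncompleteDesignError, PairingError

__all__ = [
    "PairedTestResult",
    "RmAnovaResult",
    "paired_t",
    "rm_anova_oneway",
    "pearson",
    "required_n",
    "holm_adjust",
]


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    df: int
    p_value: float
    mean_difference: float
    sd_difference: float


@dataclass(frozen=True)
class RmAnovaResult:
    f_statistic: float
    df_between: int
    df_error: int
    p_value: float
    posthoc: pd.DataFrame  # columns: condition, t, df, p_raw, p_adj


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided Student's paired t-test on within-pair differences x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError("paired samples must be 1-D and equal in length")
    n = len(x)
    if n < 2:
        raise PairingError("need at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateTestError("zero variance of within-pair differences")
    mean = float(np.mean(d))
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedTestResult(float(t), n - 1, p, mean, sd)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment; monotone in the raw p-value ordering."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def rm_anova_oneway(
    values: pd.DataFrame, reference: str | None = None
) -> RmAnovaResult:
    """Within-subject one-way ANOVA over a preparations x conditions table.

    Rows are preparations, columns are conditions; the table must be
    complete.  Sums of squares are partitioned into condition, subject
    and error terms; post hoc comparisons are Holm-adjusted paired
    t-tests of each condition against ``reference`` (default: the first
    column).
    """
    table = np.asarray(values, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise IncompleteDesignError("need >= 2 preparations and >= 2 conditions")
    if np.any(~np.isfinite(table)):
        raise IncompleteDesignError("repeated-measures table has missing cells")
    n, k = table.shape
    grand = table.mean()
    cond_means = table.mean(axis=0)
    subj_means = table.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat = 0.0 if ss_cond <= 1e-300 else np.inf
    else:
        f_stat = (ss_cond / df_cond) / ms_err
    p = float(sps.f.sf(f_stat, df_cond, df_err)) if np.isfinite(f_stat) else 0.0

    cols = list(values.columns) if isinstance(values, pd.DataFrame) else list(range(k))
    ref = reference if reference is not None else cols[0]
    ref_idx = cols.index(ref)
    rows = []
    for j, name in enumerate(cols):
        if j == ref_idx:
            continue
        try:
            res = paired_t(table[:, j], table[:, ref_idx])
            rows.append({"condition": name, "t": res.statistic, "df": res.df, "p_raw": res.p_value})
        except DegenerateTestError:
            rows.append({"condition": name, "t": 0.0, "df": n - 1, "p_raw": 1.0})
    posthoc = pd.DataFrame(rows)
    posthoc["p_adj"] = holm_adjust(posthoc["p_raw"].to_numpy()) if len(posthoc) else []
    return RmAnovaResult(float(f_stat), df_cond, df_err, p, posthoc)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise PairingError("need equal-length 1-D samples with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise DegenerateTestError("zero variance in one of the samples")
    r = float(np.sum(xc * yc) / denom)
    n = len(x)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p


def required_n(
    sd: float, delta: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 10_000
) -> int:
    """Smallest n for a two-sided paired t-test to reach the given power.

    ``sd`` is the standard deviation of within-pair differences and
    ``delta`` the mean difference to detect.  Power at each n uses the
    noncentral t distribution with ncp = (delta/sd)·sqrt(n); the search
    starts at the minimum analyzable n of 2.
    """
    if sd <= 0 or delta <= 0:
        raise ValueError("sd and delta must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    effect = delta / sd
    for n in range(2, n_max + 1):
        df = n - 1
        tcrit = sps.t.isf(alpha / 2.0, df)
        ncp = effect * np.sqrt(n)
        achieved = float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
        if achieved >= power:
            return n
    raise ValueError("required sample size exceeds n_max")
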