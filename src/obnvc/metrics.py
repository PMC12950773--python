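"""Response-magnitude summaries: AUC, coupling ratio, trend regressions.

The area under the curve (AUC) is the plain frame-sum of dF/F% over the
first 10 s after odor onset at the trace's native rate — 70 frames for the
7 Hz blood-volume channel — with no dt multiplication, so its unit is
%.frames.  Reflectance BV responses give negative AUC; a more negative AUC
means a larger blood-volume response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import AUC_WINDOW_S


def auc(
    trace: np.ndarray,
    onset_index: int,
    frame_rate_hz: float,
    window_s: float = AUC_WINDOW_S,
) -> float:
    """Frame-sum of dF/F% over ``window_s`` seconds starting at onset."""
    trace = np.asarray(trace, dtype=float)
    n = int(round(window_s * frame_rate_hz))
    if onset_index + n > trace.size:
        raise ValueError(
            f"window of {n} frames from index {onset_index} exceeds the "
            f"{trace.size}-frame trace")
    return float(trace[onset_index: onset_index + n].sum())


def coupling_ratio(bv_auc: float, ca_auc: float, floor: float = 1e-9) -> float:
    """Neurovascular coupling: oriented (positive) BV AUC over Ca AUC.

    Callers pass the BV AUC already oriented to the blood-volume-positive
    axis.  Returns NaN when the Ca AUC is below the floor (no neural
    response to normalize by).
    """
    if abs(ca_auc) < floor:
        return float("nan")
    return bv_auc / ca_auc


@dataclass
class ConcentrationTrend:
    """Per-subject linear concentration-response slopes and their test."""

    slopes: dict[str, float]
    fold_changes: dict[str, float]
    mean_slope: float
    sd_slope: float
    p_one_sided: float | None
    mean_fold: float
    sd_fold: float
    ci95_slope: tuple[float, float] | None = None


def concentration_slope(
    values: pd.DataFrame,
    metric: str = "value",
    log_scale: bool = False,
) -> ConcentrationTrend:
    """Slope of a response metric versus odor concentration, per subject.

    ``values`` needs columns ``subject``, ``concentration`` (% SVP) and the
    metric column.  Per subject an OLS slope on the linear concentration
    scale (or log10 with ``log_scale=True``) is computed, then a one-sided
    one-sample t-test of slopes > 0 across subjects (skipped, p=None, with
    fewer than 3 subjects).  The fold change is metric(max conc)/metric(min
    conc) per subject, averaging repeats at each concentration.
    """
    slopes: dict[str, float] = {}
    folds: dict[str, float] = {}
    for subject, grp in values.groupby("subject"):
        concs = grp["concentration"].to_numpy(dtype=float)
        if np.unique(concs).size < 2:
            raise ValueError(f"subject {subject} has fewer than 2 concentrations")
        x = np.log10(concs) if log_scale else concs
        y = grp[metric].to_numpy(dtype=float)
        slopes[str(subject)] = float(np.polyfit(x, y, 1)[0])
        by_conc = grp.groupby("concentration")[metric].mean()
        folds[str(subject)] = float(by_conc.loc[by_conc.index.max()] /
                                    by_conc.loc[by_conc.index.min()])
    slope_arr = np.array(list(slopes.values()))
    fold_arr = np.array(list(folds.values()))
    # slopes that are pure floating-point residue of a constant metric
    scale = max(float(np.abs(values[metric]).max()), 1e-30)
    if np.all(np.abs(slope_arr) < 1e-12 * scale):
        slope_arr = np.zeros_like(slope_arr)
        slopes = {k: 0.0 for k in slopes}
    if slope_arr.size >= 3:
        sd = slope_arr.std(ddof=1)
        m = float(slope_arr.mean())
        if sd == 0:  # degenerate: identical slopes, t undefined
            p = 0.5 if m == 0 else (0.0 if m > 0 else 1.0)
            ci = (m, m)
        else:
            p = float(sstats.ttest_1samp(slope_arr, 0.0, alternative="greater").pvalue)
            sem = sd / np.sqrt(slope_arr.size)
            tcrit = sstats.t.ppf(0.975, slope_arr.size - 1)
            ci = (float(m - tcrit * sem), float(m + tcrit * sem))
    else:
        p = None
        ci = None
    return ConcentrationTrend(
        slopes=slopes,
        fold_changes=folds,
        mean_slope=float(slope_arr.mean()),
        sd_slope=float(slope_arr.std(ddof=1)) if slope_arr.size > 1 else 0.0,
        p_one_sided=p,
        mean_fold=float(fold_arr.mean()),
        sd_fold=float(fold_arr.std(ddof=1)) if fold_arr.size > 1 else 0.0,
        ci95_slope=ci,
    )


@dataclass
class AgeTrend:
    """Per-genotype OLS of response AUC against age."""

    slope_auc_per_month: float
    slope_pct_per_month: float
    r_squared: float
    intercept: float
    n: int


def age_regression(
    table: pd.DataFrame,
    metric: str = "auc",
) -> dict[str, AgeTrend]:
    """OLS of a per-mouse AUC against age in months, per genotype group.

    ``table`` needs columns ``subject``, ``age_months``, ``genotype`` and
    the metric.  The normalized slope is expressed as percent of the group
    mean |AUC| per month, alongside the raw slope in AUC units/month.
    """
    out: dict[str, AgeTrend] = {}
    for geno, grp in table.groupby("genotype"):
        if grp["subject"].nunique() < 3:
            raise ValueError(f"group {geno} has fewer than 3 mice")
        ages = grp["age_months"].to_numpy(dtype=float)
        if np.unique(ages).size < 2:
            raise ValueError(f"group {geno} has degenerate ages")
        y = grp[metric].to_numpy(dtype=float)
        res = sstats.linregress(ages, y)
        mean_abs = np.abs(y).mean()
        out[str(geno)] = AgeTrend(
            slope_auc_per_month=float(res.slope),
            slope_pct_per_month=float(100.0 * res.slope / mean_abs) if mean_abs else float("nan"),
            r_squared=float(res.rvalue ** 2),
            intercept=float(res.intercept),
            n=int(len(grp)),
        )
    return out
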