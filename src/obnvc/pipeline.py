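"""End-to-end pipeline: session directory -> masks, traces, fits, metrics.

Stages: load + validate, per-pixel dF/F, per-concentration consistency
masks (two odorants pooled, six trials), ROI-mean traces, exponential
detrend, 25 Hz alignment, GCaMP deconvolution, per-trial transfer-function
fit, and the response-metric table.  The run is a pure function of
(session directory, config): reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AUC_WINDOW_S,
    DETREND_EXCLUDE_S,
    FIT_MAX_ITER,
    FIT_TOL,
    GCAMP_TAU_S,
    HRF_INIT,
    AlignedTrace,
    Channel,
    Hemisphere,
    RoiKind,
    TrialMovie,
    fwhm_empirical,
)
from .hrf import fit_transfer_function, predict_bv
from .metrics import auc, coupling_ratio
from .neural import deconvolve_gcamp
from .preprocess import compute_dff, fit_remove_exponential, resample_align
from .roi import consistency_mask, extract_roi_trace, pixel_response_stats, rect_mask
from .session import read_session, write_mask

# The two consistency rules: threshold multiplier and minimum trial count.
SD_RULES: dict[RoiKind, tuple[float, int]] = {
    RoiKind.SD1: (1.0, 4),
    RoiKind.SD3: (3.0, 3),
}


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, defaulting to the study protocol."""

    roi_kind: RoiKind = RoiKind.SD3
    combine_hemispheres: bool = True
    # Analysis ROI from the highest-concentration trials ("highest") or each
    # trial's own concentration ("per-concentration").  The vessel map is a
    # property of the anatomy, so the default probes it at the best SNR.
    mask_concentration: str = "highest"
    response_metric: str = "mean"          # or "peak"
    auc_window_s: float = AUC_WINDOW_S
    pre_s: float = 4.0
    post_s: float = 15.0
    pad_zeros: int = 100
    tau_decay_s: float = GCAMP_TAU_S
    hrf_init: tuple[float, float, float, float] = HRF_INIT
    fit_tol: float = FIT_TOL
    fit_max_iter: int = FIT_MAX_ITER
    detrend_exclude_s: float = DETREND_EXCLUDE_S
    multistart_seed: int = 0

    def __post_init__(self) -> None:
        self.roi_kind = RoiKind(self.roi_kind)
        self.hrf_init = tuple(self.hrf_init)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["roi_kind"] = self.roi_kind.value
        d["hrf_init"] = list(self.hrf_init)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    out_dir: Path
    fit_table: pd.DataFrame
    metrics_table: pd.DataFrame
    summary: dict
    warnings: list[str] = field(default_factory=list)


def roi_dff_trace(movie: TrialMovie, mask: np.ndarray,
                  baseline_window: tuple[int, int] | None = None) -> np.ndarray:
    """ROI-mean dF/F% trace: per-pixel dF/F restricted to the mask, averaged."""
    onset = movie.onset_frame
    b0, b1 = baseline_window if baseline_window is not None else (0, onset)
    sub = movie.frames[:, mask]
    f0 = sub[b0:b1].mean(axis=0)
    valid = f0 != 0
    if not valid.any():
        raise ValueError("all ROI pixels have zero baseline")
    dff = 100.0 * (sub[:, valid] - f0[valid]) / f0[valid]
    return dff.mean(axis=1)


def _analysis_mask(masks_by_hemi: dict[Hemisphere, "object"], combine: bool) -> np.ndarray:
    arrs = [m.mask for m in masks_by_hemi.values()]
    if combine:
        out = arrs[0] | arrs[1]
    else:
        out = arrs[0]
    return out


def run_pipeline(
    session_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on a session directory and write all artifacts."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    movies, manifest = read_session(session_dir)
    bv_movies = [m for m in movies if m.channel is Channel.BV590]
    ca_by_id = {m.trial_id: m for m in movies if m.channel is Channel.CA488}
    if not bv_movies:
        raise ValueError("session has no BV trials")

    # --- per-concentration consistency masks (odorants pooled) ---
    odor_bv = [m for m in bv_movies if not m.is_control]
    concs = sorted({m.concentration_pct_svp for m in odor_bv})
    masks_by_conc: dict[float, dict[RoiKind, dict]] = {}
    dff_by_id = {}
    for conc in concs:
        group = [m for m in odor_bv if m.concentration_pct_svp == conc]
        dffs = [compute_dff(m) for m in group]
        for m, d in zip(group, dffs):
            dff_by_id[m.trial_id] = d
        stats = pixel_response_stats(dffs, metric=config.response_metric)
        per_kind = {}
        for kind, (k_sd, min_tr) in SD_RULES.items():
            hemis = consistency_mask(stats, k_sd, min_tr)
            per_kind[kind] = hemis
            for hemi, rm in hemis.items():
                if rm.warning:
                    warnings_log.append(
                        f"{kind.value} {hemi.value} mask at {conc}%: {rm.warning}")
                write_mask(rm, out / "masks" /
                           f"{kind.value}_{hemi.value}_c{conc:g}.tif")
        per_kind[RoiKind.RECT] = rect_mask((manifest.height, manifest.width))
        masks_by_conc[conc] = per_kind
    for hemi, rm in rect_mask((manifest.height, manifest.width)).items():
        write_mask(rm, out / "masks" / f"RECT_{hemi.value}.tif")

    # --- per-trial traces, fits and metrics ---
    fit_rows = []
    metric_rows = []
    trace_rows = []
    for m in odor_bv:
        conc = m.concentration_pct_svp
        mask_conc = max(concs) if config.mask_concentration == "highest" else conc
        hemis = masks_by_conc[mask_conc][config.roi_kind]
        mask = _analysis_mask(hemis, config.combine_hemispheres)
        if not mask.any():
            warnings_log.append(f"trial {m.trial_id}: empty analysis mask, skipped")
            continue
        bv_raw = extract_roi_trace(dff_by_id[m.trial_id].values, mask)
        bv_det, bv_info = fit_remove_exponential(
            bv_raw, m.frame_rate_hz, m.odor_onset_s, config.detrend_exclude_s)
        bv_det = bv_det - bv_det[: m.onset_frame].mean()  # re-zero baseline
        if bv_info.fallback_linear:
            warnings_log.append(f"trial {m.trial_id}: BV detrend fell back to linear")
        bv_auc = auc(bv_det, m.onset_frame, m.frame_rate_hz, config.auc_window_s)
        bv_aligned = resample_align(
            bv_det, m.frame_rate_hz, m.odor_onset_s, channel=Channel.BV590,
            pre_s=config.pre_s, post_s=config.post_s, pad_zeros=config.pad_zeros)

        row_metrics = {
            "trial_id": m.trial_id, "odorant": m.odorant, "concentration": conc,
            "subject": m.subject.subject_id, "age_months": m.subject.age_months,
            "genotype": str(m.subject.genotype.value),
            "roi_kind": config.roi_kind.value,
            "bv_auc": bv_auc,
            "bv_peak_dff": float(bv_det[m.onset_frame:].min()),
            "ca_auc": np.nan, "coupling_ratio": np.nan,
        }

        ca = ca_by_id.get(m.trial_id)
        if ca is not None:
            ca_raw = roi_dff_trace(ca, mask)
            ca_det, ca_info = fit_remove_exponential(
                ca_raw, ca.frame_rate_hz, ca.odor_onset_s, config.detrend_exclude_s)
            ca_det = ca_det - ca_det[: ca.onset_frame].mean()
            if ca_info.fallback_linear:
                warnings_log.append(f"trial {m.trial_id}: Ca detrend fell back to linear")
            ca_auc = auc(ca_det, ca.onset_frame, ca.frame_rate_hz, config.auc_window_s)
            ca_aligned = resample_align(
                ca_det, ca.frame_rate_hz, ca.odor_onset_s, channel=Channel.CA488,
                pre_s=config.pre_s, post_s=config.post_s, pad_zeros=config.pad_zeros)
            rate = deconvolve_gcamp(ca_aligned, config.tau_decay_s)
            if np.any(rate.values != rate.unclipped):
                warnings_log.append(f"trial {m.trial_id}: negative rates clipped")
            fit = fit_transfer_function(
                rate, bv_aligned, init=config.hrf_init, tol=config.fit_tol,
                max_iter=config.fit_max_iter,
                multistart_seed=config.multistart_seed)
            if not fit.converged:
                warnings_log.append(f"trial {m.trial_id}: fit did not converge")
            fit_rows.append({
                "trial_id": m.trial_id, "odorant": m.odorant,
                "concentration": conc,
                "y_m": fit.hrf.y_m, "t_m": fit.hrf.t_m,
                "alpha": fit.hrf.alpha, "y_0": fit.hrf.y_0,
                "fwhm_empirical": fwhm_empirical(fit.hrf),
                "gof": fit.gof_max_xcorr, "lag": fit.gof_lag_frames,
                "converged": fit.converged,
                "bound_hit": fit.bound_hit,
                "multistart_used": fit.multistart_used,
            })
            row_metrics["ca_auc"] = ca_auc
            row_metrics["coupling_ratio"] = coupling_ratio(-bv_auc, ca_auc)
            for tr, chan in ((ca_aligned, "CA488"), ):
                times = tr.times()
                for t_s, v in zip(times, tr.values):
                    trace_rows.append((m.trial_id, chan, t_s, v))
            times = ca_aligned.times()
            for t_s, v in zip(times, rate.values):
                trace_rows.append((m.trial_id, "RATE", t_s, v))
        metric_rows.append(row_metrics)
        for t_s, v in zip(bv_aligned.times(), bv_aligned.values):
            trace_rows.append((m.trial_id, "BV590", t_s, v))

    fit_table = pd.DataFrame(fit_rows)
    metrics_table = pd.DataFrame(metric_rows)
    traces = pd.DataFrame(trace_rows,
                          columns=["trial_id", "channel", "time_s", "dff_pct"])

    # --- summary ---
    summary: dict = {"n_bv_trials": len(bv_movies), "n_odor_trials": len(odor_bv),
                     "roi_kind": config.roi_kind.value, "per_concentration": {}}
    for conc in concs:
        sel_m = metrics_table[metrics_table["concentration"] == conc]
        entry = {
            "mean_bv_auc": float(sel_m["bv_auc"].mean()),
            "mean_coupling_ratio": float(sel_m["coupling_ratio"].mean()),
        }
        if not fit_table.empty:
            sel_f = fit_table[fit_table["concentration"] == conc]
            entry.update({
                "mean_gof": float(sel_f["gof"].mean()),
                "mean_y_m": float(sel_f["y_m"].mean()),
                "mean_t_m": float(sel_f["t_m"].mean()),
            })
        summary["per_concentration"][f"{conc:g}"] = entry
    summary["warnings"] = warnings_log

    fit_table.to_csv(out / "fit_table.csv", index=False)
    metrics_table.to_csv(out / "metrics.csv", index=False)
    traces.to_csv(out / "traces.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "report.md").write_text(render_report(summary))
    config.to_yaml(out / "config_used.yaml")
    return PipelineResult(out_dir=out, fit_table=fit_table,
                          metrics_table=metrics_table, summary=summary,
                          warnings=warnings_log)


def render_report(summary: dict) -> str:
    """Markdown summary of a pipeline run."""
    lines = ["# Odor-evoked response analysis report", "",
             f"- BV trials: {summary['n_bv_trials']} "
             f"({summary['n_odor_trials']} odor trials)",
             f"- Analysis ROI: {summary['roi_kind']}", "",
             "| conc (% SVP) | mean BV AUC (%.frames) | mean gof | mean coupling |",
             "|---|---|---|---|"]
    for conc, e in summary["per_concentration"].items():
        gof = e.get("mean_gof", float("nan"))
        lines.append(
            f"| {conc} | {e['mean_bv_auc']:.2f} | {gof:.4f} | "
            f"{e['mean_coupling_ratio']:.3f} |")
    if summary.get("warnings"):
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in summary["warnings"]]
    lines.append("")
    return "\n".join(lines)
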