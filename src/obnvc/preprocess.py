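"""Raw stacks to detrended, onset-aligned dF/F traces.

Pipeline order: per-pixel dF/F against the pre-odor baseline, ROI-mean
extraction (see :mod:`obnvc.roi`), exponential detrend of the ROI trace to
remove LED dimming and photobleaching (fit everywhere except the 13 s
following odor onset), then linear-interpolation resampling to the common
25 Hz grid spanning 4 s pre-odor to 15 s post-odor with 100 appended zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    ALIGN_PAD_ZEROS,
    ALIGN_POST_S,
    ALIGN_PRE_S,
    CA_RATE_HZ,
    DETREND_EXCLUDE_S,
    AlignedTrace,
    Channel,
    TrialMovie,
)


@dataclass
class DffMovie:
    """Per-pixel dF/F (%) stack with its baseline definition.

    ``invalid_f0`` flags pixels whose baseline mean was zero; they carry
    dF/F 0 and must be excluded from ROI construction.
    """

    values: np.ndarray
    baseline_window: tuple[int, int]
    invalid_f0: np.ndarray
    frame_rate_hz: float
    channel: Channel
    odorant: str
    concentration_pct_svp: float
    odor_onset_s: float
    odor_duration_s: float
    trial_id: str = ""
    subject_id: str = ""

    @property
    def onset_frame(self) -> int:
        return int(round(self.odor_onset_s * self.frame_rate_hz))


def compute_dff(movie: TrialMovie, baseline_window: tuple[int, int] | None = None) -> DffMovie:
    """Per-pixel dF/F% = 100 (F - F0)/F0, F0 = mean over the baseline window.

    The default baseline window is every frame before odor onset.
    """
    onset = movie.onset_frame
    if baseline_window is None:
        baseline_window = (0, onset)
    b0, b1 = baseline_window
    if b1 <= b0:
        raise ValueError("baseline window is empty")
    if b1 > onset:
        raise ValueError("baseline window must end at or before odor onset")
    f0 = movie.frames[b0:b1].mean(axis=0)
    invalid = f0 == 0
    if invalid.all():
        raise ValueError("baseline is zero for every pixel")
    f0_safe = np.where(invalid, 1.0, f0)
    dff = 100.0 * (movie.frames - f0) / f0_safe
    dff[:, invalid] = 0.0
    return DffMovie(
        values=dff,
        baseline_window=(b0, b1),
        invalid_f0=invalid,
        frame_rate_hz=movie.frame_rate_hz,
        channel=movie.channel,
        odorant=movie.odorant,
        concentration_pct_svp=movie.concentration_pct_svp,
        odor_onset_s=movie.odor_onset_s,
        odor_duration_s=movie.odor_duration_s,
        trial_id=movie.trial_id,
        subject_id=movie.subject.subject_id,
    )


@dataclass
class DetrendInfo:
    a: float
    tau_s: float
    c: float
    fallback_linear: bool = False


def fit_remove_exponential(
    values: np.ndarray,
    frame_rate_hz: float,
    odor_onset_s: float,
    exclude_after_onset_s: float = DETREND_EXCLUDE_S,
) -> tuple[np.ndarray, DetrendInfo]:
    """Remove LED dimming / photobleach drift from a trace.

    Fits ``a * exp(-t/tau) + c`` by least squares to the samples outside the
    window [odor onset, onset + 13 s], then subtracts the fitted curve and
    adds back ``c`` (equivalently: subtracts only the decaying component),
    preserving the pre-odor mean.  A non-convergent fit falls back to a
    linear detrend and is flagged.
    """
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) / frame_rate_hz
    outside = (t < odor_onset_s) | (t >= odor_onset_s + exclude_after_onset_s)
    if outside.sum() < 10:
        raise ValueError("need at least 10 samples outside the exclusion window")
    tf, yf = t[outside], values[outside]

    def model(tt, a, inv_tau, c):
        return a * np.exp(-tt * inv_tau) + c

    span = yf[: max(3, yf.size // 10)].mean() - yf[-max(3, yf.size // 10):].mean()
    p0 = (span if span != 0 else 1e-3, 1.0 / max(t[-1] / 2.0, 1e-6), yf[-3:].mean())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, tf, yf, p0=p0, maxfev=5000,
                                bounds=([-np.inf, 1e-6, -np.inf],
                                        [np.inf, 100.0, np.inf]))
        a, inv_tau, c = popt
        detrended = values - a * np.exp(-t * inv_tau)
        return detrended, DetrendInfo(a=float(a), tau_s=float(1.0 / inv_tau), c=float(c))
    except (RuntimeError, ValueError):
        slope, intercept = np.polyfit(tf, yf, 1)
        detrended = values - slope * t
        return detrended, DetrendInfo(a=0.0, tau_s=np.inf, c=float(intercept),
                                      fallback_linear=True)


def resample_align(
    values: np.ndarray,
    frame_rate_hz: float,
    odor_onset_s: float,
    channel: Channel = Channel.BV590,
    target_rate_hz: float = CA_RATE_HZ,
    pre_s: float = ALIGN_PRE_S,
    post_s: float = ALIGN_POST_S,
    pad_zeros: int = ALIGN_PAD_ZEROS,
) -> AlignedTrace:
    """Resample to the target rate and align to odor onset, then zero-pad.

    Linear interpolation onto a uniform grid spanning ``[-pre_s, post_s)``
    around onset; with the defaults (19 s at 25 Hz plus 100 zeros) the
    output has 575 samples with onset at index 100.
    """
    values = np.asarray(values, dtype=float)
    t_src = np.arange(values.size) / frame_rate_hz
    n_data = int(round((pre_s + post_s) * target_rate_hz))
    t_out = odor_onset_s - pre_s + np.arange(n_data) / target_rate_hz
    if t_out[0] < t_src[0] - 1e-9 or t_out[-1] > t_src[-1] + 1e-9:
        raise ValueError(
            f"requested window [{t_out[0]:.3f}, {t_out[-1]:.3f}] s exceeds the "
            f"recording [{t_src[0]:.3f}, {t_src[-1]:.3f}] s"
        )
    data = np.interp(t_out, t_src, values)
    out = np.concatenate([data, np.zeros(pad_zeros)])
    return AlignedTrace(
        values=out,
        frame_rate_hz=target_rate_hz,
        t0_index=int(round(pre_s * target_rate_hz)),
        pre_s=pre_s,
        post_s=post_s,
        pad_zeros=pad_zeros,
        channel=channel,
    )
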