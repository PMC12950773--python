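"""Shared domain types and the gamma-variate transfer-function family.

Conventions used throughout the package:

* Image stacks are ``(time, height, width)``, row-major, 0-based.
* Times are seconds from trial start; the blood-volume (BV) channel is
  acquired at 7 Hz, the calcium (Ca) channel at 25 Hz.
* Reflectance dF/F is signed and expressed in percent.  At the 590 nm
  hemoglobin isosbestic point an *increase* in blood volume *decreases*
  reflectance, so BV responses are negative-going in dF/F.
* Discrete convolution is causal, computed as a sum multiplied by the
  sample interval, and truncated to the input length, so convolved traces
  keep units independent of the frame rate.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import brentq


class Channel(str, enum.Enum):
    """Acquisition channel: 590 nm reflectance (BV) or 488 nm GCaMP (Ca)."""

    BV590 = "BV590"
    CA488 = "CA488"


class RoiKind(str, enum.Enum):
    SD1 = "SD1"
    SD3 = "SD3"
    RECT = "RECT"


class Hemisphere(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Genotype(str, enum.Enum):
    WT = "WT"
    A4T2 = "A4T2"


# Acquisition / analysis defaults shared across modules.
BV_RATE_HZ = 7.0
CA_RATE_HZ = 25.0
ODOR_ONSET_S = 8.0
ODOR_DURATION_S = 4.0
TRIAL_DURATION_S = 30.0
GCAMP_TAU_S = 0.25
AUC_WINDOW_S = 10.0
ALIGN_PRE_S = 4.0
ALIGN_POST_S = 15.0
ALIGN_PAD_ZEROS = 100
DETREND_EXCLUDE_S = 13.0
HRF_INIT = (0.8, 4.0, 3.0, 0.2)
FIT_TOL = 1e-10
FIT_MAX_ITER = 700


@dataclass
class Subject:
    """Animal identity with the attributes that modulate response size."""

    subject_id: str
    age_months: float = 12.0
    genotype: Genotype = Genotype.WT

    def __post_init__(self) -> None:
        self.genotype = Genotype(self.genotype)


@dataclass
class TrialMovie:
    """One trial's frame stack plus its acquisition metadata.

    ``frames`` holds nonnegative camera intensities, shape
    ``(n_frames, height, width)``.
    """

    frames: np.ndarray
    frame_rate_hz: float
    channel: Channel
    odorant: str
    concentration_pct_svp: float
    odor_onset_s: float = ODOR_ONSET_S
    odor_duration_s: float = ODOR_DURATION_S
    subject: Subject = field(default_factory=lambda: Subject("unknown"))
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, height, width)")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.odor_onset_s + self.odor_duration_s >= self.duration_s:
            raise ValueError("odor presentation must end before the trial does")
        is_control = self.odorant.lower() == "control"
        if is_control != (self.concentration_pct_svp == 0):
            raise ValueError("concentration is 0 iff odorant is 'control'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.frame_rate_hz

    @property
    def onset_frame(self) -> int:
        return int(round(self.odor_onset_s * self.frame_rate_hz))

    @property
    def is_control(self) -> bool:
        return self.concentration_pct_svp == 0


@dataclass
class RoiMask:
    """Boolean pixel mask for one hemisphere with its construction rule."""

    mask: np.ndarray
    roi_kind: RoiKind
    hemisphere: Hemisphere
    k_sd: float | None = None
    min_trials: int | None = None
    n_trials: int | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        self.roi_kind = RoiKind(self.roi_kind)
        self.hemisphere = Hemisphere(self.hemisphere)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (height, width)")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class AlignedTrace:
    """A dF/F trace aligned to odor onset on a uniform grid, zero padded.

    The data window spans ``pre_s`` before onset through ``post_s`` after,
    then ``pad_zeros`` exact zeros are appended; onset sits at ``t0_index``.
    """

    values: np.ndarray
    frame_rate_hz: float
    t0_index: int
    pre_s: float = ALIGN_PRE_S
    post_s: float = ALIGN_POST_S
    pad_zeros: int = ALIGN_PAD_ZEROS
    channel: Channel = Channel.BV590

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.values = np.asarray(self.values, dtype=float)
        expected = int(round((self.pre_s + self.post_s) * self.frame_rate_hz)) + self.pad_zeros
        if self.values.size != expected:
            raise ValueError(
                f"trace length {self.values.size} != expected {expected} "
                f"({self.pre_s}+{self.post_s} s at {self.frame_rate_hz} Hz "
                f"+ {self.pad_zeros} zeros)"
            )
        if self.t0_index != int(round(self.pre_s * self.frame_rate_hz)):
            raise ValueError("t0_index must equal round(pre_s * frame_rate_hz)")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def n_data(self) -> int:
        return self.values.size - self.pad_zeros

    def times(self) -> np.ndarray:
        """Time axis in seconds relative to odor onset."""
        return (np.arange(self.values.size) - self.t0_index) * self.dt


@dataclass
class GammaHRF:
    """Gamma-variate hemodynamic transfer function.

    Parameters follow the convention that ``y_m`` is the literal peak
    amplitude reached at absolute time ``y_0 + t_m``: ``y_0`` is the onset
    delay (the start of the increase, seconds) and ``t_m`` the time to peak
    measured from the end of the delay.  ``alpha`` sets the shape: larger
    alpha gives a narrower, more symmetric response.
    """

    y_m: float
    t_m: float
    alpha: float
    y_0: float

    def __post_init__(self) -> None:
        if self.t_m <= 0:
            raise ValueError(f"t_m must be positive, got {self.t_m}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.y_0 < 0:
            raise ValueError(f"y_0 must be nonnegative, got {self.y_0}")

    def to_json(self) -> str:
        return json.dumps({"y_m": self.y_m, "t_m": self.t_m,
                           "alpha": self.alpha, "y_0": self.y_0})

    @classmethod
    def from_json(cls, s: str) -> "GammaHRF":
        d = json.loads(s)
        return cls(y_m=d["y_m"], t_m=d["t_m"], alpha=d["alpha"], y_0=d["y_0"])

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.y_m, self.t_m, self.alpha, self.y_0)


@dataclass
class FitResult:
    """Outcome of a transfer-function fit with its goodness of fit."""

    hrf: GammaHRF
    gof_max_xcorr: float
    gof_lag_frames: int
    n_iterations: int
    converged: bool
    residual_norm: float
    bound_hit: bool = False
    multistart_used: bool = False
    gof_flagged: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.gof_max_xcorr <= 1.0 + 1e-12:
            raise ValueError("gof_max_xcorr must lie in [-1, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        d["hrf"] = {"y_m": self.hrf.y_m, "t_m": self.hrf.t_m,
                    "alpha": self.hrf.alpha, "y_0": self.hrf.y_0}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        d = json.loads(s)
        d["hrf"] = GammaHRF(**d["hrf"])
        return cls(**d)


def gamma_variate(t: float | Sequence[float] | np.ndarray, hrf: GammaHRF) -> np.ndarray:
    """Evaluate the gamma-variate transfer function at times ``t`` (seconds).

    h(t) = 0 for t < y_0, otherwise ``y_m * u**alpha * exp(alpha*(1-u))``
    with ``u = (t - y_0)/t_m``.  Peak-normalized: h(y_0 + t_m) = y_m.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    scalar = t_arr.ndim == 0
    u = np.atleast_1d((t_arr - hrf.y_0) / hrf.t_m)
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = hrf.y_m * u[pos] ** hrf.alpha * np.exp(hrf.alpha * (1.0 - u[pos]))
    return out[0] if scalar else out


def fwhm_empirical(hrf: GammaHRF) -> float:
    """Full width at half maximum from the closed-form approximation
    ``(2.454 * alpha**-0.5256) * t_m`` (seconds)."""
    return (2.454 * hrf.alpha ** -0.5256) * hrf.t_m


def fwhm_numeric(hrf: GammaHRF, resolution: float | None = None) -> float:
    """Full width at half maximum found by root-solving the profile.

    Solves ``h(t) = y_m/2`` on each side of the peak by bisection; the
    result is independent of ``y_m`` and ``y_0``.  ``resolution`` bounds the
    bracketing-grid step (default ``t_m/1000``, must be <= t_m/100).
    """
    if resolution is None:
        resolution = hrf.t_m / 1000.0
    if resolution > hrf.t_m / 100.0:
        raise ValueError("resolution must be <= t_m/100")
    a = hrf.alpha

    # In peak-relative units u = (t - y_0)/t_m: g(u) = a*ln u + a*(1-u) - ln(1/2)
    def g(u: float) -> float:
        return a * np.log(u) + a * (1.0 - u) - np.log(0.5)

    step = resolution / hrf.t_m
    # left crossing: g goes from -inf at u->0 to +ln2-related positive at u=1
    lo = step
    while g(lo) > 0:
        lo /= 2.0
    u_left = brentq(g, lo, 1.0)
    # right crossing: g decreases beyond u=1
    hi = 2.0
    while g(hi) > 0:
        hi *= 2.0
    u_right = brentq(g, 1.0, hi)
    return (u_right - u_left) * hrf.t_m


def causal_convolve(x: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    """Causal discrete convolution (sum times dt) truncated to len(x)."""
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    return np.convolve(x, kernel)[: x.size] * dt
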