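"""Firing-rate estimation by inverting the GCaMP6f decay kernel.

The calcium trace is modeled as the firing rate convolved with a single
exponential of time constant 250 ms (the indicator's fluorescence decay);
with the package's convolution convention (causal, sum times dt) the exact
inverse is the two-tap recursive filter

    r[i] = (c[i] - exp(-dt/tau) * c[i-1]) / dt,   c[-1] = 0,

which is O(n), exact for the model, and free of edge artifacts.  The rise
time of the indicator is ignored.  Negative outputs (noise) are clipped by
default, but the unclipped trace is retained because the transfer-function
fit relies on linearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AlignedTrace, GCAMP_TAU_S, causal_convolve


@dataclass
class FiringRateEstimate:
    """Deconvolved rate course (arbitrary units ~ dF/F% per second)."""

    values: np.ndarray
    frame_rate_hz: float
    tau_decay_s: float = GCAMP_TAU_S
    clip_applied: bool = True
    unclipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rate values must be finite")

    @property
    def fit_values(self) -> np.ndarray:
        """The trace the transfer-function fit should use (unclipped)."""
        return self.unclipped if self.unclipped is not None else self.values


def gcamp_kernel(n: int, frame_rate_hz: float, tau_decay_s: float = GCAMP_TAU_S) -> np.ndarray:
    """Sampled indicator decay kernel exp(-t/tau) on an n-point grid."""
    t = np.arange(n) / frame_rate_hz
    return np.exp(-t / tau_decay_s)


def convolve_rate(rate: np.ndarray, frame_rate_hz: float,
                  tau_decay_s: float = GCAMP_TAU_S) -> np.ndarray:
    """Forward model: rate -> calcium trace (causal conv, sum times dt)."""
    rate = np.asarray(rate, dtype=float)
    return causal_convolve(rate, gcamp_kernel(rate.size, frame_rate_hz, tau_decay_s),
                           1.0 / frame_rate_hz)


def deconvolve_gcamp(
    ca_trace: AlignedTrace | np.ndarray,
    tau_decay_s: float = GCAMP_TAU_S,
    clip_negative: bool = True,
    frame_rate_hz: float | None = None,
) -> FiringRateEstimate:
    """Exact inverse of the single-exponential indicator kernel.

    Accepts an :class:`AlignedTrace` (its own rate is used) or a bare array
    with ``frame_rate_hz``.  Convolving the unclipped output with the kernel
    reproduces the input to machine precision.
    """
    if tau_decay_s <= 0:
        raise ValueError("tau_decay_s must be positive")
    if isinstance(ca_trace, AlignedTrace):
        values = ca_trace.values
        rate_hz = ca_trace.frame_rate_hz
    else:
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz required for bare arrays")
        values = np.asarray(ca_trace, dtype=float)
        rate_hz = frame_rate_hz
    dt = 1.0 / rate_hz
    if dt > tau_decay_s:
        warnings.warn(
            f"frame interval {dt:.3f} s exceeds tau {tau_decay_s:.3f} s; "
            "inversion is ill-conditioned at this rate (is this a BV trace?)",
            RuntimeWarning,
        )
    decay = np.exp(-dt / tau_decay_s)
    r = np.empty_like(values, dtype=float)
    r[0] = values[0] / dt
    r[1:] = (values[1:] - decay * values[:-1]) / dt
    clipped = np.clip(r, 0.0, None) if clip_negative else r
    return FiringRateEstimate(
        values=clipped,
        frame_rate_hz=rate_hz,
        tau_decay_s=tau_decay_s,
        clip_applied=clip_negative,
        unclipped=r,
    )
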