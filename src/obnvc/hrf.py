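"""Neurovascular transfer-function estimation.

The blood-volume response is modeled as the estimated firing rate
convolved with a gamma-variate impulse response; the four parameters
(peak amplitude y_m, time to peak t_m, shape alpha, onset delay y_0) are
adjusted by bounded trust-region least squares until the convolution
matches the measured BV trace.  Reflectance BV traces are sign-flipped
("oriented") before fitting so the transfer function is positive-going.
Goodness of fit is the maximum normalized cross-correlation between the
measured and predicted traces over a small lag window.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .core import (
    FIT_MAX_ITER,
    FIT_TOL,
    HRF_INIT,
    AlignedTrace,
    FitResult,
    GammaHRF,
    causal_convolve,
    gamma_variate,
)
from .neural import FiringRateEstimate

# Guardrail bounds for (y_m, t_m [s], alpha, y_0 [s]) on oriented traces.
FIT_BOUNDS_LO = (1e-9, 0.1, 0.2, 0.0)
FIT_BOUNDS_HI = (np.inf, 15.0, 50.0, 5.0)
DEFAULT_MAX_LAG = 12  # ~0.5 s at 25 Hz


def _rate_values(rate) -> tuple[np.ndarray, float]:
    if isinstance(rate, FiringRateEstimate):
        return np.asarray(rate.fit_values, dtype=float), rate.frame_rate_hz
    raise TypeError("rate must be a FiringRateEstimate")


def predict_bv(rate: FiringRateEstimate | np.ndarray, hrf: GammaHRF,
               frame_rate_hz: float | None = None) -> np.ndarray:
    """Oriented BV prediction: causal convolution of rate with the HRF.

    The output is on the oriented (blood-volume-positive) axis; compare it
    against minus the reflectance dF/F.
    """
    if isinstance(rate, FiringRateEstimate):
        values, rate_hz = _rate_values(rate)
    else:
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz required for bare arrays")
        values, rate_hz = np.asarray(rate, dtype=float), frame_rate_hz
    t = np.arange(values.size) / rate_hz
    return causal_convolve(values, gamma_variate(t, hrf), 1.0 / rate_hz)


def goodness_of_fit(
    bv_oriented: np.ndarray,
    predicted: np.ndarray,
    max_lag_frames: int = DEFAULT_MAX_LAG,
) -> tuple[float, int, bool]:
    """Maximum normalized cross-correlation and its lag.

    Both traces are zero-meaned and unit-normed over their full length;
    the correlation is scanned over lags |lag| <= ``max_lag_frames``.
    Zero-variance input yields (0.0, 0) with a flag.
    """
    a = np.asarray(bv_oriented, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    a0 = a - a.mean()
    b0 = b - b.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0 or nb == 0:
        return 0.0, 0, True
    full = np.correlate(a0, b0, mode="full") / (na * nb)
    center = a.size - 1
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    # positive lag: the prediction trails the measurement by that many frames
    window = full[center - lags]
    best = int(np.argmax(window))
    return float(window[best]), int(lags[best]), False


def fit_transfer_function(
    rate: FiringRateEstimate,
    bv_trace: AlignedTrace | np.ndarray,
    init: tuple[float, float, float, float] = HRF_INIT,
    tol: float = FIT_TOL,
    max_iter: int = FIT_MAX_ITER,
    orient: bool = True,
    max_lag_frames: int = DEFAULT_MAX_LAG,
    multistart: bool = True,
    multistart_seed: int = 0,
) -> FitResult:
    """Least-squares gamma-variate fit of the rate->BV transfer function.

    ``orient=True`` flips the reflectance BV trace so blood-volume
    increases are positive before fitting.  The appended zero padding of
    aligned traces participates in the objective.  If the first solve does
    not converge or correlates poorly (gof < 0.5), up to 8 jittered
    restarts (deterministic seed) are tried and the best kept.
    """
    values, rate_hz = _rate_values(rate)
    bv = bv_trace.values if isinstance(bv_trace, AlignedTrace) else np.asarray(bv_trace, float)
    if bv.size != values.size:
        raise ValueError("rate and BV traces must share a grid")
    if not np.all(np.isfinite(values)) or not np.all(np.isfinite(bv)):
        raise ValueError("inputs contain NaNs or infinities")
    if not np.any(values):
        raise ValueError("no neural drive: rate trace is identically zero")
    bv_or = -bv if orient else bv
    t = np.arange(values.size) / rate_hz
    dt = 1.0 / rate_hz

    def residual(p: np.ndarray) -> np.ndarray:
        hrf = GammaHRF(y_m=p[0], t_m=p[1], alpha=p[2], y_0=p[3])
        return causal_convolve(values, gamma_variate(t, hrf), dt) - bv_or

    def solve(x0):
        x0 = np.clip(x0, FIT_BOUNDS_LO, FIT_BOUNDS_HI)
        return least_squares(
            residual, x0, bounds=(FIT_BOUNDS_LO, FIT_BOUNDS_HI),
            method="trf", ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter)

    res = solve(np.asarray(init, dtype=float))
    used_multistart = False
    hrf = GammaHRF(*res.x)
    gof, lag, flagged = goodness_of_fit(bv_or, predict_bv(values, hrf, rate_hz),
                                        max_lag_frames)
    if multistart and (res.status == 0 or gof < 0.5):
        used_multistart = True
        rng = np.random.default_rng(multistart_seed)
        best = (res, gof, lag, flagged)
        for _ in range(8):
            jitter = rng.uniform(0.5, 1.5, size=4)
            cand = solve(np.asarray(init, dtype=float) * jitter)
            if cand.cost < best[0].cost:
                h = GammaHRF(*cand.x)
                g, l, f = goodness_of_fit(
                    bv_or, predict_bv(values, h, rate_hz), max_lag_frames)
                best = (cand, g, l, f)
        res, gof, lag, flagged = best
        hrf = GammaHRF(*res.x)

    lo = np.asarray(FIT_BOUNDS_LO)
    hi = np.asarray(FIT_BOUNDS_HI)
    bound_hit = bool(np.any(np.isclose(res.x, lo, rtol=1e-6, atol=1e-12) |
                            np.isclose(res.x, hi, rtol=1e-6)))
    return FitResult(
        hrf=hrf,
        gof_max_xcorr=float(np.clip(gof, -1.0, 1.0)),
        gof_lag_frames=lag,
        n_iterations=int(res.nfev),
        converged=bool(res.status > 0),
        residual_norm=float(2.0 * res.cost),
        bound_hit=bound_hit,
        multistart_used=used_multistart,
        gof_flagged=flagged,
    )
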