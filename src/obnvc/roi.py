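"""Trial-consistency ROI construction and ROI-mean trace extraction.

Pixels are selected by how consistently they show a blood-volume increase
across the six trials of a concentration (two odorants pooled, three
repetitions each).  Because an increase in blood volume decreases 590 nm
reflectance, "k SD above baseline" is evaluated on the negated dF/F: a
pixel exceeds the threshold in a trial when its response metric is more
negative than -k times its pre-odor dF/F standard deviation (strictly).

Two threshold families are used — 1 SD in at least 4/6 trials, and 3 SD in
at least 3/6 trials (artery-like) — plus an assumption-free rectangular
selection per hemisphere.  Hemispheres split at the vertical midline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AUC_WINDOW_S, Hemisphere, RoiKind, RoiMask
from .preprocess import DffMovie


@dataclass
class PixelResponseStats:
    """Per-pixel, per-trial baseline variability and response size."""

    baseline_sd: np.ndarray      # (n_trials, H, W), dF/F%
    response_metric: np.ndarray  # (n_trials, H, W), dF/F%, signed
    exceed: dict[float, np.ndarray]  # k -> bool (n_trials, H, W)
    invalid_f0: np.ndarray       # (H, W) pixels excluded from all masks
    n_trials: int
    concentration_pct_svp: float

    def exceed_counts(self, k_sd: float) -> np.ndarray:
        return self.exceed[k_sd].sum(axis=0)


def pixel_response_stats(
    dff_trials: Sequence[DffMovie],
    baseline_window: tuple[int, int] | None = None,
    response_window: tuple[int, int] | None = None,
    k_values: Sequence[float] = (1.0, 3.0),
    metric: str = "mean",
) -> PixelResponseStats:
    """Per-trial exceedance statistics over a set of same-concentration trials.

    ``response_metric`` is the mean dF/F over the response window (default:
    odor onset to onset + 10 s, matching the AUC window); ``metric="peak"``
    uses the most negative sample instead.  ``exceed[k]`` is the strict test
    ``-response_metric > k * baseline_sd``.
    """
    if not dff_trials:
        raise ValueError("need at least one trial")
    shape = dff_trials[0].values.shape[1:]
    conc = dff_trials[0].concentration_pct_svp
    for d in dff_trials:
        if d.values.shape[1:] != shape:
            raise ValueError("trial geometries differ")
        if d.concentration_pct_svp != conc:
            raise ValueError("trials must share a concentration")
    n = len(dff_trials)
    baseline_sd = np.empty((n,) + shape)
    response = np.empty((n,) + shape)
    invalid = np.zeros(shape, dtype=bool)
    for i, d in enumerate(dff_trials):
        onset = d.onset_frame
        b0, b1 = baseline_window if baseline_window is not None else (0, onset)
        r0, r1 = (
            response_window
            if response_window is not None
            else (onset, onset + int(round(AUC_WINDOW_S * d.frame_rate_hz)))
        )
        if r1 > d.values.shape[0]:
            raise ValueError("response window exceeds trial length")
        baseline_sd[i] = d.values[b0:b1].std(axis=0, ddof=1)
        if metric == "mean":
            response[i] = d.values[r0:r1].mean(axis=0)
        elif metric == "peak":
            response[i] = d.values[r0:r1].min(axis=0)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        invalid |= d.invalid_f0
    exceed = {float(k): (-response) > (float(k) * baseline_sd) for k in k_values}
    return PixelResponseStats(
        baseline_sd=baseline_sd,
        response_metric=response,
        exceed=exceed,
        invalid_f0=invalid,
        n_trials=n,
        concentration_pct_svp=conc,
    )


def consistency_mask(
    stats: PixelResponseStats,
    k_sd: float,
    min_trials: int,
) -> dict[Hemisphere, RoiMask]:
    """Consistency-thresholded masks, one per hemisphere.

    A pixel is included when it exceeded the ``k_sd`` threshold in at least
    ``min_trials`` of the trials; F0-invalid pixels are never included.
    An empty mask is returned with a warning flag rather than an error.
    """
    if min_trials > stats.n_trials:
        raise ValueError("min_trials exceeds the number of trials")
    counts = stats.exceed_counts(float(k_sd))
    full = (counts >= min_trials) & ~stats.invalid_f0
    kind = RoiKind.SD1 if k_sd == 1 else RoiKind.SD3 if k_sd == 3 else RoiKind.SD1
    h, w = full.shape
    out: dict[Hemisphere, RoiMask] = {}
    for hemi, sl in ((Hemisphere.LEFT, slice(0, w // 2)),
                     (Hemisphere.RIGHT, slice(w // 2, w))):
        m = np.zeros_like(full)
        m[:, sl] = full[:, sl]
        out[hemi] = RoiMask(
            mask=m, roi_kind=kind, hemisphere=hemi,
            k_sd=float(k_sd), min_trials=int(min_trials),
            n_trials=stats.n_trials,
            warning=None if m.any() else "empty mask",
        )
    return out


def rect_mask(
    shape_hw: tuple[int, int],
    bounds_per_hemisphere: dict[Hemisphere, tuple[int, int, int, int]] | None = None,
) -> dict[Hemisphere, RoiMask]:
    """Rectangular no-assumption ROIs, one axis-aligned box per hemisphere.

    Bounds are ``(row0, row1, col0, col1)`` half-open.  The default places a
    box over the central region of each hemisphere (1/8-margin inset).
    """
    h, w = shape_hw
    if bounds_per_hemisphere is None:
        mr, mc = h // 8, w // 16
        half = w // 2
        bounds_per_hemisphere = {
            Hemisphere.LEFT: (mr, h - mr, mc, half - mc),
            Hemisphere.RIGHT: (mr, h - mr, half + mc, w - mc),
        }
    out: dict[Hemisphere, RoiMask] = {}
    for hemi, (r0, r1, c0, c1) in bounds_per_hemisphere.items():
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(
                f"rectangle {(r0, r1, c0, c1)} degenerate or outside the "
                f"{h}x{w} image")
        m = np.zeros(shape_hw, dtype=bool)
        m[r0:r1, c0:c1] = True
        out[Hemisphere(hemi)] = RoiMask(mask=m, roi_kind=RoiKind.RECT,
                                        hemisphere=Hemisphere(hemi))
    return out


def extract_roi_trace(dff_values: np.ndarray, mask: RoiMask | np.ndarray) -> np.ndarray:
    """Unweighted mean over included pixels, per frame."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot extract a trace from an empty mask")
    return np.asarray(dff_values)[:, m].mean(axis=1)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
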