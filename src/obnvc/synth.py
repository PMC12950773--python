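"""Synthetic paired BV/Ca imaging sessions with known ground truth.

The generator emulates the acquisition protocol of an anesthetized-mouse
dorsal olfactory bulb session: per odorant, 3 control trials followed by
9 odor trials (3 concentrations x 3 repetitions), odor presented for 4 s
starting 8 s into a 30 s trial; the blood-volume (reflectance) channel is
sampled at 7 Hz and the calcium channel at 25 Hz.

The forward model per pixel is

    F(t) = baseline * (1 + s(t) * in_mask) * bleach(t) + noise

where for the Ca channel ``s(t)`` is the firing rate convolved with the
GCaMP6f single-exponential decay kernel (positive-going), and for the BV
channel ``s(t)`` is minus the firing rate convolved with a gamma-variate
transfer function (reflectance decreases when blood volume increases).
Responsive pixels form branching vessel-like masks, one per hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    ALIGN_PAD_ZEROS,
    BV_RATE_HZ,
    CA_RATE_HZ,
    GCAMP_TAU_S,
    ODOR_DURATION_S,
    ODOR_ONSET_S,
    TRIAL_DURATION_S,
    Channel,
    GammaHRF,
    Genotype,
    Subject,
    TrialMovie,
    causal_convolve,
    gamma_variate,
)

DEFAULT_CONC_GAIN: dict[float, float] = {0.3: 1.0, 1.0: 1.8, 3.0: 3.2}
AGE_REF_MONTHS = 6.0


def make_firing_rate(
    onset_s: float,
    duration_s: float,
    concentration_pct_svp: float,
    gain: float,
    seed: int | None = None,
    *,
    rate_hz: float = CA_RATE_HZ,
    total_s: float = TRIAL_DURATION_S,
    rise_tau_s: float = 0.15,
    adapt_floor: float = 0.7,
    adapt_tau_s: float = 3.0,
    offset_tau_s: float = 0.5,
) -> np.ndarray:
    """Stereotyped odor-evoked firing-rate time course (arbitrary units).

    Zero before onset, near-complete rise within ~0.5 s, mild adaptation
    toward ``adapt_floor`` of the initial transient during the odor, and an
    exponential return to exactly zero within 3 s after offset.  The peak
    equals ``gain``; a zero concentration (control trial) returns all zeros.
    ``seed`` is accepted for interface symmetry; the course is deterministic.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    r = np.zeros(n)
    if concentration_pct_svp == 0 or gain == 0:
        return r
    offset_s = onset_s + duration_s
    during = (t >= onset_s) & (t < offset_s)
    td = t[during] - onset_s
    env = (1.0 - np.exp(-td / rise_tau_s)) * (
        adapt_floor + (1.0 - adapt_floor) * np.exp(-td / adapt_tau_s)
    )
    r[during] = env
    after = t >= offset_s
    if env.size:
        end_val = env[-1]
        ta = t[after] - offset_s
        tail = end_val * np.exp(-ta / offset_tau_s)
        tail[ta > 3.0] = 0.0
        r[after] = tail
    peak = r.max()
    if peak > 0:
        r *= gain / peak
    return r


def _branching_vessel_mask(
    shape_hw: tuple[int, int],
    col_range: tuple[int, int],
    rng: np.random.Generator,
    n_seeds: int = 2,
    branch_prob: float = 0.03,
) -> np.ndarray:
    """Vessel-like mask: branching random-walk polylines dilated to 2-5 px."""
    h, w = shape_hw
    c0, c1 = col_range
    mask = np.zeros((h, w), dtype=bool)
    span = min(h, c1 - c0)
    n_steps = max(4 * span, 40)
    stack = []
    for _ in range(n_seeds):
        start = np.array([
            rng.uniform(0.25 * h, 0.75 * h),
            rng.uniform(c0 + 0.25 * (c1 - c0), c0 + 0.75 * (c1 - c0)),
        ])
        angle = rng.uniform(0, 2 * np.pi)
        stack.append((start, angle, n_steps))
    while stack:
        pos, angle, steps = stack.pop()
        pos = pos.copy()
        for _ in range(steps):
            angle += rng.normal(0, 0.25)
            pos += np.array([np.sin(angle), np.cos(angle)])
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and c0 <= c < c1):
                break
            mask[r, c] = True
            if rng.random() < branch_prob and steps > 10:
                stack.append((pos.copy(), angle + rng.choice([-1.0, 1.0]) *
                              rng.uniform(0.6, 1.4), steps // 2))
    radius = int(rng.integers(1, 3))  # dilation radius 1-2 -> width ~2-5 px
    struct = ndimage.generate_binary_structure(2, 1)
    mask = ndimage.binary_dilation(mask, structure=struct, iterations=radius)
    mask[:, : c0] = False
    mask[:, c1:] = False
    if not mask.any():  # degenerate walk left the frame immediately
        mask[h // 2, (c0 + c1) // 2] = True
    return mask


@dataclass
class SessionConfig:
    """Acquisition layout and generator parameters for one session."""

    height: int = 256
    width: int = 256
    trial_duration_s: float = TRIAL_DURATION_S
    odor_onset_s: float = ODOR_ONSET_S
    odor_duration_s: float = ODOR_DURATION_S
    odorants: tuple[str, ...] = ("EB", "MV")
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0)
    n_repeats: int = 3
    n_controls: int = 3
    channels: tuple[Channel, ...] = (Channel.BV590, Channel.CA488)
    subject: Subject = field(default_factory=lambda: Subject("sim01", 12.0, Genotype.WT))
    baseline_counts: float = 1000.0
    noise_sd_frac: float = 0.002
    bleach_amp_frac: float = 0.005
    bleach_tau_s: float = 40.0
    ca_tau_s: float = GCAMP_TAU_S
    bv_peak_dff: float = 0.02   # |dF/F| of the BV response at 3% SVP, unit gain
    ca_peak_dff: float = 0.08   # dF/F of the Ca response at 3% SVP, unit gain
    conc_gain: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_CONC_GAIN))
    age_gain_per_month: float = 0.05
    genotype_gain: float = 1.5
    true_hrf: GammaHRF = field(default_factory=lambda: GammaHRF(0.8, 4.0, 3.0, 0.2))
    dtype: str = "float64"

    def __post_init__(self) -> None:
        self.channels = tuple(Channel(c) for c in self.channels)
        gains = [self.conc_gain[c] for c in sorted(self.conc_gain)]
        if any(g <= 0 for g in gains) or any(
            b <= a for a, b in zip(gains, gains[1:])
        ):
            raise ValueError("conc_gain must be positive and strictly increasing")


@dataclass
class TrialMeta:
    """Metadata of one trial slot (shared by its BV and Ca movies)."""

    trial_index: int
    trial_id: str
    odorant: str
    concentration_pct_svp: float
    odor_onset_s: float
    odor_duration_s: float
    subject: Subject


@dataclass
class SessionGroundTruth:
    """Everything the generator injected, for downstream validation."""

    true_hrf: GammaHRF
    ca_tau_s: float
    vessel_masks: dict[str, np.ndarray]   # hemisphere name -> bool (H, W)
    bleach_tau_s: float
    bleach_amp_frac: float
    noise_sd_frac: float
    conc_gain: dict[float, float]
    age_gain_per_month: float
    genotype_gain: float
    seed: int
    config: SessionConfig

    def __post_init__(self) -> None:
        if not any(m.any() for m in self.vessel_masks.values()):
            raise ValueError("vessel masks must be nonempty")
        # dF/F scale factors set so a unit-gain subject at the top
        # concentration reaches the configured peak dF/F in each channel.
        cfg = self.config
        top = max(cfg.concentrations)
        rate = make_firing_rate(
            cfg.odor_onset_s, cfg.odor_duration_s, top, self.conc_gain[top],
            rate_hz=CA_RATE_HZ, total_s=cfg.trial_duration_s)
        t = np.arange(rate.size) / CA_RATE_HZ
        ca_kernel = np.exp(-t / self.ca_tau_s)
        bv_kernel = gamma_variate(t, self.true_hrf)
        self.ca_scale = cfg.ca_peak_dff / causal_convolve(rate, ca_kernel, 1 / CA_RATE_HZ).max()
        self.bv_scale = cfg.bv_peak_dff / causal_convolve(rate, bv_kernel, 1 / CA_RATE_HZ).max()

    @property
    def combined_mask(self) -> np.ndarray:
        out = np.zeros_like(next(iter(self.vessel_masks.values())))
        for m in self.vessel_masks.values():
            out |= m
        return out

    def subject_gain(self, subject: Subject) -> float:
        """Amplitude modifier of the neural drive for one animal.

        The LOAD-model genotype responds more strongly and its response
        grows with age; wild-type animals are age-flat.
        """
        if Genotype(subject.genotype) is Genotype.A4T2:
            g = self.genotype_gain * (
                1.0 + self.age_gain_per_month * (subject.age_months - AGE_REF_MONTHS))
            return max(g, 0.05)
        return 1.0

    def firing_rate(
        self,
        odorant: str,
        concentration_pct_svp: float,
        rate_hz: float = CA_RATE_HZ,
        subject: Subject | None = None,
    ) -> np.ndarray:
        cfg = self.config
        gain = 0.0
        if concentration_pct_svp != 0:
            gain = self.conc_gain[concentration_pct_svp]
            if subject is not None:
                gain *= self.subject_gain(subject)
        return make_firing_rate(
            cfg.odor_onset_s, cfg.odor_duration_s, concentration_pct_svp,
            gain, rate_hz=rate_hz, total_s=cfg.trial_duration_s)

    def expected_fit_ym(self) -> float:
        """Transfer-function amplitude the pipeline should recover.

        The pipeline fits oriented BV dF/F% against the rate deconvolved
        from Ca dF/F%; both carry the generator's channel scale factors, so
        the recoverable amplitude is ``y_m * bv_scale / ca_scale``.
        """
        return self.true_hrf.y_m * self.bv_scale / self.ca_scale


def _bleach_curve(t: np.ndarray, amp_frac: float, tau_s: float, total_s: float) -> np.ndarray:
    if amp_frac == 0:
        return np.ones_like(t)
    decay = (1.0 - np.exp(-t / tau_s)) / (1.0 - np.exp(-total_s / tau_s))
    return 1.0 - amp_frac * decay


def signal_time_course(
    truth: SessionGroundTruth,
    odorant: str,
    concentration_pct_svp: float,
    channel: Channel,
    subject: Subject | None = None,
    rate_hz: float | None = None,
    bv_gain: float = 1.0,
) -> np.ndarray:
    """Noiseless fractional response s(t) of in-mask pixels for one trial.

    ``bv_gain`` scales the vascular (not neural) response only — an extra
    transfer-function amplitude factor for concentration-dependent
    neurovascular-coupling scenarios.
    """
    channel = Channel(channel)
    if rate_hz is None:
        rate_hz = CA_RATE_HZ if channel is Channel.CA488 else BV_RATE_HZ
    rate = truth.firing_rate(odorant, concentration_pct_svp, rate_hz, subject)
    t = np.arange(rate.size) / rate_hz
    if channel is Channel.CA488:
        kernel = np.exp(-t / truth.ca_tau_s)
        return truth.ca_scale * causal_convolve(rate, kernel, 1.0 / rate_hz)
    kernel = gamma_variate(t, truth.true_hrf)
    return -bv_gain * truth.bv_scale * causal_convolve(rate, kernel, 1.0 / rate_hz)


def synthesize_trial(
    truth: SessionGroundTruth,
    meta: TrialMeta,
    channel: Channel,
    rng: np.random.Generator | None = None,
) -> TrialMovie:
    """Render one trial movie from the forward model."""
    channel = Channel(channel)
    cfg = truth.config
    rate_hz = CA_RATE_HZ if channel is Channel.CA488 else BV_RATE_HZ
    if rng is None:
        chan_key = 1 if channel is Channel.CA488 else 0
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=truth.seed,
                                   spawn_key=(meta.trial_index, chan_key)))
    n = int(round(cfg.trial_duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    s = signal_time_course(truth, meta.odorant, meta.concentration_pct_svp,
                           channel, meta.subject, rate_hz)
    bleach = _bleach_curve(t, truth.bleach_amp_frac, truth.bleach_tau_s,
                           cfg.trial_duration_s)
    mask = truth.combined_mask
    base_out = cfg.baseline_counts * bleach
    base_in = base_out * (1.0 + s)
    frames = np.empty((n, cfg.height, cfg.width), dtype=cfg.dtype)
    frames[:] = base_out[:, None, None]
    frames[:, mask] = base_in[:, None]
    if truth.noise_sd_frac > 0:
        noise = rng.normal(0.0, truth.noise_sd_frac * cfg.baseline_counts,
                           size=frames.shape)
        frames += noise.astype(frames.dtype, copy=False)
        np.clip(frames, 0.0, None, out=frames)
    return TrialMovie(
        frames=frames,
        frame_rate_hz=rate_hz,
        channel=channel,
        odorant=meta.odorant,
        concentration_pct_svp=meta.concentration_pct_svp,
        odor_onset_s=meta.odor_onset_s,
        odor_duration_s=meta.odor_duration_s,
        subject=meta.subject,
        trial_id=meta.trial_id,
    )


def synthesize_roi_trace(
    truth: SessionGroundTruth,
    meta: TrialMeta,
    channel: Channel,
    rng: np.random.Generator | None = None,
    n_pixels_equiv: int = 200,
    bv_gain: float = 1.0,
) -> np.ndarray:
    """Raw camera-unit trace of an in-mask ROI mean, without rendering images.

    Noise is scaled by ``1/sqrt(n_pixels_equiv)`` to emulate averaging over
    that many mask pixels.  Used for fast cohort-scale simulation.
    """
    channel = Channel(channel)
    cfg = truth.config
    rate_hz = CA_RATE_HZ if channel is Channel.CA488 else BV_RATE_HZ
    if rng is None:
        chan_key = 1 if channel is Channel.CA488 else 0
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=truth.seed,
                                   spawn_key=(meta.trial_index, chan_key)))
    n = int(round(cfg.trial_duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    s = signal_time_course(truth, meta.odorant, meta.concentration_pct_svp,
                           channel, meta.subject, rate_hz, bv_gain=bv_gain)
    bleach = _bleach_curve(t, truth.bleach_amp_frac, truth.bleach_tau_s,
                           cfg.trial_duration_s)
    trace = cfg.baseline_counts * bleach * (1.0 + s)
    if truth.noise_sd_frac > 0:
        sd = truth.noise_sd_frac * cfg.baseline_counts / np.sqrt(n_pixels_equiv)
        trace = trace + rng.normal(0.0, sd, size=n)
    return trace


def make_ground_truth(config: SessionConfig, seed: int) -> SessionGroundTruth:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    half = config.width // 2
    masks = {
        "LEFT": _branching_vessel_mask((config.height, config.width), (0, half), rng),
        "RIGHT": _branching_vessel_mask((config.height, config.width),
                                        (half, config.width), rng),
    }
    return SessionGroundTruth(
        true_hrf=config.true_hrf,
        ca_tau_s=config.ca_tau_s,
        vessel_masks=masks,
        bleach_tau_s=config.bleach_tau_s,
        bleach_amp_frac=config.bleach_amp_frac,
        noise_sd_frac=config.noise_sd_frac,
        conc_gain=dict(config.conc_gain),
        age_gain_per_month=config.age_gain_per_month,
        genotype_gain=config.genotype_gain,
        seed=seed,
        config=config,
    )


def session_trial_plan(config: SessionConfig) -> list[TrialMeta]:
    """Trial order: per odorant block, controls first then ascending
    concentrations with ``n_repeats`` each."""
    metas: list[TrialMeta] = []
    idx = 0
    for odorant in config.odorants:
        for rep in range(config.n_controls):
            metas.append(TrialMeta(
                trial_index=idx,
                trial_id=f"t{idx:03d}_{odorant}blk_control_r{rep}",
                odorant="control", concentration_pct_svp=0.0,
                odor_onset_s=config.odor_onset_s,
                odor_duration_s=config.odor_duration_s,
                subject=config.subject))
            idx += 1
        for conc in config.concentrations:
            for rep in range(config.n_repeats):
                metas.append(TrialMeta(
                    trial_index=idx,
                    trial_id=f"t{idx:03d}_{odorant}_c{conc:g}_r{rep}",
                    odorant=odorant, concentration_pct_svp=conc,
                    odor_onset_s=config.odor_onset_s,
                    odor_duration_s=config.odor_duration_s,
                    subject=config.subject))
                idx += 1
    return metas


def synthesize_session(
    config: SessionConfig | None = None,
    seed: int = 0,
) -> tuple[list[TrialMovie], SessionGroundTruth]:
    """Generate a full session: every trial slot rendered in each channel.

    With defaults this yields 24 BV trials (3 control + 9 odor per odorant
    block), i.e. 6 trials per nonzero concentration once the two odorants
    are pooled, plus the matching 24 Ca trials.
    """
    if config is None:
        config = SessionConfig()
    truth = make_ground_truth(config, seed)
    movies: list[TrialMovie] = []
    for meta in session_trial_plan(config):
        for channel in config.channels:
            movies.append(synthesize_trial(truth, meta, channel))
    return movies, truth
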