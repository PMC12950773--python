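"""Synthetic-session generator: firing rates, forward model, determinism."""

import numpy as np
import pytest

from obnvc.core import Channel, Genotype, Subject
from obnvc.neural import deconvolve_gcamp
from obnvc.synth import (
    SessionConfig,
    TrialMeta,
    make_firing_rate,
    make_ground_truth,
    session_trial_plan,
    signal_time_course,
    synthesize_session,
    synthesize_trial,
)


class TestFiringRate:
    def test_control_trial_is_silent(self):
        r = make_firing_rate(8, 4, 0.0, 5.0)
        assert np.all(r == 0)

    def test_linear_in_gain(self):
        r1 = make_firing_rate(8, 4, 1.0, 1.0)
        r2 = make_firing_rate(8, 4, 1.0, 2.0)
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-12)

    def test_peak_ratios_follow_concentration_gains(self):
        gains = {0.3: 1.0, 1.0: 1.8, 3.0: 3.2}
        peaks = {c: make_firing_rate(8, 4, c, g).max() for c, g in gains.items()}
        assert peaks[1.0] / peaks[0.3] == pytest.approx(1.8, rel=1e-9)
        assert peaks[3.0] / peaks[0.3] == pytest.approx(3.2, rel=1e-9)

    def test_temporal_envelope(self):
        rate_hz = 25.0
        r = make_firing_rate(8, 4, 1.0, 1.0, rate_hz=rate_hz)
        t = np.arange(r.size) / rate_hz
        assert np.all(r[t < 8] == 0)
        assert r[int(8.5 * rate_hz)] > 0.9 * r.max()   # rises within ~0.5 s
        assert np.all(r[t >= 15.1] == 0)               # silent 3 s after offset
        assert np.all(r >= 0)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            make_firing_rate(8, 4, 1.0, -1.0)


class TestForwardModel:
    def test_control_trial_constant_without_noise(self, clean_truth):
        meta = TrialMeta(0, "ctl", "control", 0.0, 8.0, 4.0, Subject("m0"))
        movie = synthesize_trial(clean_truth, meta, Channel.BV590)
        assert np.all(movie.frames == clean_truth.config.baseline_counts)

    def test_bv_sign_convention(self, clean_truth):
        """Reflectance drops after odor onset: the dF/F extremum is negative
        and occurs after onset."""
        meta = TrialMeta(1, "odor", "EB", 3.0, 8.0, 4.0, Subject("m0"))
        movie = synthesize_trial(clean_truth, meta, Channel.BV590)
        mask = clean_truth.combined_mask
        trace = movie.frames[:, mask].mean(axis=1)
        f0 = trace[: movie.onset_frame].mean()
        dff = (trace - f0) / f0
        assert dff.min() < -0.01
        assert np.argmin(dff) > movie.onset_frame

    def test_ca_roundtrip_recovers_firing_rate(self, clean_truth):
        """Deconvolving the noiseless in-mask calcium mean recovers the
        injected firing-rate course."""
        meta = TrialMeta(2, "odor", "EB", 1.0, 8.0, 4.0, Subject("m0"))
        movie = synthesize_trial(clean_truth, meta, Channel.CA488)
        mask = clean_truth.combined_mask
        trace = movie.frames[:, mask].mean(axis=1)
        s = trace / clean_truth.config.baseline_counts - 1.0
        est = deconvolve_gcamp(s, frame_rate_hz=25.0, clip_negative=False)
        expected = clean_truth.ca_scale * clean_truth.firing_rate("EB", 1.0, 25.0)
        err = np.linalg.norm(est.values - expected) / np.linalg.norm(expected)
        assert err < 1e-3

    def test_linearity_of_extrema_in_drive(self, clean_truth):
        sub = Subject("m0")
        s1 = signal_time_course(clean_truth, "EB", 3.0, Channel.BV590, sub)
        s2 = signal_time_course(clean_truth, "EB", 3.0, Channel.BV590, sub,
                                bv_gain=3.0)
        assert s2.min() == pytest.approx(3 * s1.min(), rel=1e-6)

    def test_bv_kinetics_fast_onset_slow_offset(self, clean_truth):
        """With the default transfer function the BV response starts rising
        within ~1 s of odor onset and its offset outlasts 10 s."""
        s = signal_time_course(clean_truth, "EB", 3.0, Channel.BV590,
                               rate_hz=25.0)
        t = np.arange(s.size) / 25.0
        mag = -s / (-s).max()
        assert mag[np.searchsorted(t, 9.0)] > 0.001  # rising by onset + 1 s
        assert mag[np.searchsorted(t, 11.0)] > 0.2   # well underway by 3 s
        assert mag[np.searchsorted(t, 19.0)] > 0.1   # offset lasts > 10 s

    def test_unknown_channel_rejected(self, clean_truth):
        meta = TrialMeta(0, "x", "EB", 1.0, 8.0, 4.0, Subject("m0"))
        with pytest.raises(ValueError):
            synthesize_trial(clean_truth, meta, "GFP")


class TestSessionLayout:
    def test_trial_counts_and_concentration_pooling(self, small_session):
        movies, _ = small_session
        bv = [m for m in movies if m.channel is Channel.BV590]
        assert len(bv) == 24
        for conc in (0.3, 1.0, 3.0):
            pooled = [m for m in bv if m.concentration_pct_svp == conc]
            assert len(pooled) == 6
            assert {m.odorant for m in pooled} == {"EB", "MV"}

    def test_same_seed_bit_identical(self):
        cfg = SessionConfig(height=8, width=8, channels=(Channel.BV590,))
        a, _ = synthesize_session(cfg, seed=11)
        b, _ = synthesize_session(cfg, seed=11)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.frames, mb.frames)

    def test_seed_changes_noise_not_structure(self):
        cfg = SessionConfig(height=8, width=8, channels=(Channel.BV590,))
        a, ta = synthesize_session(cfg, seed=11)
        b, tb = synthesize_session(cfg, seed=12)
        assert [m.trial_id for m in a] == [m.trial_id for m in b]
        assert ta.true_hrf == tb.true_hrf
        assert any(not np.array_equal(ma.frames, mb.frames)
                   for ma, mb in zip(a, b))

    def test_conc_gain_must_increase(self):
        with pytest.raises(ValueError):
            SessionConfig(conc_gain={0.3: 1.0, 1.0: 0.9, 3.0: 3.0})

    def test_subject_gain_modifiers(self, clean_truth):
        wt = Subject("w", 14.0, Genotype.WT)
        load_young = Subject("a", 6.0, Genotype.A4T2)
        load_old = Subject("b", 16.0, Genotype.A4T2)
        assert clean_truth.subject_gain(wt) == 1.0
        assert clean_truth.subject_gain(load_old) > clean_truth.subject_gain(load_young) > 1.0
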