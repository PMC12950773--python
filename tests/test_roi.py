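"""Consistency-threshold ROI construction and trace extraction."""

import numpy as np
import pytest

from obnvc.core import Channel, Hemisphere, RoiKind
from obnvc.preprocess import DffMovie, compute_dff
from obnvc.roi import (
    consistency_mask,
    extract_roi_trace,
    jaccard,
    pixel_response_stats,
    rect_mask,
)
from obnvc.synth import SessionConfig, synthesize_session


def _dff(values, conc=1.0, onset_s=8.0, rate=7.0):
    values = np.asarray(values, dtype=float)
    return DffMovie(values=values, baseline_window=(0, int(onset_s * rate)),
                    invalid_f0=np.zeros(values.shape[1:], dtype=bool),
                    frame_rate_hz=rate, channel=Channel.BV590, odorant="EB",
                    concentration_pct_svp=conc, odor_onset_s=onset_s,
                    odor_duration_s=4.0)


class TestPixelStats:
    def test_zero_response_sets_no_flags(self):
        rng = np.random.default_rng(0)
        trials = [_dff(rng.normal(0, 0.1, (210, 4, 4))) for _ in range(6)]
        # noise-only: exceedance possible but a zero-noise zero-response
        # trial set must produce none
        quiet = [_dff(np.zeros((210, 4, 4))) for _ in range(6)]
        stats = pixel_response_stats(quiet)
        assert not stats.exceed[1.0].any()
        assert not stats.exceed[3.0].any()
        stats_noise = pixel_response_stats(trials)
        assert stats_noise.exceed[3.0].sum() <= stats_noise.exceed[1.0].sum()

    def test_boundary_is_strict(self):
        """A response of exactly -k*SD must NOT be flagged."""
        sd = np.sqrt(2.0)  # ddof=1 SD of the two-sample baseline {+1, -1}
        for k in (1.0, 3.0):
            vals = np.zeros((10, 1, 1))
            vals[0, 0, 0], vals[1, 0, 0] = 1.0, -1.0
            vals[5:, 0, 0] = -k * sd
            stats = pixel_response_stats([_dff(vals)], baseline_window=(0, 2),
                                         response_window=(5, 10))
            assert not stats.exceed[k][0, 0, 0]
            vals[5:, 0, 0] = -k * sd - 1e-9
            stats = pixel_response_stats([_dff(vals)], baseline_window=(0, 2),
                                         response_window=(5, 10))
            assert stats.exceed[k][0, 0, 0]

    def test_three_sd_implies_one_sd(self):
        rng = np.random.default_rng(2)
        trials = [_dff(rng.normal(0, 0.2, (210, 6, 6)) - 0.3) for _ in range(6)]
        stats = pixel_response_stats(trials)
        assert np.all(stats.exceed[1.0] | ~stats.exceed[3.0])

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometr"):
            pixel_response_stats([_dff(np.zeros((210, 4, 4))),
                                  _dff(np.zeros((210, 5, 4)))])


class TestConsistencyMask:
    def _stats_with_counts(self, counts_k1, counts_k3, shape=(4, 4)):
        """Build stats whose per-pixel exceedance counts are prescribed."""
        n = 6
        exceed1 = np.zeros((n,) + shape, dtype=bool)
        exceed3 = np.zeros((n,) + shape, dtype=bool)
        for (r, c), m in counts_k1.items():
            exceed1[:m, r, c] = True
        for (r, c), m in counts_k3.items():
            exceed3[:m, r, c] = True
        from obnvc.roi import PixelResponseStats
        return PixelResponseStats(
            baseline_sd=np.ones((n,) + shape),
            response_metric=np.zeros((n,) + shape),
            exceed={1.0: exceed1, 3.0: exceed3},
            invalid_f0=np.zeros(shape, dtype=bool),
            n_trials=n, concentration_pct_svp=1.0)

    def test_paper_rules(self):
        stats = self._stats_with_counts({(0, 0): 4, (1, 1): 3}, {(2, 2): 3})
        sd1 = consistency_mask(stats, 1.0, 4)
        union1 = sd1[Hemisphere.LEFT].mask | sd1[Hemisphere.RIGHT].mask
        assert union1[0, 0]            # 4/6 at 1 SD: included
        assert not union1[1, 1]        # 3/6 at 1 SD: excluded
        sd3 = consistency_mask(stats, 3.0, 3)
        union3 = sd3[Hemisphere.LEFT].mask | sd3[Hemisphere.RIGHT].mask
        assert union3[2, 2]            # 3/6 at 3 SD: included

    def test_monotone_in_threshold_and_count(self):
        rng = np.random.default_rng(3)
        trials = [_dff(rng.normal(-0.15, 0.2, (210, 8, 8))) for _ in range(6)]
        stats = pixel_response_stats(trials)

        def union(k, m):
            d = consistency_mask(stats, k, m)
            return d[Hemisphere.LEFT].mask | d[Hemisphere.RIGHT].mask

        for m in (2, 3, 4, 5):
            assert np.all(union(1.0, m + 1) <= union(1.0, m))
            assert np.all(union(3.0, m) <= union(1.0, m))

    def test_empty_mask_warns_not_raises(self):
        stats = self._stats_with_counts({}, {})
        masks = consistency_mask(stats, 3.0, 3)
        assert all(m.is_empty and m.warning for m in masks.values())

    def test_hemisphere_split_at_midline(self):
        stats = self._stats_with_counts({(0, 0): 6, (0, 3): 6}, {})
        masks = consistency_mask(stats, 1.0, 4)
        assert masks[Hemisphere.LEFT].mask[0, 0]
        assert not masks[Hemisphere.LEFT].mask[0, 3]
        assert masks[Hemisphere.RIGHT].mask[0, 3]


class TestRectMask:
    def test_full_hemisphere_cardinality(self):
        h, w = 16, 16
        masks = rect_mask((h, w), {Hemisphere.LEFT: (0, h, 0, w // 2),
                                   Hemisphere.RIGHT: (0, h, w // 2, w)})
        assert masks[Hemisphere.LEFT].n_pixels == h * w // 2
        assert masks[Hemisphere.RIGHT].n_pixels == h * w // 2

    def test_default_two_rectangles(self):
        masks = rect_mask((64, 64))
        assert set(masks) == {Hemisphere.LEFT, Hemisphere.RIGHT}
        for m in masks.values():
            assert m.roi_kind is RoiKind.RECT and m.n_pixels > 0

    def test_degenerate_or_outside_rejected(self):
        with pytest.raises(ValueError):
            rect_mask((16, 16), {Hemisphere.LEFT: (0, 0, 0, 8)})
        with pytest.raises(ValueError):
            rect_mask((16, 16), {Hemisphere.LEFT: (0, 20, 0, 8)})


class TestTraceExtraction:
    def test_single_pixel_and_uniform(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (50, 4, 4))
        single = np.zeros((4, 4), dtype=bool)
        single[2, 3] = True
        np.testing.assert_array_equal(extract_roi_trace(vals, single),
                                      vals[:, 2, 3])
        uniform = np.repeat(vals[:, :1, :1], 4, axis=1).repeat(4, axis=2)
        np.testing.assert_allclose(
            extract_roi_trace(uniform, np.ones((4, 4), dtype=bool)),
            uniform[:, 0, 0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_trace(np.zeros((10, 4, 4)), np.zeros((4, 4), dtype=bool))


@pytest.fixture(scope="module")
def high_snr_stats():
    """Six 3%-odor BV trials at per-pixel SNR 20 (peak 2% vs 0.1% noise)."""
    cfg = SessionConfig(height=32, width=32, concentrations=(3.0,),
                        channels=(Channel.BV590,), noise_sd_frac=0.001,
                        dtype="float32")
    movies, truth = synthesize_session(cfg, seed=42)
    odor = [m for m in movies if not m.is_control]
    assert len(odor) == 6
    stats = pixel_response_stats([compute_dff(m) for m in odor])
    return stats, truth


class TestVesselRecovery:

    def test_sd3_mask_matches_vessel_truth(self, high_snr_stats):
        stats, truth = high_snr_stats
        masks = consistency_mask(stats, 3.0, 3)
        union = masks[Hemisphere.LEFT].mask | masks[Hemisphere.RIGHT].mask
        assert jaccard(union, truth.combined_mask) >= 0.8

    def test_flags_cover_vessel_pixels(self, high_snr_stats):
        stats, truth = high_snr_stats
        vessel = truth.combined_mask
        for trial in range(stats.n_trials):
            frac = stats.exceed[1.0][trial][vessel].mean()
            assert frac >= 0.95
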