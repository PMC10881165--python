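"""Colocalization: bleed-through correction, Costes auto-thresholds,
Manders coefficients, profile offsets, density partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from svquant import coloc
from svquant.synthetic import ImageSpec, gen_two_channel_image


class TestBleedthrough:
    def test_zero_fraction_is_median_filter_only(self, rng):
        img = rng.uniform(0, 100, (16, 16))
        src = rng.uniform(0, 100, (16, 16))
        out = coloc.bleedthrough_correct(img, src, 0.0)
        np.testing.assert_allclose(out, ndimage.median_filter(img, size=3))

    def test_exact_cancellation(self, rng):
        src = rng.uniform(10, 100, (16, 16))
        target = 0.2 * src
        out = coloc.bleedthrough_correct(target, src, 20.0)
        # median filter commutes with scaling, so residual is ~0
        assert np.abs(out).max() < 1e-9

    def test_clipped_at_zero(self, rng):
        src = np.full((8, 8), 100.0)
        target = np.full((8, 8), 5.0)
        out = coloc.bleedthrough_correct(target, src, 50.0)
        assert (out >= 0).all()

    @pytest.mark.parametrize("bad", [100.0, 150.0, -1.0])
    def test_out_of_range_fraction_rejected(self, bad, rng):
        img = rng.uniform(0, 1, (4, 4))
        with pytest.raises(ValueError):
            coloc.bleedthrough_correct(img, img, bad)


def costes_exhaustive_oracle(ref, oth):
    """Independent exhaustive scan: PCC at every discrete intensity level."""
    ref = ref.ravel().astype(float)
    oth = oth.ravel().astype(float)
    gain, offset = np.polyfit(ref, oth, 1)
    for T in np.unique(ref)[::-1]:
        mask = (ref < T) & (oth < gain * T + offset)
        sub_r, sub_o = ref[mask], oth[mask]
        if sub_r.size < 2 or np.ptp(sub_r) == 0 or np.ptp(sub_o) == 0:
            continue
        if np.corrcoef(sub_r, sub_o)[0, 1] <= 0:
            return float(T), float(gain * T + offset)
    return float(ref.min()), float(gain * ref.min() + offset)


@pytest.fixture(scope="module")
def blob_pair():
    """8-bit two-channel fixture: correlated foreground blobs over
    independent background noise."""
    rng = np.random.default_rng(11)
    yy, xx = np.mgrid[0:64, 0:64]
    fg = np.zeros((64, 64))
    for cy, cx in [(16, 16), (40, 30), (22, 50)]:
        fg += 180 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 40)
    ref = np.clip(fg + rng.uniform(0, 30, fg.shape), 0, 255).astype(np.uint8)
    oth = np.clip(0.8 * fg + rng.uniform(0, 30, fg.shape), 0, 255).astype(np.uint8)
    return ref, oth


class TestCostesThresholds:
    def test_matches_exhaustive_scan_oracle(self, blob_pair):
        ref, oth = blob_pair
        res = coloc.costes_thresholds(ref, oth, n_levels=10_000)
        t_ref, t_oth = costes_exhaustive_oracle(ref, oth)
        assert res.threshold_ref == t_ref
        assert res.threshold_other == pytest.approx(t_oth)
        assert not res.flagged

    def test_threshold_separates_foreground_from_background(self, blob_pair):
        ref, oth = blob_pair
        res = coloc.costes_thresholds(ref, oth, n_levels=10_000)
        # the threshold must sit below every blob core (all retained) and
        # inside the background intensity range (uniform below 30): the
        # correlated Gaussian tails legitimately drag it below the
        # background ceiling
        assert 0 < res.threshold_ref <= 30
        for cy, cx in [(16, 16), (40, 30), (22, 50)]:
            assert ref[cy, cx] > res.threshold_ref
            assert oth[cy, cx] > res.threshold_other

    def test_independent_noise_thresholds_near_max(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        b = rng.uniform(0, 255, (64, 64))
        res = coloc.costes_thresholds(a, b)
        # no correlated signal: PCC ~ 0 immediately, background everywhere
        assert res.threshold_ref > np.percentile(a, 90)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError):
            coloc.costes_thresholds(np.ones((8, 8)), np.zeros((8, 8)))


class TestManders:
    def test_hand_example(self):
        m1, m2 = coloc.manders(
            np.array([0.0, 10.0, 10.0]), np.array([10.0, 0.0, 10.0]), 5.0, 5.0
        )
        assert m1 == pytest.approx(0.5)
        assert m2 == pytest.approx(0.5)

    def test_identical_channels_give_unity(self, rng):
        a = rng.uniform(10, 100, (16, 16))
        m1, m2 = coloc.manders(a, a, 5.0, 5.0)
        assert m1 == pytest.approx(1.0)
        assert m2 == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.array([10.0, 10.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 10.0, 10.0])
        m1, m2 = coloc.manders(a, b, 5.0, 5.0)
        assert m1 == 0.0 and m2 == 0.0

    def test_no_signal_flagged_as_missing(self):
        with pytest.warns(UserWarning, match="zero above-threshold"):
            m1, _ = coloc.manders(np.zeros(4), np.ones(4) * 10, 5.0, 5.0)
        assert np.isnan(m1)

    @given(
        a=hnp.arrays(np.float64, (25,), elements=st.floats(0, 100)),
        b=hnp.arrays(np.float64, (25,), elements=st.floats(0, 100)),
        thr=st.floats(0, 60),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_symmetry(self, a, b, thr):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1, m2 = coloc.manders(a, b, thr, thr)
            m2_swap, m1_swap = coloc.manders(b, a, thr, thr)
        for v in (m1, m2):
            assert np.isnan(v) or 0.0 <= v <= 1.0
        np.testing.assert_equal(m1, m1_swap)
        np.testing.assert_equal(m2, m2_swap)


class TestProfileOffset:
    def _gauss_image(self, center_col, n=64):
        yy, xx = np.mgrid[0:n, 0:n]
        return np.exp(-((xx - center_col) ** 2) / 30.0)

    def test_identical_channels_zero_offset(self):
        img = self._gauss_image(32.0)
        res = coloc.profile_offset(img, img, [(0.0, 3.2), (6.3, 3.2)], 0.1)
        assert res.offset_um == pytest.approx(0.0, abs=1e-9)

    def test_known_shift_recovered(self):
        ref = self._gauss_image(30.0)
        oth = self._gauss_image(31.0)  # 1 px = 0.10 µm shift
        res = coloc.profile_offset(ref, oth, [(0.0, 3.2), (6.3, 3.2)], 0.1)
        assert res.offset_um == pytest.approx(0.10, abs=0.1)

    def test_translation_equivariance(self):
        ref = self._gauss_image(28.0)
        line = [(0.0, 3.2), (6.3, 3.2)]
        base = coloc.profile_offset(ref, self._gauss_image(28.0), line, 0.1)
        shifted = coloc.profile_offset(ref, self._gauss_image(33.0), line, 0.1)
        assert shifted.offset_um - base.offset_um == pytest.approx(0.5, abs=0.05)

    def test_plateau_peak_resolves_to_centroid(self):
        n = 64
        img = np.zeros((n, n))
        img[:, 20:31] = 5.0  # flat-topped band, centroid at column 25
        ref = self._gauss_image(25.0)
        res = coloc.profile_offset(ref, img, [(0.0, 3.2), (6.3, 3.2)], 0.1)
        assert res.offset_um == pytest.approx(0.0, abs=0.05)

    def test_flat_profile_flagged(self):
        flat = np.ones((32, 32))
        res = coloc.profile_offset(flat, flat, [(0.0, 1.6), (3.1, 1.6)], 0.1)
        assert res.flagged
        assert np.isnan(res.offset_um)


class TestDensityPartition:
    def test_uniform_signal_ratio_100(self, rng):
        n = 64
        marker = rng.uniform(0, 1, (n, n))
        marker[20:30, 20:30] += 10.0  # segmentable bright region
        signal = np.full((n, n), 7.0)
        mask = np.ones((n, n), bool)
        res = coloc.density_partition(signal, marker, mask, 0.2)
        assert res.ratio_pct == pytest.approx(100.0, abs=1e-6)

    def test_signal_confined_to_marker_blobs_ratio_near_zero(self):
        n = 64
        marker = np.zeros((n, n))
        marker[10:20, 10:20] = 100.0
        signal = np.where(marker > 50, 80.0, 0.0)
        mask = np.ones((n, n), bool)
        res = coloc.density_partition(signal, marker, mask, 0.2)
        assert res.ratio_pct == pytest.approx(0.0, abs=1e-6)

    def test_constant_marker_flagged(self):
        res = coloc.density_partition(
            np.ones((8, 8)), np.ones((8, 8)), np.ones((8, 8), bool), 0.2
        )
        assert res.flagged

    def test_generator_ground_truth_recovered(self):
        spec = ImageSpec(seed=5, density_ratio=0.2, snr=10.0)
        stack, truth = gen_two_channel_image(spec)
        res = coloc.density_partition(
            stack.channel("signal"),
            stack.channel("marker"),
            truth["axon_mask"],
            stack.pixel_size_um,
            seed=5,
        )
        assert res.ratio_pct == pytest.approx(20.0, abs=5.0)
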