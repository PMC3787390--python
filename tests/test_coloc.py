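"""Background thresholding, spot detection, classification, Pearson."""

import numpy as np
import pytest

from vesishape import (
    Image2D,
    PSFSpec,
    classify_spots,
    detect_spots,
    estimate_threshold,
    make_psf,
    pearson,
)
from vesishape.errors import (
    InsufficientBackgroundError,
    InvalidSpecError,
    ShapeMismatchError,
    ZeroVarianceError,
)


def _flat(value, shape=(128, 128), px=5.0):
    return Image2D(np.full(shape, float(value)), px)


def _spot_image(peak, at=(64, 64), shape=(128, 128), bg=0.0, px=5.0):
    """One Lorentzian-PSF-shaped spot of the given raw peak height."""
    k = make_psf(PSFSpec("lorentzian", 80.0), px).values
    img = np.full(shape, float(bg))
    r = k.shape[0] // 2
    for dx in range(-r, r + 1):
        x = at[0] + dx
        if not 0 <= x < shape[0]:
            continue
        y0 = max(0, at[1] - r)
        y1 = min(shape[1], at[1] + r + 1)
        img[x, y0:y1] += peak * k[dx + r, (y0 - at[1] + r) : (y1 - at[1] + r)] / k.max()
    return Image2D(img, px)


class TestEstimateThreshold:
    def test_constant_image(self):
        est = estimate_threshold(_flat(3.0), n_rois=100, roi_size=10, rng_seed=0)
        assert est.roi_maxima_mean == 3.0
        assert est.roi_maxima_sd == 0.0
        assert est.cutoff == 3.0
        assert est.n_rois == 100

    def test_poisson_background_matches_monte_carlo_oracle(self, rng):
        """Mean cutoff over repeats ~ E[max of roi^2 Poisson draws] + SD."""
        roi, rate = 10, 10.0
        # independent oracle: direct draws of the ROI max statistic
        draws = rng.poisson(rate, size=(200000, roi * roi)).max(axis=1)
        oracle = draws.mean() + draws.std(ddof=1)
        cutoffs = []
        for i in range(400):
            img = Image2D(rng.poisson(rate, size=(256, 256)).astype(float), 5.0)
            cutoffs.append(estimate_threshold(img, 100, roi, rng_seed=i).cutoff)
        cutoffs = np.asarray(cutoffs)
        assert cutoffs.mean() > rate
        se = np.sqrt(cutoffs.var(ddof=1) / cutoffs.size + draws.var(ddof=1) / draws.size)
        assert abs(cutoffs.mean() - oracle) < 3 * se + 0.02

    def test_cutoff_increases_with_roi_size(self, rng):
        img = Image2D(rng.poisson(10.0, size=(256, 256)).astype(float), 5.0)
        small = np.mean([estimate_threshold(img, 100, 5, rng_seed=i).cutoff for i in range(20)])
        large = np.mean([estimate_threshold(img, 100, 20, rng_seed=i).cutoff for i in range(20)])
        assert large > small

    def test_exclusion_mask_blocks_placement(self):
        mask = np.ones((64, 64), dtype=bool)
        with pytest.raises(InsufficientBackgroundError):
            estimate_threshold(_flat(1.0, (64, 64)), 10, 8, exclusion_mask=mask, rng_seed=0)

    def test_rois_avoid_masked_signal(self):
        img = np.ones((128, 128))
        img[40:60, 40:60] = 100.0
        mask = img > 1.0
        est = estimate_threshold(Image2D(img, 5.0), 100, 10, exclusion_mask=mask, rng_seed=1)
        assert est.cutoff == 1.0  # never sampled the bright block


class TestDetectSpots:
    def test_single_spot_detected_at_center(self):
        img = _spot_image(50.0, at=(64, 70))
        centers = detect_spots(img, cutoff=5.0, min_separation=160.0)
        assert centers.shape == (1, 2)
        assert abs(centers[0, 0] - (64 + 0.5) * 5.0) <= 5.0
        assert abs(centers[0, 1] - (70 + 0.5) * 5.0) <= 5.0

    def test_two_separated_spots(self):
        img = Image2D(
            _spot_image(50.0, at=(30, 30)).values + _spot_image(40.0, at=(30, 126)).values,
            5.0,
        )
        centers = detect_spots(img, cutoff=5.0, min_separation=160.0)
        assert centers.shape[0] == 2
        # ordered by decreasing intensity: brightest first
        assert centers[0, 1] < centers[1, 1]

    def test_all_below_cutoff_returns_empty(self):
        assert detect_spots(_flat(1.0), cutoff=5.0, min_separation=100.0).shape == (0, 2)

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(InvalidSpecError):
            detect_spots(_flat(1.0), cutoff=np.inf, min_separation=100.0)


class TestClassifySpots:
    @pytest.fixture()
    def single_spot_scene(self):
        ref = _spot_image(120.0, at=(64, 64), bg=1.0)
        a = _spot_image(80.0, at=(64, 64), bg=1.0)
        b = _flat(1.0)
        return ref, a, b

    def test_a_only_assignment(self, single_spot_scene):
        ref, a, b = single_spot_scene
        summary = classify_spots(ref, a, b, cutoffs={"A": 5.0, "B": 5.0})
        assert summary.counts == {"A_only": 1, "B_only": 0, "both": 0}
        assert summary.fractions["A_only"] == pytest.approx(1.0)

    def test_both_assignment_and_fraction_sum(self, single_spot_scene):
        ref, a, _ = single_spot_scene
        b = _spot_image(60.0, at=(64, 64), bg=1.0)
        summary = classify_spots(ref, a, b, cutoffs={"A": 5.0, "B": 5.0})
        assert summary.counts["both"] == 1
        assert sum(summary.fractions.values()) == pytest.approx(1.0)

    def test_oversized_spot_excluded(self):
        # an elongated spot (major FWHM 250 nm >= 150 gate) must be excluded
        from vesishape.fitting import _evaluate

        ax = (np.arange(128) + 0.5) * 5.0
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        vals = _evaluate(np.array([200.0, 1.0, ax[64], ax[64], 250.0, 90.0, 0.0]), xx, yy, "lorentzian")
        ref = Image2D(vals, 5.0)
        a = _spot_image(80.0, at=(64, 64), bg=1.0)
        b = _flat(1.0)
        summary = classify_spots(ref, a, b, cutoffs={"A": 5.0, "B": 5.0})
        assert summary.n_excluded_by_size == 1
        assert sum(summary.counts.values()) == 0

    def test_shape_mismatch_and_missing_cutoffs(self, single_spot_scene):
        ref, a, b = single_spot_scene
        with pytest.raises(ShapeMismatchError):
            classify_spots(ref, a, _flat(1.0, (64, 64)), cutoffs={"A": 1.0, "B": 1.0})
        with pytest.raises(InvalidSpecError):
            classify_spots(ref, a, b, cutoffs={"A": 1.0})


class TestPearson:
    def test_identical_images(self, rng):
        img = Image2D(rng.poisson(10.0, size=(64, 64)).astype(float), 5.0)
        assert pearson(img, img) == pytest.approx(1.0)

    def test_anticorrelated_images(self, rng):
        a = Image2D(rng.poisson(10.0, size=(64, 64)).astype(float), 5.0)
        b = Image2D(30.0 - a.values, 5.0)
        assert pearson(a, b) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = Image2D(r.poisson(10.0, size=(100, 100)).astype(float), 5.0)
            b = Image2D(r.poisson(10.0, size=(100, 100)).astype(float), 5.0)
            assert abs(pearson(a, b)) < 0.05

    def test_affine_invariance(self, rng):
        a = Image2D(rng.poisson(10.0, size=(64, 64)).astype(float), 5.0)
        b = Image2D(rng.poisson(10.0, size=(64, 64)).astype(float), 5.0)
        base = pearson(a, b)
        scaled = pearson(Image2D(3.0 * a.values + 7.0, 5.0), b)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_mask_and_errors(self, rng):
        a = Image2D(rng.poisson(10.0, size=(64, 64)).astype(float), 5.0)
        mask = np.zeros((64, 64), dtype=bool)
        mask[:32] = True
        assert -1.0 <= pearson(a, a, mask=mask) <= 1.0
        with pytest.raises(ZeroVarianceError):
            pearson(a, _flat(2.0, (64, 64)))
        with pytest.raises(ShapeMismatchError):
            pearson(a, _flat(2.0, (32, 32)))
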