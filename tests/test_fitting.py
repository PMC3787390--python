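"""Elliptical spot fitting: recovery, size/shape statistics, summaries."""

import numpy as np
import pytest

from vesishape import (
    GridParams,
    Image2D,
    NoiseParams,
    PSFSpec,
    StructureSpec,
    axis_ratio,
    fit_spot,
    image_structure,
    project,
    render_structure,
    sample_orientation,
    spot_size,
    summarize_sizes,
    tubule,
    vesicle,
)
from vesishape.errors import FlatImageError, InvalidSpecError, NotConvergedError
from vesishape.fitting import SpotFit, _evaluate


def _render_model(params, n=121, px=5.0, model="lorentzian"):
    ax = (np.arange(n) + 0.5) * px
    x, y = np.meshgrid(ax, ax, indexing="ij")
    return Image2D(_evaluate(np.asarray(params, float), x, y, model), px)


def _circular_fit(f):
    return SpotFit((0.0, 0.0), f, f, 0.0, 1.0, 0.0, True, 0.0)


class TestFitSpot:
    def test_point_source_recovers_psf_fwhm(self, point_source_frame):
        fit = fit_spot(point_source_frame, "lorentzian")
        assert fit.converged
        size = spot_size(fit, "geometric_mean")
        assert size == pytest.approx(80.0, rel=0.02)
        assert axis_ratio(fit) <= 1.02

    def test_flat_image_raises(self):
        with pytest.raises(FlatImageError):
            fit_spot(Image2D(np.full((32, 32), 7.0), 5.0))
        with pytest.raises(FlatImageError):
            fit_spot(Image2D(np.full((32, 32), np.nan), 5.0))

    @pytest.mark.parametrize("model", ["lorentzian", "gaussian"])
    def test_elliptical_parameters_recovered_within_1_percent(self, model):
        px = 5.0
        center = (60 + 0.5) * px
        true = [7.0, 1.0, center, center, 140.0, 100.0, 0.6]
        fit = fit_spot(_render_model(true, model=model), model, crop_px=None)
        assert fit.converged
        assert fit.fwhm_major == pytest.approx(140.0, rel=0.01)
        assert fit.fwhm_minor == pytest.approx(100.0, rel=0.01)
        assert fit.theta == pytest.approx(0.6, abs=0.01)
        assert fit.amplitude == pytest.approx(7.0, rel=0.01)
        assert fit.center[0] == pytest.approx(center, abs=px / 2)

    def test_round_trip_refit_is_stable(self):
        px = 5.0
        true = [5.0, 0.5, 300.0, 310.0, 130.0, 90.0, 1.1]
        first = fit_spot(_render_model(true), "lorentzian", crop_px=None)
        rendered = _render_model(
            [first.amplitude, first.offset, *first.center, first.fwhm_major,
             first.fwhm_minor, first.theta]
        )
        second = fit_spot(rendered, "lorentzian", crop_px=None)
        assert second.fwhm_major == pytest.approx(first.fwhm_major, rel=0.005)
        assert second.fwhm_minor == pytest.approx(first.fwhm_minor, rel=0.005)

    def test_vesicle_size_monotonic_in_diameter(self, grid200, sted_psf):
        sizes = []
        for d in (0.0, 60.0, 110.0, 160.0):
            spec = StructureSpec("vesicle", d, None, 5.0 if d else 0.0)
            frame = image_structure(project(render_structure(spec, grid200)), sted_psf, None)
            sizes.append(spot_size(fit_spot(frame, init_fwhm=80.0)))
        assert all(a < b for a, b in zip(sizes, sizes[1:]))

    def test_in_plane_tubule_more_elongated_than_vesicle(self, grid200, sted_psf, vesicle_frame):
        rot90y = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
        frame = image_structure(
            project(render_structure(tubule(30.0, 300.0), grid200, rot90y)), sted_psf, None
        )
        ratio_tubule = axis_ratio(fit_spot(frame, init_fwhm=80.0))
        ratio_vesicle = axis_ratio(fit_spot(vesicle_frame, init_fwhm=80.0))
        assert ratio_tubule > ratio_vesicle
        assert ratio_tubule > 1.5

    def test_fitted_size_stable_across_disjoint_seed_sets(self, grid200, sted_psf):
        raw = project(render_structure(vesicle(110.0), grid200))
        means = []
        for seeds in (range(75), range(75, 150)):
            sizes = [
                spot_size(
                    fit_spot(
                        image_structure(raw, sted_psf, NoiseParams(50.0, 5.0, s)),
                        init_fwhm=80.0,
                    )
                )
                for s in seeds
            ]
            assert np.isfinite(np.std(sizes))
            means.append(np.mean(sizes))
        assert abs(means[0] - means[1]) < 2.0

    def test_axis_ratio_nondecreasing_in_tubule_length_noise_free(self, grid200, sted_psf):
        mean_ratios = []
        for length in (80.0, 150.0, 300.0):
            rng = np.random.default_rng(123)
            ratios = [
                axis_ratio(
                    fit_spot(
                        image_structure(
                            project(render_structure(tubule(30.0, length), grid200,
                                                     sample_orientation(rng))),
                            sted_psf,
                            None,
                        ),
                        init_fwhm=80.0,
                    )
                )
                for _ in range(10)
            ]
            mean_ratios.append(np.mean(ratios))
        assert mean_ratios == sorted(mean_ratios)


class TestSizeStatistics:
    def test_symmetric_spot_size_is_fwhm(self):
        assert spot_size(_circular_fit(114.0)) == pytest.approx(114.0)
        assert spot_size(_circular_fit(114.0), "geometric_mean") == pytest.approx(114.0)

    def test_geometric_mean_and_major(self):
        f = SpotFit((0, 0), 160.0, 90.0, 0.2, 1.0, 0.0, True, 0.0)
        assert spot_size(f, "geometric_mean") == pytest.approx(120.0)
        assert spot_size(f, "major") == pytest.approx(160.0)
        assert spot_size(f, "mean") == pytest.approx(125.0)

    def test_size_invariant_to_axis_order(self):
        # SpotFit construction already normalizes major >= minor; fit_spot
        # swaps on output, so both orders give one canonical fit
        f = SpotFit((0, 0), 160.0, 90.0, 0.2, 1.0, 0.0, True, 0.0)
        g = SpotFit((0, 0), 160.0, 90.0, 0.2 + np.pi / 2, 1.0, 0.0, True, 0.0)
        for method in ("major", "geometric_mean", "mean"):
            assert spot_size(f, method) == spot_size(g, method)

    def test_non_converged_fit_raises(self):
        f = SpotFit((0, 0), 100.0, 90.0, 0.0, 1.0, 0.0, False, 1.0)
        with pytest.raises(NotConvergedError):
            spot_size(f)
        with pytest.raises(NotConvergedError):
            axis_ratio(f)

    def test_axis_ratio_at_least_one(self):
        assert axis_ratio(_circular_fit(100.0)) == pytest.approx(1.0)
        f = SpotFit((0, 0), 150.0, 100.0, 0.0, 1.0, 0.0, True, 0.0)
        assert axis_ratio(f) == pytest.approx(1.5)


class TestSummarizeSizes:
    def test_mean_matches_bruteforce(self):
        fits = [_circular_fit(v) for v in (100.0, 110.0, 120.0)]
        dist = summarize_sizes(fits)
        assert dist.n == 3
        assert dist.mean == pytest.approx(110.0)
        assert dist.sd == pytest.approx(np.std([100.0, 110.0, 120.0], ddof=1))
        np.testing.assert_allclose(sorted(dist.sizes), [100.0, 110.0, 120.0])

    def test_single_fit_has_undefined_sd(self):
        dist = summarize_sizes([_circular_fit(95.0)])
        assert dist.n == 1
        assert np.isnan(dist.sd)

    def test_no_converged_fits_raises(self):
        bad = SpotFit((0, 0), 100.0, 90.0, 0.0, 1.0, 0.0, False, 1.0)
        with pytest.raises(InvalidSpecError):
            summarize_sizes([bad])
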