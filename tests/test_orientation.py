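"""Structure-tensor orientation analysis: equivariance and recovery."""

import numpy as np
import pytest
from skimage.transform import rotate

from curvchip.orientation import (
    OrientationHistogram,
    alignment_efficiency,
    axial_distance,
    axial_mean,
    build_histogram,
    cell_axes,
    orientation_field,
    theta_cross,
)
from curvchip.synthdata import (
    ImageRecipe,
    make_image,
    make_label_ellipses,
    sample_axial_angles,
    stripe_image,
)


def _peak_angle(image, **hist_kwargs):
    hist = build_histogram(orientation_field(image), **hist_kwargs)
    return hist.angles_deg[np.argmax(hist.frequency)]


class TestOrientationField:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 75.0, -60.0])
    def test_stripe_peak_at_programmed_angle(self, angle):
        peak = _peak_angle(stripe_image(256, angle))
        assert axial_distance(peak, angle) <= 1.0

    @pytest.mark.parametrize("delta", [15.0, 30.0, 45.0])
    def test_rotation_equivariance(self, delta):
        """Rotating the image rotates the dominant angle by the same amount."""
        base = stripe_image(256, 10.0)
        rotated = rotate(base, delta, mode="reflect")
        crop = rotated[64:-64, 64:-64]  # discard interpolation borders
        peak = _peak_angle(crop)
        assert axial_distance(peak, 10.0 + delta) <= 1.0

    def test_constant_image_flagged_not_raised(self):
        field = orientation_field(np.full((64, 64), 3.0))
        assert field.is_constant
        with pytest.raises(ValueError):
            build_histogram(field)

    def test_angle_and_coherence_ranges(self):
        rng = np.random.default_rng(0)
        field = orientation_field(rng.normal(size=(128, 128)))
        assert np.all(field.angle_deg >= -90.0) and np.all(field.angle_deg < 90.0)
        assert np.all(field.coherence >= 0.0) and np.all(field.coherence <= 1.0 + 1e-12)
        assert np.all(field.energy >= 0.0)


class TestHistogram:
    def test_normalized_peak_is_exactly_one(self):
        hist = build_histogram(orientation_field(stripe_image(128, 20.0)))
        assert hist.normalized.max() == 1.0

    def test_bins_cover_half_turn_without_duplicate(self):
        hist = build_histogram(orientation_field(stripe_image(128, 0.0)))
        assert hist.angles_deg.size == 180
        assert hist.angles_deg[0] == -89.5
        assert hist.angles_deg[-1] == 89.5

    def test_isotropic_noise_has_no_prominent_mode(self):
        """Band-limited isotropic noise yields a near-flat histogram."""
        from scipy import ndimage

        rng = np.random.default_rng(12)
        noise = ndimage.gaussian_filter(rng.normal(size=(512, 512)), 2.0)
        hist = build_histogram(orientation_field(noise))
        assert hist.peaks(min_prominence=0.2) == []

    def test_von_mises_sample_mean_recovered(self):
        """Histogram circular mean sits within 2 deg of the generator mean."""
        rng = np.random.default_rng(21)
        angles = sample_axial_angles(20000, rng, "vonmises", mu_deg=25.0, kappa=4.0)
        freq, edges = np.histogram(angles, bins=180, range=(-90, 90))
        hist = OrientationHistogram((edges[:-1] + edges[1:]) / 2, freq.astype(float), 1.0)
        mean = axial_mean(hist.angles_deg, hist.frequency)
        assert axial_distance(mean, 25.0) <= 2.0


class TestThetaCross:
    def test_two_equal_orthogonal_modes(self):
        """Two equal families 90 deg apart: theta_cross is exactly right."""
        freq = np.zeros(180)
        freq[45] = freq[135] = 100.0  # -44.5 and +45.5 deg
        hist = OrientationHistogram(np.arange(-89.5, 90.0, 1.0), freq, 1.0)
        raw, acute = theta_cross(hist, min_prominence=0.01)
        assert acute == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("alpha", [60.0, 75.0, 90.0])
    def test_fiber_family_angle_recovered(self, alpha):
        recipe = ImageRecipe(
            size_px=512,
            n_nuclei=0,
            n_fibers=150,
            orientation_model="two-family",
            orientation_kappa=100.0,
            mixture_angle_deg=alpha,
            fiber_channel_amps={"green": 100.0},
            noise_gaussian_sd=1.0,
            seed=3,
        )
        channels, _ = make_image(recipe)
        hist = build_histogram(orientation_field(channels["green"]))
        _, acute = theta_cross(hist)
        assert abs(acute - alpha) <= 2.0

    def test_single_mode_raises(self):
        hist = build_histogram(orientation_field(stripe_image(128, 10.0)))
        with pytest.raises(ValueError):
            theta_cross(hist, min_prominence=0.5)


class TestAlignmentEfficiency:
    def test_uniform_distribution_analytic(self):
        """A +/-10 deg window holds 20/180 of a uniform distribution."""
        hist = OrientationHistogram(np.arange(-89.5, 90.0, 1.0), np.ones(180), 1.0)
        assert alignment_efficiency(hist, 0.0) == pytest.approx(1.0 / 9.0, abs=1e-12)

    def test_fully_aligned_population(self):
        freq = np.zeros(180)
        freq[90] = 42.0
        hist = OrientationHistogram(np.arange(-89.5, 90.0, 1.0), freq, 1.0)
        assert alignment_efficiency(hist, 0.5) == 1.0

    def test_window_wraps_across_axis_ends(self):
        """-89.5 deg sits within 10 deg of the +85 axis (period 180)."""
        freq = np.zeros(180)
        freq[0] = 1.0  # -89.5 deg
        hist = OrientationHistogram(np.arange(-89.5, 90.0, 1.0), freq, 1.0)
        assert alignment_efficiency(hist, 85.0) == 1.0

    def test_empty_histogram_rejected(self):
        hist = OrientationHistogram(np.arange(-89.5, 90.0, 1.0), np.zeros(180), 1.0)
        with pytest.raises(ValueError):
            alignment_efficiency(hist, 0.0)


class TestCellAxes:
    def test_single_ellipse_angle_and_aspect(self):
        labels, truth = make_label_ellipses(n=1, mu_deg=40.0, kappa=1e9, aspect=3.0, seed=0)
        df = cell_axes(labels)
        assert len(df) == 1
        assert df["angle_deg"].iloc[0] == pytest.approx(40.0, abs=0.5)
        assert df["aspect_ratio"].iloc[0] == pytest.approx(3.0, rel=0.1)

    def test_circle_axis_undefined(self):
        labels, _ = make_label_ellipses(n=1, mu_deg=0.0, kappa=1e9, aspect=1.0, seed=0)
        df = cell_axes(labels)
        assert not df["axis_defined"].iloc[0]
        assert np.isnan(df["angle_deg"].iloc[0])

    def test_population_mean_axis_recovered(self):
        labels, truth = make_label_ellipses(n=100, mu_deg=0.0, kappa=8.0, seed=4)
        df = cell_axes(labels)
        assert len(df) == 100
        assert axial_distance(axial_mean(df["angle_deg"]), 0.0) <= 2.0

    def test_small_objects_skipped(self):
        labels = np.zeros((32, 32), int)
        labels[0, 0] = 1  # single-pixel object
        labels[10:20, 10:14] = 2
        df = cell_axes(labels, min_area_px=10)
        assert df["cell_id"].tolist() == [2]
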