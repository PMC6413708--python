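import numpy as np
import pytest
from scipy import ndimage

from gevikit.activation_segmentation import ActivationMap
from gevikit.crosstalk import (
    AcfProfile,
    CrosstalkScenario,
    acf_orientation,
    acf_profile,
    align_average_acfs,
    amplitude_crosstalk_fraction,
    crosstalk_fraction,
    cutoff_widths,
    hex_grid_crosstalk,
    min_separation_for_crosstalk,
    mixing_oracle,
    spatial_acf,
)
from gevikit.synthetic_scene import scatter_pair_scene


def gaussian_map(sigma_px=6.0, shape=(65, 65), pixel_size=1.04, amplitude=-5.0,
                 anisotropy=1.0, angle=0.0, noise_sd=0.0, seed=0):
    rr, cc = np.meshgrid(np.arange(shape[0]) - shape[0] // 2,
                         np.arange(shape[1]) - shape[1] // 2, indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * rr + sa * cc
    v = -sa * rr + ca * cc
    data = amplitude * np.exp(-(u**2 / anisotropy**2 + v**2) / (2 * sigma_px**2))
    if noise_sd:
        data = data + np.random.default_rng(seed).normal(0, noise_sd, shape)
    return ActivationMap(data, pixel_size, "raw")


def exp_profile(lam_um=20.0, r_max=200.0, step=0.5):
    r = np.arange(0.0, r_max, step)
    v = np.exp(-r / lam_um)
    return AcfProfile(r, v, v, angle=0.0, pixel_size=1.0)


class TestSpatialAcf:
    def test_central_peak_replaced_by_neighbor_mean(self):
        """The noise-driven zero-lag spike is swapped for its 8-neighbour mean.

        Min-max normalization is affine, so the equality survives it.
        """
        rng = np.random.default_rng(8)
        data = rng.normal(0, 1.0, (21, 21))
        acf = spatial_acf(ActivationMap(data, 1.04, "raw"))
        r0, c0 = acf.center
        neigh = acf.data[r0 - 1:r0 + 2, c0 - 1:c0 + 2].copy()
        neigh[1, 1] = np.nan
        assert acf.data[r0, c0] == pytest.approx(np.nanmean(neigh))

    def test_single_pixel_map_is_degenerate(self):
        data = np.zeros((21, 21))
        data[10, 10] = -3.0
        with pytest.raises(ValueError, match="degenerate"):
            spatial_acf(ActivationMap(data, 1.04, "raw"))

    def test_gaussian_blob_acf_width_is_sqrt2_wider(self):
        """Gaussian autocorrelation widens 50 % width by sqrt(2)."""
        sigma = 6.0
        amap = gaussian_map(sigma_px=sigma)
        # blob 50% half-width
        blob_w = sigma * np.sqrt(2 * np.log(2)) * 1.04
        prof = acf_profile(spatial_acf(amap))
        long_c, short_c = cutoff_widths(prof)
        assert long_c == pytest.approx(np.sqrt(2) * blob_w, rel=0.05)
        assert short_c == pytest.approx(np.sqrt(2) * blob_w, rel=0.05)

    def test_anisotropic_map_long_axis_exceeds_short(self):
        amap = gaussian_map(anisotropy=2.5, angle=0.4)
        prof = acf_profile(spatial_acf(amap))
        long_c, short_c = cutoff_widths(prof)
        assert long_c > 1.5 * short_c

    def test_scale_invariance(self):
        a1 = spatial_acf(gaussian_map())
        a2 = spatial_acf(
            ActivationMap(gaussian_map().data * 7.3, 1.04, "raw")
        )
        np.testing.assert_allclose(a1.data, a2.data, atol=1e-12)

    def test_constant_map_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            spatial_acf(ActivationMap(np.ones((11, 11)), 1.04, "raw"))

    def test_point_symmetry(self):
        acf = spatial_acf(gaussian_map(anisotropy=2.0, angle=0.7,
                                       noise_sd=0.2, seed=4))
        assert np.allclose(acf.data, acf.data[::-1, ::-1], atol=1e-6)


class TestAlignAverage:
    def test_single_acf_round_trips(self):
        acf = spatial_acf(gaussian_map(anisotropy=2.0, angle=0.0))
        mean = align_average_acfs([acf])
        assert mean.data.shape == acf.data.shape
        r0, c0 = mean.center
        assert mean.data[r0, c0] == pytest.approx(1.0, abs=0.02)

    def test_two_rotated_copies_average_to_either(self):
        """Identical anisotropic ACFs 90 degrees apart align and agree."""
        a = spatial_acf(gaussian_map(anisotropy=2.5, angle=0.0))
        b = spatial_acf(gaussian_map(anisotropy=2.5, angle=np.pi / 2))
        mean = align_average_acfs([a, b])
        aligned_a = align_average_acfs([a])
        core = (slice(12, 53), slice(12, 53))
        assert np.abs(mean.data[core] - aligned_a.data[core]).max() < 0.02

    def test_noise_averages_down(self):
        """Averaging 8 aligned ACFs shrinks residual noise by ~1/sqrt(8).

        Both sides pass through the same rotation resampling so the
        comparison isolates the averaging itself.
        """
        clean = align_average_acfs([spatial_acf(gaussian_map())]).data
        acfs = [
            spatial_acf(gaussian_map(noise_sd=0.3, seed=s)) for s in range(8)
        ]
        mean8 = align_average_acfs(acfs).data
        mean1 = align_average_acfs(acfs[:1]).data
        r0 = clean.shape[0] // 2
        rr, cc = np.meshgrid(np.arange(clean.shape[0]) - r0,
                             np.arange(clean.shape[1]) - r0, indexing="ij")
        ring = (np.hypot(rr, cc) > 15) & (np.hypot(rr, cc) < 25)
        resid8 = (mean8 - clean)[ring].std()
        resid1 = (mean1 - clean)[ring].std()
        assert resid8 < 0.6 * resid1

    def test_mixed_pixel_sizes_rejected(self):
        a = spatial_acf(gaussian_map())
        b = spatial_acf(gaussian_map(pixel_size=2.08))
        with pytest.raises(ValueError, match="pixel"):
            align_average_acfs([a, b])


class TestCutoffWidths:
    def test_exponential_closed_form(self):
        """exp(-r/20): the 50 % cutoff is 20 ln 2 ~ 13.9 um."""
        prof = exp_profile(lam_um=20.0)
        long_c, short_c = cutoff_widths(prof)
        assert long_c == pytest.approx(20.0 * np.log(2), abs=0.05)
        assert short_c == pytest.approx(20.0 * np.log(2), abs=0.05)

    def test_level_one_gives_zero_distance(self):
        prof = exp_profile()
        long_c, short_c = cutoff_widths(prof, level=1.0)
        assert long_c == 0.0 and short_c == 0.0

    def test_never_crossing_reports_bound(self):
        r = np.arange(0.0, 50.0, 1.0)
        prof = AcfProfile(r, np.full_like(r, 0.9), np.full_like(r, 0.9),
                          0.0, 1.0)
        with pytest.raises(ValueError, match="49"):
            cutoff_widths(prof, level=0.5)


class TestCrosstalkFormula:
    def test_empty_scenario_is_zero(self):
        assert crosstalk_fraction(exp_profile(), CrosstalkScenario([])) == 0.0

    def test_neighbor_at_half_cutoff_gives_fifty_percent(self):
        prof = exp_profile(lam_um=20.0)
        r_half = 20.0 * np.log(2)
        frac = crosstalk_fraction(prof, CrosstalkScenario([(r_half, "long")]))
        assert frac == pytest.approx(0.5, abs=1e-3)

    def test_two_small_neighbors_arithmetic(self):
        r_tenth = 20.0 * np.log(10.0)  # ACF = 0.1
        prof = exp_profile(lam_um=20.0, r_max=300.0)
        frac = crosstalk_fraction(
            prof, CrosstalkScenario([(r_tenth, "long"), (r_tenth, "long")])
        )
        assert frac == pytest.approx(1.0 - 1.0 / 1.4, abs=1e-3)

    def test_monotone_in_neighbors_and_distance(self):
        prof = exp_profile()
        one = crosstalk_fraction(prof, CrosstalkScenario([(30.0, "long")]))
        two = crosstalk_fraction(
            prof, CrosstalkScenario([(30.0, "long"), (60.0, "long")])
        )
        closer = crosstalk_fraction(prof, CrosstalkScenario([(20.0, "long")]))
        assert two > one
        assert closer > one

    def test_beyond_support_counts_as_zero_with_warning(self):
        prof = exp_profile(r_max=50.0)
        with pytest.warns(UserWarning, match="beyond ACF support"):
            frac = crosstalk_fraction(prof, CrosstalkScenario([(80.0, "long")]))
        assert frac == 0.0

    def test_amplitude_fraction_is_sqrt_companion(self):
        prof = exp_profile()
        scen = CrosstalkScenario([(15.0, "long")])
        p = crosstalk_fraction(prof, scen)
        a = amplitude_crosstalk_fraction(prof, scen)
        assert a == pytest.approx(1.0 - np.sqrt(1.0 - p))


class TestHexGrid:
    def test_zero_profile_zero_crosstalk(self):
        r = np.arange(0.0, 400.0, 1.0)
        v = np.zeros_like(r)
        v[0] = 1.0
        prof = AcfProfile(r, v, v, 0.0, 1.0)
        best, worst = hex_grid_crosstalk(prof, side=100.0)
        assert best == pytest.approx(0.0, abs=1e-6)
        assert worst == pytest.approx(0.0, abs=1e-6)

    def test_first_shell_arithmetic(self):
        """Six neighbours at ACF 0.5 give 1 - 1/7."""
        r = np.arange(0.0, 400.0, 1.0)
        v = np.where(r == 0, 1.0, np.where(np.isclose(r, 100.0), 0.5, 0.0))
        # flat-zero except spikes; linear interp keeps value 0.5 only at 100
        prof = AcfProfile(r, v, v, 0.0, 1.0)
        best, worst = hex_grid_crosstalk(prof, side=100.0, max_radius=100.0)
        assert worst == pytest.approx(1.0 - 1.0 / 7.0, abs=1e-6)

    def test_grid_dominates_single_pair(self):
        prof = exp_profile(lam_um=40.0, r_max=400.0)
        best, worst = hex_grid_crosstalk(prof, side=100.0)
        pair = crosstalk_fraction(prof, CrosstalkScenario([(100.0, "long")]))
        assert worst >= pair
        assert worst >= best  # long axis carries more overlap


class TestPlanSparsity:
    def test_min_separation_inverts_pair_crosstalk(self):
        prof = exp_profile(lam_um=20.0, r_max=300.0)
        d = min_separation_for_crosstalk(prof, max_fraction=0.2)
        achieved = crosstalk_fraction(prof, CrosstalkScenario([(d, "long")]))
        assert achieved <= 0.2
        before = crosstalk_fraction(prof, CrosstalkScenario([(d - 2.0, "long")]))
        assert before > 0.2


class TestMixingOracle:
    def test_distant_neighbor_contributes_nothing(self):
        geoms, config, protocol = scatter_pair_scene(400.0, seed=0, halo_sigma=10.0)
        # neighbour far outside the target's halo
        res = mixing_oracle(geoms, config, protocol)
        assert res.amplitude_fraction < 0.01

    def test_colocated_identical_neurons_split_evenly(self):
        geoms, config, protocol = scatter_pair_scene(30.0, seed=0, halo_sigma=20.0)
        geoms[1] = geoms[0]
        with pytest.raises(ValueError, match="overlap"):
            mixing_oracle(geoms, config, protocol)
        # nearly co-located: amplitude fraction approaches 1/2 by symmetry
        geoms, config, protocol = scatter_pair_scene(2.0, seed=0, halo_sigma=20.0)
        res = mixing_oracle(geoms, config, protocol)
        assert res.amplitude_fraction == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("sep", [30.0, 90.0, 150.0])
    def test_formula_tracks_oracle(self, sep):
        """Power-crosstalk formula vs direct simulation within 15 %."""
        from gevikit.synthetic_scene import render_neurons

        geoms, config, protocol = scatter_pair_scene(sep, seed=3)
        res = mixing_oracle(geoms, config, protocol)
        single = render_neurons(geoms[:1], config, blur=True)
        amap = ActivationMap(-single, config.pixel_size, "raw")
        prof = acf_profile(spatial_acf(amap), angle=np.pi / 2)
        formula = crosstalk_fraction(prof, CrosstalkScenario([(sep, "long")]))
        assert formula == pytest.approx(res.power_fraction, rel=0.15)
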