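"""Spheroid detection, radial profiling, enclosure radius, sorting, PI death."""

import numpy as np
import pytest

from spheroquant import synthetic as syn
from spheroquant.image import MultiChannelImage
from spheroquant.spheroid import (
    RadialProfile,
    detect_spheroid_mask,
    normalize_profile,
    pi_death_score,
    radial_profile,
    radius_enclosing_fraction,
    sorting_analysis,
    sorting_statistic,
)


def _disk_image(radius, size=256, value=1.0, background=0.0):
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    img = np.full((size, size), background, dtype=float)
    img[(xx - c) ** 2 + (yy - c) ** 2 <= radius**2] = value
    return img, (c, c)


class TestDetectSpheroidMask:
    def test_uniform_disk_area_within_two_percent(self):
        disk, _ = _disk_image(100, size=300, value=10.0)
        img = MultiChannelImage({"brightfield": disk})
        m = detect_spheroid_mask(img, channel="brightfield")
        assert abs(m.area_px - np.pi * 100**2) / (np.pi * 100**2) < 0.02

    def test_all_zero_image_errors(self):
        img = MultiChannelImage({"brightfield": np.zeros((64, 64))})
        with pytest.raises(ValueError, match="no spheroid"):
            detect_spheroid_mask(img, channel="brightfield")

    def test_larger_of_two_disks_selected(self):
        arr = np.zeros((200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        arr[(xx - 60) ** 2 + (yy - 60) ** 2 <= 40**2] = 5.0  # ~5000 px²
        arr[(xx - 160) ** 2 + (yy - 160) ** 2 <= 16**2] = 5.0  # ~800 px²
        m = detect_spheroid_mask(MultiChannelImage({"bf": arr}), channel="bf")
        cx, cy = m.centroid
        assert abs(cx - 60) < 5 and abs(cy - 60) < 5


class TestRadialProfile:
    def test_uniform_image_gives_flat_profile(self):
        arr = np.ones((101, 101))
        prof = radial_profile(arr, (50.0, 50.0))
        np.testing.assert_allclose(prof.mean, 1.0)

    def test_total_intensity_conserved_exactly(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(size=(121, 121))
        prof = radial_profile(arr, (60.0, 60.0))
        yy, xx = np.mgrid[0:121, 0:121]
        rr = np.hypot(xx - 60.0, yy - 60.0)
        covered = np.floor(rr) < len(prof.mean)
        assert prof.total_intensity == pytest.approx(arr[covered].sum(), rel=1e-12)

    def test_radially_symmetric_function_recovered(self):
        size = 301
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        rr = np.hypot(xx - c, yy - c)
        arr = np.exp(-rr / 60.0)
        prof = radial_profile(arr, (c, c))
        expect = np.exp(-prof.midpoints / 60.0)
        np.testing.assert_allclose(prof.mean, expect, rtol=0.02)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            radial_profile(np.ones((50, 50)), (100.0, 10.0))

    def test_single_bright_center_pixel(self):
        arr = np.zeros((51, 51))
        arr[25, 25] = 100.0
        prof = radial_profile(arr, (25.0, 25.0))
        assert prof.mean[0] > 0
        assert prof.mean[5:].max() == 0.0


class TestRadiusEnclosingFraction:
    @pytest.mark.parametrize("R", [50, 75, 100])
    def test_uniform_disk_matches_sqrt_fraction_closed_form(self, R):
        disk, center = _disk_image(R, size=2 * R + 61)
        prof = radial_profile(disk, center)
        r95 = radius_enclosing_fraction(prof, 0.95)
        assert abs(r95 - np.sqrt(0.95) * R) / (np.sqrt(0.95) * R) < 0.015

    def test_all_intensity_in_center(self):
        arr = np.zeros((51, 51))
        arr[25, 25] = 10.0
        prof = radial_profile(arr, (25.0, 25.0))
        assert radius_enclosing_fraction(prof, 0.95) <= 1.0

    def test_fraction_one_returns_outermost_nonzero(self):
        disk, center = _disk_image(40, size=121)
        prof = radial_profile(disk, center)
        r = radius_enclosing_fraction(prof, 1.0)
        assert 40 <= r <= 42

    def test_zero_intensity_errors(self):
        prof = radial_profile(np.zeros((51, 51)), (25.0, 25.0))
        with pytest.raises(ValueError, match="zero total"):
            radius_enclosing_fraction(prof)


class TestNormalizeProfile:
    def _flat(self, value=2.0, n=100):
        return RadialProfile(
            edges=np.arange(n + 1, dtype=float),
            mean=np.full(n, value),
            count=np.ones(n),
            center=(0.0, 0.0),
        )

    def test_flat_profile_becomes_ones(self):
        out = normalize_profile(self._flat(2.0), spheroid_radius=80.0)
        np.testing.assert_allclose(out.mean, 1.0)
        assert out.normalization == "center"

    def test_value_scaled_by_center(self):
        prof = self._flat(2.0)
        prof.mean[56:68] = 6.0  # band around r = 0.77 * 80 px
        out = normalize_profile(prof, spheroid_radius=80.0)
        assert out.value_at(0.77) == pytest.approx(3.0, rel=0.02)

    def test_hollow_center_errors(self):
        prof = self._flat(0.0)
        with pytest.raises(ValueError, match="undefined"):
            normalize_profile(prof, spheroid_radius=80.0)


class TestSortingStatistic:
    def _norm_flat(self, value=1.0):
        grid = np.linspace(0, 1.2, 100)
        step = grid[1] - grid[0]
        return RadialProfile(
            edges=np.concatenate([grid - step / 2, [grid[-1] + step / 2]]),
            mean=np.full(100, value),
            count=np.ones(100),
            center=(0.0, 0.0),
            normalization="center",
        )

    def test_twenty_flat_profiles_ratio_one_sem_zero(self):
        stat = sorting_statistic([self._norm_flat() for _ in range(20)])
        assert stat.edge_center_ratio == pytest.approx(1.0)
        assert stat.sem == pytest.approx(0.0)
        assert stat.n_spheroids == 20

    def test_single_profile_sem_undefined(self):
        stat = sorting_statistic([self._norm_flat(2.0)])
        assert stat.edge_center_ratio == pytest.approx(2.0)
        assert np.isnan(stat.sem)

    def test_short_profile_excluded_with_warning(self):
        short = self._norm_flat()
        short = RadialProfile(
            edges=short.edges[:40], mean=short.mean[:39], count=short.count[:39],
            center=(0, 0), normalization="center",
        )
        with pytest.warns(UserWarning, match="excluded"):
            stat = sorting_statistic([short, self._norm_flat()])
        assert stat.n_spheroids == 1


class TestSortingPipeline:
    def test_well_mixed_ratio_near_one(self):
        imgs = [
            syn.gen_spheroid_image(syn.SyntheticSpheroidSpec(seed=s))[0]
            for s in range(10)
        ]
        stat = sorting_analysis(imgs)
        assert abs(stat.edge_center_ratio - 1.0) < 0.15

    def test_ratio_monotone_in_sorting_strength(self):
        from scipy.stats import spearmanr

        strengths = [0.0, 0.5, 1.0, 1.5, 2.0]
        ratios = []
        for k, s in enumerate(strengths):
            imgs = [
                syn.gen_spheroid_image(
                    syn.SyntheticSpheroidSpec(sorting_strength=s, seed=1000 * k + i)
                )[0]
                for i in range(6)
            ]
            ratios.append(sorting_analysis(imgs).edge_center_ratio)
        rho = spearmanr(strengths, ratios).statistic
        assert rho > 0.9


class TestPiDeath:
    def _well(self, pi_value):
        arr = np.zeros((120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        mask = (xx - 60) ** 2 + (yy - 60) ** 2 <= 40**2
        arr[mask] = pi_value
        img = MultiChannelImage({"PI": arr, "brightfield": mask * 10.0})
        return img, mask

    def test_treated_equal_to_control_scores_one(self):
        img, mask = self._well(3.0)
        assert pi_death_score(img, mask, [(img, mask)]) == pytest.approx(1.0)

    def test_fourfold_integral_scores_four(self):
        ctrl, cmask = self._well(1.0)
        treated, tmask = self._well(4.0)
        score = pi_death_score(treated, tmask, [(ctrl, cmask), (ctrl, cmask)])
        assert score == pytest.approx(4.0)

    def test_empty_mask_errors(self):
        img, mask = self._well(1.0)
        with pytest.raises(ValueError, match="empty"):
            pi_death_score(img, np.zeros_like(mask), [(img, mask)])

    def test_zero_control_errors(self):
        ctrl, cmask = self._well(0.0)
        treated, tmask = self._well(1.0)
        with pytest.raises(ValueError, match="control"):
            pi_death_score(treated, tmask, [(ctrl, cmask)])
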