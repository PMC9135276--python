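"""Generator ground truth: determinism, placement statistics, closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spheroquant import synthetic as syn
from spheroquant.qpcr import cnv_from_ct


class TestSpheroidGenerator:
    def test_seeded_determinism(self):
        spec = syn.SyntheticSpheroidSpec(seed=7)
        img1, truth1 = syn.gen_spheroid_image(spec)
        img2, truth2 = syn.gen_spheroid_image(spec)
        for ch in img1.channel_names:
            np.testing.assert_array_equal(img1[ch], img2[ch])
        np.testing.assert_array_equal(truth1.cell_centers, truth2.cell_centers)

    def test_labeled_fraction_binomial(self):
        spec = syn.SyntheticSpheroidSpec(sorting_strength=0.0, seed=7)
        _, truth = syn.gen_spheroid_image(spec)
        n = spec.n_cells
        frac = np.mean(truth.populations == "labeled")
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * se

    def test_strong_sorting_places_labeled_in_shell(self):
        spec = syn.SyntheticSpheroidSpec(
            sorting_strength=5.0, shell_band=(0.7, 1.0), seed=5
        )
        _, truth = syn.gen_spheroid_image(spec)
        lab = truth.populations == "labeled"
        cx, cy = truth.center
        r = np.hypot(
            truth.cell_centers[lab, 0] - cx, truth.cell_centers[lab, 1] - cy
        ) / truth.radius_px
        assert np.mean(r > 0.7) >= 0.90

    def test_uniform_placement_chi2_over_50_seeds(self):
        """Radial counts of labeled cells match the uniform-disk law."""
        edges = np.linspace(0.0, 1.0, 11)
        counts = np.zeros(10)
        for seed in range(50):
            spec = syn.SyntheticSpheroidSpec(
                image_size_px=(272, 272), spheroid_radius_px=120.0,
                sorting_strength=0.0, noise_sd=0.0, seed=seed,
            )
            _, truth = syn.gen_spheroid_image(spec)
            lab = truth.populations == "labeled"
            cx, cy = truth.center
            r = np.hypot(
                truth.cell_centers[lab, 0] - cx, truth.cell_centers[lab, 1] - cy
            ) / truth.radius_px
            counts += np.histogram(r, bins=edges)[0]
        expected = counts.sum() * np.diff(edges**2)  # area-proportional
        p = stats.chisquare(counts, expected).pvalue
        assert p > 0.001

    def test_true_ratio_one_when_unsorted(self):
        spec = syn.SyntheticSpheroidSpec(sorting_strength=0.0)
        assert spec.true_edge_center_ratio == 1.0

    def test_spheroid_must_fit_with_margin(self):
        with pytest.raises(ValueError, match="does not fit"):
            syn.SyntheticSpheroidSpec(image_size_px=(200, 200), spheroid_radius_px=95.0)

    def test_strength_for_ratio_round_trip(self):
        s = syn.SyntheticSpheroidSpec.strength_for_ratio(3.0)
        spec = syn.SyntheticSpheroidSpec(sorting_strength=s)
        assert spec.true_edge_center_ratio == pytest.approx(3.0)


class TestProtectionGenerator:
    DOSES = tuple(np.logspace(-10, -4, 11))

    def test_independent_mode_is_exact_mixture(self):
        spec = syn.ProtectionGenSpec(1e-8, 3e-6, self.DOSES, mode="independent_2d")
        tabs = syn.gen_protection_tables(spec)
        v_s = tabs.mono_sensitive.groupby("dose_M")["value"].mean()
        v_r = tabs.mono_resistant.groupby("dose_M")["value"].mean()
        v_co = tabs.co_culture.groupby("dose_M")["value"].mean()
        np.testing.assert_allclose(v_co, (3 * v_s + v_r) / 4, rtol=1e-12)

    def test_attenuation_one_reduces_to_independent(self):
        base = dict(
            ic50_sensitive=1e-8, ic50_resistant=3e-6, concentrations=self.DOSES
        )
        ind = syn.gen_protection_tables(
            syn.ProtectionGenSpec(**base, mode="independent_2d")
        )
        shield = syn.gen_protection_tables(
            syn.ProtectionGenSpec(
                **base, mode="shell_shielding_spheroid", attenuation_factor=1.0
            )
        )
        pd.testing.assert_frame_equal(ind.co_culture, shield.co_culture)

    def test_shielding_raises_observed_above_expected(self):
        dose = 1e-8 * 10
        spec = syn.ProtectionGenSpec(
            1e-8, 3e-6, (dose,), mode="shell_shielding_spheroid",
            attenuation_factor=10.0,
        )
        tabs = syn.gen_protection_tables(spec)
        observed = tabs.co_culture["value"].mean()
        expected = (
            3 * syn.three_param_viability(dose, 1e-8)
            + syn.three_param_viability(dose, 3e-6)
        ) / 4
        assert observed > expected

    def test_observed_at_least_expected_all_doses_when_shielded(self):
        doses = tuple(np.logspace(-13, -4, 10))  # reaches the no-kill limit
        spec = syn.ProtectionGenSpec(
            1e-8, 3e-6, doses, mode="shell_shielding_spheroid",
            attenuation_factor=5.0,
        )
        tabs = syn.gen_protection_tables(spec)
        v_s = tabs.mono_sensitive.groupby("dose_M")["value"].mean().to_numpy()
        v_r = tabs.mono_resistant.groupby("dose_M")["value"].mean().to_numpy()
        v_co = tabs.co_culture.groupby("dose_M")["value"].mean().to_numpy()
        expected = (3 * v_s + v_r) / 4
        assert np.all(v_co >= expected - 1e-12)
        # equality in the no-kill limit at the lowest dose
        assert v_co[0] == pytest.approx(expected[0], abs=1e-4)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.ProtectionGenSpec(1e-8, 3e-6, (0.0, 1e-8))


class TestGrowthGenerator:
    def test_logistic_midpoint_and_asymptote(self):
        df = syn.gen_growth_curve(80.0, 0.05, 50.0, np.array([50.0, 5000.0]))
        assert df["confluency"].iloc[0] == pytest.approx(40.0)
        assert df["confluency"].iloc[1] == pytest.approx(80.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            syn.gen_growth_curve(80.0, -0.1, 50.0, np.arange(10.0))

    def test_seeded_determinism(self):
        t = np.arange(0, 181, 4.0)
        a = syn.gen_growth_curve(90.0, 0.03, 80.0, t, noise_sd=1.0, seed=5)
        b = syn.gen_growth_curve(90.0, 0.03, 80.0, t, noise_sd=1.0, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestMonolayerGenerator:
    def test_enrichment_zero_marker_uniform_within_cells(self, monolayer_uniform):
        img, truth = monolayer_uniform
        marker = img["marker"]
        inside = truth.cell_labels > 0
        vals = marker[inside]
        # uniform up to blur/noise at the sheet boundary
        assert np.median(vals) == pytest.approx(50.0, rel=0.05)
        assert truth.intended_ratio == 1.0

    def test_enrichment_five_raster_ratio_above_two(self, monolayer_enriched):
        """Brute-force pixel oracle: band vs interior mean intensity."""
        img, truth = monolayer_enriched
        from scipy.ndimage import distance_transform_edt
        from skimage.segmentation import find_boundaries

        marker = img["marker"]
        labels = truth.cell_labels
        d = distance_transform_edt(~find_boundaries(labels, mode="thick"))
        band = (labels > 0) & (d <= 2.0)
        interior = (labels > 0) & (d > 7.0)
        assert marker[band].mean() / marker[interior].mean() > 2.0

    def test_seeded_reproducibility(self):
        a, _ = syn.gen_monolayer_image(30, 2.0, seed=9)
        b, _ = syn.gen_monolayer_image(30, 2.0, seed=9)
        np.testing.assert_array_equal(a["marker"], b["marker"])

    def test_too_dense_rejected(self):
        with pytest.raises(ValueError, match="dense"):
            syn.gen_monolayer_image(
                400, seed=0, image_size_px=(128, 128), min_separation_px=28.0
            )


class TestMigrationGenerator:
    def test_truth_mean_normalized_distance(self):
        _, truth = syn.gen_migration_image(200.0, [300.0, 280.0, 260.0], seed=1)
        assert truth.mean_top3_normalized == pytest.approx(1.4)

    def test_empty_sheet_list_gives_bare_spheroid(self):
        img, truth = syn.gen_migration_image(200.0, [], seed=1)
        assert truth.sheet_end_distances_px == ()
        # all signal inside the initial mask
        assert img["CTG"][~truth.initial_mask].max() == 0.0

    def test_sheet_inside_spheroid_rejected(self):
        with pytest.raises(ValueError, match="does not exceed"):
            syn.gen_migration_image(200.0, [90.0], seed=1)

    def test_identical_distances_stay_distinct(self):
        from skimage.measure import label as cc_label

        img, truth = syn.gen_migration_image(200.0, [260.0, 260.0, 260.0], seed=2)
        outside = img["CTG"] * ~truth.initial_mask
        n = cc_label(outside > 0).max()
        assert n == 3


class TestCtGenerator:
    def test_reference_recovers_two_noiseless(self):
        ct = syn.gen_ct_table({"HUVEC": 2.0, "X": 6.0}, "HUVEC")
        res = cnv_from_ct(ct, "HUVEC")
        assert res.n_abs("HUVEC") == pytest.approx(2.0)
        assert res.n_abs("X") == pytest.approx(6.0)

    def test_copy_eight_shifts_delta_ct_by_minus_two(self):
        ct = syn.gen_ct_table({"HUVEC": 2.0, "X": 8.0}, "HUVEC")
        res = cnv_from_ct(ct, "HUVEC")
        tab = res.table.set_index("sample")
        assert tab.loc["X", "delta_ct"] - tab.loc["HUVEC", "delta_ct"] == pytest.approx(-2.0)

    def test_seeded_reproducibility(self):
        a = syn.gen_ct_table({"HUVEC": 2.0}, "HUVEC", replicate_sd=0.2, seed=4)
        b = syn.gen_ct_table({"HUVEC": 2.0}, "HUVEC", replicate_sd=0.2, seed=4)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_nonpositive_copy_number_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.gen_ct_table({"HUVEC": 2.0, "X": 0.0}, "HUVEC")
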