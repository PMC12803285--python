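"""Measurement operators: recovery of generator ground truth."""

import numpy as np
import pytest

import tftimer as tt
from tftimer.quantify import (
    QuantifyError,
    compartment_partition,
    detect_puncta,
    intensity_overlap,
    membrane_mask_from_channel,
    membrane_ratio,
    plot_profile,
    subtract_background,
)
from tftimer.synthetic import NoiseModel, scenario_preset


class TestPlotProfile:
    def test_constant_image_gives_flat_profile(self):
        prof = plot_profile(np.full((40, 60), 7.5), pixel_size=0.2)
        assert np.allclose(prof.values, 7.5)
        assert prof.positions_um.size == 60
        assert np.all(np.diff(prof.positions_um) > 0)

    def test_step_image_steps_at_boundary(self):
        img = np.full((20, 100), 5.0)
        img[:, 50:] = 95.0
        prof = plot_profile(img, pixel_size=0.2)
        assert np.allclose(prof.values[:50], 5.0)
        assert np.allclose(prof.values[50:], 95.0)

    def test_wild_type_fast_profile_ordering(self, wt):
        image, truth = wt["image"], wt["truth"]
        prof = plot_profile(
            image.channel("basolateral", "fast"),
            image.pixel_size,
            region_masks=truth.region_masks,
        )
        means = {r: prof.region_mean(r) for r in ("P", "ptc_band", "far_A")}
        assert means["P"] > means["ptc_band"] > means["far_A"]

    def test_empty_mask_rejected(self):
        with pytest.raises(QuantifyError):
            plot_profile(np.ones((5, 5)), 0.2, mask=np.zeros((5, 5), bool))


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        out = subtract_background(np.full((10, 10), 3.0))
        assert np.allclose(out, 0.0)

    def test_offset_invariance_of_partition(self, wt):
        image, truth = wt["image"], wt["truth"]
        hh = image.channel("apical", "hh")
        p0 = compartment_partition(subtract_background(hh), truth.ap_masks)
        p1 = compartment_partition(subtract_background(hh + 50.0), truth.ap_masks)
        assert p0["P"] == pytest.approx(p1["P"], abs=1e-3)

    def test_noisy_flat_field_residual_small(self):
        rng = np.random.default_rng(3)
        sd = 2.0
        img = rng.normal(100.0, sd, size=(200, 200))
        resid = subtract_background(img)
        assert abs(resid.mean()) < 2 * sd


class TestCompartmentPartition:
    def test_all_signal_in_one_mask(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 3.0
        masks = {"A": np.zeros((10, 10), bool), "P": np.zeros((10, 10), bool)}
        masks["A"][:, :5] = True
        masks["P"][:, 5:] = True
        frac = compartment_partition(img, masks)
        assert frac["P"] == pytest.approx(1.0)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_even_split_recovered(self):
        sc = scenario_preset("wild_type", seed=9, hh_partition=0.5)
        image, truth = tt.generate_disc_image(sc)
        frac = compartment_partition(
            subtract_background(image.channel("apical", "hh")), truth.ap_masks
        )
        assert frac["P"] == pytest.approx(0.5, abs=0.02)

    def test_wild_type_recovers_95_5(self, wt):
        frac = wt["quant"]["partition"]
        assert frac["P"] == pytest.approx(0.95, abs=0.02)
        assert frac["A"] == pytest.approx(0.05, abs=0.02)

    def test_errors(self):
        masks = {"A": np.ones((4, 4), bool), "B": np.ones((4, 4), bool)}
        with pytest.raises(QuantifyError):
            compartment_partition(np.ones((4, 4)), masks)  # overlapping
        disjoint = {"A": np.zeros((4, 4), bool), "B": np.zeros((4, 4), bool)}
        disjoint["A"][:2] = True
        disjoint["B"][2:] = True
        with pytest.raises(QuantifyError):
            compartment_partition(np.zeros((4, 4)), disjoint)  # zero signal


def render_spot_field(n=100, shape=(600, 600), seed=0, amplitude=3000.0):
    """Non-overlapping Gaussian spots plus Poisson-Gaussian noise."""
    from tftimer.synthetic import NoiseModel, _place_points, _render_spots

    rng = np.random.default_rng(seed)
    mask = np.ones(shape, bool)
    pts = _place_points(rng, n, mask, 0.2, min_sep_px=14.0)
    img = np.zeros(shape)
    _render_spots(img, pts, 2.0, amplitude)
    noisy = NoiseModel(poisson_scale=4.0, gaussian_sd=0.5, background=2.0).apply(
        img, rng
    )
    return noisy, pts


class TestDetectPuncta:
    def test_blank_image_gives_empty_set(self):
        det = detect_puncta(np.zeros((50, 50)), pixel_size=0.2)
        assert len(det) == 0

    def test_recall_and_precision_on_100_spots(self):
        noisy, pts = render_spot_field(n=100, seed=1)
        det = detect_puncta(noisy, pixel_size=0.2, spot_sigma_um=0.4)
        true_yx = pts * 0.2
        found = np.column_stack([det.table.y_um - 0.1, det.table.x_um - 0.1])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(found).query(true_yx)
        recall = np.mean(d < 0.4)
        d2, _ = cKDTree(true_yx).query(found)
        precision = np.mean(d2 < 0.4)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_determinism(self):
        noisy, _ = render_spot_field(n=30, shape=(300, 300), seed=2)
        a = detect_puncta(noisy, 0.2).table
        b = detect_puncta(noisy, 0.2).table
        assert a.equals(b)

    def test_positive_integrated_intensities(self):
        noisy, _ = render_spot_field(n=30, shape=(300, 300), seed=3)
        det = detect_puncta(noisy, 0.2)
        assert (det.table.intensity > 0).all()


class TestIntensityOverlap:
    def test_partner_mask_covering_signal_gives_one(self):
        # all signal lies inside the bright partner object -> fraction 1
        sig = np.zeros((60, 60))
        sig[20:40, 20:40] = 5.0
        partner = np.zeros((60, 60))
        partner[15:45, 15:45] = 100.0
        region = np.ones((60, 60), bool)
        res = intensity_overlap(sig, partner, region, 0.2, mask_dilation_px=0)
        assert res.fraction == pytest.approx(1.0, abs=0.01)

    def test_empty_partner_gives_zero(self):
        rng = np.random.default_rng(0)
        sig = rng.uniform(1, 2, (60, 60))
        res = intensity_overlap(sig, np.zeros((60, 60)), np.ones((60, 60), bool), 0.2)
        assert res.fraction == 0.0

    def test_wild_type_recovers_generator_overlaps(self, wt):
        ov = wt["quant"]["overlaps"]
        assert 0.80 <= ov["A"].fraction <= 0.90
        assert ov["P"].fraction == pytest.approx(0.50, abs=0.07)
        for r in ov.values():
            assert 0.0 <= r.fraction <= 1.0
            assert r.ci_lo <= r.fraction <= r.ci_hi

    def test_zero_signal_rejected(self):
        with pytest.raises(QuantifyError):
            intensity_overlap(
                np.zeros((30, 30)), np.ones((30, 30)), np.ones((30, 30), bool), 0.2
            )


class TestMembraneRatio:
    def test_identical_channels_give_unit_ratio(self, wt):
        truth = wt["truth"]
        img = wt["image"].channel("basolateral", "fast")
        res = membrane_ratio(img, img, truth.membrane_mask, truth.region_masks)
        for r in res.values():
            assert r.status == "ok"
            assert r.ratio == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_region_at_3h_residence(self, pair):
        sc = scenario_preset("uniform_turnover", seed=0, noise=None)
        image, truth = tt.generate_disc_image(sc)
        res = membrane_ratio(
            image.channel("basolateral", "slow"),
            image.channel("basolateral", "fast"),
            truth.membrane_mask,
            truth.region_masks,
        )
        for r in res.values():
            assert r.ratio == pytest.approx(0.6287, abs=2e-3)

    def test_wild_type_ratio_ordering_matches_truth(self, wt):
        res = wt["quant"]["membrane_ratios"]
        tau = wt["truth"].residence_times
        order_meas = sorted(res, key=lambda k: res[k].ratio)
        order_true = sorted(tau, key=lambda k: tau[k])
        assert order_meas == order_true == ["far_A", "ptc_band", "P"]

    def test_quenched_fast_channel_flagged_undefined(self, wt):
        truth = wt["truth"]
        rng = np.random.default_rng(0)
        noise_only = rng.normal(2.0, 0.5, truth.membrane_mask.shape)
        res = membrane_ratio(
            wt["image"].channel("basolateral", "slow"),
            noise_only,
            truth.membrane_mask,
            truth.region_masks,
        )
        for r in res.values():
            assert r.status == "undefined"
            assert np.isnan(r.ratio)

    def test_uniform_null_is_flat_across_regions(self, uniform):
        res = uniform["quant"]["membrane_ratios"]
        vals = [r.ratio for r in res.values()]
        assert max(vals) - min(vals) < 0.01
        expected = tt.steady_state_ratio(1 / 3.0, uniform["scenario"].fluorophores)
        for v in vals:
            assert v == pytest.approx(expected, abs=0.01)


class TestMembraneMask:
    def test_recovers_generator_lattice(self, wt):
        from scipy.ndimage import distance_transform_edt

        mask = membrane_mask_from_channel(wt["image"].channel("basolateral", "membrane"))
        truth_mask = wt["truth"].membrane_mask
        # nearly all detected membrane pixels lie within 1 px of the true
        # lattice (the skeleton+dilate band straddles the 2-px outline)
        dist = distance_transform_edt(~truth_mask)
        assert np.mean(dist[mask] <= 1.0) > 0.95
        # and the detected band covers most of the true lattice
        dist_m = distance_transform_edt(~mask)
        assert np.mean(dist_m[truth_mask] <= 1.0) > 0.9


class TestUncertaintyCalibration:
    def test_bootstrap_cis_cover_truth(self):
        """95% CIs of ratio and overlap estimators cover ground truth in
        >= 90% of seeded replicate discs."""
        n_seeds = 20
        hits_ratio, total_ratio, hits_ov = 0, 0, 0
        from tftimer.pipeline import quantify_disc

        for seed in range(n_seeds):
            sc = scenario_preset("wild_type", seed=100 + seed)
            image, truth = tt.generate_disc_image(sc)
            q = quantify_disc(image, truth, seed=seed)
            for label, r in q["membrane_ratios"].items():
                expected = tt.steady_state_ratio(
                    1 / truth.residence_times[label], sc.fluorophores
                )
                hits_ratio += r.ci_lo <= expected <= r.ci_hi
                total_ratio += 1
            ov = q["overlaps"]["A"]
            hits_ov += ov.ci_lo <= truth.overlap_realized["A"] <= ov.ci_hi
        assert hits_ratio / total_ratio >= 0.9
        assert hits_ov / n_seeds >= 0.9
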