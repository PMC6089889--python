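"""Synthetic spot/cohort generator: determinism, geometry, fixtures."""

import numpy as np
import pytest

from tmagleason.synthetic import (
    HazardParams,
    MASK_CODES,
    SyntheticSpotConfig,
    generate_cohort,
    generate_label_mask,
    generate_spot,
    one_hot_probability_map,
    patch_texture_stats,
    region_spec_for_score,
)


class TestGenerateSpot:
    def test_only_requested_labels_appear(self):
        cfg = SyntheticSpotConfig(spot_size_px=500,
                                  region_spec=[("G3", 0.5)], rng_seed=0)
        _, mask = generate_spot(cfg)
        assert set(np.unique(mask)) <= {0, MASK_CODES["G3"]}

    def test_same_seed_bit_identical(self):
        cfg = SyntheticSpotConfig(spot_size_px=400,
                                  region_spec=[("G4", 0.4), ("benign", 0.3)],
                                  rng_seed=7)
        rgb1, m1 = generate_spot(cfg)
        rgb2, m2 = generate_spot(cfg)
        assert np.array_equal(rgb1, rgb2)
        assert np.array_equal(m1, m2)

    def test_region_area_fraction_matches_request(self):
        cfg = SyntheticSpotConfig(spot_size_px=800,
                                  region_spec=[("G3", 0.3)], rng_seed=3)
        _, mask = generate_spot(cfg)
        disk_area = np.pi * (0.48 * 800) ** 2
        frac = (mask == MASK_CODES["G3"]).sum() / disk_area
        assert abs(frac - 0.3) <= 0.1

    def test_fractions_summing_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticSpotConfig(region_spec=[("G3", 0.7), ("G4", 0.6)])

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpotConfig(region_spec=[("G3", -0.1)])

    def test_mask_only_path_matches_full_render(self):
        cfg = SyntheticSpotConfig(spot_size_px=300,
                                  region_spec=[("G5", 0.5), ("G3", 0.2)],
                                  rng_seed=9)
        _, mask = generate_spot(cfg)
        assert np.array_equal(mask, generate_label_mask(cfg))

    def test_pixels_outside_disk_are_background(self):
        cfg = SyntheticSpotConfig(spot_size_px=400,
                                  region_spec=[("G3", 1.0)], rng_seed=0,
                                  noise_sigma=0.0)
        rgb, mask = generate_spot(cfg)
        assert mask[0, 0] == 0
        assert (rgb[0, 0] > 230).all()  # bright background corner


class TestTextureSeparability:
    def test_patterns_have_distinct_gland_statistics(self):
        """Mean gland count / lumen area separate all pattern pairs."""
        from scipy.stats import ttest_ind

        stats = {}
        for pattern in ("benign", "G3", "G4", "G5"):
            cfg = SyntheticSpotConfig(spot_size_px=1550,
                                      region_spec=[(pattern, 1.0)],
                                      rng_seed=17)
            rgb, mask = generate_spot(cfg)
            rng = np.random.default_rng(0)
            counts, lumens, n = [], [], 0
            while n < 20:
                y, x = rng.integers(0, 1550 - 375, 2)
                window = mask[y + 125:y + 250, x + 125:x + 250]
                labs = np.unique(window)
                labs = labs[labs != 0]
                if labs.size != 1:
                    continue
                s = patch_texture_stats(rgb[y:y + 375, x:x + 375],
                                        tissue_mask=mask[y:y + 375, x:x + 375] > 0)
                counts.append(s["gland_count"])
                lumens.append(s["lumen_fraction"])
                n += 1
            stats[pattern] = (np.array(counts), np.array(lumens))
        patterns = list(stats)
        for i, a in enumerate(patterns):
            for b in patterns[i + 1:]:
                p_count = ttest_ind(stats[a][0], stats[b][0],
                                    equal_var=False).pvalue
                p_lumen = ttest_ind(stats[a][1], stats[b][1],
                                    equal_var=False).pvalue
                assert min(p_count, p_lumen) < 1e-3, (a, b)


class TestOneHotProbabilityMap:
    def test_zero_smoothing_is_one_hot(self):
        mask = np.array([[0, 3], [2, 4]], dtype=np.uint8)  # G4, G3, G5
        pmap = one_hot_probability_map(mask, smoothing=0.0)
        assert np.allclose(pmap.probs[0, 1], [0, 0, 1, 0])  # G4 channel
        assert np.allclose(pmap.probs[1, 0], [0, 1, 0, 0])  # G3
        assert not pmap.tissue_mask[0, 0]
        assert np.allclose(pmap.probs[0, 0], 0)

    def test_smoothing_spreads_uniformly(self):
        mask = np.full((3, 3), 2, dtype=np.uint8)
        pmap = one_hot_probability_map(mask, smoothing=0.3)
        expected = np.array([0.1, 0.7, 0.1, 0.1])
        assert np.allclose(pmap.probs[1, 1], expected)

    @pytest.mark.parametrize("smoothing", [0.0, 0.15, 0.6])
    def test_channels_sum_to_one_on_tissue(self, smoothing):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 5, size=(20, 20)).astype(np.uint8)
        pmap = one_hot_probability_map(mask, smoothing=smoothing)
        sums = pmap.probs[pmap.tissue_mask].sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_invalid_smoothing_rejected(self):
        with pytest.raises(ValueError):
            one_hot_probability_map(np.ones((2, 2), np.uint8), smoothing=1.0)


class TestCohort:
    def test_zero_spots_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0)

    def test_referential_integrity_and_positive_times(self, small_cohort):
        ids = {s.spot_id for s in small_cohort.spots}
        assert set(small_cohort.clinical["spot_id"]) <= ids
        assert (small_cohort.clinical["time_months"] > 0).all()
        assert set(small_cohort.clinical["event"]) <= {0, 1}

    def test_cohort_deterministic(self):
        c1 = generate_cohort(5, rng_seed=3, spot_size_px=300)
        c2 = generate_cohort(5, rng_seed=3, spot_size_px=300)
        assert c1.clinical.equals(c2.clinical)
        m1 = c1.spots[0].realize_mask()
        m2 = c2.spots[0].realize_mask()
        assert np.array_equal(m1, m2)

    def test_region_spec_realizes_score_fractions(self):
        rng = np.random.default_rng(0)
        for score in (0, 6, 7, 8, 9, 10):
            spec = region_spec_for_score(score, rng)
            fracs = dict()
            for pattern, f in spec:
                fracs[pattern] = fracs.get(pattern, 0) + f
            assert sum(fracs.values()) <= 1.0
            if score == 0:
                assert set(fracs) == {"benign"}
            else:
                cancer = {p: f for p, f in fracs.items() if p != "benign"}
                # every intended pattern holds > 0.25 of the area
                assert all(f > 0.25 for f in cancer.values())

    def test_all_benign_mix_allowed(self):
        cohort = generate_cohort(4, score_mix={0: 1.0}, rng_seed=1,
                                 spot_size_px=300)
        assert (cohort.clinical["true_score"] == 0).all()

    def test_hazard_ordering_in_expectation(self):
        """Higher risk tiers die faster under the tiered hazard model."""
        mix = {6: 0.5, 9: 0.5}
        cohort = generate_cohort(400, score_mix=mix, rng_seed=5,
                                 spot_size_px=300,
                                 hazard=HazardParams(baseline_hazard=0.01,
                                                     ratio=4.0))
        df = cohort.clinical
        low = df[df["true_score"] == 6]
        high = df[df["true_score"] == 9]
        assert high["event"].mean() > low["event"].mean()
        assert (high[high["event"] == 1]["time_months"].mean()
                < low[low["event"] == 1]["time_months"].mean())
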