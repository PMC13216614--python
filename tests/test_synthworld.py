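"""Synthetic world generator: determinism, structure, and ground truth."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_world_config
from oceangap import synthworld
from oceangap.geogrid import DEPTH_ZONES, assign_band
from oceangap.synthworld import WorldConfig, generate_species_pool, generate_world


class TestConfigValidation:
    def test_resolution_must_divide_180(self):
        with pytest.raises(ValueError):
            WorldConfig(raster_resolution=7.0)

    def test_proportions_bounded(self):
        with pytest.raises(ValueError):
            WorldConfig(land_fraction=1.5)

    def test_unknown_corruption_rule(self):
        with pytest.raises(ValueError):
            WorldConfig(corruption_rates={"typo_rule": 0.1})

    def test_depth_mix_sums_to_one(self):
        with pytest.raises(ValueError):
            WorldConfig(depth_mix=(0.5, 0.2, 0.2))


class TestWorld:
    def test_identical_seed_gives_identical_world(self):
        cfg = small_world_config(seed=3)
        b1, l1 = generate_world(cfg)
        b2, l2 = generate_world(cfg)
        np.testing.assert_array_equal(b1.values, b2.values)
        for k in l1:
            np.testing.assert_array_equal(l1[k].values, l2[k].values)

    def test_no_land_when_land_fraction_zero(self):
        cfg = small_world_config(land_fraction=0.0)
        bathy, _ = generate_world(cfg)
        assert np.all(np.isfinite(bathy.values))
        assert np.all(bathy.values > 0)
        assert np.all(bathy.values <= 11000)

    def test_land_fraction_respected(self):
        cfg = small_world_config(land_fraction=0.3)
        bathy, _ = generate_world(cfg)
        frac = np.mean(~np.isfinite(bathy.values))
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_temperature_decreases_with_latitude(self):
        cfg = small_world_config()
        bathy, layers = generate_world(cfg)
        t = layers["temperature_surface"]
        lat2d = np.meshgrid(t.lon_centers, t.lat_centers)[1]
        m = np.isfinite(t.values)
        r = np.corrcoef(t.values[m], np.abs(lat2d[m]))[0, 1]
        assert r < -0.8

    def test_pelagic_o2_is_affine_in_temperature(self):
        _, layers = generate_world(small_world_config())
        t = layers["temperature_surface"].values
        o = layers["o2_surface"].values
        m = np.isfinite(t)
        assert abs(np.corrcoef(t[m], o[m])[0, 1]) > 0.9999

    def test_realm_tags(self):
        _, layers = generate_world(small_world_config())
        assert layers["temperature_surface"].realm == "surface"
        assert layers["nitrate_benthic"].realm == "benthic"
        assert layers["temperature_mesopelagic"].realm == "mesopelagic"


class TestSpeciesPool:
    def test_flat_gradient_equal_band_richness(self):
        # 120 species split 72/30/18 across zones, each divisible by the
        # 6 latitude blocks, so per-band richness is exactly constant
        cfg = small_world_config(gradient_shape="flat", n_species=120)
        _, truth = generate_species_pool(cfg)
        for zone, rich in truth.true_richness_per_band.items():
            assert len(set(rich.tolist())) == 1, zone

    def test_bimodal_peaks_exceed_equator(self):
        cfg = small_world_config(gradient_shape="bimodal",
                                 gradient_peaks=(-25.0, 25.0))
        _, truth = generate_species_pool(cfg)
        total = sum(truth.true_richness_per_band.values())
        b_m25, b_0, b_p25 = assign_band(-25.0), assign_band(0.0), assign_band(25.0)
        assert total[b_m25] > total[b_0]
        assert total[b_p25] > total[b_0]

    def test_registry_synonym_counts(self):
        cfg = small_world_config(n_species=100, synonym_rate=0.2)
        registry, _ = generate_species_pool(cfg)
        acc = registry[(registry["status"] == "accepted")
                       & (registry["kingdom"] == "Animalia")
                       & registry["is_marine"]]
        assert len(acc) == 100
        assert (registry["status"] == "synonym").sum() == 20

    def test_synonyms_point_at_accepted_rows(self):
        registry, _ = generate_species_pool(small_world_config())
        accepted = set(registry.loc[registry["status"] == "accepted", "raw_name"])
        syn = registry[registry["status"] == "synonym"]
        assert set(syn["accepted_name"]).issubset(accepted)

    def test_depth_mix_quotas(self):
        cfg = small_world_config(n_species=200, depth_mix=(0.5, 0.3, 0.2))
        _, truth = generate_species_pool(cfg)
        counts = truth.species_ranges["zone"].value_counts()
        assert counts["shallow"] == 100 and counts["mesopelagic"] == 60 \
            and counts["deep"] == 40


class TestOccurrences:
    def test_identical_config_and_seed_byte_identical(self):
        cfg = small_world_config(seed=5, n_records=2000)
        d1 = synthworld.generate_dataset(cfg)
        d2 = synthworld.generate_dataset(cfg)
        pd.testing.assert_frame_equal(d1[4], d2[4])

    def test_missing_depth_rate_binomial(self):
        cfg = small_world_config(n_records=10_000, seed=13)
        *_, occ = synthworld.generate_dataset(cfg)
        n_missing = occ["depth"].isna().sum()
        assert 600 <= n_missing <= 800           # 700 +- 100 at rate 0.07

    def test_equatorial_deficit_suppresses_record_counts(self):
        ratios = []
        for seed in range(10):
            cfg = small_world_config(seed=100 + seed, n_records=4000,
                                     equatorial_deficit=0.1,
                                     corruption_rates={})
            *_, occ = synthworld.generate_dataset(cfg)
            band = assign_band(occ["latitude"].to_numpy())
            eq = np.isin(band, [17, 18])                # [-5, 5)
            mid = (np.abs(occ["latitude"]) >= 20) & (np.abs(occ["latitude"]) < 40)
            per_eq = eq.sum() / 2
            per_mid = mid.sum() / 8
            ratios.append(per_eq / per_mid)
        assert np.mean(ratios) < 0.25

    def test_clean_records_lie_inside_species_ranges(self, small_dataset):
        bathy, layers, registry, truth, occ = small_dataset
        sp = truth.species_ranges
        clean = occ[occ["_qc_truth"] == ""]
        merged = clean.merge(sp, left_on="_species_id", right_on="species_id")
        assert ((merged["latitude"] >= merged["lat_lo"])
                & (merged["latitude"] <= merged["lat_hi"])).all()
        dlon = (merged["longitude"] - merged["lon_center"] + 180) % 360 - 180
        assert (np.abs(dlon) <= merged["lon_halfwidth"]).all()
        lo = merged["zone"].map({z: b[0] for z, b in DEPTH_ZONES.items()})
        hi = merged["zone"].map({z: b[1] for z, b in DEPTH_ZONES.items()})
        assert ((merged["depth"] >= lo) & (merged["depth"] <= hi)).all()

    def test_effort_bias_independent_of_flat_richness(self):
        cfg = small_world_config(gradient_shape="flat", n_species=120,
                                 seed=21, corruption_rates={})
        bathy, layers, registry, truth, occ = synthworld.generate_dataset(cfg)
        rich = sum(truth.true_richness_per_band.values())
        assert np.std(rich) == 0                 # constant truth ...
        band = assign_band(occ["latitude"].to_numpy())
        counts = np.bincount(band, minlength=36)
        assert np.std(counts[counts > 0]) > 0    # ... while effort varies

    def test_depth_conflict_corruption_exceeds_margin(self, small_dataset):
        bathy, _, _, _, occ = small_dataset
        bad = occ[occ["_qc_truth"] == "depth_conflict"]
        local = bathy.sample(bad["latitude"].to_numpy(), bad["longitude"].to_numpy())
        assert np.all(bad["depth"].to_numpy() > local + 50.0)
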