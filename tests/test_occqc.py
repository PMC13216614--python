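"""Quality-control rules, ordering, and exact accounting."""

import numpy as np
import pandas as pd
import pytest

from conftest import record_frame, small_world_config
from oceangap import occqc, synthworld
from oceangap.rasters import Raster


@pytest.fixture()
def coastal_bathy():
    """4x4 1° raster at (0..4, 0..4): west half ocean 3000 m, east half land."""
    vals = np.full((4, 4), 3000.0)
    vals[:, 2:] = np.nan
    return Raster(vals, lat_min=0.0, lon_min=0.0, resolution=1.0)


@pytest.fixture()
def registry():
    return pd.DataFrame([
        {"raw_name": "Mya marina", "accepted_name": "Mya marina",
         "status": "accepted", "is_marine": True, "is_brackish": False,
         "kingdom": "Animalia"},
        {"raw_name": "Mya antiqua", "accepted_name": "Mya marina",
         "status": "synonym", "is_marine": True, "is_brackish": False,
         "kingdom": "Animalia"},
        {"raw_name": "Unio dulcis", "accepted_name": "Unio dulcis",
         "status": "accepted", "is_marine": False, "is_brackish": False,
         "kingdom": "Animalia"},
        {"raw_name": "Fucus algae", "accepted_name": "Fucus algae",
         "status": "accepted", "is_marine": True, "is_brackish": False,
         "kingdom": "Plantae"},
    ])


class TestDeduplicate:
    def test_identical_rows_collapse(self):
        df = pd.concat([record_frame(), record_frame()], ignore_index=True)
        assert len(occqc.deduplicate(df)) == 1

    def test_different_dataset_id_kept(self):
        df = pd.concat([record_frame(), record_frame(dataset_id="d2")],
                       ignore_index=True)
        assert len(occqc.deduplicate(df)) == 2

    def test_uncertainty_not_part_of_key(self):
        df = pd.concat([record_frame(), record_frame(coord_uncertainty=999.0)],
                       ignore_index=True)
        assert len(occqc.deduplicate(df)) == 1

    def test_fixture_with_three_duplicates(self):
        rows = [record_frame(latitude=float(i)) for i in range(7)]
        rows += [record_frame(latitude=0.0), record_frame(latitude=1.0),
                 record_frame(latitude=2.0)]
        df = pd.concat(rows, ignore_index=True)
        assert len(df) == 10
        assert len(occqc.deduplicate(df)) == 7


class TestFlagAndCoordinateRules:
    def test_absent_removed(self):
        assert len(occqc.filter_flags(record_frame(status="absent"))) == 0

    def test_fossil_removed(self):
        assert len(occqc.filter_flags(record_frame(basis="FossilSpecimen"))) == 0

    def test_present_specimen_kept(self):
        df = record_frame(basis="PreservedSpecimen", status="present")
        assert len(occqc.filter_flags(df)) == 1

    @pytest.mark.parametrize("lat,lon,kept", [
        (91.0, 0.0, False), (-91.0, 0.0, False), (np.nan, 0.0, False),
        (0.0, np.nan, False), (45.0, 179.9, True), (45.0, -180.0, True)])
    def test_coordinate_validity(self, lat, lon, kept):
        out = occqc.validate_coordinates(record_frame(latitude=lat, longitude=lon))
        assert (len(out) == 1) == kept

    def test_lon_180_normalized(self):
        out = occqc.validate_coordinates(record_frame(longitude=180.0))
        assert len(out) == 1 and out["longitude"].iloc[0] == -180.0


class TestLandAndDepthRules:
    def test_land_point_dropped_ocean_kept(self, coastal_bathy):
        df = pd.concat([record_frame(latitude=0.5, longitude=0.5, depth=100.0),
                        record_frame(latitude=0.5, longitude=3.5)],
                       ignore_index=True)
        mask = occqc.on_land_mask(df, coastal_bathy)
        assert list(mask) == [False, True]

    def test_cell_edge_uses_floor_convention(self, coastal_bathy):
        # lon = 2.0 is the shared edge between ocean column 1 and land
        # column 2; the floor convention puts it in the land cell
        df = record_frame(latitude=0.5, longitude=2.0)
        assert occqc.on_land_mask(df, coastal_bathy)[0]
        df = record_frame(latitude=0.5, longitude=np.nextafter(2.0, -1))
        assert not occqc.on_land_mask(df, coastal_bathy)[0]

    def test_outside_raster_domain_raises(self, coastal_bathy):
        with pytest.raises(ValueError):
            occqc.on_land_mask(record_frame(latitude=30.0, longitude=0.5),
                               coastal_bathy)

    @pytest.mark.parametrize("depth,flagged", [
        (3050.0, False), (3051.0, True), (np.nan, False), (10.0, False)])
    def test_depth_margin_boundary(self, coastal_bathy, depth, flagged):
        df = record_frame(latitude=0.5, longitude=0.5, depth=depth)
        assert occqc.depth_conflict_mask(df, coastal_bathy)[0] == flagged


class TestUncertaintyAndTaxa:
    @pytest.mark.parametrize("unc,kept", [
        (150_000.0, False), (100_000.0, True), (np.nan, True), (10.0, True)])
    def test_uncertainty_threshold_strict(self, unc, kept):
        out = occqc.uncertainty_filter(record_frame(coord_uncertainty=unc))
        assert (len(out) == 1) == kept

    def test_synonym_resolved_to_accepted(self, registry):
        out = occqc.match_taxa(record_frame(raw_name="Mya antiqua"), registry)
        assert out["accepted_species"].iloc[0] == "Mya marina"

    def test_unmatched_removed(self, registry):
        assert len(occqc.match_taxa(record_frame(raw_name="Nemo ignotus"),
                                    registry)) == 0

    def test_freshwater_removed(self, registry):
        assert len(occqc.match_taxa(record_frame(raw_name="Unio dulcis"),
                                    registry)) == 0

    def test_non_animal_removed(self, registry):
        assert len(occqc.match_taxa(record_frame(raw_name="Fucus algae"),
                                    registry)) == 0


class TestRunQC:
    def test_empty_input(self, registry, coastal_bathy):
        empty = record_frame().iloc[:0]
        out, rep = occqc.run_qc(empty, registry, coastal_bathy)
        assert len(out) == 0 and rep.records_in == 0 and rep.records_out == 0
        assert all(v == 0 for v in rep.removed.values())

    def test_no_corruption_means_no_removals(self):
        cfg = small_world_config(seed=11, corruption_rates={})
        bathy, layers, registry, truth, occ = synthworld.generate_dataset(cfg)
        out, rep = occqc.run_qc(occ, registry, bathy)
        assert rep.records_out == rep.records_in == len(occ)
        assert all(v == 0 for v in rep.removed.values())

    def test_injected_corruption_counts_recovered(self, small_dataset):
        bathy, layers, registry, truth, occ = small_dataset
        out, rep = occqc.run_qc(occ, registry, bathy)
        truth_counts = occ["_qc_truth"].value_counts()
        for rule in ("duplicate", "fossil", "absent", "on_land",
                     "depth_conflict", "high_uncertainty"):
            assert rep.removed[rule] == int(truth_counts.get(rule, 0)), rule
        # non-removing corruptions survive
        assert rep.removed["unmatched_taxon"] == 0
        rep.check()

    def test_reconciliation_identity(self, small_dataset):
        bathy, _, registry, _, occ = small_dataset
        out, rep = occqc.run_qc(occ, registry, bathy)
        assert rep.records_in - sum(rep.removed.values()) == rep.records_out

    def test_idempotent(self, small_dataset):
        bathy, _, registry, _, occ = small_dataset
        once, rep1 = occqc.run_qc(occ, registry, bathy)
        twice, rep2 = occqc.run_qc(once.drop(columns=["accepted_species"]),
                                   registry, bathy)
        assert len(twice) == len(once)
        assert sum(rep2.removed.values()) == 0

    def test_tightening_margin_never_increases_survivors(self, small_dataset):
        bathy, _, registry, _, occ = small_dataset
        loose, _ = occqc.run_qc(occ, registry, bathy, margin_m=50.0)
        tight, _ = occqc.run_qc(occ, registry, bathy, margin_m=10.0)
        tighter, _ = occqc.run_qc(occ, registry, bathy, max_uncertainty_m=1000.0)
        assert len(tight) <= len(loose)
        assert len(tighter) <= len(loose)

    def test_zero_zero_rule_optional(self, registry, coastal_bathy):
        df = record_frame(latitude=0.0, longitude=0.0, raw_name="Mya marina")
        bathy = Raster(np.full((4, 4), 3000.0), lat_min=-2, lon_min=-2,
                       resolution=1.0)
        kept, _ = occqc.run_qc(df, registry, bathy)
        dropped, rep = occqc.run_qc(df, registry, bathy, flag_zero_zero=True)
        assert len(kept) == 1 and len(dropped) == 0
        assert rep.removed["bad_coords"] == 1
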