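"""The shipped Oregon parameter bundle and bundle serialization."""

import math

import pytest
import yaml

from ncsim.bundle import bundle_from_dict, bundle_sha256, load_bundle
from ncsim.errors import BundleValidationError


class TestOregonBundle:
    def test_activity_roster(self, oregon_bundle):
        assert len(oregon_bundle.activity_ids) == 13  # riparian split by region
        assert "deferred_harvest" in oregon_bundle.activity_ids
        assert set(oregon_bundle.scenarios) == {"limited", "moderate", "ambitious"}

    def test_avoided_conversion_baselines(self, oregon_bundle):
        ac = oregon_bundle.avoided_conversion
        assert ac["forest_rural"].baseline_conversion_rate == 1930
        assert ac["forest_urban"].baseline_conversion_rate == 148
        assert ac["sagebrush_conversion"].baseline_conversion_rate == 4000
        assert ac["grassland"].baseline_conversion_rate == 930

    def test_flux_distributions(self, oregon_bundle):
        sage = oregon_bundle.avoided_conversion["sagebrush_conversion"]
        assert (sage.one_time.family, sage.one_time.p1, sage.one_time.p2) == (
            "normal", 16.13, 6.6,
        )
        assert (sage.ongoing.p1, sage.ongoing.p2) == (0.81, 0.44)
        grass = oregon_bundle.avoided_conversion["grassland"]
        assert (grass.one_time.p1, grass.one_time.p2) == (67.6, 7.66)
        assert grass.ongoing.family == "point" and grass.ongoing.p1 == 0.0
        tidal = oregon_bundle.cohort["tidal"]
        assert (tidal.rate.family, tidal.rate.p1, tidal.rate.p2) == ("normal", 8.84, 3.92)
        assert tidal.cap_ha == 5205
        assert tidal.baseline_rate_ha == pytest.approx(48.9)

    def test_restoration_baselines_and_caps(self, oregon_bundle):
        c = oregon_bundle.cohort
        assert c["riparian_interior"].baseline_rate_ha == 1713
        assert c["riparian_coastal"].baseline_rate_ha == 683
        assert c["riparian_interior"].cap_ha == 76_635
        assert c["riparian_coastal"].cap_ha == 125_780
        assert c["sagebrush_restoration"].baseline_rate_ha == 5590
        assert (c["riparian_interior"].rate.p1, c["riparian_interior"].rate.p2) == (12.17, 0.43)
        assert (c["riparian_coastal"].rate.p1, c["riparian_coastal"].rate.p2) == (15.81, 0.45)

    def test_land_management_baselines(self, oregon_bundle):
        assert oregon_bundle.per_area["cover_crops"].baseline_area_ha == 48_740
        assert oregon_bundle.per_area["no_till"].baseline_area_ha == 403_280
        nut = oregon_bundle.nutrient
        assert nut.baseline_n_mg == 186_294  # working value used in computation
        assert oregon_bundle.metadata["notes"]["table_nutrient_n_mg"] == 193_000
        assert (nut.ef.family, nut.ef.p1, nut.ef.p2) == ("uniform", 0.01, 0.0254)
        dh = oregon_bundle.deferred_harvest
        assert dh.baseline_volume_m3 == pytest.approx(3.4e6 * 5.66)
        assert sum(dh.ownership_shares.values()) == pytest.approx(1.0)
        assert (dh.delta_c_seq["interior"].p1, dh.delta_c_seq["coastal"].p1) == (30.04, 108.16)

    def test_replanting_params(self, oregon_bundle):
        rep = oregon_bundle.replanting
        assert (rep.p_replanted.p1, rep.p_replanted.p2) == (0.09, 0.12)
        assert rep.natural_regen_delay == 10
        assert set(rep.classes) == {"low", "medium", "high"}

    def test_forest_one_time_within_reported_range(self, oregon_bundle):
        """Per-hectare committed emissions for forest conversion fall in the
        reported 125-400 Mg CO2e/ha range."""
        rural = oregon_bundle.avoided_conversion["forest_rural"].one_time.p1
        urban = oregon_bundle.avoided_conversion["forest_urban"].one_time.p1
        assert 125 <= rural <= 400
        assert 125 <= urban <= 400
        assert urban == pytest.approx(2 * rural, rel=1e-9)


class TestSerialization:
    def test_roundtrip_through_yaml(self, oregon_bundle, tmp_path):
        path = tmp_path / "bundle.yaml"
        path.write_text(yaml.safe_dump(oregon_bundle.raw))
        reloaded = load_bundle(path)
        assert reloaded.activity_ids == oregon_bundle.activity_ids
        assert bundle_sha256(reloaded) == bundle_sha256(oregon_bundle)

    def test_missing_schedule_rejected(self, oregon_bundle):
        doc = yaml.safe_load(yaml.safe_dump(oregon_bundle.raw))  # deep copy
        del doc["scenarios"]["limited"]["schedules"]["tidal"]
        with pytest.raises(BundleValidationError, match="tidal"):
            bundle_from_dict(doc)

    def test_malformed_distribution_rejected(self, oregon_bundle):
        doc = yaml.safe_load(yaml.safe_dump(oregon_bundle.raw))
        doc["restoration"]["tidal"]["rate"] = {"family": "normal"}  # no parameters
        with pytest.raises(BundleValidationError):
            bundle_from_dict(doc)

    def test_unbounded_cap_default(self):
        doc = {
            "restoration": {
                "x": {"baseline_rate_ha": 1.0, "rate": {"family": "point", "p1": 1.0}}
            },
        }
        bundle = bundle_from_dict(doc)
        assert math.isinf(bundle.cohort["x"].cap_ha)
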