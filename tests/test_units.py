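"""Unit-conversion layer: exact constants, linearity, error handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncsim.errors import ConfigurationError, InvalidQuantityError
from ncsim.units import (
    EmissionFactors,
    c_to_co2e,
    mbf_to_m3,
    n_to_n2o_co2e,
    volume_to_carbon,
)


class TestCToCO2e:
    @pytest.mark.parametrize(
        "mass_c, expected",
        [
            (18.44, 18.44 * 44 / 12),  # meadow root biomass, ~67.61 Mg CO2e/ha
            (0.0, 0.0),
            (12.0, 44.0),
            (-3.0, -11.0),  # sign-preserving
        ],
    )
    def test_values(self, mass_c, expected):
        assert c_to_co2e(mass_c) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidQuantityError):
            c_to_co2e(float("nan"))
        with pytest.raises(InvalidQuantityError):
            c_to_co2e(math.inf)

    def test_roundtrip_identity(self):
        x = np.array([0.1, 1.0, 67.6, 1234.5])
        back = c_to_co2e(x) / EmissionFactors().co2_per_c
        assert np.allclose(back, x, rtol=1e-12)


class TestVolumeToCarbon:
    @pytest.mark.parametrize(
        "volume, region, expected",
        [
            (1.0, "coastal", 0.2115),
            (1.0, "interior", 0.1985),
            (0.0, "coastal", 0.0),
        ],
    )
    def test_values(self, volume, region, expected):
        assert volume_to_carbon(volume, region) == pytest.approx(expected, rel=1e-9)

    def test_unknown_region(self):
        with pytest.raises(ConfigurationError):
            volume_to_carbon(1.0, "montane")

    def test_negative_rejected(self):
        with pytest.raises(InvalidQuantityError):
            volume_to_carbon(-1.0, "coastal")


class TestMbfToM3:
    def test_requires_configured_factor(self):
        with pytest.raises(ConfigurationError):
            mbf_to_m3(1000.0, EmissionFactors())

    def test_linear_in_volume(self):
        f = EmissionFactors(mbf_to_m3=5.66)
        assert mbf_to_m3(1000.0, f) == pytest.approx(5660.0)
        assert mbf_to_m3(0.0, f) == 0.0
        assert mbf_to_m3(2000.0, f) == pytest.approx(2 * mbf_to_m3(1000.0, f))


class TestN2O:
    def test_n2o_n_convention(self):
        # 1000 Mg N at the 2.54% EF: x 44/28 before applying GWP 298
        expected = 1000 * 0.0254 * (44 / 28) * 298
        assert n_to_n2o_co2e(1000.0, 0.0254, "n2o_n") == pytest.approx(expected)
        assert expected == pytest.approx(11894.457, abs=0.01)

    def test_n2o_direct_convention(self):
        assert n_to_n2o_co2e(1000.0, 0.0254, "n2o_direct") == pytest.approx(7569.2)

    def test_zero_nitrogen(self):
        assert n_to_n2o_co2e(0.0, 0.02, "n2o_n") == 0.0
        assert n_to_n2o_co2e(0.0, 0.02, "n2o_direct") == 0.0

    def test_unknown_convention(self):
        with pytest.raises(ConfigurationError):
            n_to_n2o_co2e(1.0, 0.02, "n2o_inverse")

    def test_ef_bounds(self):
        with pytest.raises(InvalidQuantityError):
            n_to_n2o_co2e(1.0, 1.5)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    scale=st.floats(0.0, 1e6),
    x=st.floats(1e-6, 1e6),
)
def test_conversions_are_homogeneous(scale, x):
    """All conversions are linear maps: f(a*x) = a*f(x) for a >= 0."""
    f = EmissionFactors(mbf_to_m3=2.36)
    assert c_to_co2e(scale * x) == pytest.approx(scale * c_to_co2e(x), rel=1e-9)
    assert volume_to_carbon(scale * x, "interior") == pytest.approx(
        scale * volume_to_carbon(x, "interior"), rel=1e-9
    )
    assert mbf_to_m3(scale * x, f) == pytest.approx(scale * mbf_to_m3(x, f), rel=1e-9)
    assert n_to_n2o_co2e(scale * x, 0.01) == pytest.approx(
        scale * n_to_n2o_co2e(x, 0.01), rel=1e-9
    )


def test_default_factors_match_accounting_constants():
    f = EmissionFactors()
    assert f.co2_per_c == pytest.approx(44 / 12)
    assert f.agb_emission_fraction == 0.54
    assert (f.rural_pool_fraction, f.urban_seq_loss, f.rural_seq_loss) == (0.5, 0.84, 0.50)
    assert (f.residue_roundwood_ratio, f.root_shoot_ratio) == (0.25, 0.2)
    assert (f.residue_bgb_committed, f.mill_residue_fraction) == (0.56, 0.15)
    assert f.retired_products_fraction == 0.28
    assert (f.specific_gravity_interior, f.specific_gravity_coastal) == (0.397, 0.423)
    assert (f.carbon_fraction, f.gwp_n2o) == (0.5, 298.0)
    assert f.mbf_to_m3 is None  # no silent default


def test_invalid_factors_rejected():
    with pytest.raises(ConfigurationError):
        EmissionFactors(agb_emission_fraction=1.5)
    with pytest.raises(ConfigurationError):
        EmissionFactors(specific_gravity_coastal=-0.4)
    with pytest.raises(ConfigurationError):
        EmissionFactors(mbf_to_m3=0.0)
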