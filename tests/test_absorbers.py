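"""Extinction-matrix construction and two-wavelength unmixing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dotphantom.absorbers import (ADS830WS, EPSON673, Absorber, AbsorptionPair,
                                  ConcentrationPair, build_extinction_system,
                                  concentrations_from_mua,
                                  default_extinction_system,
                                  mua_from_concentrations,
                                  read_extinction_csv,
                                  recipe_mass_concentration, unmix_map,
                                  write_extinction_csv)
from dotphantom.images import DeltaMuaMap

LN10 = math.log(10.0)


class TestBuildSystem:
    def test_tabulated_absorbers_give_nonsingular_system(self):
        sys_ = build_extinction_system(ADS830WS, EPSON673)
        det = np.linalg.det(sys_.matrix)
        assert det != 0
        assert np.isfinite(sys_.condition_number)
        # entries are eps * 0.1 (per-cm -> per-mm) * ln10 (natural scale)
        assert sys_.matrix[0, 0] == pytest.approx(56049.20 * 0.1 * LN10)
        assert sys_.matrix[1, 1] == pytest.approx(1520.56 * 0.1 * LN10)

    def test_identical_absorbers_rejected(self):
        with pytest.raises(ValueError, match="singular|ill-conditioned"):
            build_extinction_system(ADS830WS, ADS830WS)

    def test_decadic_unit_conversion_is_a_tenth(self):
        a = Absorber("u1", {670.0: 1.0, 830.0: 0.0}, 1.0)
        b = Absorber("u2", {670.0: 0.0, 830.0: 1.0}, 1.0)
        sys_ = build_extinction_system(a, b, log_convention="decadic")
        assert np.allclose(sys_.matrix, [[0.1, 0.0], [0.0, 0.1]])

    def test_missing_wavelength_rejected(self):
        a = Absorber("only670", {670.0: 10.0}, 1.0)
        with pytest.raises(ValueError, match="no extinction"):
            build_extinction_system(a, EPSON673)


class TestForwardInverse:
    def test_zero_concentration_maps_to_zero(self, system):
        out = mua_from_concentrations(system, ConcentrationPair(0.0, 0.0))
        assert out.mua_l1 == 0.0 and out.mua_l2 == 0.0

    def test_forward_matches_hand_evaluated_product(self):
        # decadic: mua(l) = 0.1 * (eps_dye(l) * 1e-6 + eps_ink(l) * 10e-6)
        sys_ = build_extinction_system(ADS830WS, EPSON673,
                                       log_convention="decadic")
        out = mua_from_concentrations(sys_, ConcentrationPair(1.0, 10.0))
        assert out.mua_l1 == pytest.approx(0.03701447, abs=1e-9)
        assert out.mua_l2 == pytest.approx(0.00781123, abs=1e-8)

    def test_linearity_doubling(self, system):
        one = mua_from_concentrations(system, ConcentrationPair(1.3, 4.2))
        two = mua_from_concentrations(system, ConcentrationPair(2.6, 8.4))
        assert two.mua_l1 == pytest.approx(2 * one.mua_l1, rel=1e-12)
        assert two.mua_l2 == pytest.approx(2 * one.mua_l2, rel=1e-12)

    def test_zero_mua_solves_to_zero(self, system):
        out = concentrations_from_mua(system, AbsorptionPair(0.0, 0.0))
        assert out.dye == 0.0 and out.inks == 0.0

    def test_fabrication_recipe_round_trip(self, system):
        # shell dye load and benign-core ink load of the fabricated spheres
        conc = ConcentrationPair(1.541, 177.3)
        mua = mua_from_concentrations(system, conc)
        back = concentrations_from_mua(system, mua)
        assert back.dye == pytest.approx(1.541, rel=1e-10)
        assert back.inks == pytest.approx(177.3, rel=1e-10)

    def test_inverse_agrees_with_cramers_rule(self, system):
        mua = AbsorptionPair(0.013, 0.0042)
        m = system.matrix
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        dye = (mua.mua_l1 * m[1, 1] - m[0, 1] * mua.mua_l2) / det * 1e6
        inks = (m[0, 0] * mua.mua_l2 - mua.mua_l1 * m[1, 0]) / det * 1e6
        out = concentrations_from_mua(system, mua)
        assert out.dye == pytest.approx(dye, rel=1e-12)
        assert out.inks == pytest.approx(inks, rel=1e-12)

    def test_nonfinite_mua_rejected(self, system):
        with pytest.raises(ValueError):
            AbsorptionPair(float("nan"), 0.0)


@settings(max_examples=200, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_round_trip_property_random_systems(seed):
    """Forward-then-inverse is the identity to 1e-10 relative error."""
    rng = np.random.default_rng(seed)
    for _ in range(5):
        eps = rng.uniform(10.0, 1e5, size=(2, 2))
        a = Absorber("a", {670.0: eps[0, 0], 830.0: eps[1, 0]}, 100.0)
        b = Absorber("b", {670.0: eps[0, 1], 830.0: eps[1, 1]}, 100.0)
        try:
            sys_ = build_extinction_system(a, b, max_condition=1e6)
        except ValueError:
            continue
        conc = ConcentrationPair(*rng.uniform(-100, 100, size=2))
        back = concentrations_from_mua(sys_, mua_from_concentrations(sys_, conc))
        assert back.dye == pytest.approx(conc.dye, rel=1e-10, abs=1e-12)
        assert back.inks == pytest.approx(conc.inks, rel=1e-10, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_concentration_ratio_invariant_to_log_convention(seed):
    """The ln(10) factor cancels in dye/ink ratios."""
    rng = np.random.default_rng(seed)
    nat = build_extinction_system(ADS830WS, EPSON673, log_convention="natural")
    dec = build_extinction_system(ADS830WS, EPSON673, log_convention="decadic")
    mua = AbsorptionPair(*rng.uniform(1e-4, 1e-2, size=2))
    c_nat = concentrations_from_mua(nat, mua)
    c_dec = concentrations_from_mua(dec, mua)
    assert c_nat.dye / c_nat.inks == pytest.approx(c_dec.dye / c_dec.inks,
                                                   rel=1e-9)


class TestRecipe:
    def test_zero(self):
        assert recipe_mass_concentration(ConcentrationPair(0, 0),
                                         ADS830WS, EPSON673) == (0.0, 0.0)

    def test_masses_from_molecular_weights(self):
        g_dye, g_ink = recipe_mass_concentration(
            ConcentrationPair(1.541, 177.3), ADS830WS, EPSON673)
        assert g_dye == pytest.approx(1.541e-6 * 827.49, rel=1e-12)
        assert g_ink == pytest.approx(177.3e-6 * 68.14, rel=1e-12)


def _dmua(values, wavelength, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return DeltaMuaMap(values, valid, wavelength, 100.0, 0.625)


class TestUnmixMap:
    def test_zero_maps(self, system):
        out = unmix_map(system, _dmua(np.zeros((4, 4)), 670.0),
                        _dmua(np.zeros((4, 4)), 830.0))
        assert np.allclose(out.dye_uM, 0.0)
        assert np.allclose(out.inks_uM, 0.0)

    def test_constant_field_round_trip(self, system):
        dye, inks = 0.7, -2.3  # uM changes (differences may be negative)
        m = system.matrix
        d1 = np.full((8, 8), (m[0, 0] * dye + m[0, 1] * inks) * 1e-6)
        d2 = np.full((8, 8), (m[1, 0] * dye + m[1, 1] * inks) * 1e-6)
        out = unmix_map(system, _dmua(d1, 670.0), _dmua(d2, 830.0))
        assert np.allclose(out.dye_uM, dye, rtol=1e-9)
        assert np.allclose(out.inks_uM, inks, rtol=1e-9)

    def test_single_pixel_stays_single_pixel(self, system):
        d1 = np.zeros((6, 6))
        d2 = np.zeros((6, 6))
        d1[2, 3] = 1e-3
        d2[2, 3] = 2e-3
        out = unmix_map(system, _dmua(d1, 670.0), _dmua(d2, 830.0))
        nz = np.abs(out.dye_uM) + np.abs(out.inks_uM) > 0
        assert nz.sum() == 1 and nz[2, 3]

    def test_linearity_of_sums(self, system, rng):
        a1, a2 = rng.normal(0, 1e-3, (2, 5, 5))
        b1, b2 = rng.normal(0, 1e-3, (2, 5, 5))
        sum_out = unmix_map(system, _dmua(a1 + b1, 670.0),
                            _dmua(a2 + b2, 830.0))
        out_a = unmix_map(system, _dmua(a1, 670.0), _dmua(a2, 830.0))
        out_b = unmix_map(system, _dmua(b1, 670.0), _dmua(b2, 830.0))
        assert np.allclose(sum_out.dye_uM, out_a.dye_uM + out_b.dye_uM,
                           atol=1e-9)

    def test_shape_mismatch_rejected(self, system):
        with pytest.raises(ValueError, match="shape"):
            unmix_map(system, _dmua(np.zeros((4, 4)), 670.0),
                      _dmua(np.zeros((5, 5)), 830.0))

    def test_invalid_pixels_propagate(self, system):
        valid = np.ones((4, 4), dtype=bool)
        valid[1, 1] = False
        out = unmix_map(system, _dmua(np.zeros((4, 4)), 670.0, valid),
                        _dmua(np.zeros((4, 4)), 830.0))
        assert not out.valid[1, 1]
        assert np.isnan(out.dye_uM[1, 1])


def test_extinction_csv_round_trip(tmp_path):
    path = tmp_path / "eps.csv"
    write_extinction_csv(path, [ADS830WS, EPSON673])
    table = read_extinction_csv(path)
    assert table["ADS830WS"].epsilon[830.0] == ADS830WS.epsilon[830.0]
    assert table["Epson673"].molecular_weight == EPSON673.molecular_weight
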