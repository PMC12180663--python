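"""Monte Carlo transport: sampling primitives, conservation, physics oracles."""

import math

import numpy as np
import pytest

from dotphantom.diffusion import (SlabModel, cw_total_transmittance,
                                  mean_total_pathlength)
from dotphantom.mc import (DetectorSpec, SourceSpec, fresnel_boundary,
                           roulette, sample_scattering, simulate)
from dotphantom.phantom import (OpticalProperties, build_slab,
                                fixture_phantom, host_properties)


class TestHenyeyGreensteinSampling:
    def test_isotropic_limit_mean_cosine_zero(self):
        cost, phi = sample_scattering(0.0, 1_000_000, seed=1)
        se = cost.std(ddof=1) / math.sqrt(cost.size)
        assert abs(cost.mean()) < 3 * se
        assert phi.min() >= 0 and phi.max() < 2 * math.pi

    def test_mean_cosine_equals_anisotropy(self):
        g = 0.9
        cost, _ = sample_scattering(g, 1_000_000, seed=2)
        se = cost.std(ddof=1) / math.sqrt(cost.size)
        assert abs(cost.mean() - g) < 3 * se

    def test_empirical_cdf_matches_analytic(self):
        g = 0.7
        cost, _ = sample_scattering(g, 100_000, seed=3)
        xs = np.sort(cost)

        def cdf(c):
            return (1 - g * g) / (2 * g) * (
                1.0 / np.sqrt(1 + g * g - 2 * g * c) - 1.0 / (1 + g))

        emp = (np.arange(xs.size) + 0.5) / xs.size
        assert np.max(np.abs(emp - cdf(xs))) < 0.005

    def test_out_of_range_anisotropy_rejected(self):
        with pytest.raises(ValueError):
            sample_scattering(1.0, 10)


class TestFresnelBoundary:
    def test_matched_indices_always_transmit(self, rng):
        refl, ct = fresnel_boundary(1.4, 1.4, 0.3)
        assert refl == 0.0 and ct == 0.3
        reflected, _ = fresnel_boundary(1.4, 1.4, 0.3, rng)
        assert reflected is False

    def test_normal_incidence_air_to_resin(self):
        refl, ct = fresnel_boundary(1.0, 1.56, 1.0)
        assert refl == pytest.approx(((1.56 - 1.0) / (1.56 + 1.0)) ** 2,
                                     rel=1e-12)
        assert ct == pytest.approx(1.0)

    def test_total_internal_reflection(self, rng):
        # past the critical angle (sin > 1/1.56) reflection is certain
        ci = 0.4  # cos 66 deg, theta_c ~ 39.9 deg for 1.56 -> 1.0
        refl, _ = fresnel_boundary(1.56, 1.0, ci)
        assert refl == 1.0
        assert fresnel_boundary(1.56, 1.0, ci, rng)[0] is True


class TestRoulette:
    def test_above_threshold_unchanged(self, rng):
        assert roulette(0.5, rng=rng) == 0.5

    def test_expected_weight_preserved(self, rng):
        w = 1e-5
        outcomes = np.array([roulette(w, rng=rng) for _ in range(20_000)])
        assert set(np.round(np.unique(outcomes), 12)) <= {0.0, 1e-4}
        se = outcomes.std(ddof=1) / math.sqrt(outcomes.size)
        assert abs(outcomes.mean() - w) < 3 * se

    def test_default_parameters(self, rng):
        # defaults: threshold 1e-4, survival factor 10
        assert roulette(2e-4, rng=rng) == 2e-4
        boosted = {roulette(5e-5, rng=rng) for _ in range(200)}
        assert boosted <= {0.0, 5e-4}


def _ballistic_phantom(mua=0.025):
    host = OpticalProperties(mua, 1e-9, g=0.0, n=1.0)
    return build_slab((80.0, 80.0, 40.0), host, exterior_n=1.0)


class TestSimulate:
    def test_ballistic_beer_lambert(self):
        # no scattering, mua * d = 1: every packet exits on-axis with e^-1
        img, stats = simulate(_ballistic_phantom(), n_photons=1000, seed=5)
        frac = stats.detected_weight / stats.n_photons
        assert frac == pytest.approx(math.exp(-1.0), rel=1e-6)
        assert stats.mean_total_pathlength == pytest.approx(40.0, rel=1e-6)
        r, c = np.unravel_index(np.argmax(img.data), img.data.shape)
        assert (r, c) == (64, 64)

    def test_weight_conservation_with_roulette_accounting(self):
        ph = fixture_phantom("ADC", "solid", 670)
        _, stats = simulate(ph, n_photons=20_000, seed=7)
        assert stats.weight_balance_error() < 1e-9
        assert stats.roulette_gain >= 0 and stats.roulette_killed >= 0

    def test_bit_reproducibility_and_seed_sensitivity(self):
        ph = fixture_phantom("FADN", "solid", 670, include_inclusion=False)
        img_a, st_a = simulate(ph, n_photons=5000, seed=11)
        img_b, st_b = simulate(ph, n_photons=5000, seed=11)
        img_c, _ = simulate(ph, n_photons=5000, seed=12)
        assert np.array_equal(img_a.data, img_b.data)
        assert st_a.detected_weight == st_b.detected_weight
        assert not np.array_equal(img_a.data, img_c.data)

    def test_homogeneous_image_is_laterally_symmetric(self):
        ph = fixture_phantom("FADN", "solid", 670, include_inclusion=False)
        img, stats = simulate(ph, n_photons=200_000, seed=13)
        d = img.data
        tol = 3.0 / math.sqrt(stats.detected_packets / 2)
        for half_a, half_b in [(d[:64], d[64:]), (d[:, :64], d[:, 64:])]:
            a, b = half_a.sum(), half_b.sum()
            assert abs(a - b) / (a + b) < tol

    def test_invalid_inputs_rejected(self):
        ph = _ballistic_phantom()
        with pytest.raises(ValueError):
            simulate(ph, n_photons=0)
        with pytest.raises(ValueError, match="outside"):
            simulate(ph, source=SourceSpec(x=500.0), n_photons=10)

    def test_radiance_mode_image_nonnegative(self):
        ph = fixture_phantom("FADN", "solid", 670, include_inclusion=False)
        img, _ = simulate(ph, detector=DetectorSpec(mode="radiance"),
                          n_photons=50_000, seed=17)
        assert (img.data >= 0).all()
        assert img.data.sum() > 0


class TestAgainstDiffusionTheory:
    @pytest.mark.parametrize("host", ["solid", "liquid"])
    @pytest.mark.parametrize("wavelength", [670.0, 830.0])
    def test_transmittance_and_pathlength_match_closed_forms(
            self, host, wavelength):
        """Homogeneous slab (musp * d ~ 30-45): MC within 5% of diffusion."""
        props = host_properties(host, wavelength)
        ph = fixture_phantom("FADN", host, wavelength,
                             include_inclusion=False)
        _, stats = simulate(ph, n_photons=300_000, seed=19)
        slab = SlabModel(props.mua, props.musp, 40.0, n_in=props.n, n_out=1.0)
        assert stats.total_transmittance == pytest.approx(
            cw_total_transmittance(slab), rel=0.05)
        assert stats.mean_total_pathlength == pytest.approx(
            mean_total_pathlength(slab), rel=0.05)
        assert stats.mean_total_pathlength > 40.0

    def test_transport_similarity_in_anisotropy(self):
        """At fixed musp the transmittance is insensitive to g."""
        t = {}
        for g in (0.0, 0.9):
            host = OpticalProperties(0.01, 1.0, g=g, n=1.4)
            ph = build_slab((80.0, 80.0, 10.0), host)
            _, stats = simulate(ph, n_photons=60_000, seed=23)
            t[g] = stats.total_transmittance
        assert t[0.0] == pytest.approx(t[0.9], rel=0.05)
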