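import math

import numpy as np
import pytest

from xbmech import energetics, geometry, kinetics, lattice
from xbmech.geometry import TipPosition
from xbmech.params import (BindingParams, KineticParams, SpringSpec,
                           CrossBridgeModel, ThermoParams, two_spring)


@pytest.fixture(scope="module")
def corr2(m2):
    return lattice.correction_factor(m2)


@pytest.fixture(scope="module")
def corr4(m4):
    return lattice.correction_factor(m4)


class TestDiffusion:
    def test_equipartition_of_spring_offsets(self, m2, thermo):
        """Thermal offsets of each spring carry kT/2: variance kT/k."""
        rng = np.random.default_rng(11)
        tips = kinetics.diffuse(m2, rng, 100_000, kt=thermo.kt)
        th = np.arctan2(tips[:, 1], tips[:, 0])
        arm = np.hypot(tips[:, 0], tips[:, 1])
        base, ext = m2.springs
        assert th.var() == pytest.approx(thermo.kt / base.stiffness,
                                         rel=0.02)
        assert arm.var() == pytest.approx(thermo.kt / ext.stiffness,
                                          rel=0.02)
        assert th.mean() == pytest.approx(base.rest_pre, abs=0.005)
        assert arm.mean() == pytest.approx(ext.rest_pre, abs=0.02)

    def test_stiff_limit_collapses_to_rest(self, thermo):
        stiff = CrossBridgeModel("2sXB", (
            SpringSpec("torsional", 0.8, 1.2, 1e9),
            SpringSpec("extensional", 19.0, 16.0, 1e9)))
        rng = np.random.default_rng(0)
        tips = kinetics.diffuse(stiff, rng, 1000, kt=thermo.kt)
        rest = geometry.rest_tip(stiff, 2)
        assert np.allclose(tips.mean(axis=0),
                           [rest.axial, rest.radial], atol=1e-3)
        assert tips.std(axis=0).max() < 1e-3

    def test_seeded_streams_reproduce(self, m4, thermo):
        a = kinetics.diffuse(m4, np.random.default_rng(5), 100, thermo.kt)
        b = kinetics.diffuse(m4, np.random.default_rng(5), 100, thermo.kt)
        assert np.array_equal(a, b)


class TestBindingProbability:
    def test_saturates_at_site(self):
        p = kinetics.binding_probability(np.array([[3.0, 15.0]]),
                                         np.array([3.0, 15.0]), tau=72.0)
        assert p[0] == 1.0

    def test_monotone_decreasing_in_distance(self):
        site = np.array([0.0, 15.0])
        d = np.linspace(0, 8, 50)
        tips = np.column_stack([site[0] + d, np.full_like(d, site[1])])
        p = kinetics.binding_probability(tips, site, tau=72.0)
        assert np.all(np.diff(p) <= 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_matches_literal_formula(self, rng):
        """Oracle: independent re-implementation of the probability law."""
        for tau in (12.0, 72.0, 144.0):
            tips = rng.uniform([-5, 10], [25, 20], size=(50, 2))
            site = np.array([10.0, 15.5])
            p = kinetics.binding_probability(tips, site, tau)
            d2 = ((tips - site) ** 2).sum(axis=1)
            expected = np.minimum(1.0, tau * np.exp(-d2))
            assert np.allclose(p, expected, rtol=0, atol=1e-15)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            kinetics.binding_probability(np.zeros((1, 2)),
                                         np.zeros(2), tau=0.0)


class TestAttachmentRate:
    def test_unreachable_site_has_negligible_rate(self, m2, thermo):
        site = TipPosition(60.0, 40.0)
        r = kinetics.attachment_rate_r12(
            m2, site, 34.0, BindingParams(tau=72.0, ensemble_n=2000),
            thermo)
        assert r.value == 0.0

    def test_monte_carlo_convergence(self, m2, thermo, corr2):
        """Estimates at N and 4N agree within two combined standard
        errors."""
        site = energetics.site_tip(m2, 12.0, 34.0, corr2)
        r1 = kinetics.attachment_rate_r12(
            m2, site, 34.0, BindingParams(tau=72.0, ensemble_n=4000,
                                          seed=1), thermo)
        r2 = kinetics.attachment_rate_r12(
            m2, site, 34.0, BindingParams(tau=72.0, ensemble_n=16000,
                                          seed=2), thermo)
        assert abs(r1.value - r2.value) < 2 * math.hypot(r1.se, r2.se)

    def test_rate_decreases_away_from_rest_spacing(self, m2, thermo, corr2):
        """Attachment slows as the lattice swells, across the high-rate
        region at and beyond the peak offset.  (Below the peak the trend
        can invert: the thermal cloud's arc passes closer to the more
        distant binding plane at small offsets.)"""
        for axial in (12.0, 14.0, 16.0):
            rates = {}
            for d10 in (34.0, 38.0):
                site = energetics.site_tip(m2, axial, d10, corr2)
                rates[d10] = kinetics.attachment_rate_r12(
                    m2, site, d10,
                    BindingParams(tau=72.0, ensemble_n=20000, seed=9),
                    thermo).value
            assert rates[38.0] < rates[34.0]


class TestEnergyDrivenRates:
    def test_powerstroke_depends_only_on_energy_difference(self, thermo,
                                                           kin):
        """Shifting both state energies by a constant leaves r23 fixed."""
        def rate(g2, g3):
            arg = kin.r23_shift + kin.r23_slope * (g2 - g3) / thermo.kt
            return 0.5 * kin.r23_max * (1 + math.tanh(arg))

        for shift in (-30.0, 0.0, 25.0):
            assert rate(-10.0 + shift, -25.0 + shift) == \
                pytest.approx(rate(-10.0, -25.0))

    def test_powerstroke_neutral_point(self, m2, thermo, kin, corr2):
        """Where G2 = G3 the sigmoid sits at its (near-maximal) neutral
        value; strongly uphill strokes shut off."""
        neutral = 0.5 * kin.r23_max * (1 + math.tanh(kin.r23_shift))
        # downhill site: stroke near the neutral/maximal plateau
        site = energetics.site_tip(m2, 5.0, 34.0, corr2)
        r = kinetics.powerstroke_rate_r23(m2, site, 34.0, thermo, kin)
        assert r.value <= kin.r23_max
        assert r.value == pytest.approx(neutral, rel=0.01)
        # far-extended offsets make the stroke strongly uphill (the
        # stretched post-stroke arm stores far more energy than the pre)
        site = energetics.site_tip(m2, 30.0, 34.0, corr2)
        r_uphill = kinetics.powerstroke_rate_r23(m2, site, 34.0, thermo,
                                                 kin)
        assert r_uphill.value < 0.05 * kin.r23_max

    def test_detachment_floor_at_rest_spacing(self, m4, thermo, kin, corr4):
        """The slowest detachment at rest spacing is the unstrained rate,
        attained at the post-stroke rest offset."""
        a3 = energetics.argmin_energy_offset(m4, 3, 34.0, corr4)
        site = energetics.site_tip(m4, a3, 34.0, corr4)
        r = kinetics.detachment_rate_r31(m4, site, 34.0, thermo, kin)
        assert r.value == pytest.approx(kin.r31_rest, rel=1e-4)

    def test_detachment_floor_rises_away_from_rest(self, m4, thermo, kin,
                                                   corr4):
        floors = {}
        for d10 in (30.0, 32.0, 34.0, 36.0, 38.0):
            a3 = energetics.argmin_energy_offset(m4, 3, d10, corr4)
            site = energetics.site_tip(m4, a3, d10, corr4)
            floors[d10] = kinetics.detachment_rate_r31(m4, site, d10,
                                                       thermo, kin).value
        assert floors[30.0] > floors[32.0] > floors[34.0]
        assert floors[34.0] < floors[36.0] < floors[38.0]

    def test_calibration_matches_default(self, m4, thermo, kin):
        rest, alpha = kinetics.calibrate_detachment(m4, thermo)
        assert rest == kin.r31_rest
        assert alpha == pytest.approx(kin.r31_alpha, abs=5e-4)


class TestReverseRates:
    def test_equal_energies_give_equal_rates(self):
        r = kinetics.reverse_rate(100.0, 0.0)
        assert r.value == pytest.approx(100.0)

    def test_boltzmann_identity(self):
        """reverse/forward ratio is exactly the Boltzmann factor of the
        forward free-energy drop."""
        kt = 4.11
        for dg in np.linspace(-80, 80, 33):
            rev = kinetics.reverse_rate(123.4, dg, kt=kt, clamp=100.0)
            assert rev.value / 123.4 == pytest.approx(
                math.exp(dg / kt), rel=1e-12)

    def test_strongly_downhill_forward_has_no_reverse(self):
        assert kinetics.reverse_rate(1e3, -400.0).value < 1e-18

    def test_clamp_guards_overflow(self):
        r = kinetics.reverse_rate(1.0, 1e6, clamp=50.0)
        assert r.value == pytest.approx(math.exp(50.0))

    def test_transition_is_swapped(self):
        fwd = kinetics.RateConstant(10.0, (2, 3))
        assert kinetics.reverse_rate(fwd, -1.0).transition == (3, 2)

    def test_negative_forward_rejected(self):
        with pytest.raises(ValueError):
            kinetics.reverse_rate(-1.0, 0.0)


class TestRateTable:
    def test_all_rates_non_negative_and_finite(self, m4, thermo, kin,
                                               corr4):
        site = energetics.site_tip(m4, 8.0, 34.0, corr4)
        table = kinetics.rate_table(m4, site, 34.0, thermo,
                                    BindingParams(tau=12.0, ensemble_n=2000,
                                                  seed=0), kin)
        for k, v in table.items():
            assert v >= 0 and np.isfinite(v), k

    def test_probability_rate_conversions_invert(self):
        for p in (0.0, 0.1, 0.9):
            r = kinetics.rate_from_probability(p, 1e-3)
            assert kinetics.probability_from_rate(r, 1e-3) == \
                pytest.approx(p, abs=1e-12)
        assert kinetics.rate_from_probability(0.2, 1e-3, mode="linear") == \
            pytest.approx(200.0)
        with pytest.raises(ValueError):
            kinetics.rate_from_probability(1.5, 1e-3)
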