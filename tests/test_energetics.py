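import numpy as np
import pytest

from xbmech import energetics, geometry, lattice
from xbmech.energetics import ForceVector
from xbmech.geometry import TipPosition


@pytest.fixture(scope="module")
def corr4(m4):
    return lattice.correction_factor(m4)


@pytest.fixture(scope="module")
def corr2(m2):
    return lattice.correction_factor(m2)


class TestFreeEnergy:
    def test_unbound_state_is_zero_everywhere(self, m4, thermo, corr4):
        for d10 in (30.0, 34.0, 38.0):
            for axial in (-5.0, 0.0, 12.0):
                g = energetics.free_energy_at(m4, 1, axial, d10, thermo,
                                              corr4)
                assert g.value == 0.0

    def test_pure_atp_term_at_rest_tip(self, m4, thermo):
        tip = geometry.rest_tip(m4, 2)
        g = energetics.free_energy(m4, 2, tip, 34.0, thermo)
        assert g.value == pytest.approx(thermo.baseline(2), abs=1e-8)
        assert g.value < 0

    def test_bound_states_ordered_by_efficiency_at_rest(self, m2, thermo):
        g2 = energetics.free_energy(m2, 2, geometry.rest_tip(m2, 2), 34.0,
                                    thermo)
        g3 = energetics.free_energy(m2, 3, geometry.rest_tip(m2, 3), 34.0,
                                    thermo)
        assert g3.value < g2.value < 0


class TestReactionForce:
    def test_zero_at_rest_tip(self, m4):
        f = energetics.reaction_force(m4, 3, geometry.rest_tip(m4, 3))
        assert abs(f.axial) < 1e-8 and abs(f.radial) < 1e-8

    def test_matches_finite_differences(self, m4, m2, rng, thermo):
        """Analytic (envelope) gradient vs central finite differences of
        the converter-optimised energy, over random tips."""
        h = 1e-4
        for model, n in ((m2, 60), (m4, 40)):
            for _ in range(n):
                x = rng.uniform(-5, 25)
                y = rng.uniform(13.2, 18.8)
                f = energetics.reaction_force(model, 3, TipPosition(x, y))
                ex = geometry.elastic_energy
                fd_ax = -(ex(model, TipPosition(x + h, y), 3)
                          - ex(model, TipPosition(x - h, y), 3)) / (2 * h)
                fd_rad = -(ex(model, TipPosition(x, y + h), 3)
                           - ex(model, TipPosition(x, y - h), 3)) / (2 * h)
                assert f.axial == pytest.approx(fd_ax, abs=1e-4)
                assert f.radial == pytest.approx(fd_rad, abs=1e-4)

    def test_envelope_property(self, m4, rng):
        """Differentiating the converter-optimised energy equals
        differentiating with the converter frozen at its optimum."""
        from xbmech.geometry import solve_4sxb, elastic_gradient

        for _ in range(10):
            tip = TipPosition(rng.uniform(-2, 20), rng.uniform(13.5, 18.5))
            g_env = elastic_gradient(m4, tip, 3)
            # frozen-converter finite difference
            sol = solve_4sxb(m4, tip, 3)
            xc, yc = sol.converter_point
            h = 1e-5

            def frozen(x, y):
                import math
                conv, lcd = m4.springs[2], m4.springs[3]
                dx, dy = x - xc, y - yc
                th3 = math.atan2(dy, -dx)
                l4 = math.hypot(dx, dy)
                return (0.5 * conv.stiffness * (th3 - conv.rest(3)) ** 2
                        + 0.5 * lcd.stiffness * (l4 - lcd.rest(3)) ** 2)

            fd = np.array([
                (frozen(tip.axial + h, tip.radial)
                 - frozen(tip.axial - h, tip.radial)) / (2 * h),
                (frozen(tip.axial, tip.radial + h)
                 - frozen(tip.axial, tip.radial - h)) / (2 * h)])
            assert np.allclose(g_env, fd, atol=1e-3)

    def test_radial_force_sign_flips_across_rest_spacing(self, m4, corr4):
        """Expansive below the calibration spacing, compressive above."""
        rest = geometry.rest_tip(m4, 3)
        f = {}
        for d10 in (32.0, 36.0):
            y = lattice.ssls_from_d10(d10, corr4)
            f[d10] = energetics.reaction_force(m4, 3,
                                               TipPosition(rest.axial, y))
        assert f[32.0].radial > 0 > f[36.0].radial

    def test_one_spring_model_has_no_radial_force(self, m1, rng):
        for _ in range(20):
            tip = TipPosition(rng.uniform(-10, 10), 1.0)
            f = energetics.reaction_force(m1, 3, tip)
            assert f.radial == 0.0

    def test_unbound_state_rejected(self, m4):
        with pytest.raises(ValueError):
            energetics.reaction_force(m4, 1, TipPosition(0, 15))


class TestStepSize:
    def test_one_spring_step_is_rest_difference(self, m1):
        for d10 in (30.0, 34.0, 38.0):
            assert energetics.step_size(m1, d10) == pytest.approx(5.0)

    def test_positive_forward_stroke(self, m4, m2, corr4, corr2):
        for model, corr in ((m4, corr4), (m2, corr2)):
            for d10 in (30.0, 34.0, 38.0):
                assert energetics.step_size(model, d10, corr) > 0

    def test_two_spring_step_has_interior_maximum(self, m2, corr2):
        d10s = np.arange(30.0, 38.5, 1.0)
        steps = [energetics.step_size(m2, d, corr2) for d in d10s]
        k = int(np.argmax(steps))
        assert 0 < k < len(d10s) - 1
        assert steps[0] < steps[k] and steps[-1] < steps[k]

    def test_energy_minimum_shift_with_lattice_spacing(self, m4, m2,
                                                       corr4, corr2):
        """The pre-stroke energy minimum sits > 3 nm further out at a
        compressed (32 nm) than at an expanded (38 nm) spacing."""
        for model, corr in ((m4, corr4), (m2, corr2)):
            a32 = energetics.argmin_energy_offset(model, 2, 32.0, corr)
            a38 = energetics.argmin_energy_offset(model, 2, 38.0, corr)
            assert a32 - a38 >= 3.0


class TestForceVector:
    def test_iterable(self):
        f = ForceVector(1.0, -2.0)
        assert tuple(f) == (1.0, -2.0)
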