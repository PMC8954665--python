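"""Dielectric mixture model family: closed forms, implicit rules, blends."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from graindiel.mixtures import (
    ConfocalSpec,
    FourPhaseSpec,
    PhaseConfiguration,
    SPHERE,
    configuration_volume_fractions,
    confocal_three_phase,
    deloor_four_phase,
    ema_blend,
    generalized_ellipsoid_mixture,
    maxwell_garnett,
    swa_fraction,
)
from graindiel.shape import depolarization_factors


def confocal_oracle(e0, e1, e2, phi1, phi2, n1, n2):
    """Independent transcription of the confocal three-phase formula,
    evaluated with sympy to guard against transcription slips."""
    import sympy as sp

    e0s, e1s, e2s = sp.Float(e0, 30), sp.Float(e1, 30), sp.Float(e2, 30)
    phi = sp.Float(phi1, 30) + sp.Float(phi2, 30)
    q = sp.Float(phi2, 30) / phi
    total_a = sp.S.Zero
    total_na = sp.S.Zero
    for N1i, N2i in zip(n1.axes, n2.axes):
        N1s, N2s = sp.Float(N1i, 30), sp.Float(N2i, 30)
        tail = (e2s - e1s) * q / (e1s + N2s * (e2s - e1s))
        numer = (e1s - e0s) + (e1s + N1s * (e0s - e1s)) * tail
        denom = (e0s + N1s * (e1s - e0s)) + N1s * (1 - N1s) * (e1s - e0s) * tail
        a_i = phi * numer / denom
        total_a += a_i
        total_na += N1s * a_i
    result = e0s + (e0s / 3) * total_a / (1 - total_na / 3)
    return float(result)


class TestMaxwellGarnett:
    def test_empty_and_full_limits(self):
        assert maxwell_garnett(2.0, 40.0, 0.0) == pytest.approx(2.0)
        assert maxwell_garnett(2.0, 40.0, 1.0) == pytest.approx(40.0)

    def test_matched_phases(self):
        assert maxwell_garnett(3.3, 3.3, 0.37) == pytest.approx(3.3)

    def test_dense_solid_in_air(self):
        assert maxwell_garnett(1.0, 3.3, 0.6) == pytest.approx(2.056, abs=5e-4)

    def test_monotone_in_fraction(self):
        vals = [maxwell_garnett(1.0, 80.0, p) for p in np.linspace(0, 1, 50)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_complex_lossy_inclusions(self):
        eps = maxwell_garnett(1.0, 80.0 - 10.0j, 0.3)
        assert isinstance(eps, complex)
        assert eps.imag < 0  # passive medium keeps the loss sign


class TestGeneralizedEllipsoidMixture:
    def test_spherical_nu_zero_reduces_to_maxwell_garnett(self):
        for e0, e1, phi in [(1, 3.3, 0.6), (2, 40, 0.2), (1, 80, 0.9)]:
            assert generalized_ellipsoid_mixture(e0, e1, phi, SPHERE) == pytest.approx(
                maxwell_garnett(e0, e1, phi), abs=1e-10
            )

    def test_reduction_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            e0 = rng.uniform(1, 5)
            e1 = rng.uniform(1, 80)
            phi = rng.uniform(0, 1)
            assert generalized_ellipsoid_mixture(e0, e1, phi, SPHERE) == pytest.approx(
                maxwell_garnett(e0, e1, phi), abs=1e-10
            )

    @pytest.mark.parametrize(
        "mode", ["maxwell_garnett", "polder_van_santen", "coherent_potential"]
    )
    def test_zero_fraction_returns_background(self, mode):
        n = depolarization_factors(1.4)
        assert generalized_ellipsoid_mixture(2.2, 60.0, 0.0, n, mode) == pytest.approx(
            2.2, abs=1e-10
        )

    def test_coherent_potential_against_root_finder(self):
        """The damped iteration lands on the bisection root of the residual."""
        from graindiel.mixtures import _generalized_rhs

        got = generalized_ellipsoid_mixture(1.0, 80.0, 0.3, SPHERE, "coherent_potential")

        def residual(e):
            return _generalized_rhs(e, 1.0, 80.0, 0.3, SPHERE, (1.0, 1.0, 1.0)).real - e

        oracle = brentq(residual, 1.0, 80.0, xtol=1e-12)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_polder_van_santen_self_consistency(self):
        """The returned value satisfies its own implicit equation."""
        from graindiel.mixtures import _generalized_rhs

        n = depolarization_factors(2.0)
        nu = tuple(1.0 - x for x in n.axes)
        got = generalized_ellipsoid_mixture(1.0, 78.54, 0.4, n, "polder_van_santen")
        assert _generalized_rhs(got, 1.0, 78.54, 0.4, n, nu).real == pytest.approx(
            got, abs=1e-8
        )


class TestConfocalThreePhase:
    def test_degenerate_shell_equals_two_phase(self):
        spec = ConfocalSpec(1.0, 3.3, 3.3, 0.25, 0.35)
        assert confocal_three_phase(spec) == pytest.approx(
            maxwell_garnett(1.0, 3.3, 0.6), abs=1e-12
        )

    def test_no_inclusions_returns_background(self):
        spec = ConfocalSpec(2.7, 40.0, 80.0, 0.0, 0.0)
        assert confocal_three_phase(spec) == pytest.approx(2.7)

    def test_against_independent_transcription(self):
        n = SPHERE
        spec = ConfocalSpec(1.0, 78.54, 2.5, 0.1, 0.6, n, n)
        assert confocal_three_phase(spec) == pytest.approx(
            confocal_oracle(1.0, 78.54, 2.5, 0.1, 0.6, n, n), rel=1e-12
        )

    def test_against_oracle_nonspherical(self):
        n = depolarization_factors(1.4)
        spec = ConfocalSpec(1.0, 30.0, 2.5, 0.15, 0.5, n, n)
        assert confocal_three_phase(spec) == pytest.approx(
            confocal_oracle(1.0, 30.0, 2.5, 0.15, 0.5, n, n), rel=1e-12
        )

    def test_continuous_in_core_fraction_at_zero(self):
        base = ConfocalSpec(1.0, 40.0, 2.5, 0.3, 0.0)
        eps0 = confocal_three_phase(base)
        epsd = confocal_three_phase(ConfocalSpec(1.0, 40.0, 2.5, 0.3, 1e-9))
        assert epsd == pytest.approx(eps0, abs=1e-6)

    def test_continuous_in_core_shell_contrast(self):
        same = confocal_three_phase(ConfocalSpec(1.0, 40.0, 40.0, 0.3, 0.3))
        near = confocal_three_phase(ConfocalSpec(1.0, 40.0, 40.0 + 1e-9, 0.3, 0.3))
        assert near == pytest.approx(same, abs=1e-6)


class TestDeLoorFourPhase:
    def test_uniform_medium(self):
        spec = FourPhaseSpec(7.7, 7.7, 7.7, 7.7, 0.2, 0.1, 0.3)
        assert deloor_four_phase(spec) == pytest.approx(7.7)

    def test_pure_solid(self):
        spec = FourPhaseSpec(2.5, 78.54, 10.0, 1.0, 0.0, 0.0, 0.0)
        assert deloor_four_phase(spec) == pytest.approx(2.5)

    def test_moist_porous_solid(self):
        spec = FourPhaseSpec(2.5, 78.54, 10.0, 1.0, 0.2, 0.0, 0.3)
        assert deloor_four_phase(spec) == pytest.approx(37.016 / 3.2564, abs=2e-3)
        assert deloor_four_phase(spec) == pytest.approx(11.37, abs=0.01)


class TestConfigurationVolumeFractions:
    def test_solid_core_water_shell(self):
        fr = configuration_volume_fractions(0.4, 0.1, "SWA")
        assert (fr.phi_2, fr.phi_1, fr.phi_0) == pytest.approx((0.6, 0.1, 0.3))
        assert (fr.core, fr.shell, fr.background) == ("S", "W", "A")

    def test_water_core_solid_shell(self):
        fr = configuration_volume_fractions(0.4, 0.1, "WSA")
        assert (fr.phi_2, fr.phi_1, fr.phi_0) == pytest.approx((0.1, 0.6, 0.3))

    def test_dry_grain_has_empty_water_role(self):
        fr = configuration_volume_fractions(0.4, 0.0, "SWA")
        assert fr.phi_1 == 0.0

    def test_conservation_over_all_orderings(self):
        for ordering in ("SWA", "WSA", "ASW", "AWS", "SAW", "WAS"):
            fr = configuration_volume_fractions(0.45, 0.2, ordering)
            assert fr.phi_0 + fr.phi_1 + fr.phi_2 == pytest.approx(1.0, abs=1e-15)

    def test_water_beyond_pore_space_rejected(self):
        with pytest.raises(ValueError, match="pore space"):
            configuration_volume_fractions(0.4, 0.45, "SWA")


class TestSwaFraction:
    def test_below_critical_all_shell_configured(self):
        assert swa_fraction(0.08, 0.16) == (1.0, 0.0)

    def test_at_critical(self):
        assert swa_fraction(0.16, 0.16) == (1.0, 0.0)

    def test_twice_critical(self):
        assert swa_fraction(0.32, 0.16) == pytest.approx((0.5, 0.5))

    def test_continuous_at_junction(self):
        just_above = swa_fraction(0.16 + 1e-12, 0.16)
        assert just_above[0] == pytest.approx(1.0, abs=1e-10)

    def test_fractions_sum_to_one(self):
        for m_v in (0.01, 0.16, 0.2, 0.39):
            f1, f2 = swa_fraction(m_v, 0.16)
            assert f1 + f2 == pytest.approx(1.0)
            config = PhaseConfiguration("SWA", 0.16, f1, f2)
            assert config.f_swa == f1


class TestEmaBlend:
    def test_pure_component_limits(self):
        assert ema_blend(5.0, 20.0, 1.0, 0.0) == pytest.approx(5.0, abs=1e-12)
        assert ema_blend(5.0, 20.0, 0.0, 1.0) == pytest.approx(20.0, abs=1e-12)

    def test_identical_components(self):
        assert ema_blend(7.0, 7.0, 0.3, 0.7) == pytest.approx(7.0)

    def test_even_blend(self):
        got = ema_blend(5.0, 20.0, 0.5, 0.5)
        assert got == pytest.approx(3.125 + math.sqrt(9.7656 + 50.0), abs=2e-4)
        assert got == pytest.approx(10.86, abs=5e-3)

    def test_symmetric_under_component_swap(self):
        assert ema_blend(5.0, 20.0, 0.3, 0.7) == pytest.approx(
            ema_blend(20.0, 5.0, 0.7, 0.3), abs=1e-12
        )

    def test_is_bruggeman_root(self):
        """The closed form solves sum f_i (e_i - e)/(e_i + 2e) = 0 exactly."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            ea, eb = rng.uniform(1, 80, 2)
            f = rng.uniform(0, 1)
            eps = ema_blend(ea, eb, f, 1 - f)
            residual = f * (ea - eps) / (ea + 2 * eps) + (1 - f) * (eb - eps) / (
                eb + 2 * eps
            )
            assert abs(residual) < 1e-10

    def test_mismatched_fractions_rejected(self):
        with pytest.raises(ValueError):
            ema_blend(5.0, 20.0, 0.6, 0.6)


class TestBoundsProperties:
    """All mixture rules stay inside constituent and Wiener bounds across
    the parameter regime grain modeling occupies (background = air or
    air+solid average, inclusions up to free water, moderate loading)."""

    def test_two_phase_family_bounds(self, rng):
        n_draws = 1000
        for _ in range(n_draws):
            e0 = rng.uniform(1, 5)
            e1 = rng.uniform(1, 80)
            aspect = rng.uniform(0.8, 3.3)
            n = depolarization_factors(aspect)
            for mode, phi in (
                ("maxwell_garnett", rng.uniform(0, 1)),
                ("polder_van_santen", rng.uniform(0, 0.7)),
                ("coherent_potential", rng.uniform(0, 0.7)),
            ):
                eps = generalized_ellipsoid_mixture(e0, e1, phi, n, mode)
                lo, hi = min(e0, e1), max(e0, e1)
                wiener_lo = 1.0 / ((1 - phi) / e0 + phi / e1)
                wiener_hi = (1 - phi) * e0 + phi * e1
                assert lo - 1e-8 <= eps <= hi + 1e-8, (mode, e0, e1, phi)
                assert wiener_lo - 1e-8 <= eps <= wiener_hi + 1e-8, (mode, e0, e1, phi)

    def test_confocal_and_blend_bounds(self, rng):
        for _ in range(1000):
            e0 = rng.uniform(1, 5)
            e1 = rng.uniform(1, 80)
            e2 = rng.uniform(1, 80)
            phi_b = rng.uniform(0.2, 0.6)
            m_v = rng.uniform(0, phi_b)
            n = depolarization_factors(rng.uniform(0.8, 3.3))
            fr = configuration_volume_fractions(phi_b, m_v, "SWA")
            shell_eps = e1 if fr.phi_1 > 0 else e2
            eps = confocal_three_phase(
                ConfocalSpec(e0, shell_eps, e2, fr.phi_1, fr.phi_2, n, n)
            )
            phases = [(fr.phi_0, e0), (fr.phi_1, shell_eps), (fr.phi_2, e2)]
            lo = min(e for _, e in phases)
            hi = max(e for _, e in phases)
            wiener_lo = 1.0 / sum(w / e for w, e in phases)
            wiener_hi = sum(w * e for w, e in phases)
            assert lo - 1e-8 <= eps <= hi + 1e-8
            assert wiener_lo - 1e-6 <= eps <= wiener_hi + 1e-6

            f = rng.uniform(0, 1)
            blend = ema_blend(e1, e2, f, 1 - f)
            assert min(e1, e2) - 1e-8 <= blend <= max(e1, e2) + 1e-8

    def test_four_phase_bounds(self, rng):
        for _ in range(1000):
            spec = FourPhaseSpec(
                rng.uniform(2, 5),
                rng.uniform(60, 80),
                rng.uniform(2, 40),
                1.0,
                *(rng.uniform(0, 0.33, 3)),
            )
            eps = deloor_four_phase(spec)
            values = [spec.eps_s, spec.eps_fw, spec.eps_bw, spec.eps_a]
            assert min(values) - 1e-8 <= eps <= max(values) + 1e-8
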