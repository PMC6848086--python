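"""Photokinetics: excitation rates, photostationary states, protocol simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bphpkit.kinetics import (
    DarkComponent,
    IlluminationProtocol,
    LightSource,
    PhotochromeParams,
    ProtocolSegment,
    excitation_rate,
    photostationary_fraction,
    relaxation_rate,
    simulate_protocol,
)
from bphpkit.spectral import (
    ChromophoreBasis,
    GroundState,
    State,
    StateFractions,
    default_grid,
)
from bphpkit.inference import fit_dark_reversion
from bphpkit.synth import FIXTURE_IRRADIANCE, FixtureName, make_protocol_fixture


def flat_basis(eps_pr=1.0, eps_pfr=1.0, ground=GroundState.PR_GROUND):
    """Wavelength-independent basis: isolates the rate algebra."""
    wl = default_grid()
    return ChromophoreBasis(
        "flat", wl, np.full(wl.size, eps_pr), np.full(wl.size, eps_pfr), ground
    )


def params(phi_fwd, phi_rev, ground=GroundState.PR_GROUND, dark=()):
    return PhotochromeParams(phi_fwd, phi_rev, ground, tuple(dark))


class TestExcitationRate:
    def test_zero_irradiance(self):
        basis = flat_basis(eps_pr=50000.0)
        assert excitation_rate(basis, State.PR, LightSource(700.0, 0.0)) == 0.0

    def test_linear_in_irradiance(self):
        basis = flat_basis(eps_pr=50000.0)
        k1 = excitation_rate(basis, State.PR, LightSource(700.0, 30.0))
        k2 = excitation_rate(basis, State.PR, LightSource(700.0, 60.0))
        assert k2 == pytest.approx(2.0 * k1)

    def test_hand_evaluated_constant(self):
        """eps = 80 000 M^-1 cm^-1 at 60 umol m^-2 s^-1 -> ~1.1 s^-1.

        ln(10)*1e-7 * 80000 * 60 = 1.105...
        """
        basis = flat_basis(eps_pr=80000.0)
        k = excitation_rate(basis, State.PR, LightSource(700.0, 60.0))
        assert k == pytest.approx(math.log(10) * 1e-7 * 80000 * 60, rel=1e-12)
        assert k == pytest.approx(1.1, abs=0.01)

    def test_off_grid_wavelength_rejected(self):
        basis = flat_basis()
        with pytest.raises(ValueError):
            excitation_rate(basis, State.PR, LightSource(900.0, 10.0))


class TestPhotostationaryFraction:
    def test_isosbestic_source_yield_ratio_two_gives_two_thirds_pr(self):
        """Equal extinctions with Pfr->Pr yield twice Pr->Pfr leave 2/3 Pr."""
        basis = flat_basis(1.0, 1.0, ground=GroundState.PFR_GROUND)
        p = params(0.1, 0.2, ground=GroundState.PFR_GROUND)
        f = photostationary_fraction(basis, p, [LightSource(660.0, 65.0)])
        assert f.f_pr == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_symmetric_system_reaches_one_half(self):
        basis = flat_basis(1.0, 1.0)
        p = params(0.1, 0.1)
        f = photostationary_fraction(basis, p, [LightSource(700.0, 65.0)])
        assert f.f_pfr == pytest.approx(0.5, abs=1e-12)

    def test_far_red_balance_gives_one_third_pfr(self):
        """eps ratio 13 against a 6.5-fold yield advantage: 6.5/(6.5+13)=1/3."""
        basis = flat_basis(1.0, 13.0)
        p = params(0.13, 0.02)
        f = photostationary_fraction(basis, p, [LightSource(780.0, 65.0)])
        assert f.f_pfr == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_all_rates_zero_rejected(self):
        basis = flat_basis(1.0, 1.0)
        p = params(0.1, 0.1)
        with pytest.raises(ValueError):
            photostationary_fraction(basis, p, [LightSource(700.0, 0.0)])

    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_under_irradiance_scaling_without_dark(self, scale):
        basis = flat_basis(1.0, 2.0)
        p = params(0.2, 0.1)
        f1 = photostationary_fraction(basis, p, [LightSource(700.0, 65.0)])
        f2 = photostationary_fraction(basis, p, [LightSource(700.0, 65.0 * scale)])
        assert f1.f_pfr == pytest.approx(f2.f_pfr, abs=1e-12)

    def test_monotone_approach_to_strong_light_limit_with_dark(self):
        basis = flat_basis(50000.0, 100000.0)
        p = params(0.2, 0.1, dark=[DarkComponent(1.0, 0.01)])
        limit = photostationary_fraction(
            basis, p, [LightSource(700.0, 65.0)], include_dark_reversion=False
        ).f_pfr
        values = [
            photostationary_fraction(
                basis, p, [LightSource(700.0, e)], include_dark_reversion=True
            ).f_pfr
            for e in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(v < limit for v in values)
        assert values[-1] == pytest.approx(limit, abs=0.01)

    @given(
        e1=st.floats(1.0, 100.0),
        e2=st.floats(1.0, 100.0),
        s1=st.floats(0.1, 10.0),
        s2=st.floats(0.1, 10.0),
    )
    def test_combined_sources_between_single_source_fractions(self, e1, e2, s1, s2):
        wl = default_grid()
        eps_pfr = np.interp(wl, [wl[0], wl[-1]], [s1, s2])
        basis = ChromophoreBasis(
            "ramp", wl, np.ones(wl.size), eps_pfr, GroundState.PR_GROUND
        )
        p = params(0.2, 0.1)
        src1, src2 = LightSource(500.0, e1), LightSource(800.0, e2)
        f1 = photostationary_fraction(basis, p, [src1]).f_pfr
        f2 = photostationary_fraction(basis, p, [src2]).f_pfr
        f12 = photostationary_fraction(basis, p, [src1, src2]).f_pfr
        lo, hi = min(f1, f2), max(f1, f2)
        assert lo - 1e-12 <= f12 <= hi + 1e-12


class TestRelaxationRate:
    def test_dark_only_single_component(self):
        basis = flat_basis()
        p = params(0.1, 0.1, dark=[DarkComponent(1.0, 0.0123)])
        assert relaxation_rate(basis, p, []) == pytest.approx(0.0123)

    def test_additive_over_sources(self):
        basis = flat_basis(1.0, 2.0)
        p = params(0.2, 0.1)
        s1, s2 = LightSource(650.0, 30.0), LightSource(750.0, 45.0)
        r1 = relaxation_rate(basis, p, [s1])
        r2 = relaxation_rate(basis, p, [s2])
        assert relaxation_rate(basis, p, [s1, s2]) == pytest.approx(r1 + r2)

    def test_simulated_approach_recovers_rate(self, basis_bphp1, params_bphp1):
        """A mono-exponential fit of the simulated approach matches the
        closed-form relaxation rate within 0.1%."""
        src = [LightSource(660.0, FIXTURE_IRRADIANCE)]
        lam = relaxation_rate(basis_bphp1, params_bphp1, src)
        protocol = IlluminationProtocol(
            segments=(ProtocolSegment(tuple(src), 8.0 / lam),),
        )
        traj = simulate_protocol(
            basis_bphp1, params_bphp1, protocol, StateFractions.from_pfr(0.0)
        )
        fit = fit_dark_reversion(traj.times, traj.f_pfr, max_components=1)
        assert fit.rates[0] == pytest.approx(lam, rel=1e-3)


class TestSimulateProtocol:
    def test_dark_monoexponential_decay_analytic(self):
        """Pure dark reversion of a PFR_GROUND protein: f_pr(t) = exp(-k t)."""
        k = 0.01
        basis = flat_basis(ground=GroundState.PFR_GROUND)
        p = params(0.1, 0.1, ground=GroundState.PFR_GROUND,
                   dark=[DarkComponent(1.0, k)])
        protocol = IlluminationProtocol(segments=(ProtocolSegment((), 600.0),))
        traj = simulate_protocol(basis, p, protocol, StateFractions(1.0, 0.0))
        np.testing.assert_allclose(traj.f_pr, np.exp(-k * traj.times), atol=1e-12)
        # half of the initial Pr population remains at t = ln2 / k
        t_half = math.log(2.0) / k
        assert np.interp(t_half, traj.times, traj.f_pr) == pytest.approx(0.5, abs=1e-5)

    def test_long_segment_reaches_photostationary_state(self, basis_bphp1, params_bphp1):
        src = (LightSource(660.0, FIXTURE_IRRADIANCE),)
        lam = relaxation_rate(basis_bphp1, params_bphp1, src)
        protocol = IlluminationProtocol(segments=(ProtocolSegment(src, 20.0 / lam),))
        traj = simulate_protocol(
            basis_bphp1, params_bphp1, protocol, StateFractions.from_pfr(0.0)
        )
        f_ss = photostationary_fraction(
            basis_bphp1, params_bphp1, list(src), include_dark_reversion=True
        )
        assert traj.f_pfr[-1] == pytest.approx(f_ss.f_pfr, abs=1e-6)

    def test_fig4_left_segment_ordering(self):
        """Far-red light makes ~1/3 Pfr, adding red ~0.9, red alone ~1, and a
        final dark period relaxes back toward the Pr ground state."""
        fx = make_protocol_fixture(FixtureName.FIG4_LEFT)
        traj = simulate_protocol(fx.basis, fx.params, fx.protocol, fx.initial)
        ends = [
            float(traj.f_pfr[np.searchsorted(traj.times, t, side="right") - 1])
            for t in fx.protocol.boundaries()[1:]
        ]
        f_780a, f_mixed, f_660a, f_780b, f_660b, f_dark = ends
        assert f_780a == pytest.approx(1.0 / 3.0, abs=0.06)
        assert f_mixed == pytest.approx(0.9, abs=0.02)
        assert f_660a > 0.95
        assert f_780b == pytest.approx(f_780a, abs=0.01)
        assert f_660b > 0.95
        assert f_780a < f_mixed < f_660a
        assert f_dark < 0.15

    def test_conservation_everywhere(self):
        fx = make_protocol_fixture(FixtureName.FIG4_RIGHT)
        traj = simulate_protocol(fx.basis, fx.params, fx.protocol, fx.initial)
        np.testing.assert_allclose(traj.f_pr + traj.f_pfr, 1.0, atol=1e-9)
        assert np.all((traj.f_pfr >= 0.0) & (traj.f_pfr <= 1.0))

    @pytest.mark.parametrize("name", [FixtureName.FIG4_LEFT, FixtureName.FIG4_RIGHT])
    def test_analytic_matches_stiff_ode(self, name):
        fx = make_protocol_fixture(name)
        kwargs = dict(dt=min(s.duration for s in fx.protocol.segments) / 12.0)
        t_analytic = simulate_protocol(
            fx.basis, fx.params, fx.protocol, fx.initial, **kwargs
        )
        t_ode = simulate_protocol(
            fx.basis, fx.params, fx.protocol, fx.initial, method="ode", **kwargs
        )
        np.testing.assert_allclose(t_analytic.f_pfr, t_ode.f_pfr, atol=1e-6)

    def test_absorbance_traces_consistent_with_mixture(self, basis_bphp2, params_bphp2):
        from bphpkit.spectral import mixture_spectrum

        protocol = IlluminationProtocol(
            segments=(ProtocolSegment((LightSource(780.0, 65.0),), 60.0),),
            observation_wavelengths=(755.0, 690.0),
        )
        cl = 1e-5
        traj = simulate_protocol(
            basis_bphp2, params_bphp2, protocol, StateFractions.from_pfr(1.0),
            concentration_pathlength=cl,
        )
        for i in (0, traj.times.size // 2, traj.times.size - 1):
            spec = mixture_spectrum(
                basis_bphp2, StateFractions.from_pfr(traj.f_pfr[i]), cl
            )
            for w in (755.0, 690.0):
                expected = float(np.interp(w, spec.wavelengths, spec.absorbance))
                assert traj.trace(w)[i] == pytest.approx(expected, rel=1e-12)

    def test_invalid_dt_rejected(self, basis_bphp1, params_bphp1):
        protocol = IlluminationProtocol(
            segments=(ProtocolSegment((LightSource(660.0, 65.0),), 100.0),)
        )
        with pytest.raises(ValueError):
            simulate_protocol(
                basis_bphp1, params_bphp1, protocol, StateFractions.from_pfr(0.0),
                dt=50.0,
            )


class TestParamValidation:
    def test_yield_bounds(self):
        with pytest.raises(ValueError):
            params(0.0, 0.5)
        with pytest.raises(ValueError):
            params(0.5, 1.5)

    def test_dark_amplitudes_must_sum_to_one(self):
        with pytest.raises(ValueError):
            params(0.1, 0.1, dark=[DarkComponent(0.5, 0.01), DarkComponent(0.2, 0.1)])

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError):
            LightSource(700.0, -1.0)
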