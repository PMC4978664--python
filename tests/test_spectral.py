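"""Characteristic-equation analysis: coefficients, Hopf curves, stability."""

import cmath
import math

import numpy as np
import pytest

from delogistic import (
    characteristic_residual,
    classify,
    critical_delays,
    hopf_frequencies,
    mode_coefficients,
    mode_cutoff,
    transversality,
    trivial_equilibrium_spectrum,
)
from delogistic.spectral import minimal_critical_delay

from _oracle import imaginary_axis_crossings, newton_root
from conftest import random_hopf_params

OMEGA0 = 0.348266
TAU0 = 5.81966


class TestModeCoefficients:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (0, (1.24, 0.24, 0.24, 0.44)),
            (1, (1.615, 0.58125, 0.24, 0.5)),
        ],
    )
    def test_reference_values(self, ref_params, n, expected):
        mc = mode_coefficients(ref_params, n, "reduced")
        assert (mc.A, mc.B, mc.C, mc.D) == pytest.approx(expected, rel=1e-12)

    def test_no_diffusion_removes_mode_dependence(self, ref_params):
        p = ref_params.replace(d1=1e-14, d2=1e-14)
        base = mode_coefficients(p, 0)
        for n in (1, 3, 10):
            mc = mode_coefficients(p, n)
            assert (mc.A, mc.B, mc.C, mc.D) == pytest.approx(
                (base.A, base.B, base.C, base.D), rel=1e-9
            )

    def test_all_coefficients_positive(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_hopf_params(rng)
            for n in (0, 1, 4):
                for conv in ("reduced", "exact"):
                    mc = mode_coefficients(p, n, conv)
                    assert min(mc.A, mc.B, mc.C, mc.D) > 0

    def test_conventions_agree_when_r_is_one(self, ref_params):
        p = ref_params.replace(r=1.0)
        for n in (0, 2):
            red = mode_coefficients(p, n, "reduced")
            exa = mode_coefficients(p, n, "exact")
            # coupling entries coincide at r=1; remaining cross terms differ
            # only through the d1-vs-d2 bookkeeping, which vanishes at n=0
            if n == 0:
                assert (red.A, red.B, red.C, red.D) == pytest.approx(
                    (exa.A, exa.B, exa.C, exa.D), rel=1e-12
                )


class TestTrivialEquilibrium:
    def test_reference_mode0(self, ref_params):
        pairs, verdict = trivial_equilibrium_spectrum(ref_params, 3)
        assert pairs[0] == pytest.approx((0.6, -1.0))
        assert verdict == "unstable"

    def test_always_unstable_and_monotone(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            p = random_hopf_params(rng)
            pairs, verdict = trivial_equilibrium_spectrum(p, 6)
            assert verdict == "unstable"
            assert pairs[0][0] == pytest.approx(p.r)
            l1 = [a for a, _ in pairs]
            l2 = [b for _, b in pairs]
            assert all(x > y for x, y in zip(l1, l1[1:]))
            assert all(x > y for x, y in zip(l2, l2[1:]))


class TestHopfFrequencies:
    def test_reference_mode0(self, ref_params):
        freqs = hopf_frequencies(ref_params, 0)
        assert len(freqs) == 1
        assert freqs[0] == pytest.approx(OMEGA0, rel=1e-5)

    def test_reference_mode1_empty(self, ref_params):
        assert hopf_frequencies(ref_params, 1) == []

    def test_delay_independent_regime_has_no_frequencies(self, ref_params):
        # a1 > a2 + b*c*K/(a*r): no mode ever admits an imaginary root
        p = ref_params.replace(a1=5.0, a2=1.0)
        assert p.a1 > p.a2 + p.b * p.c * p.K / (p.a * p.r)
        for n in range(0, 51, 5):
            assert hopf_frequencies(p, n) == []


class TestModeCutoff:
    def test_reference_is_zero(self, ref_params):
        assert mode_cutoff(ref_params) == 0

    def test_none_in_delay_independent_regime(self, ref_params):
        assert mode_cutoff(ref_params.replace(a1=5.0, a2=1.0)) is None

    def test_shrinking_domain_cannot_increase_cutoff(self, ref_params):
        # B_n^2 - D_n^2 depends on n only through n^2/l^2
        rng = np.random.default_rng(13)
        for _ in range(10):
            p = random_hopf_params(rng)
            big = mode_cutoff(p.replace(l=max(p.l, 2.0)))
            small = mode_cutoff(p.replace(l=0.2))
            if big is None:
                assert small is None
            else:
                assert small is not None and small <= big


class TestCriticalDelays:
    def test_reference_first_three(self, ref_params):
        pts = critical_delays(ref_params, 0, 2)
        taus = [hp.tau for hp in pts]
        assert taus == pytest.approx([5.81966, 23.861, 41.9024], rel=1e-4)

    def test_spacing_is_two_pi_over_omega(self, ref_params):
        pts = critical_delays(ref_params, 0, 3)
        gaps = np.diff([hp.tau for hp in pts])
        assert np.allclose(gaps, 2 * math.pi / pts[0].omega, rtol=1e-9)

    def test_residual_defines_the_points(self, ref_params):
        for hp in critical_delays(ref_params, 0, 2):
            res = characteristic_residual(ref_params, 0, 1j * hp.omega, hp.tau)
            assert abs(res) < 1e-9

    def test_error_when_no_frequency(self, ref_params):
        with pytest.raises(ValueError, match="no Hopf"):
            critical_delays(ref_params, 1, 0)

    def test_sin_omega_tau_positive(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            p = random_hopf_params(rng)
            hp = critical_delays(p, 0, 0)[0]
            assert math.sin(hp.omega * hp.tau) > 0
            mc = mode_coefficients(p, 0)
            assert mc.A * mc.D - mc.B * mc.C > 0


class TestCharacteristicResidual:
    def test_lambda_zero_gives_b_plus_d(self, ref_params):
        mc = mode_coefficients(ref_params, 0)
        res = characteristic_residual(ref_params, 0, 0.0, 3.0)
        assert res == pytest.approx(mc.B + mc.D)
        assert res.real > 0  # zero is never a characteristic root

    def test_printed_rounding_of_reference_point(self, ref_params):
        res = characteristic_residual(ref_params, 0, 1j * OMEGA0, TAU0)
        assert abs(res) < 1e-4  # limited by the 6-digit rounding of the inputs

    def test_brute_force_crossings_match_closed_form(self):
        """Grid + Newton root search over the characteristic function finds
        the same (omega, tau0) as the arccos closed form (20 random sets)."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = random_hopf_params(rng)
            hp = critical_delays(p, 0, 0)[0]

            def char(lam):
                return characteristic_residual(p, 0, lam, hp.tau)

            roots = imaginary_axis_crossings(char, omega_max=2.5 * hp.omega)
            assert roots, "brute force found no imaginary-axis root"
            best = min(roots, key=lambda z: abs(z.imag - hp.omega))
            assert best.imag == pytest.approx(hp.omega, rel=1e-6)


class TestTransversality:
    def test_reference_sign_positive(self, ref_params):
        hp = critical_delays(ref_params, 0, 0)[0]
        tv = transversality(ref_params, hp)
        assert tv.sign == +1
        assert tv.d_lambda_d_tau.real > 0

    def test_matches_numerical_root_tracking(self, ref_params):
        hp = critical_delays(ref_params, 0, 0)[0]
        tv = transversality(ref_params, hp)
        h = 1e-4

        def root_at(tau):
            return newton_root(
                lambda lam: characteristic_residual(ref_params, 0, lam, tau),
                1j * hp.omega,
            )

        num = (root_at(hp.tau + h) - root_at(hp.tau - h)) / (2 * h)
        assert num.real == pytest.approx(tv.d_lambda_d_tau.real, rel=1e-4)
        assert num.imag == pytest.approx(tv.d_lambda_d_tau.imag, rel=1e-4)

    def test_sign_constant_across_branches(self, ref_params):
        for hp in critical_delays(ref_params, 0, 2):
            assert transversality(ref_params, hp).d_lambda_d_tau.real > 0


class TestClassify:
    @pytest.mark.parametrize("tau, verdict", [(2.0, "stable"), (10.0, "unstable"), (0.0, "stable")])
    def test_reference_verdicts(self, ref_params, tau, verdict):
        assert classify(ref_params, tau).verdict == verdict

    def test_tau_zero_stable_for_random_parameters(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            p = random_hopf_params(rng)
            assert classify(p, 0.0).verdict == "stable"

    def test_at_bifurcation_window(self, ref_params):
        tau0 = minimal_critical_delay(ref_params)[0]
        assert classify(ref_params, tau0).verdict == "at_bifurcation"
        assert classify(ref_params, tau0 + 1e-6).verdict == "unstable"

    def test_delay_independent_regime(self, ref_params):
        p = ref_params.replace(a1=5.0, a2=1.0)
        cls = classify(p, 50.0)
        assert cls.regime == "delay_independent_stable"
        assert cls.verdict == "stable"

    def test_flags_a1_below_a2(self, ref_params):
        cls = classify(ref_params.replace(a1=1.5, a2=2.0), 1.0)
        assert cls.outside_stated_regime


class TestTrigConsistency:
    def test_cos_sin_on_unit_circle(self):
        """The split real/imaginary crossing equations define a point on the
        unit circle at every computed Hopf frequency."""
        from delogistic.spectral import _trig_of_omega_tau

        rng = np.random.default_rng(31)
        for _ in range(20):
            p = random_hopf_params(rng)
            mc = mode_coefficients(p, 0)
            for omega in hopf_frequencies(p, 0):
                c, s = _trig_of_omega_tau(mc, omega)
                assert c * c + s * s == pytest.approx(1.0, abs=1e-9)
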