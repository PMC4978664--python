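"""Per-mode characteristic analysis of the positive equilibrium.

Expanding perturbations in the Neumann eigenfunctions ``cos(n x / l)`` turns
the linearized problem into a family of transcendental characteristic
equations, one per spatial mode ``n``:

    lambda^2 + A_n*lambda + B_n + exp(-lambda*tau) * (C*lambda + D_n) = 0.

A conjugate pair ``+-i*omega_n`` crossing the imaginary axis at a critical
delay ``tau_j^(n)`` signals a Hopf bifurcation of mode ``n``.  This module
computes the coefficients, the Hopf frequencies (roots of a quadratic in
``omega^2``), the critical delays (principal arccos branch plus its
``2*pi*j/omega`` translates), the largest destabilizable mode ``N0``, the
transversality derivative ``d lambda / d tau``, and a stability verdict.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass

from .model import coupling_entry, positive_equilibrium, _check_convention
from .params import ModelParameters

#: Default safety bound for mode scans.
DEFAULT_N_MAX = 200

#: Treat |B_n^2 - D_n^2| below this as a tie (classified as >= 0).
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ModeCoefficients:
    """Coefficients A_n, B_n, C, D_n of the mode-n characteristic equation."""

    n: int
    A: float
    B: float
    C: float
    D: float

    @property
    def P(self) -> float:
        """Quadratic-in-omega^2 linear coefficient, A_n^2 - 2 B_n - C^2.

        Computed directly from the coefficient values (robust against
        algebraic re-expansions of the same quantity).
        """
        return self.A * self.A - 2.0 * self.B - self.C * self.C

    @property
    def Q(self) -> float:
        """Quadratic-in-omega^2 constant coefficient, B_n^2 - D_n^2."""
        return self.B * self.B - self.D * self.D


@dataclass(frozen=True)
class HopfPoint:
    """A purely imaginary characteristic root: mode n, branch j, (omega, tau)."""

    n: int
    j: int
    omega: float
    tau: float


@dataclass(frozen=True)
class StabilityClassification:
    regime: str  # delay_independent_stable | conditionally_stable
    n0: int | None
    tau0: float | None
    verdict: str  # stable | unstable | at_bifurcation
    outside_stated_regime: bool = False


def mode_coefficients(params: ModelParameters, n: int, convention: str = "reduced") -> ModeCoefficients:
    """Characteristic coefficients for spatial mode ``n``.

    ``reduced`` follows the classical displays for this model (control
    coupling ``b*c*N*`` and ``d1`` in the cross terms of B_n, D_n);
    ``exact`` expands the determinant of the true Jacobian (coupling
    ``r*b*c*N*`` and ``d2`` cross terms).  The two coincide at ``n = 0``
    up to the coupling factor ``r``.
    """
    if n < 0:
        raise ValueError("mode index n must be nonnegative")
    _check_convention(convention)
    p = params
    nstar = positive_equilibrium(params).nstar
    k2 = (n / p.l) ** 2
    s1 = p.r * p.a1 / p.K * nstar  # instantaneous self-limitation entry
    s2 = p.r * p.a2 / p.K * nstar  # delayed self-limitation entry
    cpl = coupling_entry(params, convention)
    A = (p.d1 + p.d2) * k2 + p.a + s1
    C = s2
    if convention == "reduced":
        B = p.d1 * p.d2 * k2 * k2 + (p.a + s1) * p.d1 * k2 + p.a * s1
        D = s2 * p.d1 * k2 + p.a * s2 + p.b * cpl
    else:
        B = (p.d1 * k2 + s1) * (p.d2 * k2 + p.a)
        D = s2 * (p.d2 * k2 + p.a) + p.b * cpl
    return ModeCoefficients(n=n, A=A, B=B, C=C, D=D)


def characteristic_residual(
    params: ModelParameters, n: int, lam: complex, tau: float, convention: str = "reduced"
) -> complex:
    """Left side of the mode-n characteristic equation at (lambda, tau)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    mc = mode_coefficients(params, n, convention)
    return lam * lam + mc.A * lam + mc.B + cmath.exp(-lam * tau) * (mc.C * lam + mc.D)


def trivial_equilibrium_spectrum(params: ModelParameters, n_max: int):
    """Eigenvalues at the extinction state E0 = (0, 0) and its verdict.

    The spectrum is real and explicit: lambda_{1,n} = -d1*n^2/l^2 + r and
    lambda_{2,n} = -d2*n^2/l^2 - a.  Since lambda_{1,0} = r > 0, E0 is
    always unstable: the population invades from low density.
    """
    if n_max < 0:
        raise ValueError("n_max must be nonnegative")
    p = params
    pairs = [
        (-p.d1 * (n / p.l) ** 2 + p.r, -p.d2 * (n / p.l) ** 2 - p.a)
        for n in range(n_max + 1)
    ]
    return pairs, "unstable"


def hopf_frequencies(params: ModelParameters, n: int, convention: str = "reduced") -> list[float]:
    """Positive frequencies omega with +-i*omega solving the mode-n equation.

    Squaring the real/imaginary split of the characteristic equation yields
    omega^4 + P_n*omega^2 + Q_n = 0 with P_n = A_n^2 - 2B_n - C^2 and
    Q_n = B_n^2 - D_n^2; the returned list holds the square roots of all
    strictly positive real roots in omega^2 (descending).  When Q_n < 0 the
    list has exactly one element, matching the closed form
    sqrt((-P_n + sqrt(P_n^2 - 4 Q_n)) / 2).
    """
    mc = mode_coefficients(params, n, convention)
    P, Q = mc.P, mc.Q
    disc = P * P - 4.0 * Q
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    roots = [(-P + sq) / 2.0, (-P - sq) / 2.0]
    out = sorted((math.sqrt(x) for x in roots if x > _TIE_TOL), reverse=True)
    if Q < -_TIE_TOL:
        # unique positive root regime; cross-check against the closed form
        assert len(out) == 1
        closed = math.sqrt((-P + math.sqrt(P * P - 4.0 * Q)) / 2.0)
        assert abs(out[0] - closed) <= 1e-12 * max(1.0, closed)
    return out


def mode_cutoff(
    params: ModelParameters, n_max: int = DEFAULT_N_MAX, convention: str = "reduced"
) -> int | None:
    """Largest mode index N0 with B_n^2 - D_n^2 < 0, or None.

    Modes up to N0 admit purely imaginary characteristic roots (and hence
    Hopf bifurcations); higher modes never destabilize.  Ties within 1e-12
    are classified as >= 0 (no Hopf) with a warning.  With a1 >= a2 the sign
    is provably monotone in n^2, allowing an early stop; otherwise the scan
    runs to ``n_max`` and raises if the sign has not stabilized.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    n0: int | None = None
    for n in range(n_max + 1):
        q = mode_coefficients(params, n, convention).Q
        if abs(q) <= _TIE_TOL:
            warnings.warn(
                f"B_n^2 - D_n^2 within {_TIE_TOL} of zero at n={n}; classifying as >= 0",
                stacklevel=2,
            )
            q = abs(q)
        if q < 0:
            n0 = n
        elif params.a1 >= params.a2:
            # B_n + D_n > 0 always and B_n - D_n is increasing in n^2 when
            # a1 >= a2, so the first nonnegative sign is final.
            return n0
    if mode_coefficients(params, n_max, convention).Q < -_TIE_TOL:
        raise RuntimeError(
            f"sign of B_n^2 - D_n^2 has not stabilized by n_max={n_max}; increase n_max"
        )
    return n0


def _trig_of_omega_tau(mc: ModeCoefficients, omega: float) -> tuple[float, float]:
    """cos(omega*tau) and sin(omega*tau) at a crossing, from the split equations."""
    w2 = omega * omega
    den = mc.C * mc.C * w2 + mc.D * mc.D
    cosv = ((mc.D - mc.A * mc.C) * w2 - mc.B * mc.D) / den
    sinv = (mc.C * w2 * omega + (mc.A * mc.D - mc.B * mc.C) * omega) / den
    return cosv, sinv


def critical_delays(
    params: ModelParameters,
    n: int,
    j_max: int,
    convention: str = "reduced",
    residual_tol: float = 1e-9,
) -> list[HopfPoint]:
    """Critical delays tau_j^(n), j = 0..j_max, for every Hopf frequency of mode n.

    tau_0^(n) comes from the principal arccos of the crossing condition; the
    principal branch is valid because A_n*D_n - B_n*C > 0 forces
    sin(omega*tau) > 0.  Higher branches are translates by 2*pi*j/omega.
    Every returned point is verified to satisfy the characteristic equation
    to ``residual_tol``.
    """
    if j_max < 0:
        raise ValueError("j_max must be nonnegative")
    freqs = hopf_frequencies(params, n, convention)
    if not freqs:
        raise ValueError(f"no Hopf for this mode (n={n}): no positive frequency root")
    mc = mode_coefficients(params, n, convention)
    points: list[HopfPoint] = []
    for omega in freqs:
        cosv, sinv = _trig_of_omega_tau(mc, omega)
        if sinv <= 0:
            raise RuntimeError(
                "sin(omega*tau) <= 0 at a crossing; principal arccos branch invalid "
                "(A_n*D_n - B_n*C should be positive)"
            )
        tau0 = math.acos(max(-1.0, min(1.0, cosv))) / omega
        for j in range(j_max + 1):
            tau = tau0 + 2.0 * math.pi * j / omega
            res = characteristic_residual(params, n, 1j * omega, tau, convention)
            if abs(res) > residual_tol:
                raise RuntimeError(
                    f"characteristic residual {abs(res):.2e} exceeds {residual_tol} "
                    f"at (n={n}, j={j})"
                )
            points.append(HopfPoint(n=n, j=j, omega=omega, tau=tau))
    points.sort(key=lambda hp: hp.tau)
    return points


@dataclass(frozen=True)
class TransversalityResult:
    sign: int
    d_lambda_d_tau: complex
    re_inverse: float  # Re (d lambda / d tau)^{-1}, closed form


def transversality(
    params: ModelParameters, hopf: HopfPoint, convention: str = "reduced"
) -> TransversalityResult:
    """Speed of the eigenvalue crossing at a Hopf point.

    Evaluates (d lambda / d tau)^{-1} = ((2*lambda + A)*e^{lambda*tau} + C)
    / (lambda*(C*lambda + D)) - tau/lambda at lambda = i*omega and returns its
    reciprocal.  The real part of the inverse equals
    (omega^4 + D^2 - B^2) / ((C*omega^2)^2 + (D*omega)^2), which is positive
    whenever a crossing exists, so Re(d lambda / d tau) > 0: roots always move
    rightward as the delay grows.
    """
    mc = mode_coefficients(params, hopf.n, convention)
    lam = 1j * hopf.omega
    tau = hopf.tau
    denom = lam * (mc.C * lam + mc.D)
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("vanishing denominator in transversality evaluation")
    inv = ((2.0 * lam + mc.A) * cmath.exp(lam * tau) + mc.C) / denom - tau / lam
    w2 = hopf.omega * hopf.omega
    re_closed = (w2 * w2 + mc.D * mc.D - mc.B * mc.B) / (
        (mc.C * w2) ** 2 + (mc.D * hopf.omega) ** 2
    )
    if abs(inv.real - re_closed) > 1e-9 * max(1.0, abs(re_closed)):
        raise RuntimeError("transversality inverse disagrees with its closed form")
    deriv = 1.0 / inv
    if deriv.real <= 0:
        raise RuntimeError("Re(d lambda / d tau) <= 0 at a Hopf point; upstream failure")
    return TransversalityResult(sign=+1, d_lambda_d_tau=deriv, re_inverse=re_closed)


def minimal_critical_delay(
    params: ModelParameters, convention: str = "reduced", n_max: int = DEFAULT_N_MAX
) -> tuple[float, HopfPoint] | None:
    """Smallest critical delay tau_0 over all destabilizable modes, or None."""
    n0 = mode_cutoff(params, n_max, convention)
    if n0 is None:
        return None
    best: HopfPoint | None = None
    for n in range(n0 + 1):
        if not hopf_frequencies(params, n, convention):
            continue
        hp = critical_delays(params, n, 0, convention)[0]
        if best is None or hp.tau < best.tau:
            best = hp
    assert best is not None
    return best.tau, best


def classify(
    params: ModelParameters,
    tau: float,
    convention: str = "reduced",
    n_max: int = DEFAULT_N_MAX,
    bifurcation_tol: float = 1e-9,
) -> StabilityClassification:
    """Stability of E* at a given delay.

    At tau = 0 the equilibrium is always locally asymptotically stable (the
    Routh--Hurwitz conditions A_n + C > 0, B_n + D_n > 0 hold for every mode;
    in particular diffusion alone cannot destabilize: no Turing instability).
    When no mode admits imaginary roots the stability is delay-independent;
    otherwise E* is stable for tau < tau_0 and unstable for tau > tau_0.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    # Routh--Hurwitz / no-Turing check at tau = 0 for a sample of modes.
    for n in (0, 1, 2, 5, 10, n_max):
        mc = mode_coefficients(params, n, convention)
        if not (mc.A + mc.C > 0 and mc.B + mc.D > 0):
            raise RuntimeError(f"Routh-Hurwitz violated at tau=0 for mode {n}")
    outside = params.a1 < params.a2
    result = minimal_critical_delay(params, convention, n_max)
    if result is None:
        return StabilityClassification(
            regime="delay_independent_stable",
            n0=None,
            tau0=None,
            verdict="stable",
            outside_stated_regime=outside,
        )
    tau0, _ = result
    n0 = mode_cutoff(params, n_max, convention)
    if abs(tau - tau0) <= bifurcation_tol:
        verdict = "at_bifurcation"
    elif tau < tau0:
        verdict = "stable"
    else:
        verdict = "unstable"
    return StabilityClassification(
        regime="conditionally_stable",
        n0=n0,
        tau0=tau0,
        verdict=verdict,
        outside_stated_regime=outside,
    )
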