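"""Center-manifold normal form at a Hopf point.

Projects the delayed dynamics onto the two-dimensional critical eigenspace and
computes the cubic normal-form coefficient c1(0), whose real part decides the
orbital stability of the bifurcating cycle, together with the classical
indices mu2 (direction), beta2 = 2 Re c1(0) (orbit stability) and T2 (period
trend).

Conventions
-----------
Time is *not* rescaled by the delay: the reduced equation reads

    dz/dt = i*omega* z + g20 z^2/2 + g11 z z̄ + g02 z̄^2/2 + g21 z^2 z̄ / 2 + ...

with the right eigenvector normalized so that its first (population)
component is 1.  In this chart the saturated cycle of the first component has
half peak-to-trough amplitude 2*|z| with |z|^2 = Re(lambda'(tau*)) * (tau -
tau*) / (-Re c1(0)) — the relation used by the simulator cross-checks.  The
whole chain (eigenvectors, normalization M, g-coefficients, E1/E2 blocks,
W20/W11 evaluations, c1) is validated against an independent pseudospectral
discretization of the delay system in the test suite.

Only the spatially homogeneous mode (n = 0) is fully validated; for n >= 1
the quadratic projections vanish identically (the spatial average of cos^3
is zero) and the cubic term is evaluated with the corresponding cos^4
averages, but no independent check covers that path and results carry
``validated=False``.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from .model import coupling_entry, positive_equilibrium, taylor_coefficients, _check_convention
from .params import ModelParameters
from .spectral import HopfPoint, transversality

_EIG_TOL = 1e-8


@dataclass(frozen=True)
class EigenData:
    """Critical eigenpair data at a Hopf point.

    xi: second component of the right eigenvector q = (1, xi) e^{i w theta};
    eta: second component of the left (row) eigenvector (1, eta);
    M: normalization constant making the adjoint pairing (q*, q) equal 1.
    """

    omega: float
    tau: float
    n: int
    xi: complex
    eta: complex
    M: complex
    convention: str


def _delta(params: ModelParameters, lam: complex, tau: float, n: int, convention: str) -> np.ndarray:
    """Characteristic matrix Delta(lambda) of mode n (zero determinant at roots)."""
    p = params
    nstar = positive_equilibrium(params).nstar
    k2 = (n / p.l) ** 2
    s1 = p.r * p.a1 / p.K * nstar
    s2 = p.r * p.a2 / p.K * nstar
    cpl = coupling_entry(params, convention)
    el = cmath.exp(-lam * tau)
    return np.array(
        [
            [lam + p.d1 * k2 + s1 + s2 * el, cpl],
            [-p.b * el, lam + p.d2 * k2 + p.a],
        ],
        dtype=complex,
    )


def eigen_data(params: ModelParameters, hopf: HopfPoint, convention: str = "reduced") -> EigenData:
    """Eigenvectors and normalization at a Hopf point.

    xi = b e^{-i w tau} / (i w + a + d2 n^2/l^2)
    eta = -cpl / (i w + a + d2 n^2/l^2)        (row eigenvector)
    M = [1 + xi*eta + tau e^{-i w tau} (b*eta - (r a2 / K) N*)]^{-1}

    Both eigenvector properties are verified by substitution into the
    characteristic matrix (residual below 1e-8).
    """
    _check_convention(convention)
    p = params
    w, tau, n = hopf.omega, hopf.tau, hopf.n
    nstar = positive_equilibrium(params).nstar
    k2 = (n / p.l) ** 2
    s2 = p.r * p.a2 / p.K * nstar
    cpl = coupling_entry(params, convention)
    den = 1j * w + p.a + p.d2 * k2
    if abs(den) < 1e-12:
        raise ZeroDivisionError("i*omega + a + d2*n^2/l^2 vanishes")
    e = cmath.exp(-1j * w * tau)
    xi = p.b * e / den
    eta = -cpl / den
    M = 1.0 / (1.0 + xi * eta + tau * e * (p.b * eta - s2))

    delta = _delta(params, 1j * w, tau, n, convention)
    right = delta @ np.array([1.0, xi])
    left = np.array([1.0, eta]) @ delta
    resid = max(np.max(np.abs(right)), np.max(np.abs(left)))
    if resid > _EIG_TOL:
        raise RuntimeError(
            f"eigenvector residual {resid:.2e} exceeds {_EIG_TOL}; "
            "is the supplied HopfPoint on the critical curve?"
        )
    return EigenData(omega=w, tau=tau, n=n, xi=xi, eta=eta, M=M, convention=convention)


@dataclass(frozen=True)
class CenterManifoldBlocks:
    """Second-order manifold data: E1/E2 vectors and W20/W11 evaluations."""

    E1: np.ndarray
    E2: np.ndarray
    W20_at_0: np.ndarray
    W20_at_m1: np.ndarray
    W11_at_0: np.ndarray
    W11_at_m1: np.ndarray


@dataclass(frozen=True)
class GCoefficients:
    g20: complex
    g11: complex
    g02: complex
    g21: complex
    blocks: CenterManifoldBlocks
    validated: bool


def g_coefficients(params: ModelParameters, ed: EigenData, n: int | None = None) -> GCoefficients:
    """Quadratic and cubic projection coefficients at a Hopf point.

    The kinetics are exactly quadratic, with first-component coefficients
    (-r a1/K, -r a2/K, -r c) on phi1(0)^2, phi1(0) phi1(-tau), phi1(0) phi2(0).
    For n = 0 the spatial averages are trivial; for n >= 1 the quadratic
    projections vanish (integral of cos^3) and the cubic assembly uses the
    cos^4 average, unvalidated by any independent oracle.
    """
    if n is None:
        n = ed.n
    p = params
    w, tau = ed.omega, ed.tau
    xi, M = ed.xi, ed.M
    tc = taylor_coefficients(params)
    k1q, k2q, k3q = -tc.c_nn, -tc.c_nnd, -tc.c_nu  # positive magnitudes
    e = cmath.exp(-1j * w * tau)

    # z^2 and z*zbar coefficients of the first reaction component on the
    # critical eigenspace (phi = q z + conj(q) zbar).
    z2 = -(k1q + k2q * e + k3q * xi)
    zz = -(2.0 * k1q + 2.0 * k3q * xi.real + 2.0 * k2q * cmath.cos(w * tau).real)

    if n == 0:
        g20 = 2.0 * M * z2
        g11 = M * zz
        g02 = 2.0 * M * np.conj(z2)
        quad_avg = 1.0  # (1/(l pi)) integral of cos^2(0) = 1
        validated = True
    else:
        g20 = g11 = g02 = 0.0 + 0.0j
        # product of three cosines of the same mode averages to zero; the
        # surviving cubic couplings carry mean(cos^4)/mean(cos^2) = 3/4
        quad_avg = 0.75
        validated = False

    cpl = coupling_entry(params, ed.convention)

    def delta(lam: complex) -> np.ndarray:
        return _delta(params, lam, tau, n, ed.convention)

    d1m = delta(2j * w)
    if abs(np.linalg.det(d1m)) < 1e-12:
        raise RuntimeError("resonant center-manifold system: Delta(2 i omega) singular")
    E1 = np.linalg.solve(d1m, np.array([2.0 * z2, 0.0]))
    d0m = delta(0.0)
    if abs(np.linalg.det(d0m)) < 1e-12:
        raise RuntimeError("resonant center-manifold system: Delta(0) singular")
    E2 = np.linalg.solve(d0m, np.array([zz + 0.0j, 0.0]))

    def q_of(theta: float) -> np.ndarray:
        return np.array([1.0, xi]) * cmath.exp(1j * w * tau * theta)

    def w20(theta: float) -> np.ndarray:
        base = E1 * cmath.exp(2j * w * tau * theta)
        if n == 0:
            base = base + 1j * g20 / w * q_of(theta) + 1j * np.conj(g02) / (3.0 * w) * np.conj(q_of(theta))
        return base

    def w11(theta: float) -> np.ndarray:
        base = E2.copy()
        if n == 0:
            base = base - 1j * g11 / w * q_of(theta) + 1j * np.conj(g11) / w * np.conj(q_of(theta))
        return base

    W20_0, W20_m1 = w20(0.0), w20(-1.0)
    W11_0, W11_m1 = w11(0.0), w11(-1.0)

    # z^2 zbar coefficient of the first reaction component with the manifold
    # correction phi = q z + conj(q) zbar + W20 z^2/2 + W11 z zbar + ...
    S = (
        -k1q * (2.0 * W11_0[0] + W20_0[0])
        - k2q * (W11_m1[0] + e * W11_0[0] + 0.5 * W20_m1[0] + 0.5 * np.conj(e) * W20_0[0])
        - k3q * (W11_0[1] + xi * W11_0[0] + 0.5 * W20_0[1] + 0.5 * np.conj(xi) * W20_0[0])
    )
    g21 = 2.0 * M * quad_avg * S

    blocks = CenterManifoldBlocks(
        E1=E1, E2=E2, W20_at_0=W20_0, W20_at_m1=W20_m1, W11_at_0=W11_0, W11_at_m1=W11_m1
    )
    return GCoefficients(g20=g20, g11=g11, g02=g02, g21=g21, blocks=blocks, validated=validated)


@dataclass(frozen=True)
class NormalFormResult:
    hopf: HopfPoint
    eigen: EigenData
    g: GCoefficients
    c1: complex
    lambda_prime: complex
    mu2: float
    beta2: float
    T2: float
    direction: str  # supercritical | subcritical
    orbit_stability: str  # stable | unstable
    period_trend: str  # increasing | decreasing


def bifurcation_properties(
    params: ModelParameters, hopf: HopfPoint, convention: str = "reduced"
) -> NormalFormResult:
    """Full normal-form chain at a Hopf point.

    c1(0) = i/(2 omega) (g20 g11 - 2|g11|^2 - |g02|^2/3) + g21/2
    mu2 = -Re c1(0) / Re lambda'(tau*)      (direction: supercritical if > 0)
    beta2 = 2 Re c1(0)                      (orbit stable if < 0)
    T2 = -(Im c1(0) + mu2 Im lambda'(tau*)) / (omega* tau*)
    """
    ed = eigen_data(params, hopf, convention)
    g = g_coefficients(params, ed)
    w = hopf.omega
    c1 = (1j / (2.0 * w)) * (g.g20 * g.g11 - 2.0 * abs(g.g11) ** 2 - abs(g.g02) ** 2 / 3.0) + g.g21 / 2.0
    tv = transversality(params, hopf, convention)
    lam_p = tv.d_lambda_d_tau
    if lam_p.real <= 0:
        raise RuntimeError("Re lambda'(tau*) <= 0: contradicts transversality")
    mu2 = -c1.real / lam_p.real
    beta2 = 2.0 * c1.real
    T2 = -(c1.imag + mu2 * lam_p.imag) / (w * hopf.tau)
    return NormalFormResult(
        hopf=hopf,
        eigen=ed,
        g=g,
        c1=c1,
        lambda_prime=lam_p,
        mu2=mu2,
        beta2=beta2,
        T2=T2,
        direction="supercritical" if mu2 > 0 else "subcritical",
        orbit_stability="stable" if beta2 < 0 else "unstable",
        period_trend="increasing" if T2 > 0 else "decreasing",
    )
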