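"""Reaction terms, equilibria, boundedness/permanence predicates and the
local expansion of the kinetics at the positive equilibrium.

Two linearization conventions
-----------------------------
The Jacobian of the first reaction component with respect to the control
variable ``u`` is ``-r*c*N*`` (``exact`` convention).  The classical analysis
chain for this model instead carries the coupling entry as ``-c*N*``, i.e.
without the growth-rate factor (``reduced`` convention); the two coincide when
``r = 1``.  The spectral and normal-form modules accept either; everything that
is compared against the nonlinear simulator uses ``exact``, while the shipped
reference tables use ``reduced``.  See docs/methods.md for the full story.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

CONVENTIONS = ("reduced", "exact")


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


def coupling_entry(params: ModelParameters, convention: str = "reduced") -> float:
    """Magnitude of the control-coupling entry of the linearization.

    ``reduced``: c*N*;  ``exact``: r*c*N* (the true Jacobian entry).
    """
    _check_convention(convention)
    nstar = positive_equilibrium(params).nstar
    if convention == "exact":
        return params.r * params.c * nstar
    return params.c * nstar


@dataclass(frozen=True)
class Equilibria:
    """The two nonnegative spatially constant steady states."""

    e0: tuple[float, float]
    estar: tuple[float, float]

    @property
    def nstar(self) -> float:
        return self.estar[0]

    @property
    def ustar(self) -> float:
        return self.estar[1]


def positive_equilibrium(params: ModelParameters) -> Equilibria:
    """Closed-form steady states.

    N* = a*K / (a*(a1+a2) + b*c*K)  and  u* = (b/a) * N*; the denominator is
    positive for any valid parameter set, so E* always exists and is positive.
    """
    p = params
    nstar = p.a * p.K / (p.a * (p.a1 + p.a2) + p.b * p.c * p.K)
    ustar = p.b / p.a * nstar
    return Equilibria(e0=(0.0, 0.0), estar=(nstar, ustar))


def reaction_terms(params: ModelParameters, n, u, n_delayed):
    """Kinetic part of the model (no diffusion).

    Returns ``(f1, f2)`` with
    f1 = r*N*(1 - (a1*N + a2*N_tau)/K - c*u)  and  f2 = b*N_tau - a*u.
    Accepts scalars or arrays.
    """
    p = params
    f1 = p.r * n * (1.0 - (p.a1 * n + p.a2 * n_delayed) / p.K - p.c * u)
    f2 = p.b * n_delayed - p.a * u
    return f1, f2


def equilibrium_residual(params: ModelParameters, point: tuple[float, float]) -> float:
    """Max absolute reaction residual at a spatially constant state."""
    n, u = point
    f1, f2 = reaction_terms(params, n, u, n)
    return max(abs(f1), abs(f2))


def dissipative_bounds(params: ModelParameters) -> tuple[float, float]:
    """Ultimate upper bounds for N and u: (K/a1, b*K/(a*a1)).

    Every nonnegative solution eventually stays below these constants,
    independently of the delay and of the initial history.
    """
    p = params
    return p.K / p.a1, p.b * p.K / (p.a * p.a1)


@dataclass(frozen=True)
class PermanenceResult:
    """Outcome of the sufficient permanence test a*a1 > a*a2 + b*c*K."""

    holds: bool
    margin: float
    lower_bounds: tuple[float, float] | None

    def __bool__(self) -> bool:  # allows `if permanence_condition(p): ...`
        return self.holds


def permanence_condition(params: ModelParameters) -> PermanenceResult:
    """Sufficient condition for permanence, with its signed margin.

    When ``a*a1 > a*a2 + b*c*K`` (strictly) the system is permanent and
    explicit positive lower bounds for the ultimate values of N and u are
    returned.  A false result does *not* assert non-permanence: the test is
    sufficient only.
    """
    p = params
    margin = p.a * p.a1 - p.a * p.a2 - p.b * p.c * p.K
    if margin > 0:
        factor = margin / (p.a * p.a1)
        nb, ub = dissipative_bounds(params)
        return PermanenceResult(True, margin, (nb * factor, ub * factor))
    return PermanenceResult(False, margin, None)


@dataclass(frozen=True)
class Linearization:
    """Linear part of the kinetics at E*: d/dt phi = J0 phi(0) + J1 phi(-tau)."""

    j0: np.ndarray  # 2x2, instantaneous
    j1: np.ndarray  # 2x2, delayed
    convention: str


def linearization(params: ModelParameters, convention: str = "exact") -> Linearization:
    """Jacobian blocks of the kinetics at the positive equilibrium.

    With phi the deviation from E*:

        J0 = [[-r*a1*N*/K, -cpl], [0, -a]]     J1 = [[-r*a2*N*/K, 0], [b, 0]]

    where ``cpl`` is ``r*c*N*`` for the ``exact`` convention (true Jacobian)
    and ``c*N*`` for ``reduced``.
    """
    _check_convention(convention)
    p = params
    nstar = positive_equilibrium(params).nstar
    cpl = coupling_entry(params, convention)
    j0 = np.array([[-p.r * p.a1 / p.K * nstar, -cpl], [0.0, -p.a]])
    j1 = np.array([[-p.r * p.a2 / p.K * nstar, 0.0], [p.b, 0.0]])
    return Linearization(j0=j0, j1=j1, convention=convention)


@dataclass(frozen=True)
class TaylorCoefficients:
    """Quadratic Taylor coefficients of f1 at E* (f2 is exactly linear).

    f1(E* + phi) = linear part
                   + c_nn * phi1(0)^2 + c_nnd * phi1(0)*phi1(-tau)
                   + c_nu * phi1(0)*phi2(0)

    The expansion terminates at second order: the kinetics are quadratic.
    """

    c_nn: float
    c_nnd: float
    c_nu: float


def taylor_coefficients(params: ModelParameters) -> TaylorCoefficients:
    """Exact quadratic coefficients: (-r*a1/K, -r*a2/K, -r*c)."""
    p = params
    return TaylorCoefficients(c_nn=-p.r * p.a1 / p.K, c_nnd=-p.r * p.a2 / p.K, c_nu=-p.r * p.c)
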