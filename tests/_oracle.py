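"""Independent oracles for the test suite.

``pseudospectral_c1`` computes the cubic Hopf coefficient of a planar delay
system by Chebyshev-collocating the history segment into a large ODE system
and applying the finite-dimensional center-manifold reduction (projection
onto the critical eigenplane, solves for the second-order manifold
coefficients, Hassard's resonant-cubic assembly).  It shares no code with the
package's closed-form normal-form chain.

``newton_root`` polishes characteristic roots for the brute-force
imaginary-axis crossing searches.
"""

from __future__ import annotations

import cmath

import numpy as np
from scipy.linalg import eig, solve


def cheb(n: int, tau: float):
    """Chebyshev nodes on [-tau, 0] (node 0 at time 0) and differentiation matrix."""
    j = np.arange(n + 1)
    theta = (np.cos(np.pi * j / n) - 1.0) * tau / 2.0
    c = np.ones(n + 1)
    c[0] = c[n] = 2.0
    c *= (-1.0) ** j
    x = np.tile(theta, (n + 1, 1)).T
    dx = x - x.T + np.eye(n + 1)
    d = np.outer(c, 1.0 / c) / dx
    d -= np.diag(d.sum(axis=1))
    return theta, d


def pseudospectral_c1(
    j0: np.ndarray,
    j1: np.ndarray,
    tau: float,
    omega: float,
    quad,
    n_cheb: int = 48,
):
    """Hopf cubic coefficient of  dx/dt = j0 x(t) + j1 x(t - tau) + f(x, x_tau).

    ``quad(head, delayed_head)`` maps the 2-vector state at time t and at
    t - tau to the 2-vector of quadratic kinetic terms.  Returns (lambda, c1)
    with the right eigenvector normalized to first head component 1; the
    supplied (omega, tau) must put +-i*omega on the critical curve.
    """
    _, d = cheb(n_cheb, tau)
    m = n_cheb + 1
    a = np.zeros((2 * m, 2 * m))
    for i in range(1, m):
        a[i, :m] = d[i]
        a[m + i, m:] = d[i]
    # head rows: components 1 and 2 at theta = 0 (index 0), delayed at index n_cheb
    a[0, 0] += j0[0, 0]
    a[0, m] += j0[0, 1]
    a[0, n_cheb] += j1[0, 0]
    a[0, m + n_cheb] += j1[0, 1]
    a[m, 0] += j0[1, 0]
    a[m, m] += j0[1, 1]
    a[m, n_cheb] += j1[1, 0]
    a[m, m + n_cheb] += j1[1, 1]

    def fvec(x):
        out = np.zeros(2 * m, dtype=complex)
        head = np.array([x[0], x[m]])
        dly = np.array([x[n_cheb], x[m + n_cheb]])
        f = quad(head, dly)
        out[0], out[m] = f[0], f[1]
        return out

    def bil(u, v):
        return fvec(u + v) - fvec(u) - fvec(v)

    w, v = eig(a)
    i0 = int(np.argmin(np.abs(w - 1j * omega)))
    lam = w[i0]
    if abs(lam - 1j * omega) > 1e-6:
        raise RuntimeError(f"no eigenvalue near i*omega: closest {lam}")
    q = v[:, i0] / v[0, i0]
    wl, vl = eig(a.conj().T)
    p = vl[:, int(np.argmin(np.abs(wl + 1j * omega)))]
    p = p / np.conj(np.vdot(p, q))  # <p, q> = 1 in the conjugating inner product
    om = lam.imag
    eye = np.eye(2 * m)
    g20 = np.vdot(p, bil(q, q))
    g11 = np.vdot(p, bil(q, q.conj()))
    g02 = np.vdot(p, bil(q.conj(), q.conj()))
    w20 = solve(2j * om * eye - a, bil(q, q) - g20 * q - np.conj(g02) * q.conj())
    w11 = solve(-a, bil(q, q.conj()) - g11 * q - np.conj(g11) * q.conj())
    g21 = np.vdot(p, bil(q.conj(), w20)) + 2.0 * np.vdot(p, bil(q, w11))
    c1 = (1j / (2.0 * om)) * (g20 * g11 - 2.0 * abs(g11) ** 2 - abs(g02) ** 2 / 3.0) + g21 / 2.0
    return lam, c1


def newton_root(char, lam0: complex, tol: float = 1e-12, max_iter: int = 60) -> complex | None:
    """Newton iteration for a characteristic function of one complex variable."""
    lam = lam0
    h = 1e-7
    for _ in range(max_iter):
        f = char(lam)
        if abs(f) < tol:
            return lam
        df = (char(lam + h) - char(lam - h)) / (2.0 * h)
        if df == 0:
            return None
        step = f / df
        lam = lam - step
        if abs(step) > 1e3:
            return None
    return lam if abs(char(lam)) < 1e-9 else None


def imaginary_axis_crossings(char, omega_max: float = 2.0, n_grid: int = 80):
    """Brute-force search for roots on (near) the imaginary axis.

    Newton-polishes starts from a grid over Re in [-1, 1], Im in (0, omega_max]
    and returns the distinct roots with |Re| < 1e-8, sorted by imaginary part.
    """
    found: list[complex] = []
    for re0 in np.linspace(-1.0, 1.0, 9):
        for im0 in np.linspace(omega_max / n_grid, omega_max, n_grid):
            root = newton_root(char, complex(re0, im0))
            if root is None or root.imag <= 0:
                continue
            if abs(root.real) > 1e-8:
                continue
            if all(abs(root - r) > 1e-6 for r in found):
                found.append(root)
    return sorted(found, key=lambda z: z.imag)
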