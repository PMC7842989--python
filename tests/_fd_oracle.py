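"""Brute-force explicit finite-difference oracle for the gel diffusion problem.

Solves dc/dtau = d^2 c / dxi^2 on the unit interval in dimensionless form
(xi = x/h_g, tau = D_g t / h_g^2), with a reflective boundary at xi = 0, an
absorbing boundary at xi = 1 and a unit-mass Dirac initial condition at
xi = 0 (all mass in the first node, trapezoid-normalised).  Independent of
the series solution it is used to check.
"""

from __future__ import annotations

import numpy as np


def fd_solve(taus, n: int = 500, lam: float = 0.4) -> dict[float, tuple[np.ndarray, float]]:
    """March once and record (dimensionless profile, absorbed fraction) at
    each requested tau."""
    dxi = 1.0 / n
    c = np.zeros(n + 1)
    c[0] = 2.0 / dxi  # trapezoid mass = 1
    dtau = lam * dxi * dxi
    out: dict[float, tuple[np.ndarray, float]] = {}
    tau = 0.0
    for target in sorted(taus):
        steps = int(round((target - tau) / dtau))
        for _ in range(steps):
            lap = np.empty_like(c)
            lap[1:-1] = c[2:] - 2.0 * c[1:-1] + c[:-2]
            lap[0] = 2.0 * (c[1] - c[0])  # reflective ghost node
            lap[-1] = 0.0
            c += lam * lap
            c[-1] = 0.0  # absorbing
        tau = target
        out[target] = (c.copy(), 1.0 - float(np.trapezoid(c, dx=dxi)))
    return out


def fd_grid_xi(n: int = 500) -> np.ndarray:
    return np.linspace(0.0, 1.0, n + 1)
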