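"""Independent finite-difference oracle for the coupled fractional system.

Time: the L1 discretisation of the Caputo derivative,

``D^alpha u(t_k) ~ (dt**-alpha / Gamma(2-alpha))
                   sum_{j=0}^{k-1} b_j (u^{k-j} - u^{k-j-1})``,
``b_j = (j+1)**(1-alpha) - j**(1-alpha)``,

which degenerates to backward Euler at ``alpha = 1`` and carries accuracy
order ``2 - alpha`` for solutions smooth away from ``t = 0``.

Space: standard second-order central differences for the axisymmetric
radial Laplacian ``u'' + u'/xi`` on a uniform grid, with the axis handled
through the symmetry condition ``du/dxi = 0`` at ``xi = 0`` (the
regularised stencil ``4 (u_1 - u_0)/dr**2``).

The diffusion operators are treated implicitly (tridiagonal solves), and
the fluid/particle drag coupling is eliminated exactly at each step: the
particle update is a scalar linear relation ``g^k = G0 + kappa f^k``
(g's equation has no spatial derivatives), which is substituted into the
fluid solve.  The scheme is unconditionally stable on this linear system.

Crucially, ``g`` is stepped from its own fractional relaxation equation
``D^alpha g = (f - g)/Pm`` — not from the convolution representation — so
the solver is a genuinely independent check of the analytic
particle-velocity solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import gamma as _gamma

from .params import DimensionlessParams

__all__ = ["Grid", "SolutionGrid", "l1_caputo_weights", "solve_fd"]


@dataclass(frozen=True)
class Grid:
    """Uniform space-time grid on ``[0,1] x [0, T_final]``."""

    n_r: int = 64
    n_t: int = 256
    T_final: float = 1.0

    def __post_init__(self) -> None:
        if self.n_r < 8 or self.n_t < 8:
            raise ValueError("need n_r >= 8 and n_t >= 8")
        if self.T_final <= 0:
            raise ValueError("T_final must be > 0")

    @property
    def dr(self) -> float:
        return 1.0 / self.n_r

    @property
    def dt(self) -> float:
        return self.T_final / self.n_t

    @property
    def xi(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_r + 1)

    @property
    def tau(self) -> np.ndarray:
        return np.linspace(0.0, self.T_final, self.n_t + 1)


@dataclass(frozen=True)
class SolutionGrid:
    grid: Grid
    theta: np.ndarray             # (n_t+1, n_r+1)
    phi: np.ndarray
    f: np.ndarray
    g: np.ndarray


def l1_caputo_weights(alpha: float, k: int) -> np.ndarray:
    """L1 weights ``b_j = (j+1)**(1-alpha) - j**(1-alpha)``, ``j = 0..k-1``.

    Positive, strictly decreasing for ``0 < alpha < 1``; ``(1, 0, 0, ...)``
    at ``alpha = 1`` (backward Euler).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        # the 0**0 = 1 convention would zero b_0; the classical limit is
        # the Kronecker delta (no memory)
        w = np.zeros(k)
        if k:
            w[0] = 1.0
        return w
    j = np.arange(k, dtype=float)
    return (j + 1.0) ** (1.0 - alpha) - j ** (1.0 - alpha)


def _laplacian_bands(n_r: int, dr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sub/main/super diagonals of the axisymmetric Laplacian on the
    interior + axis unknowns (wall value is Dirichlet data)."""
    # unknowns: i = 0 .. n_r-1 (xi_i = i*dr); wall i = n_r is data
    lo = np.zeros(n_r)
    di = np.zeros(n_r)
    up = np.zeros(n_r)
    inv2 = 1.0 / dr**2
    di[0] = -4.0 * inv2
    up[0] = 4.0 * inv2
    for i in range(1, n_r):
        xi = i * dr
        lo[i] = inv2 * (1.0 - 0.5 * dr / xi)
        di[i] = -2.0 * inv2
        up[i] = inv2 * (1.0 + 0.5 * dr / xi)
    return lo, di, up


def _implicit_solve(lo, di, up, diag_shift, rhs, wall_value, wall_coupling):
    """Solve (diag_shift*I - L) u = rhs with the wall contribution folded in."""
    n = di.size
    ab = np.zeros((3, n))
    ab[0, 1:] = -up[:-1]
    ab[1, :] = diag_shift - di
    ab[2, :-1] = -lo[1:]
    b = rhs.copy()
    b[-1] += wall_coupling * wall_value
    return solve_banded((1, 1), ab, b)


def solve_fd(dp: DimensionlessParams, grid: Grid) -> SolutionGrid:
    """March the coupled system; returns all four fields on the full grid."""
    alpha = dp.alpha
    n_r, n_t = grid.n_r, grid.n_t
    dr, dt = grid.dr, grid.dt
    tau = grid.tau
    mu = _gamma(2.0 - alpha) * dt**alpha     # L1 scale: D^a u ~ (1/mu) sum ...
    w = l1_caputo_weights(alpha, n_t)

    lo, di, up = _laplacian_bands(n_r, dr)
    # wall coupling coefficient: the superdiagonal entry of the last
    # interior row applied to the known wall value
    xi_last = (n_r - 1) * dr
    wall_coef = (1.0 / dr**2) * (1.0 + 0.5 * dr / xi_last)

    shape = (n_t + 1, n_r + 1)
    theta = np.zeros(shape)
    phi = np.zeros(shape)
    f = np.zeros(shape)
    g = np.zeros(shape)
    theta[:, -1] = 1.0
    phi[:, -1] = 1.0
    f[:, -1] = 1.0
    theta[0, -1] = phi[0, -1] = f[0, -1] = 0.0   # fields start from rest
    # the wall value of g follows from its own relaxation equation below

    inv_mu = 1.0 / mu
    kappa_g = (1.0 / dp.Pm) / (inv_mu + 1.0 / dp.Pm)   # weight of f^k in g^k
    # histories stored as increments for the L1 memory sum
    dth = np.zeros((n_t, n_r))        # theta increments (interior+axis)
    dph = np.zeros((n_t, n_r))
    dfv = np.zeros((n_t, n_r + 1))    # f, g increments including wall
    dgv = np.zeros((n_t, n_r + 1))

    for k in range(1, n_t + 1):
        t_k = tau[k]
        # L1 memory terms: (1/mu) * sum_{j=1}^{k-1} b_j * du[k-j-1]
        if k > 1:
            bj = w[1:k][::-1]                       # b_{k-1} ... b_1
            hist_th = bj @ dth[: k - 1]
            hist_ph = bj @ dph[: k - 1]
            hist_f = bj @ dfv[: k - 1]
            hist_g = bj @ dgv[: k - 1]
        else:
            hist_th = np.zeros(n_r)
            hist_ph = np.zeros(n_r)
            hist_f = np.zeros(n_r + 1)
            hist_g = np.zeros(n_r + 1)

        # --- scalars: (1/mu) I - (1/Pr) L, wall value 1
        for arr, darr, hist, diffu in (
            (theta, dth, hist_th, 1.0 / dp.Pr),
            (phi, dph, hist_ph, 1.0 / dp.Sc),
        ):
            rhs = inv_mu * (arr[k - 1, :-1] - hist)
            sol = _implicit_solve(diffu * lo, diffu * di, diffu * up,
                                  inv_mu, rhs, 1.0, diffu * wall_coef)
            arr[k, :-1] = sol
            darr[k - 1] = arr[k, :-1] - arr[k - 1, :-1]

        # --- particle relation at step k: g^k = G0 + kappa_g f^k
        G0 = (inv_mu * (g[k - 1] - hist_g)) / (inv_mu + 1.0 / dp.Pm)

        # --- fluid: ((1/mu) + M0 + Pc - Pc*kappa_g) I - L, source terms
        forcing = (dp.A0 + dp.A1 * np.cos(dp.omega * t_k)
                   + dp.Pc * G0[:-1]
                   + dp.Gr * theta[k, :-1] + dp.Gm * phi[k, :-1])
        rhs = inv_mu * (f[k - 1, :-1] - hist_f[:-1]) + forcing
        shift = inv_mu + dp.M0 + dp.Pc * (1.0 - kappa_g)
        f[k, :-1] = _implicit_solve(lo, di, up, shift, rhs, 1.0, wall_coef)
        f[k, -1] = 1.0

        g[k] = G0 + kappa_g * f[k]
        dfv[k - 1] = f[k] - f[k - 1]
        dgv[k - 1] = g[k] - g[k - 1]

    return SolutionGrid(grid=grid, theta=theta, phi=phi, f=f, g=g)
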