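"""Exact fluid- and particle-velocity solutions.

After Laplace and finite Hankel transformation the coupled fluid/particle
momentum balance

``D_tau^alpha f = A0 + A1 cos(omega tau) + (f'' + f'/xi) + Pc (g - f)
                 + Gr Theta + Gm Phi - M0 f``
``D_tau^alpha g = (f - g)/Pm``

collapses, mode by mode, to a rational function of ``y = l**alpha``::

    fH(eps_n, l) = { eps J1/l  +  F0(l) J1/eps
                     + Gr (1/l - l**(a-1)/(y+a1)) J1/eps
                     + Gm (1/l - l**(a-1)/(y+a2)) J1/eps }
                   * (y + Y2) / ((y + Y3)(y + Y4))

with ``Y2 = 1/Pm``, ``Y0 = eps**2 + M0 + Pc + 1/Pm``,
``Y1 = (eps**2 + M0)/Pm`` and ``Y3, Y4`` the roots of
``x**2 - Y0 x + Y1 = 0`` (always real, distinct unless ``Pc = 0`` and
``eps**2 + M0 = 1/Pm`` exactly).  ``F0(l) = A0/l + A1 l/(l**2+omega**2)``
is the oscillating pressure forcing.

Partial-fraction residue algebra in ``y`` turns each mode into the
seven-term time-domain brace

``1 + N1 R(-Y3) + N2 R(-Y4) + N3 cos*F(-Y3) + N4 cos*F(-Y4)
   + N5 R(-a1) + N6 R(-a2)``

with ``R(-b) = R_{alpha,-1}(-b,tau) = (1 - E_alpha(-b tau**alpha))/b`` and
``cos*F`` the cosine/Robotnov convolution.  The N-weights are computed
exactly from the residues (never transcribed), and the Laplace image
itself is kept as a second, independent evaluation path through numerical
Bromwich inversion.

The particle velocity is the singular-kernel convolution
``g = (1/Pm) F_alpha(-1/Pm, tau) * f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import j0

from .hankel import HankelBasis
from .params import DimensionlessParams
from .specfun import (DEFAULT_CONTROL, LaplaceImage, SeriesControl,
                      conv_with_F_kernel, inverse_laplace, ml_neg)

__all__ = [
    "ModeCoefficients",
    "VelocityField",
    "DegenerateModeError",
    "mode_coefficients",
    "laplace_velocity_mode",
    "mode_image_from_partial_fractions",
    "velocity_fluid",
    "velocity_particle",
    "classical_velocity",
    "velocity_gm0",
]


class DegenerateModeError(ValueError):
    """Repeated rational-image root (Y3 = Y4) or a pole collision with a
    thermal/solutal decay rate; the partial-fraction series branch does
    not apply (the numerical-inversion path still does)."""


@dataclass(frozen=True)
class ModeCoefficients:
    """Per-mode rational-image constants.

    ``upsilon`` holds (Y0..Y8); ``c3, c4`` are the residues of
    ``(y+Y2)/((y+Y3)(y+Y4))``; ``d*_a1 / d*_a2`` the residues of the same
    bracket with an extra ``(y+a)`` pole from the buoyancy sources;
    ``n1..n6`` the brace weights; ``p`` the printed-ledger constants kept
    only as cross-checks.
    """

    eps: float
    j1: float
    upsilon: np.ndarray           # Y0..Y8
    a1: float
    a2: float
    c3: float
    c4: float
    d1_a1: float
    d3_a1: float
    d4_a1: float
    d1_a2: float
    d3_a2: float
    d4_a2: float
    n1: float
    n2: float
    n3: float
    n4: float
    n5: float
    n6: float
    A0: float
    A1: float
    omega: float
    p: np.ndarray                 # printed p0..p17 ledger (cross-check only)

    @property
    def Y2(self): return self.upsilon[2]
    @property
    def Y3(self): return self.upsilon[3]
    @property
    def Y4(self): return self.upsilon[4]


def _three_pole_residues(Y2, Y3, Y4, a):
    """Residues of (y+Y2)/((y+a)(y+Y3)(y+Y4)) at -a, -Y3, -Y4."""
    d1 = (Y2 - a) / ((Y3 - a) * (Y4 - a))
    d3 = (Y2 - Y3) / ((a - Y3) * (Y4 - Y3))
    d4 = (Y2 - Y4) / ((a - Y4) * (Y3 - Y4))
    return d1, d3, d4


def mode_coefficients(n: int, dp: DimensionlessParams, basis: HankelBasis) -> ModeCoefficients:
    """Exact rational-image constants for mode ``n`` (0-based index)."""
    if not 0 <= n < basis.n_modes:
        raise IndexError(f"mode {n} outside basis of {basis.n_modes} modes")
    eps = float(basis.roots[n])
    j1v = float(basis.j1_at_roots[n])
    e2 = eps * eps
    Y2 = 1.0 / dp.Pm
    Y0 = e2 + dp.M0 + dp.Pc + Y2
    Y1 = (e2 + dp.M0) / dp.Pm
    disc = Y0 * Y0 - 4.0 * Y1
    if disc <= 1e-12 * Y0 * Y0:
        raise DegenerateModeError(
            f"mode {n}: repeated rational-image root (disc={disc:.3e}); "
            "use the numerical-inversion path"
        )
    rt = math.sqrt(disc)
    Y3 = 0.5 * (Y0 + rt)
    Y4 = 0.5 * (Y0 - rt)
    Y5, Y6 = Y3 + Y4, Y3 * Y4
    Y7 = e2 - Y5
    Y8 = e2 * Y2 - Y6
    a1 = e2 / dp.Pr
    a2 = e2 / dp.Sc
    for a, lbl in ((a1, "a1"), (a2, "a2")):
        if min(abs(Y3 - a), abs(Y4 - a)) < 1e-9 * max(1.0, a):
            raise DegenerateModeError(
                f"mode {n}: decay rate {lbl}={a:.6g} collides with an image pole"
            )
    c3 = (Y2 - Y3) / (Y4 - Y3)
    c4 = (Y2 - Y4) / (Y3 - Y4)
    d1_a1, d3_a1, d4_a1 = _three_pole_residues(Y2, Y3, Y4, a1)
    d1_a2, d3_a2, d4_a2 = _three_pole_residues(Y2, Y3, Y4, a2)
    S = e2 + dp.A0 + dp.Gr + dp.Gm
    n1 = -(S * c3 + Y3 * (dp.Gr * d3_a1 + dp.Gm * d3_a2))
    n2 = -(S * c4 + Y4 * (dp.Gr * d4_a1 + dp.Gm * d4_a2))
    n3 = -dp.A1 * c3
    n4 = -dp.A1 * c4
    n5 = -dp.Gr * a1 * d1_a1
    n6 = -dp.Gm * a2 * d1_a2

    # printed coefficient ledger (cross-check only; not used in evaluation)
    dY = Y3 - Y4
    p = np.full(18, np.nan)
    p[0] = (Y8 - Y7 * Y3 - Y3**2) / dY
    p[1] = (-Y8 + Y7 * Y4 + Y4**2) / dY
    p[2] = (Y3 - Y2) / dY          # printed "Y1 - Y2" is a typo for Y3 - Y2
    p[3] = (Y2 - Y4) / dY
    p[4] = a1 / (a1 - Y3)
    p[5] = Y3 / (a1 - Y3)
    p[6] = a1 / (a1 - Y4)
    p[7] = Y4 / (a1 - Y4)
    p[8] = p[4] + p[6]
    p[9] = p[2] + p[5]
    p[10] = p[3] + p[7]
    p[11] = a2 / (a2 - Y3)
    p[12] = Y3 / (a2 - Y3)
    p[13] = a2 / (a2 - Y4)
    p[14] = Y4 / (a2 - Y4)
    p[15] = p[11] + p[13]
    p[16] = p[2] + p[12]
    p[17] = p[3] + p[14]

    return ModeCoefficients(
        eps=eps, j1=j1v,
        upsilon=np.array([Y0, Y1, Y2, Y3, Y4, Y5, Y6, Y7, Y8]),
        a1=a1, a2=a2, c3=c3, c4=c4,
        d1_a1=d1_a1, d3_a1=d3_a1, d4_a1=d4_a1,
        d1_a2=d1_a2, d3_a2=d3_a2, d4_a2=d4_a2,
        n1=n1, n2=n2, n3=n3, n4=n4, n5=n5, n6=n6,
        A0=dp.A0, A1=dp.A1, omega=dp.omega, p=p,
    )


# ----------------------------------------------------------------------
# Laplace-domain images
# ----------------------------------------------------------------------

def laplace_velocity_mode(l, n: int, dp: DimensionlessParams, basis: HankelBasis):
    """Direct evaluation of the transformed mode ``fH(eps_n, l)``.

    Accepts scalar or array ``l`` with ``Re(l) > 0``; raises near the
    forcing poles ``l = +-i omega``.
    """
    l = np.asarray(l, dtype=complex)
    eps = basis.roots[n]
    j1v = basis.j1_at_roots[n]
    e2 = eps * eps
    alpha = dp.alpha
    a1 = e2 / dp.Pr
    a2 = e2 / dp.Sc
    Y2 = 1.0 / dp.Pm
    Y0 = e2 + dp.M0 + dp.Pc + Y2
    Y1 = (e2 + dp.M0) / dp.Pm
    denom_p = l * l + dp.omega**2
    if np.any(np.abs(denom_p) < 1e-12 * max(1.0, dp.omega**2)):
        raise ValueError("l too close to the forcing poles +-i*omega")
    y = l**alpha
    F0 = dp.A0 / l + dp.A1 * l / denom_p
    brace = (
        eps * j1v / l
        + F0 * j1v / eps
        + dp.Gr * (1.0 / l - l ** (alpha - 1.0) / (y + a1)) * j1v / eps
        + dp.Gm * (1.0 / l - l ** (alpha - 1.0) / (y + a2)) * j1v / eps
    )
    return brace * (y + Y2) / (y * y + Y0 * y + Y1)


def mode_image_from_partial_fractions(mc: ModeCoefficients, alpha: float, l,
                                      Gr: float, Gm: float):
    """Recombine the residue decomposition into the Laplace image.

    Used to certify that the time-domain series evaluates exactly the
    same rational function as :func:`laplace_velocity_mode`.
    """
    l = np.asarray(l, dtype=complex)
    y = l**alpha
    eps, j1v = mc.eps, mc.j1
    Y3, Y4 = mc.Y3, mc.Y4
    e2 = eps * eps

    def pole_pair(c3, c4):
        return c3 / (y + Y3) + c4 / (y + Y4)

    img = eps * j1v * pole_pair(mc.c3, mc.c4) / l
    img += (j1v / eps) * mc.A0 * pole_pair(mc.c3, mc.c4) / l
    img += (j1v / eps) * mc.A1 * (l / (l * l + mc.omega**2)) * pole_pair(mc.c3, mc.c4)
    for G, (d1, d3, d4), a in (
        (Gr, (mc.d1_a1, mc.d3_a1, mc.d4_a1), mc.a1),
        (Gm, (mc.d1_a2, mc.d3_a2, mc.d4_a2), mc.a2),
    ):
        img += G * (j1v / eps) * (
            pole_pair(mc.c3, mc.c4) / l
            - l ** (alpha - 1.0) * (d1 / (y + a) + d3 / (y + Y3) + d4 / (y + Y4))
        )
    return img


# ----------------------------------------------------------------------
# Time-domain evaluation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class VelocityField:
    """Blood (``f``) and particle (``g``) velocities on the ``(xi, tau)`` grid."""

    xi: np.ndarray
    tau: np.ndarray
    f: np.ndarray                 # shape (n_xi, n_tau)
    g: np.ndarray | None = None


def _R_minus1_matrix(alpha: float, rates: np.ndarray, tau: np.ndarray,
                     ctrl: SeriesControl) -> np.ndarray:
    """``R_{alpha,-1}(-b_n, tau) = (1 - E_alpha(-b_n tau**alpha)) / b_n``."""
    x = np.outer(rates, tau**alpha)
    return (1.0 - ml_neg(alpha, 1.0, x, ctrl)) / rates[:, None]


def _cosF_matrix(alpha: float, rates: np.ndarray, omega: float, tau: np.ndarray,
                 ctrl: SeriesControl) -> np.ndarray:
    """``cos(omega .) * F_alpha(-b_n, .)`` for every mode/time pair.

    Termwise cosine-series convolution:
    ``sum_m (-omega**2)**m tau**(2m+alpha) E_{alpha,alpha+2m+1}(-b tau**alpha)``.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros((rates.size, tau.size))
    pos = tau > 0
    if not pos.any():
        return out
    tp = tau[pos]
    x = np.outer(rates, tp**alpha)
    tmax = float(tp.max())
    m_max = int(max(10, math.ceil(0.5 * math.e * omega * tmax) + 14))
    coef = np.ones_like(tp)
    acc = np.zeros((rates.size, tp.size))
    for m in range(m_max):
        if m > 0:
            coef = coef * (-(omega**2)) * tp * tp
        acc += coef * tp**alpha * ml_neg(alpha, alpha + 2 * m + 1, x, ctrl).reshape(x.shape)
    out[:, pos] = acc
    return out


def _brace_matrix(dp: DimensionlessParams, basis: HankelBasis, tau: np.ndarray,
                  ctrl: SeriesControl) -> np.ndarray:
    """The seven-term time-domain brace b_n(tau) for every mode."""
    mcs = [mode_coefficients(n, dp, basis) for n in range(basis.n_modes)]
    Y3 = np.array([m.Y3 for m in mcs])
    Y4 = np.array([m.Y4 for m in mcs])
    a1 = np.array([m.a1 for m in mcs])
    a2 = np.array([m.a2 for m in mcs])
    N = np.array([[m.n1, m.n2, m.n3, m.n4, m.n5, m.n6] for m in mcs]).T  # (6, n_modes)
    alpha = dp.alpha
    R3 = _R_minus1_matrix(alpha, Y3, tau, ctrl)
    R4 = _R_minus1_matrix(alpha, Y4, tau, ctrl)
    Ra1 = _R_minus1_matrix(alpha, a1, tau, ctrl)
    Ra2 = _R_minus1_matrix(alpha, a2, tau, ctrl)
    C3 = _cosF_matrix(alpha, Y3, dp.omega, tau, ctrl)
    C4 = _cosF_matrix(alpha, Y4, dp.omega, tau, ctrl)
    return (1.0
            + N[0][:, None] * R3 + N[1][:, None] * R4
            + N[2][:, None] * C3 + N[3][:, None] * C4
            + N[4][:, None] * Ra1 + N[5][:, None] * Ra2)


def _lift(basis: HankelBasis, xi: np.ndarray, brace: np.ndarray) -> np.ndarray:
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    w = 1.0 / (basis.roots * basis.j1_at_roots)
    Jn = j0(np.outer(xi, basis.roots))
    Jn[xi == 1.0] = 0.0   # J0(eps_n) = 0 analytically; keep the wall row exact
    return 1.0 - 2.0 * (Jn * w) @ brace


def _validate_grid(xi, tau):
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(xi < 0) or np.any(xi > 1):
        raise ValueError("xi must lie in [0, 1]")
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    return xi, tau


def velocity_fluid(xi, tau, dp: DimensionlessParams,
                   ctrl: SeriesControl = DEFAULT_CONTROL,
                   path: str = "series") -> VelocityField:
    """Blood velocity ``f(xi, tau)``.

    ``path="series"`` evaluates the exact partial-fraction series;
    ``path="ilt"`` numerically inverts the Laplace-domain mode images
    (independent route, agreeing to ~1e-4 relative).
    """
    xi, tau = _validate_grid(xi, tau)
    basis = HankelBasis.build(ctrl.n_modes)
    if path == "series":
        brace = _brace_matrix(dp, basis, tau, ctrl)
    elif path == "ilt":
        brace = np.empty((basis.n_modes, tau.size))
        for n in range(basis.n_modes):
            eps = basis.roots[n]
            j1v = basis.j1_at_roots[n]

            def dev(l, n=n, eps=eps, j1v=j1v):
                # scaled deviation from the static wall term: its inverse
                # is -(brace_n(tau) - 0) ... i.e. m_n(tau) - 1 = -b_n(tau)
                return laplace_velocity_mode(l, n, dp, basis) * eps / j1v - 1.0 / l

            img = LaplaceImage(dev)
            for k, t in enumerate(tau):
                brace[n, k] = 1.0 if t == 0 else -inverse_laplace(img, t, ctrl)
    else:
        raise ValueError(f"unknown path {path!r}")
    return VelocityField(xi=xi, tau=tau, f=_lift(basis, xi, brace))


def velocity_particle(xi, tau, dp: DimensionlessParams,
                      ctrl: SeriesControl = DEFAULT_CONTROL,
                      f: VelocityField | None = None,
                      path: str = "series") -> VelocityField:
    """Particle velocity ``g = (1/Pm) F_alpha(-1/Pm, tau) * f``.

    ``tau`` must be a uniform grid starting at 0 (the convolution memory
    runs from the start of motion).  The kernel's ``tau**(alpha-1)``
    singularity is handled by exact product integration against
    piecewise-linear ``f``; the impulsive wall start enters through the
    jump value ``f(xi, 0+)``.
    """
    xi, tau = _validate_grid(xi, tau)
    if tau.size < 2 or tau[0] != 0.0 or not np.allclose(np.diff(tau), tau[1] - tau[0]):
        raise ValueError("velocity_particle needs a uniform tau grid starting at 0")
    dt = float(tau[1] - tau[0])
    if f is None:
        f = velocity_fluid(xi, tau, dp, ctrl, path=path)
    rate = 1.0 / dp.Pm
    g = np.empty_like(f.f)
    for i in range(xi.size):
        row = f.f[i]
        g[i] = conv_with_F_kernel(dp.alpha, rate, row, dt, f0plus=row[0], ctrl=ctrl)
    return VelocityField(xi=xi, tau=tau, f=f.f, g=g)


def classical_velocity(xi, tau, dp: DimensionlessParams,
                       ctrl: SeriesControl = DEFAULT_CONTROL) -> VelocityField:
    """Classical (``alpha = 1``) closed forms: exponential relaxation plus
    the exact in-phase/quadrature oscillatory response.

    Independent of the fractional kernel machinery (plain ``exp``/``cos``/
    ``sin`` only), hence an oracle for ``velocity_fluid`` at ``alpha = 1``:

    ``cos(omega .) * exp(-b .) = (b cos(omega tau) + omega sin(omega tau)
    - b exp(-b tau)) / (b**2 + omega**2)``.
    """
    xi, tau = _validate_grid(xi, tau)
    basis = HankelBasis.build(ctrl.n_modes)
    om = dp.omega
    mcs = [mode_coefficients(n, dp, basis) for n in range(basis.n_modes)]
    brace = np.empty((basis.n_modes, tau.size))
    for n, mc in enumerate(mcs):
        Y3, Y4, a1, a2 = mc.Y3, mc.Y4, mc.a1, mc.a2
        e3, e4 = np.exp(-Y3 * tau), np.exp(-Y4 * tau)
        osc3 = (Y3 * np.cos(om * tau) + om * np.sin(om * tau) - Y3 * e3) / (Y3**2 + om**2)
        osc4 = (Y4 * np.cos(om * tau) + om * np.sin(om * tau) - Y4 * e4) / (Y4**2 + om**2)
        brace[n] = (1.0
                    + mc.n1 * (1.0 - e3) / Y3 + mc.n2 * (1.0 - e4) / Y4
                    + mc.n3 * osc3 + mc.n4 * osc4
                    + mc.n5 * (1.0 - np.exp(-a1 * tau)) / a1
                    + mc.n6 * (1.0 - np.exp(-a2 * tau)) / a2)
    fvals = _lift(basis, xi, brace)
    # particle velocity: product-integration convolution with the exact
    # exponential kernel antiderivatives (no fractional machinery)
    g = None
    if tau.size >= 2 and tau[0] == 0.0 and np.allclose(np.diff(tau), tau[1] - tau[0]):
        dt = float(tau[1] - tau[0])
        b = 1.0 / dp.Pm
        K = 1.0 - np.exp(-b * tau)
        IK = tau - (1.0 - np.exp(-b * tau)) / b
        g = np.empty_like(fvals)
        dIK = np.diff(IK)
        for i in range(xi.size):
            row = fvals[i]
            gi = row[0] * K
            slopes = np.diff(row) / dt
            gi[1:] += np.convolve(slopes, dIK)[: tau.size - 1]
            g[i] = gi
    return VelocityField(xi=xi, tau=tau, f=fvals, g=g)


def velocity_gm0(xi, tau, dp: DimensionlessParams,
                 ctrl: SeriesControl = DEFAULT_CONTROL,
                 path: str = "series") -> VelocityField:
    """Special case ``Gm = 0``: the solutal-buoyancy terms drop out and the
    remaining brace weights are recomputed with ``Gm = 0``."""
    return velocity_fluid(xi, tau, dp.replace(Gm=0.0), ctrl, path=path)
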