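"""Finite Hankel transform of order zero on the unit interval.

The axisymmetric Laplacian with Dirichlet wall data is diagonalised by the
Fourier-Bessel basis ``J0(xi * eps_n)``, where ``eps_n`` are the positive
zeros of ``J0``.  Forward transform, inversion and the root table all live
here so that every series solution downstream shares one consistent basis.

Conventions (fixed for the whole package):

* forward:  ``F_n = int_0^1 xi f(xi) J0(xi eps_n) dxi``
* inverse:  ``f(xi) = 2 sum_n F_n J0(xi eps_n) / J1(eps_n)**2``
* transform of the Laplacian:
  ``H{f'' + f'/xi} = -eps_n**2 F_n + eps_n J1(eps_n) f(1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate
from scipy.special import j0, j1, jn_zeros

__all__ = ["HankelBasis", "ModeSpectrum", "j0_zeros", "fht", "ifht"]


def j0_zeros(n: int) -> np.ndarray:
    """First ``n`` positive zeros of the Bessel function ``J0``."""
    if n < 1:
        raise ValueError("need at least one root")
    return jn_zeros(0, n)


@dataclass(frozen=True)
class HankelBasis:
    roots: np.ndarray
    j1_at_roots: np.ndarray

    @classmethod
    def build(cls, n_modes: int) -> "HankelBasis":
        roots = j0_zeros(n_modes)
        return cls(roots=roots, j1_at_roots=j1(roots))

    @property
    def n_modes(self) -> int:
        return len(self.roots)

    def __post_init__(self) -> None:
        r = np.asarray(self.roots)
        if np.any(np.diff(r) <= 0):
            raise ValueError("roots must be strictly increasing")
        if np.max(np.abs(j0(r))) > 1e-11:
            raise ValueError("roots are not zeros of J0 to tolerance")


@dataclass(frozen=True)
class ModeSpectrum:
    coefficients: np.ndarray
    basis: HankelBasis

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.basis.n_modes:
            raise ValueError("spectrum length must match basis mode count")


def fht(profile: Callable[[np.ndarray], np.ndarray], basis: HankelBasis,
        tol: float = 1e-11) -> ModeSpectrum:
    """Forward finite Hankel transform of a radial profile on [0, 1].

    Adaptive quadrature per mode; for the oscillatory high modes the
    integrand's zeros are handed to the subdivider.
    """
    coeffs = np.empty(basis.n_modes)
    for i, eps in enumerate(basis.roots):
        # interior sign changes of J0(xi*eps): at xi = eps_k/eps for eps_k < eps
        pts = [z / eps for z in basis.roots[: i]] or None
        val, err = integrate.quad(
            lambda xi: xi * profile(xi) * j0(xi * eps),
            0.0, 1.0, epsabs=tol, epsrel=tol, limit=max(60, 4 * (i + 2)),
            points=pts,
        )
        if err > 100 * max(tol, 1e-14):
            raise RuntimeError(
                f"Hankel quadrature did not converge for mode {i + 1}: err={err:.2e}"
            )
        coeffs[i] = val
    return ModeSpectrum(coefficients=coeffs, basis=basis)


def ifht(spectrum: ModeSpectrum, xi) -> np.ndarray:
    """Inverse transform: ``2 sum_n F_n J0(xi eps_n) / J1(eps_n)**2``.

    ``spectrum.coefficients`` may be 1-D (one value per mode) or 2-D with
    shape ``(n_modes, n_times)``, in which case the result has shape
    ``(n_xi, n_times)``.
    """
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    roots = spectrum.basis.roots
    Jn = j0(np.outer(xi, roots))                       # (n_xi, n_modes)
    weights = 2.0 / spectrum.basis.j1_at_roots**2
    coeffs = np.asarray(spectrum.coefficients)
    if coeffs.ndim == 1:
        return Jn @ (weights * coeffs)
    return Jn @ (weights[:, None] * coeffs)
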