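"""Exact temperature and concentration fields.

Both scalars obey the same time-fractional diffusion problem on the unit
disc (Caputo order ``alpha``, diffusivity ``1/Pr`` or ``1/Sc``, unit wall
data switched on at ``tau = 0``), so the solutions differ only by the
per-mode decay rates ``a1_n = eps_n**2 / Pr`` and ``a2_n = eps_n**2 / Sc``:

``Theta(xi, tau) = 1 - 2 sum_n J0(xi eps_n)/(eps_n J1(eps_n))
                     * E_alpha(-a1_n tau**alpha)``

where ``E_alpha(-a tau**alpha)`` is the Lorenzo-Hartley kernel
``R_{alpha,1-alpha}(-a, tau)``.  The classical (``alpha = 1``) limit
replaces the Mittag-Leffler relaxation with plain exponentials and serves
as an independent oracle for the fractional machinery.

Two evaluation paths are provided: the closed series above, and numerical
Bromwich inversion of the per-mode Laplace image
``(J1/eps) [1/l - l**(alpha-1)/(l**alpha + a_n)]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import j0

from .hankel import HankelBasis
from .params import DimensionlessParams
from .specfun import DEFAULT_CONTROL, LaplaceImage, SeriesControl, inverse_laplace, ml_neg

__all__ = ["ModeDecayRates", "ScalarField", "temperature", "concentration",
           "classical_fields", "scalar_mode_image"]


@dataclass(frozen=True)
class ModeDecayRates:
    """Per-mode relaxation rates ``eps_n**2 / Pr`` and ``eps_n**2 / Sc``."""

    a1: np.ndarray
    a2: np.ndarray

    @classmethod
    def from_basis(cls, basis: HankelBasis, dp: DimensionlessParams) -> "ModeDecayRates":
        e2 = basis.roots**2
        return cls(a1=e2 / dp.Pr, a2=e2 / dp.Sc)


@dataclass(frozen=True)
class ScalarField:
    """A scalar field sampled on the tensor grid ``(xi, tau)``."""

    xi: np.ndarray
    tau: np.ndarray
    values: np.ndarray            # shape (n_xi, n_tau)
    kind: str                     # "temperature" or "concentration"


def _lifted_series(basis: HankelBasis, xi: np.ndarray, brace: np.ndarray) -> np.ndarray:
    """Assemble ``1 - 2 sum_n J0(xi eps_n)/(eps_n J1_n) * brace_n(tau)``.

    The unit wall value is carried exactly (each ``J0(eps_n)`` vanishes at
    ``xi = 1``), so the wall row equals 1 identically and the series only
    represents the deviation from it.
    """
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    w = 1.0 / (basis.roots * basis.j1_at_roots)         # (n_modes,)
    Jn = j0(np.outer(xi, basis.roots))                  # (n_xi, n_modes)
    Jn[xi == 1.0] = 0.0   # J0(eps_n) = 0 analytically; keep the wall row exact
    return 1.0 - 2.0 * (Jn * w) @ brace


def _relaxation_matrix(alpha: float, rates: np.ndarray, tau: np.ndarray,
                       ctrl: SeriesControl) -> np.ndarray:
    """``E_alpha(-a_n tau**alpha)`` for every mode/time pair."""
    x = np.outer(rates, np.atleast_1d(tau).astype(float) ** alpha)
    return ml_neg(alpha, 1.0, x, ctrl).reshape(x.shape)


def scalar_mode_image(a_n: float, alpha: float) -> LaplaceImage:
    """Laplace image of one scaled scalar mode: ``1/l - l**(alpha-1)/(l**alpha + a)``.

    The scaling strips the ``J1(eps)/eps`` Hankel weight, so the inverse
    is exactly the brace complement ``1 - E_alpha(-a tau**alpha)``.
    """
    def ev(l):
        y = l**alpha
        return 1.0 / l - l ** (alpha - 1.0) / (y + a_n)
    return LaplaceImage(ev)


def _scalar_field(xi, tau, dp: DimensionlessParams, rates: np.ndarray, kind: str,
                  ctrl: SeriesControl, path: str) -> ScalarField:
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(xi < 0) or np.any(xi > 1):
        raise ValueError("xi must lie in [0, 1]")
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    basis = HankelBasis.build(ctrl.n_modes)
    if path == "series":
        brace = _relaxation_matrix(dp.alpha, rates, tau, ctrl)
    elif path == "ilt":
        brace = np.empty((basis.n_modes, tau.size))
        for i, a_n in enumerate(rates):
            img = scalar_mode_image(a_n, dp.alpha)
            for k, t in enumerate(tau):
                # the inversion yields 1 - E; E itself at tau = 0 is 1
                brace[i, k] = 1.0 - inverse_laplace(img, t, ctrl) if t > 0 else 1.0
    else:
        raise ValueError(f"unknown path {path!r}")
    vals = _lifted_series(basis, xi, brace)
    return ScalarField(xi=xi, tau=tau, values=vals, kind=kind)


def temperature(xi, tau, dp: DimensionlessParams,
                ctrl: SeriesControl = DEFAULT_CONTROL, path: str = "series") -> ScalarField:
    """Fractional temperature field ``Theta(xi, tau)``.

    ``Theta(1, tau) = 1`` exactly; ``Theta(xi, 0) = 0`` up to Fourier-Bessel
    truncation ripple.
    """
    basis = HankelBasis.build(ctrl.n_modes)
    rates = ModeDecayRates.from_basis(basis, dp).a1
    return _scalar_field(xi, tau, dp, rates, "temperature", ctrl, path)


def concentration(xi, tau, dp: DimensionlessParams,
                  ctrl: SeriesControl = DEFAULT_CONTROL, path: str = "series") -> ScalarField:
    """Fractional concentration field ``Phi(xi, tau)`` (same model, Sc for Pr)."""
    basis = HankelBasis.build(ctrl.n_modes)
    rates = ModeDecayRates.from_basis(basis, dp).a2
    return _scalar_field(xi, tau, dp, rates, "concentration", ctrl, path)


def classical_fields(xi, tau, dp: DimensionlessParams,
                     ctrl: SeriesControl = DEFAULT_CONTROL) -> tuple[ScalarField, ScalarField]:
    """Classical (``alpha = 1``) limits: exponential-kernel series.

    Evaluated directly from ``exp(-a_n tau)`` with no Mittag-Leffler
    machinery, so this is an independent oracle for the ``alpha -> 1``
    limit of :func:`temperature` / :func:`concentration`.
    """
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    basis = HankelBasis.build(ctrl.n_modes)
    rates = ModeDecayRates.from_basis(basis, dp)
    th = _lifted_series(basis, xi, np.exp(-np.outer(rates.a1, tau)))
    ph = _lifted_series(basis, xi, np.exp(-np.outer(rates.a2, tau)))
    return (
        ScalarField(xi=xi, tau=tau, values=th, kind="temperature"),
        ScalarField(xi=xi, tau=tau, values=ph, kind="concentration"),
    )
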