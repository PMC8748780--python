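"""Model parameters: physical properties, dimensionless groups, validation.

The flow of blood carrying magnetic particles through a rigid cylindrical
tube of radius ``r0`` is governed, after nondimensionalisation with the
scales ``xi = r/r0``, ``tau = nu*t/r0**2``, ``f = u/u0``, by a small set of
dimensionless groups:

========  =============================================================
``M``     magnetic (Hartmann-squared) parameter, sigma*B0**2*r0**2/mu
``beta1`` Brinkman bulk-drag parameter, beta*r0**2/nu
``M0``    combined damping entering the momentum equation
``Pc``    particle concentration parameter, K*N*r0**2/mu
``Pm``    particle mass parameter; the particle relaxation rate is 1/Pm
``Gr``    thermal Grashof number
``Gm``    solutal (mass) Grashof number
``Pr``    Prandtl number, mu*cp/k
``Sc``    Schmidt number, nu/D
``A0``    steady pressure-gradient amplitude (dimensionless)
``A1``    oscillatory pressure-gradient amplitude
``omega`` dimensionless forcing frequency
``alpha`` Caputo fractional order in (0, 1]
========  =============================================================

Two conventions are configurable because the source material is
internally inconsistent on them:

* ``m0_convention``: both the Lorentz term ``-M f`` and the Brinkman term
  ``-beta1 f`` damp the flow, so physically ``M0 = M + beta1`` (the
  default, ``"sum"``).  The convention ``"difference"`` gives
  ``M0 = M - beta1`` as some presentations print it.
* the particle relaxation rate is ``1/Pm`` everywhere (the only choice
  consistent with the particle-velocity convolution solution and the wall
  condition ``g(1, tau) = 1 - exp(-b*tau)`` with ``b = 1/Pm``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import yaml

__all__ = [
    "PhysicalParams",
    "DimensionlessParams",
    "ValidationReport",
    "compute_dimensionless",
    "validate_params",
    "load_config",
    "figure_defaults",
]


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional fluid, particle and thermal properties (SI units).

    ``D_mass`` is in m^2/s (callers converting from mm^2/s must divide by 1e6).
    """

    rho: float = 1050.0            # fluid density, kg/m^3
    mu: float = 3.2548e-3          # dynamic viscosity, kg/(m s)
    cp: float = 3617.0             # specific heat, J/(kg K)
    k_thermal: float = 0.52        # thermal conductivity, J/(m s K)
    D_mass: float = 1.6e-10        # mass diffusivity, m^2/s
    sigma: float = 0.8             # electrical conductivity, S/m
    B0: float = 0.0                # magnetic flux density, T
    K_stokes: float = 6.0e-11      # Stokes drag coefficient, kg/s
    N_count: float = 1.0e12        # particle number density, 1/m^3
    m_particle: float = 1.0e-14    # particle mass, kg
    beta_brinkman: float = 0.0     # Brinkman drag rate, 1/s
    r0: float = 1.0e-3             # tube radius, m
    u0: float = 1.0e-2             # reference velocity, m/s
    g_accel: float = 9.81          # gravity, m/s^2
    betaT: float = 0.0             # thermal expansion coefficient, 1/K
    betaC: float = 0.0             # solutal expansion coefficient
    Tw: float = 310.0              # wall temperature, K
    Tinf: float = 300.0            # ambient temperature, K
    Cw: float = 1.0                # wall concentration
    Cinf: float = 0.0              # ambient concentration
    lambda0: float = 0.0           # steady pressure-gradient amplitude, Pa/m
    lambda1: float = 0.0           # oscillatory pressure-gradient amplitude, Pa/m
    omega_dim: float = 0.0         # forcing angular frequency, 1/s

    # fields that may legitimately be zero (no Lorentz force, no Brinkman
    # drag, no buoyancy, no pressure forcing)
    _ZERO_OK = frozenset(
        {"B0", "lambda0", "lambda1", "beta_brinkman", "betaT", "betaC",
         "omega_dim", "Cinf", "sigma"}
    )

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            if f_.name.startswith("_"):
                continue
            v = getattr(self, f_.name)
            if f_.name in ("Tinf", "Cw", "Tw"):
                continue
            if f_.name in self._ZERO_OK:
                if v < 0:
                    raise ValueError(f"physical parameter {f_.name} must be >= 0, got {v}")
            elif f_.name in ("Cinf",):
                continue
            elif v <= 0:
                raise ValueError(f"physical parameter {f_.name} must be > 0, got {v}")
        if self.Tw < self.Tinf:
            raise ValueError("buoyancy convention requires Tw >= Tinf")
        if self.Cw < self.Cinf:
            raise ValueError("buoyancy convention requires Cw >= Cinf")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, m^2/s."""
        return self.mu / self.rho


@dataclass(frozen=True)
class DimensionlessParams:
    alpha: float = 0.5
    M: float = 0.5
    beta1: float = 0.5
    Pc: float = 0.5
    Pm: float = 0.5
    Gr: float = 320.0
    Gm: float = 0.5
    Pr: float = 22.64
    Sc: float = 1.9e4
    A0: float = 0.5
    A1: float = 0.5
    omega: float = 5.0 * np.pi / 8.0
    m0_convention: str = "sum"

    def __post_init__(self) -> None:
        if self.m0_convention not in ("sum", "difference"):
            raise ValueError("m0_convention must be 'sum' or 'difference'")

    @property
    def M0(self) -> float:
        """Combined damping; ``M + beta1`` ('sum') or ``M - beta1`` ('difference')."""
        if self.m0_convention == "sum":
            return self.M + self.beta1
        return self.M - self.beta1

    @property
    def b(self) -> float:
        """Particle boundary-relaxation rate; tied to ``1/Pm``."""
        return 1.0 / self.Pm

    def replace(self, **kw) -> "DimensionlessParams":
        return dataclasses.replace(self, **kw)


@dataclass
class ValidationReport:
    messages: list[tuple[str, str]] = field(default_factory=list)  # (severity, text)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _ in self.messages)

    def error(self, text: str) -> None:
        self.messages.append(("error", text))

    def warn(self, text: str) -> None:
        self.messages.append(("warning", text))

    def __str__(self) -> str:
        if not self.messages:
            return "ok: no findings"
        return "\n".join(f"[{sev}] {txt}" for sev, txt in self.messages)


def compute_dimensionless(
    phys: PhysicalParams,
    alpha: float = 0.5,
    m0_convention: str = "sum",
) -> DimensionlessParams:
    """Map dimensional properties to the model's dimensionless groups.

    Uses ``nu = mu/rho`` and the scales ``xi = r/r0``, ``tau = nu t/r0^2``,
    ``f = u/u0``.  The particle mass parameter is the reciprocal of the
    dimensionless relaxation rate, ``Pm = m nu/(K r0^2) = 1/b``, so that the
    particle momentum balance reads ``D^alpha g = (f - g)/Pm``.
    """
    nu = phys.nu
    r2 = phys.r0**2
    b = phys.K_stokes * r2 / (phys.m_particle * nu)
    scale_p = r2 / (phys.mu * phys.u0)   # maps a pressure gradient (Pa/m) to A
    return DimensionlessParams(
        alpha=alpha,
        M=phys.sigma * phys.B0**2 * r2 / phys.mu,
        beta1=phys.beta_brinkman * r2 / nu,
        Pc=phys.K_stokes * phys.N_count * r2 / phys.mu,
        Pm=1.0 / b,
        Gr=phys.g_accel * r2 * phys.betaT * (phys.Tw - phys.Tinf) / (phys.u0 * nu),
        Gm=phys.g_accel * r2 * phys.betaC * (phys.Cw - phys.Cinf) / (phys.u0 * nu),
        Pr=phys.mu * phys.cp / phys.k_thermal,
        Sc=nu / phys.D_mass,
        A0=phys.lambda0 * scale_p,
        A1=phys.lambda1 * scale_p,
        omega=phys.omega_dim * r2 / nu,
        m0_convention=m0_convention,
    )


def validate_params(dp: DimensionlessParams) -> ValidationReport:
    """Check a dimensionless configuration; never mutates its input."""
    rep = ValidationReport()
    if not (0.0 < dp.alpha <= 1.0):
        rep.error(f"alpha must lie in (0, 1], got {dp.alpha}")
    if dp.Pr <= 0:
        rep.error(f"Pr must be > 0, got {dp.Pr}")
    if dp.Sc <= 0:
        rep.error(f"Sc must be > 0, got {dp.Sc}")
    if dp.Pm == 0:
        rep.error("Pm must be nonzero (particle relaxation rate 1/Pm is singular)")
    elif dp.Pm < 0:
        rep.error(f"Pm must be > 0, got {dp.Pm}")
    if dp.Pc < 0:
        rep.error(f"Pc must be >= 0, got {dp.Pc}")
    if dp.M < 0:
        rep.error(f"M must be >= 0, got {dp.M}")
    if dp.omega < 0:
        rep.error(f"omega must be >= 0, got {dp.omega}")
    if dp.m0_convention == "difference" and dp.M0 < 0:
        rep.warn(
            "M0 = M - beta1 is negative under the 'difference' convention; "
            "the flow is then anti-damped"
        )
    return rep


def figure_defaults(**overrides) -> DimensionlessParams:
    """The parameter set the graphical study holds fixed.

    Pr = 22.64 and Sc = 1.9e4 follow from the blood properties (rho = 1050
    kg/m^3, mu = 3.2548e-3 kg/(m s), cp = 3617 J/(kg K), k = 0.52 J/(m s K),
    D = 1.6e-4 mm^2/s); omega = 5*pi/8 so that the quoted phase omega*tau
    equals 5*pi/8 at tau = 1; the remaining groups default to 0.5 with
    Gr = 3.2e2.
    """
    return DimensionlessParams().replace(**overrides)


_SECTIONS = ("physical", "dimensionless", "numerics")


def load_config(path: str | Path):
    """Read a key-value (YAML) config with sections physical/dimensionless/numerics.

    Exactly one of the ``physical`` / ``dimensionless`` sections must be
    present; keys mirror the dataclass field names.  Returns
    ``(DimensionlessParams, numerics_dict)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    has_phys = "physical" in raw
    has_dim = "dimensionless" in raw
    if has_phys == has_dim:
        raise ValueError("config must contain exactly one of 'physical' or 'dimensionless'")
    numerics = dict(raw.get("numerics") or {})
    if has_phys:
        sec = dict(raw["physical"])
        alpha = float(sec.pop("alpha", 0.5))
        conv = sec.pop("m0_convention", "sum")
        _check_keys(sec, PhysicalParams, "physical")
        dp = compute_dimensionless(PhysicalParams(**sec), alpha=alpha, m0_convention=conv)
    else:
        sec = dict(raw["dimensionless"])
        _check_keys(sec, DimensionlessParams, "dimensionless")
        dp = DimensionlessParams(**sec)
    return dp, numerics


def _check_keys(sec: dict, cls, name: str) -> None:
    allowed = {f_.name for f_ in dataclasses.fields(cls) if not f_.name.startswith("_")}
    bad = set(sec) - allowed
    if bad:
        raise ValueError(f"unknown keys in '{name}' section: {sorted(bad)}")
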