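# Example configuration: physical blood properties (SI units).
# Exactly one of the sections `physical` / `dimensionless` may be present;
# keys mirror the PhysicalParams / DimensionlessParams field names.
physical:
  rho: 1050.0          # kg/m^3
  mu: 3.2548e-3        # kg/(m s)
  cp: 3617.0           # J/(kg K)
  k_thermal: 0.52      # J/(m s K)
  D_mass: 1.6e-10      # m^2/s
  alpha: 0.5           # Caputo order
numerics:
  n_modes: 60
  n_xi: 21
  n_tau: 40
  t_final: 2.0
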