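"""Magnetic-parameter sweep: Lorentz damping decelerates the flow.

Repeats the magnetic-field study: centerline blood and particle
velocities at tau = 1 for increasing magnetic parameter M, holding the
remaining groups at the study defaults.
"""

from hemoflow.cli import RunConfig, run_sweep
from hemoflow.params import figure_defaults
from hemoflow.specfun import SeriesControl

cfg = RunConfig(dp=figure_defaults(), ctrl=SeriesControl(n_modes=40))
table = run_sweep(cfg, "M", [0.5, 2.0, 5.0, 10.0], tau_report=1.0)
print(table.to_frame().to_string(index=False))
verdict = "strictly decreasing" if table.monotone_decreasing else "NOT monotone"
print(f"\ncenterline blood velocity is {verdict} in M")
# Raising M strengthens the resistive Lorentz force -M*f, so both phases
# slow down -- the handle used to steer magnetic drug carriers.
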