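"""Simulate mouse and human tumor dynamics.

Runs the Simeoni TGI model for a control and a treated xenograft arm, then
the exponential-growth / first-order-kill human model under the standard
weekly gemcitabine-style protocol, and prints a few trajectory points.
"""

import numpy as np

import xenoscale as xs
from xenoscale.io import default_pk_spec
from xenoscale.synthdata import default_mouse_regimen

# --- mouse: q3d x 4 i.p. dosing --------------------------------------------
pk = default_pk_spec("mouse_ip")
regimen = default_mouse_regimen(horizon_days=43.0)
conc = xs.simulate_pk(pk, regimen, np.linspace(0, 43, 301))

params = xs.SimeoniParams(lambda0=0.08, lambda1=0.15, k1=0.4, k2=0.4, w0=0.25)
grid = np.arange(0.0, 43.0, 3.0)
control = xs.simulate_simeoni(
    xs.SimeoniParams(0.08, 0.15, 0.4, 0.0, 0.25), None, grid
)
treated = xs.simulate_simeoni(params, conc, grid)

print("mouse tumor burden [cm^3] (day: control / treated)")
for i in range(0, len(grid), 3):
    print(f"  day {grid[i]:4.0f}: {control.tv[i]:6.3f} / {treated.tv[i]:6.3f}")
print(
    "Growth in the treated arm is suppressed while dosing (days 0-9, "
    f"cumulative exposure {conc.cauc[-1]:.2f} mg*day/L) and resumes at the "
    "control pace afterwards."
)

# --- human: closed-form model, months axis ----------------------------------
human_conc = xs.simulate_pk(
    default_pk_spec("human_gemcitabine"),
    xs.build_regimen("gemcitabine_standard", 14 * 30.0, bsa_m2=1.8),
).to_unit("month")
hp = xs.HumanTGIParams(lambda0_human=0.17, k2_human=0.85, tv0=1.0)
months = np.arange(0.0, 14.5, 2.0)
traj = xs.simulate_human_tumor(hp, human_conc, months)
print("\nhuman tumor diameter [cm] by month:")
print("  " + "  ".join(f"{m:.0f}:{d:.3f}" for m, d in zip(months, traj.td)))
print(
    "Growth rate 0.17/month against a drug kill proportional to plasma "
    "concentration; the diameter is the sphere-equivalent of the volume."
)
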