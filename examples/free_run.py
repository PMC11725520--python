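"""Free-running dynamics in darkness: period, amplitude, and saturation.

Simulate each pacemaker model on its dark attractor, recover the
free-running period from successive CBTmin markers, and demonstrate
photic saturation: under constant bright light the photoreceptor drive
peaks immediately and decays to a lower steady state as the activated
fraction n builds up.
"""

import numpy as np

import circamp as ca
from circamp.oscillators import dark_equilibrium_R, dark_period

for name in ca.registered_models():
    spec = ca.get_model(name)
    state = ca.limit_cycle_state(spec)
    traj = ca.integrate(spec, state, None, 0.0, 120.0, 0.01)
    spacing = np.diff(ca.circadian_markers(traj)["cbt_min_times"])
    line = (
        f"{name:<12} dark period {spacing.mean():.3f} h"
        f" (nominal {dark_period(spec):.3f} h)"
    )
    if not spec.is_vdp:
        line += (
            f"; dark R {traj.states[-1, 0]:.4f}"
            f" (closed form {dark_equilibrium_R(spec):.4f})"
        )
    print(line)

print("\nphotic saturation under constant 8000 lux (forger99):")
spec = ca.get_model("forger99")
state = ca.limit_cycle_state(spec)
light = ca.LightSchedule(breakpoints=(0.0, 6.0), levels=(8000.0,))
traj = ca.integrate(spec, state, light, 0.0, 6.0, 0.01)
for t in (0.0, 0.5, 1.0, 3.0, 6.0):
    n = traj.states[traj.index_of(t), 2]
    drive = ca.process_l_drive(spec, n, 8000.0)
    print(f"  t = {t:3.1f} h   n = {n:.3f}   Process-L drive = {drive:.3f}")

print(
    "\nReading: the drive is maximal at light onset after dark adaptation"
    "\nand settles well below its peak - morning light hits a maximally"
    "\nresponsive system."
)
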