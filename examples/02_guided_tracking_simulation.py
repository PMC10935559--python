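"""Simulate guided patellar tracking on the default (stable) bench.

The femur and tibia follow the synthetic capture; the patella is free and
held in the trochlear groove by the two tendon straps and the contact
force.  Prints the spring tensions and contact force over one second of
motion plus the patellar excursion in the femur frame.
"""

import numpy as np

from pftwin.analysis import kinematics_from_trajectory
from pftwin.bench import ScenarioConfig, grouped_tensions, prepare_run
from pftwin.dynamics import SimConfig, simulate

cfg = ScenarioConfig()
model, state, truth, markers = prepare_run(cfg)
print(f"static equilibrium found; initial contact force "
      f"{sum(p.force for p in state.patches if hasattr(p, 'force')) or '...'}")

traj = simulate(model, (0.0, 1.0), SimConfig(h=1e-3), state=state)
kin = kinematics_from_trajectory(traj)
ten = grouped_tensions(traj)

print(f"simulated {traj.stats['n_steps']} steps "
      f"({traj.stats['realtime_ratio']:.2f}x realtime)")
print(f"contact force:  {traj.contact_force.min():6.2f} .. "
      f"{traj.contact_force.max():6.2f} N")
print(f"quad tension:   {ten['femoral'].min():6.2f} .. {ten['femoral'].max():6.2f} N")
print(f"tendon tension: {ten['tibial'].min():6.2f} .. {ten['tibial'].max():6.2f} N")
print(f"patella sagittal travel: "
      f"{1e3 * np.ptp(kin.position[:, 0]):.1f} mm; "
      f"medial-lateral stay: {1e3 * np.abs(kin.position[:, 1]).max():.1f} mm "
      f"(ridge at {1e3 * cfg.groove.groove_halfwidth:.0f} mm)")
print(f"max constraint residual: {traj.max_phi.max():.2e}")
print("-> the patella glides a few mm along the groove while staying")
print("   centered: a stable, normal tracking pattern.")
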