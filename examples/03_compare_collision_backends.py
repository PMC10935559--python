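"""Compare collision backends on a common prescribed sweep.

The sphere is swept along the groove with a known indentation history;
each backend's Flores force history is scored against the closed-form
reference.  The coarse mesh shows the discretization artifact: spurious
high-frequency force oscillations tied to the facet size.
"""

import numpy as np

from pftwin.bench import ScenarioConfig
from pftwin.compare import backend_force_history, highband_power, sweep_reference

cfg = ScenarioConfig()
fs, dur = 1000.0, 0.6
t, ref = sweep_reference(cfg, fs=fs, duration=dur)
print(f"reference peak force {ref.max():.1f} N over {dur} s at {fs:.0f} Hz")

for spec in ("analytic:2", "analytic:5", "mesh:coarse", "mesh:fine"):
    _, f = backend_force_history(cfg, spec, fs=fs, duration=dur)
    rmse = np.sqrt(np.mean((f - ref) ** 2))
    hp = highband_power(f, fs)
    print(f"{spec:12s} rmse {100 * rmse / ref.max():6.2f} % of peak   "
          f">50 Hz power {hp:10.3e} N^2")
print("-> the exact-order analytic surface matches the reference; the")
print("   coarse mesh is close on average but carries facet-induced")
print("   oscillations (large >50 Hz power) that the fine mesh suppresses.")
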