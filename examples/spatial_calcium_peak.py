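"""Local calcium microdomain at the active zone (spatial engine).

Runs particle-based single-AP trials and reports the local calcium
peak 10 nm from the active zone, plus the effective diffusion constant
of calcium in the calbindin-buffered cytosol.
"""
import numpy as np

from boutonsim.analysis import estimate_effective_D
from boutonsim.config import SimConfig
from boutonsim.spatial import (measure_peak_local_ca, run_spatial_trial,
                               tagged_ion_positions)

cfg = SimConfig().validate()

res = run_spatial_trial(cfg, duration_ms=6.0, seed=1)
print(f"one trial: {res.total_influx_ions} ions entered, "
      f"peak open channels {res.open_counts.max()}, "
      f"local peak {res.trace.peak():.1f} uM")

peak = measure_peak_local_ca(cfg, n_trials=20, seed=2, duration_ms=6.0)
print(f"mean local calcium peak over 20 trials: {peak:.1f} uM "
      "(measured value: 12 +- 4.8 uM)")

times, xs = tagged_ion_positions(cfg, n_ions=800, seed=3)
d_eff = estimate_effective_D(times, xs)
print(f"effective diffusion with 45 uM calbindin: {d_eff:.0f} um^2/s "
      "(free constant 220; measured apparent value ~50)")
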