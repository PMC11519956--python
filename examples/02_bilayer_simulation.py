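"""A small tensionless bilayer simulation, start to finish.

Builds a 64-lipid-per-leaflet bilayer (the smallest square patch whose
lateral box safely exceeds twice the 2.5 nm cutoff), minimizes it, runs
Langevin dynamics at 315 K with semi-isotropic (zero-surface-tension)
Berendsen coupling, and prints the area per lipid.  The run is short,
so the area is still relaxing toward its stationary value (~0.56 nm^2
for this parameter set; a few nanoseconds are needed to converge).
"""

import numpy as np

from ucgmem import observables as obs
from ucgmem.engine import SimConfig, build_bilayer, minimize, run_ld
from ucgmem.forcefield import ForceFieldParams

ff = ForceFieldParams.optimal()
sys_ = build_bilayer(64, apl0=0.68, ff=ff)
print(f"built bilayer: {sys_.n_molecules} lipids, box {np.round(sys_.box, 2)} nm")

sys_ = minimize(sys_, ff, max_steps=300)
sys_.thermalize(315.0, np.random.default_rng(0))

cfg = SimConfig(temperature=315.0, n_steps=4000, seed=1, report_interval=20)
traj = run_ld(sys_, ff, cfg)

series = obs.BoxSeries.from_trajectory(traj)
apl, err = obs.area_per_lipid(series, 64)
print(f"area per lipid over {traj.times[-1]:.0f} ps: "
      f"{apl:.3f} +/- {err:.3f} nm^2")
print(f"final lateral box: {traj.final_system.box[0]:.2f} nm "
      "(the barostat contracts the initially oversized area)")
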