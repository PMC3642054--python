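# ramsim

A simulator of cell-pattern emergence in the *Arabidopsis thaliana* root
apical meristem (RAM), for researchers studying how stem-cell niches
partition a growing organ into proliferation and elongation domains.

The root tip is modeled as a two-dimensional longitudinal section: each
cell is the Voronoi region of a mobile generating point, bounded by fixed
points standing for the epidermis and root cap.  Three coupled dynamics
run on this tessellation:

* **Elastic field.**  Each cell i carries a harmonic potential
  `V_i = K_v (A_i − Ā)² + K_c |r_i − c_i|²` penalizing deviations of its
  area `A_i` from the equilibrium share `Ā` and of its generating point
  `r_i` from its centroid `c_i`.  Generators move by damped Newtonian
  dynamics, `dv/dt = F − λv` with `F = −∇ Σ V_i` evaluated analytically.
* **Polar auxin transport.**  A per-cell auxin concentration `C_i`
  (max-normalized each step) is exchanged through cell walls by
  PIN-carrier "gates" arranged in the reverse-fountain pattern: toward the
  apex through the inner tissue, laterally below the quiescent centre
  (QC), baseward along the surface.  The gates set the flux direction and
  the local potential difference sets its rate, plus a small ungated
  diffusive term; the result is an apical-basal gradient with its maximum
  at the QC.
* **Cell-cycle clock.**  Each cell runs a Lotka–Volterra oscillator for
  the activator/inhibitor cyclin pair (CYCD/CYCB) with period
  `T_c = 2π/√α`, where `α` is a linear function of local auxin; the cycle
  arrests outside an auxin window.  A cell divides when its clock passes
  `m·T_c` and it has regrown toward adult size; each division extends the
  domain's upper edge by exactly `Ā`.  The QC divides tenfold slower.

The emergent outcome, with parameters calibrated to seven days ≈ 3400
iterations, is a meristem of ≈350 cells whose divisions stay confined
within a stationary distance of the tip, a ≈12 h single-cell cycle, and
an elongation zone beyond the meristem — the characteristic patterning of
the root stem-cell niche.

## Worked example

```python
import numpy as np
from ramsim import SimConfig, run, analysis

trace = run(SimConfig(seed=1, snapshot_every=850))
print("final cells:", trace.n_cells_final)
print("divisions:", len(trace.events))
print("meristem length (µm):", round(analysis.ram_length(trace), 1))
final = trace.snapshots[3400]
prof = analysis.auxin_profile(trace, final, bin_width=50.0)
print("auxin vs distance-from-tip (50 µm bins):",
      np.round(prof.values[:5], 2))
```

prints

```
final cells: 342
divisions: 332
meristem length (µm): 48.4
auxin vs distance-from-tip (50 µm bins): [0.46 0.02 0.   0.   0.  ]
```

i.e. the root grew from 10 cells to 342 in seven simulated days, all late
divisions happen within ~50 µm of the tip (the stationary meristem), and
the auxin concentration decays from its maximum at the quiescent centre to
near zero in the elongation zone.

The same experiment from the shell, plus figure output:

```sh
ramsim run --seed 1 --out scratch/run1          # trace CSVs + SVG snapshots
ramsim analyze --seed 1 --out scratch/profiles  # Fig-style profile CSVs
ramsim relax --n-cells 100 --out scratch/relax  # mechanics-only relaxation
ramsim scan --out scratch/scan                  # meristem length vs D
```

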