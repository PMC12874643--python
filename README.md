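# dpdgel

Mesoscale simulation and analysis of hydrogel friction against a smooth
rigid wall, using dissipative particle dynamics (DPD) with explicit
solvent.

Hydrogels — swollen, cross-linked polymer networks — lubricate many
biological sliding interfaces (cartilage, the ocular surface) with
friction coefficients that depend strongly on sliding velocity and
normal load.  `dpdgel` implements a complete in-silico tribometer for
this problem: it builds a random cross-linked bead–spring network,
immerses it in a DPD solvent between a no-slip bottom wall and a loaded,
solvent-permeable sliding top wall, and measures friction, near-wall
structure and gel deformation.  It is intended for soft-matter and
biolubrication researchers who want a transparent, scriptable, fully
testable model of gel-on-wall friction.

## Model in brief

Beads interact with the standard DPD triplet (conservative soft
repulsion `a·w(r)`, pair drag `−γ w²(r)(r̂·v)r̂`, and pair noise
`σ w(r) ζ Δt^(−1/2) r̂` with `σ² = 2γk_BT`), with `ρ0 = 3, a = 25,
γ = 4.5, k_BT = 1, Δt = 0.01`.  Chains are harmonic-bonded
(`U = k_bond (r − r_eq)²`, `k_bond = 16`) with cosine bending
(`U = k_bend (1 + cos θ)`, `k_bend = 10`).  The generated network is
calibrated to porosity ε ≈ 0.89, mean chain length N₀ ≈ 6.2 monomers and
mean mesh size ξ₀ ≈ 3.2 (largest-inscribed-sphere statistic).

Runs are controlled by two dimensionless groups:

- the Weissenberg number `Wi = V η ξ₀² / k_BT`, the ratio of the polymer
  relaxation time to the shear time, and
- the reduced load `P = F_n / (A E)`,

where the solvent viscosity η, mesh size ξ₀ and gel modulus E are
*measured* by the package's own calibration protocols (periodic
Poiseuille viscometry, pore-size sampling, quasi-static compression).
The friction coefficient is `μ = ⟨F_f⟩ / F_n`, with F_f the horizontal
force the sliding wall applies to the gel through its tethers.

## Worked example

Measure the solvent viscosity, build a gel, and run one sliding
experiment at Wi = 1, P = 0.14 in a 12³ cell:

```python
import numpy as np
from dpdgel import (NetworkParams, WallSpec, MaterialProps,
                    ShearCell, measure_viscosity)
from dpdgel.shear import V_from_Wi
from dpdgel.analysis import shear_strain

eta, err, _ = measure_viscosity(steps=60_000, warmup=10_000, seed=3)
print(f"eta = {eta:.3f} +/- {err:.3f}")          # eta = 0.847 +/- 0.016

props = MaterialProps.reference()                 # packaged calibration
net   = NetworkParams(box=(12., 12., 12.), seed=4)
walls = WallSpec(F_n=0.14 * 144 * props.E,        # P = 0.14
                 V=V_from_Wi(1.0, props))         # Wi = 1
cell  = ShearCell.build(net, walls=walls, seed=4)
cell.equilibrate(15_000)
rec, profiles, disp = cell.produce(20_000)
gel = cell.sim.system.gel_mask
print(f"mu = {rec.mu:.2f} +/- {rec.mu_err:.2f}")  # mu = 1.73 +/- 0.71
print(f"gamma = {shear_strain(disp[gel], cell.ref_pos[gel, 2]):.2f}")
```

`mu ≈ 1.7` at Wi = 1 is the viscous-drag regime: friction comes from
shearing the thin solvent layer between the depleted gel interface and
the wall, so μ grows roughly linearly with Wi there, while for
Wi ≲ 0.01 it flattens to a small thermal value (and the per-run error
at this reduced cell size is substantial).  `gamma` is the bulk shear
tilt of the gel relative to its unloaded reference (≈ 0.03 here, zero
within noise at low Wi).  At fixed Wi, μ falls with increasing P as the
gel densifies near the interface.

The same experiment from the shell:

```bash
dpdgel build --seed 2 --out network.data          # LAMMPS-format network
dpdgel calibrate viscosity --out props.json
dpdgel run-shear --wi 0.1 --pload 0.14 --seed 7 --out run
dpdgel run-sweep --scale 0.2 --seed 1 --out sweep_out
dpdgel analyze sweep_out/sweep.csv --out tables
```

Externally deposited bead–spring networks in the LAMMPS data dialect can
be ingested with `dpdgel.workflow.read_geometry`.

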