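# fetalflow

Analysis pipeline for fetal **4D-flow phase-contrast cardiovascular MR**
(PC-CMR): from velocity-encoded phase volumes to quantitative fetal
hemodynamics — reconstruction of de-aliased velocity fields from
dual-VENC acquisitions, per-vessel flow quantification with
conservation-of-mass consistency checks, method-comparison statistics,
and pathline-based visualisation of shunt streaming. A first-class
analytic phantom of the fetal circulation provides ground truth with
exact flux oracles, standing in for in-utero acquisitions that cannot be
shared.

**Who it is for:** researchers developing or validating fetal (or other
small-vessel) 4D-flow processing — the phantom exposes every error
source of the real pipeline (phase wrapping, eddy-current background
phase, partial-volume flux loss, streaming quantification) with known
answers.

## The science in brief

Phase-contrast MRI encodes velocity into signal phase: a voxel moving at
*v* along an encoding axis acquires phase φ = π·v/VENC, where the
velocity-encoding parameter VENC (cm/s) maps to a phase of π. Velocities
beyond ±VENC alias (wrap by multiples of 2·VENC). Fetal protocols
therefore acquire two encodings — VENC 50 cm/s for precision in slow
venous flow and VENC 150 cm/s to cover arterial jets — and combine them:

1. **background correction** — a low-order polynomial fitted to the
   apparent velocity of static tissue is subtracted (eddy-current
   phase offsets);
2. **unwrapping** of the high-VENC field (temporal, then spatial region
   growing; every correction is a multiple of 2·VENC);
3. **dual-VENC merge** — the precise low-VENC value is kept, shifted by
   the nearest multiple of 2·VENC_low when the unwrapped high-VENC field
   reveals aliasing.

Flow through each vessel is the integral of the through-plane velocity
over an oriented lumen cross-section, cycle-averaged and indexed to
fetal weight (mL/min per kg). Fetal-specific derived quantities follow:

* combined ventricular output **CVO = 1.03·(MPA + AAo)** (the 3%
  accounts for unmeasured coronary flow) and the flow distribution
  **%CVO** per vessel;
* conservation-of-mass identities unique to the fetal circulation:
  IVCp = RHV + DV + IVCd, SVC + IVCp = MPA + FO, MPA = DA + PBF,
  IVCp = DAo — reported as symmetric percent differences;
* Bland-Altman limits of agreement, least-squares regression and a
  paired t-test for comparing against 2D PC-CMR;
* pathlines (RK4 advection through the cardiac-periodic field) and
  source→sink streaming fractions, quantifying e.g. the preferential
  routing of oxygenated ductus-venosus blood through the foramen ovale.

The phantom rasterizes a 14-vessel fetal network (umbilical vein,
ductus venosus, caval veins, foramen ovale, great arteries, ductus
arteriosus, …) with Poiseuille profiles and class-specific pulsatile
waveforms (peaked arterial, biphasic venous, near-constant umbilical),
then MR-encodes it with wrapping, background phase and noise at chosen
VENCs.

## Worked example

Generate a noise-free dual-VENC phantom at study geometry (2.8 kg fetus,
140 bpm, 96³ × 1.25 mm voxels, 8 cardiac frames, VENC 50/150 cm/s),
reconstruct it, and quantify every vessel:

```python
import numpy as np
from fetalflow import (
    AcquisitionSpec, build_phantom, encode, reconstruct_dual_venc,
    make_default_network, build_table, flow_waveform, junction_check,
    consistency_summary,
)
from fetalflow.quant import STANDARD_JUNCTIONS, default_measurement_planes

net = make_default_network(weight=2.8, heart_rate=140.0)
acq = AcquisitionSpec(grid_shape=(96, 96, 96), spacing=1.25, n_frames=8,
                      vencs=(50.0, 150.0), snr=None)
phantom = build_phantom(net, acq)
stacks = encode(phantom.truth, acq, phantom=phantom)
velocity, static = reconstruct_dual_venc(stacks)

planes = default_measurement_planes(net, velocity)
waveforms = [flow_waveform(velocity, p, net.weight) for p in planes.values()]
table = build_table(waveforms, net.weight)
print(f"CVO = {table.cvo:.0f} mL/min/kg")
for v in ("MPA", "AAo", "DAo", "FO", "DV"):
    print(f"  {v:4s} {table.flows[v]:6.1f} mL/min/kg  ({table.pct_cvo[v]}% of CVO)")
checks = [junction_check(table, i, o, name=n) for n, i, o in STANDARD_JUNCTIONS]
mean, sd, n = consistency_summary(checks)
print(f"junction consistency: {mean:.1f} +/- {sd:.1f}% (n={n})")
```

Output:

```
CVO = 543 mL/min/kg
  MPA   283.4 mL/min/kg  (52% of CVO)
  AAo   244.3 mL/min/kg  (45% of CVO)
  DAo   333.0 mL/min/kg  (61% of CVO)
  FO    226.6 mL/min/kg  (42% of CVO)
  DV    142.9 mL/min/kg  (26% of CVO)
junction consistency: 0.7 +/- 0.6% (n=4)
```

Reading it: indexed flows are recovered within ~2% of the network's
ground-truth means (MPA truth 284, AAo 245, DAo 333 mL/min per kg); the
main pulmonary artery carries 52% and the ascending aorta 45% of
combined ventricular output; the four conservation identities close to
under a percent on noise-free data, against ~14% reported for in-vivo
measurements.

The same pipeline runs from the shell, driven by one YAML config:

```bash
fetalflow all --config config.yaml --seed 1 --out run1/
# or stage by stage: fetalflow phantom / reconstruct / quantify / trace
```

outputs are NIfTI volumes with JSON sidecars, CSV waveform/streaming
tables, a JSON quantification report and legacy-VTK pathlines.

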