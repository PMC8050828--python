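# guvpart

Quantification of amphiphilic DNA-nanostructure partitioning between the
coexisting lipid phases of giant unilamellar vesicles (GUVs).

## The problem

Ternary lipid membranes (e.g. DOPC/DPPC/cholestanol) de-mix into
liquid-ordered (Lo) and liquid-disordered (Ld) phases. A DNA construct
carrying hydrophobic anchors — cholesteryl-TEG ("sC"), double cholesteryl
("dC"), α-tocopherol ("sT") — inserts into the outer leaflet and enriches
one phase or the other depending on its anchor makeup. In an equatorial
confocal section a de-mixed ("Janus") GUV appears as a bright ring split
into two arcs; a lipid dye (TexasRed-DHPE) marks the Ld arc and a second
channel carries the construct label.

The measurement chain implemented here, for users analysing such two-channel
micrographs (or validating analysis code against synthetic ones):

1. **detect** each vesicle's membrane ring (sub-pixel circle fit),
2. **profile** the annulus into angular bins,
3. **segment** the bins into one Lo and one Ld arc from the lipid channel,
4. **quantify** background-corrected construct intensities I_Lo, I_Ld and
   the fractional intensity

   *f*<sub>p,Lo</sub> = I_Lo / (I_Lo + I_Ld),

   optionally after linear spectral-bleed-through correction,
5. convert to a partitioning free energy (natural log, kBT units)

   ΔG<sub>p,Lo</sub> = −ln( f<sub>p,Lo</sub> / f<sub>p,Ld</sub> ),

6. aggregate population statistics (box-scatter summaries, Mann–Whitney
   comparisons, radius-independence), test the **additive anchor rule**
   ΔG<sub>pred</sub> = Σ<sub>i</sub> ΔG<sub>i</sub> over the anchors, and
7. simulate the **fuel/antifuel responsive device**: a three-state cargo
   machine (sT-anchored → bridged → dC-anchored) driven by toehold-mediated
   strand displacement, with exponential relaxation between partitioning
   states.

Because no raw micrographs ship with the package, a first-class synthetic
generator renders two-channel Janus-GUV frames with known ground truth
(ring geometry, arc split, Boltzmann construct contrast e^(−ΔG), PSF blur,
bleed-through, shot noise), so every stage is validated against programmed
truth.

## Worked example

```python
from guvpart import (PopulationParams, ImagingParams, simulate_population,
                     fraction_to_dG)
from guvpart.pipeline import quantify_frame
import numpy as np

pop = PopulationParams(n_vesicles=1, dG_true=-0.8)       # dC-like construct
frames = simulate_population(pop, ImagingParams(frame_size=(192, 192)),
                             n_frames=20, seed=4)
f = [r.f_p_Lo for frame, _ in frames for r in quantify_frame(frame)[0]]
print(f"mean f_p_Lo = {np.mean(f):.3f}")
print(f"dG = {fraction_to_dG(float(np.mean(f))):+.2f} kBT")
```

prints

```
mean f_p_Lo = 0.697
dG = -0.83 kBT
```

i.e. the pipeline recovers the programmed free energy of −0.8 kBT (ground
truth f = 1/(1+e^(−0.8)) = 0.690) from 20 rendered images alone; the
0.03 kBT gap is the sampling error of a 20-vesicle population whose
per-vesicle free energies scatter by 0.15 kBT.

The numbered scripts under `analysis/` run the full study narrative —
simulate the four duplex populations, quantify them, compare populations,
test anchor additivity, and trace the responsive device — writing tables
and figures to `results/`. The `guvpart` console command exposes the same
stages (`simulate`, `quantify`, `analyze`, `dynamics`) for shell use.

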