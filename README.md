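# lv4dflow

Pathline-based flow-component analysis of left-ventricular (LV) 4D-flow
cardiovascular MRI, with the repeatability statistics used to characterise
scan-rescan and interval variability, and a synthetic velocity phantom with
exact ground truth for validating the whole chain.

## Who this is for

4D flow CMR yields a three-directional velocity field over the cardiac
cycle. A standard analysis seeds one *pathline* from the centre of every
voxel of the end-diastolic (ED) LV segmentation, integrates it forwards to
the next end systole (ES) and backwards to the preceding ES through the
temporally periodic velocity data, and classifies each pathline by where
its two ES endpoints lie relative to the ES cavity:

| component             | at preceding ES | at next ES |
|-----------------------|-----------------|------------|
| direct flow           | outside         | outside    |
| retained inflow       | outside         | inside     |
| delayed ejection flow | inside          | outside    |
| residual volume       | inside          | inside     |

Each component's volume is `count x voxel volume` (the four volumes
partition the EDV exactly) and its kinetic energy is

```
KE_c(t) = sum over pathlines p in c of  1/2 · rho_blood · V_p · |v_p(t)|²
```

with `rho_blood = 1060 kg/m³` and `V_p` one voxel volume; the ED value per
millilitre of component volume (µJ/ml) removes cavity-size dependence.
Around this core the package provides third-order polynomial background
phase-offset correction, nearest-neighbour ED-mask resampling onto the flow
grid, LV volumetric indices (EDV/ESV/SV/EF/CO), the inflow-vs-outflow QC
rule (exclusion above 10% relative difference), and the repeatability
layer: within-subject CoV by the root-mean-square method
(`SD = |x1-x2|/√2`), group CoV as the RMS of subject CoVs, Bland-Altman
bias and 95% limits of agreement, and Mann-Whitney comparison of CoV
distributions.

No in-vivo data ship with the package; the `phantom` module generates
temporally periodic, ventricle-like velocity datasets at 4D-flow
acquisition geometry (3×3×3 mm³ voxels, 52 ms frames, VENC 100 cm/s) in
which every pathline's true component label is known in closed form — the
test substrate for everything else.

## Worked example

```python
from lv4dflow import AnalysisConfig, analyze_dataset
from lv4dflow.phantom import PhantomSpec, realize

ds = realize(PhantomSpec())          # noise-free reference phantom
res = analyze_dataset(ds.field, ds.segmentation, ds.subject,
                      AnalysisConfig(background_correction=False))
for comp, pct in res.components.pct_edv.items():
    print(f"{comp:24s} {pct:5.1f} % EDV")
print("QC relative difference:", f"{100*res.components.qc.relative_difference:.1f}%")
```

prints

```
direct_flow               38.3 % EDV
retained_inflow           15.7 % EDV
delayed_ejection_flow     15.9 % EDV
residual_volume           30.2 % EDV
QC relative difference: 0.4%
```

— the pipeline recovers the phantom's programmed fractions
(38/16/16/30 % EDV, the healthy-cohort pattern) to a fraction of a
percentage point, and the transported inflow and outflow volumes agree far
inside the 10% exclusion threshold. The scripts in `examples/` walk through
each capability: phantom generation, the full analysis, background
correction, kinetic energy, and a simulated repeatability study.

A thin command-line interface mirrors the library
(`lv4dflow run / phantom / phantom-pair / repeatability`; see
`lv4dflow --help`).

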