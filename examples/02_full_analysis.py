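"""Run the complete flow-component analysis on one synthetic acquisition.

Pipeline: background phase-offset correction, ED-mask resampling, pathline
tracking of the whole end-diastolic volume over one cycle, four-component
classification with the inflow/outflow QC rule, and kinetic energy.
"""

from lv4dflow import AnalysisConfig, analyze_dataset
from lv4dflow.phantom import PhantomSpec, realize

dataset = realize(PhantomSpec(noise_sigma=2.0, seed=11))
result = analyze_dataset(
    dataset.field,
    dataset.segmentation,
    dataset.subject,
    AnalysisConfig(),
    static_mask=dataset.truth.static_mask,  # the phantom's known rest tissue
)

idx = result.indices
print(f"EDV {idx.edv:.1f} ml  ESV {idx.esv:.1f} ml  SV {idx.sv:.1f} ml  "
      f"EF {idx.ef:.1f}%  CO {idx.cardiac_output:.2f} L/min")
print(f"{'component':24s} {'%EDV':>6s} {'truth':>6s} {'KE@ED uJ/ml':>12s}")
for comp, pct in result.components.pct_edv.items():
    truth_pct = 100 * dataset.truth.fractions[comp]
    ke = result.components.ke_at_ed_uJ_per_ml[comp]
    print(f"{comp:24s} {pct:6.1f} {truth_pct:6.1f} {ke:12.2f}")
qc = result.components.qc
print(f"QC inflow {qc.inflow_ml:.1f} ml vs outflow {qc.outflow_ml:.1f} ml "
      f"({100 * qc.relative_difference:.1f}% difference, "
      f"{'pass' if qc.passed else 'FAIL'})")

# The measured %EDV columns should track the truth column to within the
# voxel discretisation and the injected noise; the QC difference stays well
# under the 10% exclusion threshold on a well-formed dataset.
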