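"""Component classification truth table, volume conservation, QC and KE."""

import numpy as np
import pytest

from lv4dflow import (
    ComponentLabel,
    VelocityField4D,
    classify,
    component_volumes,
    ke_at_ed_per_ml,
    kinetic_energy_curves,
    qc_inflow_outflow,
)
from lv4dflow.components import ALL_COMPONENTS
from lv4dflow.pathlines import PathlineBundle


def two_point_bundle(back_ends, fwd_ends, speeds_cm_s=None, volume_ml=0.027):
    """Minimal bundle with prescribed track endpoints (n pathlines)."""
    n = len(back_ends)
    seeds = np.tile([[7.5, 7.5, 7.5]], (n, 1))
    tf = np.array([0.0, 416.0])
    tb = np.array([0.0, -624.0])
    pf = np.stack([seeds, np.asarray(fwd_ends, dtype=float)], axis=1)
    pb = np.stack([seeds, np.asarray(back_ends, dtype=float)], axis=1)
    sp = np.zeros((n, 2, 3))
    if speeds_cm_s is not None:
        sp[..., 0] = np.asarray(speeds_cm_s)[:, None]
    return PathlineBundle(
        seeds, volume_ml, tf, pf, sp.copy(), np.zeros(n, bool),
        tb, pb, sp.copy(), np.zeros(n, bool),
    )


@pytest.fixture
def es_setup():
    """5x5x5 ES mask block inside a small field."""
    fld = VelocityField4D(np.zeros((10, 10, 10, 4, 3)), 3.0, 260.0)
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[2:7, 2:7, 2:7] = True
    inside = [9.0, 9.0, 9.0]
    outside = [27.0, 27.0, 27.0]
    return fld, mask, inside, outside


class TestClassification:
    def test_truth_table_enumerates_all_components(self, es_setup):
        fld, mask, inside, outside = es_setup
        bundle = two_point_bundle(
            back_ends=[outside, outside, inside, inside],
            fwd_ends=[outside, inside, outside, inside],
        )
        labels = classify(bundle, mask, fld)
        assert list(labels) == [
            ComponentLabel.DIRECT_FLOW.value,
            ComponentLabel.RETAINED_INFLOW.value,
            ComponentLabel.DELAYED_EJECTION_FLOW.value,
            ComponentLabel.RESIDUAL_VOLUME.value,
        ]

    def test_left_fov_counts_as_outside(self, es_setup):
        fld, mask, inside, _ = es_setup
        bundle = two_point_bundle([inside, inside], [inside, inside])
        bundle.left_fov_forward[0] = True
        labels = classify(bundle, mask, fld)
        assert labels[0] == ComponentLabel.DELAYED_EJECTION_FLOW.value
        assert labels[1] == ComponentLabel.RESIDUAL_VOLUME.value

    def test_partition_is_exhaustive_on_phantom(self, reference_analysis):
        labels = reference_analysis.components.labels
        counts = sum(
            int(np.sum(labels == c.value)) for c in ALL_COMPONENTS
        )
        assert counts == len(labels)


class TestVolumes:
    def test_cohort_pattern_ratios(self):
        labels = np.repeat(
            [c.value for c in ALL_COMPONENTS], [380, 160, 160, 300]
        )
        volumes, ratios = component_volumes(labels, 0.027, 1000 * 0.027)
        assert ratios["direct_flow"] == pytest.approx(38.0)
        assert ratios["retained_inflow"] == pytest.approx(16.0)
        assert ratios["delayed_ejection_flow"] == pytest.approx(16.0)
        assert ratios["residual_volume"] == pytest.approx(30.0)

    def test_single_label_gets_everything(self):
        labels = np.array([ComponentLabel.DIRECT_FLOW.value] * 10)
        volumes, ratios = component_volumes(labels, 0.027, 0.27)
        assert ratios["direct_flow"] == pytest.approx(100.0)
        assert ratios["residual_volume"] == 0.0

    def test_ratios_sum_to_100(self, reference_analysis):
        assert sum(reference_analysis.components.pct_edv.values()) == pytest.approx(
            100.0, abs=1e-9
        )
        assert sum(reference_analysis.components.volumes_ml.values()) == pytest.approx(
            reference_analysis.components.edv_ml, abs=1e-9
        )


class TestQC:
    def test_cohort_worked_example_passes(self):
        # inflow 82 ml vs outflow 81 ml -> 1.2% relative difference
        volumes = {
            "direct_flow": 60.0,
            "retained_inflow": 22.0,
            "delayed_ejection_flow": 21.0,
            "residual_volume": 40.0,
        }
        qc = qc_inflow_outflow(volumes)
        assert qc.inflow_ml == pytest.approx(82.0)
        assert qc.outflow_ml == pytest.approx(81.0)
        assert qc.relative_difference == pytest.approx(0.0123, abs=2e-4)
        assert qc.passed

    def test_equal_flows_pass_trivially(self):
        volumes = dict.fromkeys(
            [c.value for c in ALL_COMPONENTS], 10.0
        )
        qc = qc_inflow_outflow(volumes)
        assert qc.relative_difference == 0.0 and qc.passed

    def test_imbalanced_flows_fail(self):
        volumes = {
            "direct_flow": 30.0,
            "retained_inflow": 30.0,
            "delayed_ejection_flow": 10.0,
            "residual_volume": 30.0,
        }
        qc = qc_inflow_outflow(volumes)  # inflow 60 vs outflow 40
        assert qc.relative_difference == pytest.approx(0.4)
        assert not qc.passed

    def test_no_transport_fails_with_message(self):
        volumes = dict.fromkeys([c.value for c in ALL_COMPONENTS], 0.0)
        qc = qc_inflow_outflow(volumes)
        assert not qc.passed and "zero" in qc.message


class TestKineticEnergy:
    def test_single_pathline_closed_form(self, es_setup):
        fld, mask, inside, outside = es_setup
        # 27 mm^3 at 1 m/s and 1060 kg/m^3: KE = 14.31 uJ
        bundle = two_point_bundle([outside], [outside], speeds_cm_s=[100.0])
        labels = classify(bundle, mask, fld)
        t, curves = kinetic_energy_curves(bundle, labels, rho_blood=1060.0)
        i_ed = int(np.argmin(np.abs(t)))
        assert curves["direct_flow"][i_ed] == pytest.approx(14.31, abs=0.01)

    def test_zero_velocity_zero_ke(self, es_setup):
        fld, mask, _, outside = es_setup
        bundle = two_point_bundle([outside], [outside], speeds_cm_s=[0.0])
        labels = classify(bundle, mask, fld)
        _, curves = kinetic_energy_curves(bundle, labels)
        assert np.all(curves["direct_flow"] == 0.0)

    def test_doubling_speed_quadruples_ke(self, reference_analysis):
        # quadratic scaling of the KE functional on a fixed set of pathlines
        bundle = reference_analysis.pathlines
        labels = reference_analysis.components.labels
        _, base = kinetic_energy_curves(bundle, labels)
        bundle.vel_forward *= 2.0
        bundle.vel_backward *= 2.0
        try:
            _, doubled = kinetic_energy_curves(bundle, labels)
        finally:
            bundle.vel_forward /= 2.0
            bundle.vel_backward /= 2.0
        for comp in base:
            np.testing.assert_allclose(doubled[comp], 4.0 * base[comp], rtol=1e-12)

    def test_rho_must_be_positive(self, es_setup):
        fld, mask, _, outside = es_setup
        bundle = two_point_bundle([outside], [outside])
        labels = classify(bundle, mask, fld)
        with pytest.raises(ValueError):
            kinetic_energy_curves(bundle, labels, rho_blood=-1.0)

    def test_ke_per_ml_arithmetic_and_zero_volume_nan(self):
        curves = {"direct_flow": np.array([100.0, 50.0]),
                  "residual_volume": np.array([5.0, 1.0])}
        t = np.array([0.0, 52.0])
        ke_ed, per_ml = ke_at_ed_per_ml(
            curves, t, 0.0, {"direct_flow": 50.0, "residual_volume": 0.0}
        )
        assert per_ml["direct_flow"] == pytest.approx(2.0)
        assert np.isnan(per_ml["residual_volume"])

    def test_ke_invariant_under_rigid_translation(self, reference_spec):
        from dataclasses import replace

        from lv4dflow import AnalysisConfig, analyze_dataset
        from lv4dflow.phantom import realize

        ds0 = realize(reference_spec)
        ds1 = realize(replace(reference_spec, anatomy_offset=(3.0, -3.0, 3.0)))
        cfg = AnalysisConfig(background_correction=False)
        r0 = analyze_dataset(ds0.field, ds0.segmentation, ds0.subject, cfg)
        r1 = analyze_dataset(ds1.field, ds1.segmentation, ds1.subject, cfg)
        # whole-voxel translation moves field and masks together: identical KE
        for comp in r0.components.ke_at_ed_uJ:
            assert r1.components.ke_at_ed_uJ[comp] == pytest.approx(
                r0.components.ke_at_ed_uJ[comp], rel=1e-6
            )
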