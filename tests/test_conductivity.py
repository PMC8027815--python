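"""Baseline / intra-pulse conductivity, percent increase, curve assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tissuecond as tc
from tissuecond.errors import (
    AggregationError,
    DomainError,
    MeasurementError,
    ProtocolMismatchError,
)


def protocol(n=100, field_v_per_cm=2500.0):
    return tc.PulseProtocol(n, 100e-6, 1.0, tc.FieldStrength.from_v_per_cm(field_v_per_cm))


# -- baseline ----------------------------------------------------------------


def test_baseline_matches_hand_ohms_law(mold_sample, flat_sigma_model):
    """sigma0 = K * I / V on the raw plateau, here 0.200 S/m."""
    rec = tc.synth_diagnostic(flat_sigma_model, mold_sample, voltage_v=20.0)
    base = tc.baseline_conductivity(rec, mold_sample)
    k = tc.cell_constant(mold_sample)
    i_hand = 0.2 * 20.0 * mold_sample.area_m2 / mold_sample.thickness_m
    assert base.sigma_s_per_m == pytest.approx(k * i_hand / 20.0, rel=1e-9)
    assert base.sigma_s_per_m == pytest.approx(0.200, rel=1e-9)
    assert base.source == "baseline"
    # the diagnostic field, not an IRE field (~36 V/cm for 20 V / 0.56 cm)
    assert base.field.v_per_cm == pytest.approx(35.71, abs=0.01)


def test_baseline_identity_point(mold_sample):
    """A sample with sigma = 1 S/m has R = K numerically, so sigma0 = 1."""
    model = tc.DynamicConductivityModel(1.0, 1.0)
    rec = tc.synth_diagnostic(model, mold_sample)
    assert tc.baseline_conductivity(rec, mold_sample).sigma_s_per_m == pytest.approx(
        1.0, rel=1e-12
    )


def test_baseline_recovers_generator_sigma(mold_sample):
    """Noiseless round trip at the ground-truth value mirroring 0.242 S/m."""
    model = tc.DynamicConductivityModel(0.242, 0.242)
    rec = tc.synth_diagnostic(model, mold_sample)
    assert tc.baseline_conductivity(rec, mold_sample).sigma_s_per_m == pytest.approx(
        0.242, rel=1e-12
    )


def test_baseline_rejects_multi_pulse(mold_sample, sigmoid_model):
    rec = tc.synth_pulse_train(sigmoid_model, mold_sample, protocol(n=3, field_v_per_cm=36))
    with pytest.raises(ProtocolMismatchError):
        tc.baseline_conductivity(rec, mold_sample)


def test_baseline_rejects_nonpositive_current(mold_sample, square_recording):
    from dataclasses import replace

    rec = replace(square_recording, current_a=-square_recording.current_a)
    with pytest.raises(MeasurementError):
        tc.baseline_conductivity(rec, mold_sample)


# -- intra-pulse -------------------------------------------------------------


def test_intra_pulse_flat_sigma(mold_sample):
    model = tc.DynamicConductivityModel(0.3, 0.3)
    rec = tc.synth_pulse_train(model, mold_sample, protocol(n=100))
    per_pulse, summary = tc.intra_pulse_conductivity(rec, mold_sample, protocol(n=100))
    assert len(per_pulse) == 100
    for m in per_pulse:
        assert m.sigma_s_per_m == pytest.approx(0.300, rel=1e-12)
        assert m.field.v_per_cm == 2500.0
    assert summary == pytest.approx(0.300, rel=1e-12)


def test_intra_pulse_single_pulse_summary(mold_sample, sigmoid_model):
    rec = tc.synth_pulse_train(sigmoid_model, mold_sample, protocol(n=1))
    per_pulse, summary = tc.intra_pulse_conductivity(rec, mold_sample, protocol(n=1))
    assert summary == per_pulse[0].sigma_s_per_m


def test_intra_pulse_noise_within_one_percent(mold_sample, sigmoid_model):
    prot = protocol(n=100)
    rec = tc.synth_pulse_train(
        sigmoid_model, mold_sample, prot, tc.NoiseSpec(relative_gaussian_sd=0.01, seed=11)
    )
    _, summary = tc.intra_pulse_conductivity(rec, mold_sample, prot)
    truth = sigmoid_model.sigma_at(prot.nominal_field)
    assert summary == pytest.approx(truth, rel=0.01)


def test_intra_pulse_count_mismatch_policies(mold_sample, sigmoid_model):
    rec = tc.synth_pulse_train(sigmoid_model, mold_sample, protocol(n=10))
    with pytest.raises(ProtocolMismatchError):
        tc.intra_pulse_conductivity(rec, mold_sample, protocol(n=100))
    with pytest.warns(UserWarning, match="detected 10"):
        _, summary = tc.intra_pulse_conductivity(
            rec, mold_sample, protocol(n=100), count_policy="warn"
        )
    assert summary > 0


# -- percent increase / adjusted sigma ---------------------------------------


@pytest.mark.parametrize(
    "sigma_e, sigma_0, expected",
    [
        (0.25, 0.25, 0.0),
        (0.288, 0.231, 24.675),  # ratio of printed group means
        (0.1, 0.2, -50.0),
    ],
)
def test_percent_increase_values(sigma_e, sigma_0, expected):
    assert tc.percent_increase(sigma_e, sigma_0) == pytest.approx(expected, abs=1e-3)


def test_percent_increase_rejects_nonpositive_baseline():
    with pytest.raises(DomainError):
        tc.percent_increase(0.3, 0.0)


@pytest.mark.parametrize(
    "baseline, pct, expected",
    [(0.242, 0.0, 0.242), (0.242, 36.78, 0.3310), (1.0, 100.0, 2.0)],
)
def test_adjusted_conductivity_values(baseline, pct, expected):
    assert tc.adjusted_conductivity(baseline, pct) == pytest.approx(expected, abs=5e-4)


@given(
    sigma=st.floats(min_value=1e-3, max_value=10),
    sigma0=st.floats(min_value=1e-3, max_value=10),
)
def test_adjusted_inverts_percent_increase(sigma, sigma0):
    pct = tc.percent_increase(sigma, sigma0)
    assert tc.adjusted_conductivity(sigma0, pct) == pytest.approx(sigma, rel=1e-12)


# -- curve assembly ----------------------------------------------------------


def meas(sample_id, sigma, field_v_per_cm, source, pulse_index=None):
    return tc.ConductivityMeasurement(
        sample_id, sigma, tc.FieldStrength.from_v_per_cm(field_v_per_cm), source, pulse_index
    )


def test_curve_single_sample_degenerate():
    curve = tc.assemble_curve(
        [meas("a", 0.2, 36, "baseline"), meas("a", 0.3, 1000, "intra_pulse", 0)], "g"
    )
    row = curve.table.iloc[0]
    assert row["n"] == 1
    assert row["sigma_sd"] == 0.0
    assert bool(row["degenerate"])
    assert row["pct_increase_mean"] == pytest.approx(50.0)


def test_curve_paper_design_has_seven_points(mold_sample, sigmoid_model, runs_factory):
    records = tc.synth_cohort([("g", sigmoid_model, 1)])
    res = tc.PulsedFieldStudy(runs_factory(records), group="g").fit()
    assert len(res.curve.table) == 7
    assert list(res.curve.table["field_V_per_cm"]) == [500, 750, 1000, 1500, 2000, 2500, 3000]
    # conservation of n: each sample contributes one field
    assert int(res.curve.table["n"].sum()) == 7
    # monotone response to a sigmoid ground truth
    assert np.all(np.diff(res.curve.table["sigma_mean_S_per_m"]) >= -1e-12)


def test_curve_identical_samples_zero_sd():
    ms = []
    for sid in ("a", "b"):
        ms.append(meas(sid, 0.2, 36, "baseline"))
        ms.append(meas(sid, 0.3, 1000, "intra_pulse", 0))
    curve = tc.assemble_curve(ms, "g")
    assert curve.table["sigma_sd"].iloc[0] == 0.0
    assert curve.table["n"].iloc[0] == 2


def test_curve_requires_baseline_pairing():
    ms = [meas("a", 0.2, 36, "baseline"), meas("b", 0.3, 1000, "intra_pulse", 0)]
    with pytest.raises(AggregationError):
        tc.assemble_curve(ms, "g")


def test_curve_adjusted_equals_baseline_at_zero_increase():
    ms = [meas("a", 0.25, 36, "baseline"), meas("a", 0.25, 500, "intra_pulse", 0)]
    curve = tc.assemble_curve(ms, "g")
    assert curve.table["pct_increase_mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert curve.table["sigma_adjusted"].iloc[0] == pytest.approx(
        curve.baseline_mean_s_per_m, rel=1e-12
    )


def test_percent_increase_modes_agree_for_identical_samples():
    """With identical baselines the per-sample and ratio-of-means readings coincide."""
    ms = []
    for sid in ("a", "b"):
        ms.append(meas(sid, 0.2, 36, "baseline"))
        ms.append(meas(sid, 0.31, 2500, "intra_pulse", 0))
    per_sample = tc.assemble_curve(ms, "g", "per_sample")
    ratio = tc.assemble_curve(ms, "g", "ratio_of_means")
    assert per_sample.table["pct_increase_mean"].iloc[0] == pytest.approx(
        ratio.table["pct_increase_mean"].iloc[0], rel=1e-12
    )


# -- Joule-heating QC --------------------------------------------------------


def test_qc_flat_trace_passes():
    trace = tc.TemperatureTrace(np.arange(5) * 0.5, np.full(5, 22.0))
    qc = tc.joule_heating_qc(trace, max_rise_c=2.0)
    assert qc.passed and qc.max_rise_c == 0.0


def test_qc_adiabatic_high_field_fails(mold_sample):
    thermal = tc.ThermalModel(density_kg_per_m3=1000, specific_heat_j_per_kg_k=3600)
    prot = tc.PulseProtocol(100, 100e-6, 1.0, tc.FieldStrength.from_v_per_cm(2500))
    trace = tc.synth_temperature(thermal, 0.2, prot.nominal_field, prot)
    qc = tc.joule_heating_qc(trace, max_rise_c=10.0)
    assert not qc.passed
    assert qc.max_rise_c == pytest.approx(34.72, abs=0.01)


def test_qc_boundary_is_inclusive():
    trace = tc.TemperatureTrace(np.arange(3) * 0.5, np.array([20.0, 21.0, 23.0]))
    assert tc.joule_heating_qc(trace, max_rise_c=3.0).passed


def test_temperature_csv_round_trip(tmp_path):
    trace = tc.TemperatureTrace(np.arange(4) * 0.5, np.array([22.0, 22.3, 22.7, 23.0]))
    path = tmp_path / "temp.csv"
    trace.to_csv(path)
    back = tc.TemperatureTrace.from_csv(path)
    np.testing.assert_allclose(back.temp_c, trace.temp_c, rtol=1e-12)


# -- model / results object --------------------------------------------------


def test_results_summary_and_tables(mold_sample, sigmoid_model, runs_factory):
    records = tc.synth_cohort([("Panc01 tumor", sigmoid_model, 1)])
    res = tc.PulsedFieldStudy(runs_factory(records), group="Panc01 tumor").fit()
    text = res.summary()
    assert "Panc01 tumor" in text
    assert "baseline sigma0" in text
    assert len(res.baseline_table) == 7
    assert len(res.pulse_table) == 700
    assert res.sigma_at(2500.0) == pytest.approx(
        sigmoid_model.sigma_at(tc.FieldStrength.from_v_per_cm(2500)), rel=1e-9
    )


def test_curve_csv_round_trip(tmp_path, sigmoid_model, runs_factory):
    records = tc.synth_cohort([("g", sigmoid_model, 1)])
    res = tc.PulsedFieldStudy(runs_factory(records), group="g").fit()
    path = tmp_path / "curve.csv"
    res.curve.to_csv(path)
    import pandas as pd

    back = pd.read_csv(path)
    np.testing.assert_allclose(
        back["sigma_mean_S_per_m"], res.curve.table["sigma_mean_S_per_m"], rtol=1e-12
    )
    assert set(back["group"]) == {"g"}
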