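"""Conditioning (DC removal, Butterworth) and pulse segmentation."""

import numpy as np
import pytest

import tissuecond as tc
from tissuecond.errors import (
    ConditioningError,
    DomainError,
    FilterDesignError,
    InvalidRecordingError,
    ParseError,
    SegmentationError,
)
from tissuecond.signal import characterize_segments, pulse_table


def shifted(rec, dv, da):
    from dataclasses import replace

    return replace(rec, voltage_v=rec.voltage_v + dv, current_a=rec.current_a + da)


# -- recording invariants ----------------------------------------------------


def test_recording_rejects_non_uniform_time():
    t = np.array([0.0, 1e-6, 3e-6, 4e-6])
    with pytest.raises(InvalidRecordingError):
        tc.PulseRecording(t, np.zeros(4), np.zeros(4), sampling_rate_hz=1e6)


def test_recording_rejects_length_mismatch():
    with pytest.raises(InvalidRecordingError):
        tc.PulseRecording(np.arange(3) / 1e6, np.zeros(3), np.zeros(2), sampling_rate_hz=1e6)


def test_recording_csv_round_trip(tmp_path, square_recording):
    path = tmp_path / "rec.csv"
    square_recording.to_csv(path)
    back = tc.PulseRecording.from_csv(path)
    np.testing.assert_allclose(back.voltage_v, square_recording.voltage_v, rtol=1e-12)
    np.testing.assert_allclose(back.current_a, square_recording.current_a, rtol=1e-12)
    assert back.sampling_rate_hz == pytest.approx(1e6, rel=1e-6)


def test_csv_parse_error_names_offender(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("time_s,voltage_V,current_A\n0.0,1.0,0.1\n1e-6,oops,0.1\n")
    with pytest.raises(ParseError, match="voltage_V.*row 1"):
        tc.PulseRecording.from_csv(path)
    path.write_text("time_s,voltage_V\n0.0,1.0\n")
    with pytest.raises(ParseError, match="current_A"):
        tc.PulseRecording.from_csv(path)


# -- DC-offset removal -------------------------------------------------------


def test_constant_offset_removed_exactly(square_recording):
    rec = shifted(square_recording, 0.5, 1e-3)
    clean = tc.remove_dc_offset(rec, (0, 300))
    np.testing.assert_allclose(clean.voltage_v, square_recording.voltage_v, atol=1e-12)
    np.testing.assert_allclose(clean.current_a, square_recording.current_a, atol=1e-15)


def test_zero_offset_is_identity(square_recording):
    clean = tc.remove_dc_offset(square_recording, (0, 300))
    np.testing.assert_array_equal(clean.voltage_v, square_recording.voltage_v)


def test_quiet_window_mean_is_zero_after_removal(square_recording):
    clean = tc.remove_dc_offset(shifted(square_recording, 0.3, 2e-3), (0, 300))
    assert abs(np.mean(clean.voltage_v[:300])) < 1e-12
    assert abs(np.mean(clean.current_a[:300])) < 1e-15


def test_quiet_window_overlapping_pulse_rejected(square_recording):
    with pytest.raises(ConditioningError):
        tc.remove_dc_offset(square_recording, (350, 450))


def test_offsets_do_not_bias_resistance(mold_sample, flat_sigma_model):
    """Offset-corrupted synthetic train recovers the ground-truth resistance."""
    rec = tc.synth_diagnostic(
        flat_sigma_model,
        mold_sample,
        noise=tc.NoiseSpec(dc_offset_v=0.5, dc_offset_a=0.001),
    )
    segs = tc.detect_pulses(rec)
    clean = tc.remove_dc_offset(rec, (0, segs[0].start - 4))
    seg = characterize_segments(clean, tc.detect_pulses(clean))[0]
    r_true = mold_sample.thickness_m / (0.2 * mold_sample.area_m2)
    assert seg.resistance_ohm == pytest.approx(r_true, rel=1e-9)


# -- Butterworth smoothing ---------------------------------------------------


def test_smooth_preserves_constant(square_recording):
    from dataclasses import replace

    const = replace(
        square_recording,
        voltage_v=np.full(len(square_recording), 2.0),
        current_a=np.full(len(square_recording), 0.1),
    )
    out = tc.smooth(const, cutoff_hz=1e4)
    np.testing.assert_allclose(out.voltage_v, 2.0, rtol=1e-9)


def test_smooth_preserves_square_plateau():
    # cutoff = 50 / pulse_width keeps the flat top within 0.1%
    fs, width = 1e7, 100e-6
    n = 10_000
    v = np.zeros(n)
    v[4000 : 4000 + int(width * fs)] = 1.0
    rec = tc.PulseRecording(np.arange(n) / fs, v, v * 1e-3, sampling_rate_hz=fs)
    out = tc.smooth(rec, cutoff_hz=50 / width)
    seg = tc.detect_pulses(out)[0]
    v_plat, _ = tc.plateau_stats(seg, out, central_fraction=0.5)
    assert v_plat == pytest.approx(1.0, rel=1e-3)


def test_smooth_reduces_noise_variance(square_recording):
    from dataclasses import replace

    rng = np.random.default_rng(0)
    noisy = replace(square_recording, voltage_v=rng.standard_normal(len(square_recording)))
    out = tc.smooth(noisy, cutoff_hz=noisy.sampling_rate_hz / 100)
    assert np.var(out.voltage_v) < np.var(noisy.voltage_v)


def test_smooth_rejects_cutoff_at_nyquist(square_recording):
    with pytest.raises(FilterDesignError):
        tc.smooth(square_recording, cutoff_hz=square_recording.sampling_rate_hz / 2)


# -- pulse detection ---------------------------------------------------------


def test_detect_100_pulses_noiseless(mold_sample, sigmoid_model):
    protocol = tc.PulseProtocol(100, 100e-6, 1.0, tc.FieldStrength.from_v_per_cm(1500))
    rec = tc.synth_pulse_train(sigmoid_model, mold_sample, protocol)
    assert len(tc.detect_pulses(rec)) == 100


def test_detect_flat_zero_trace():
    rec = tc.PulseRecording(
        np.arange(100) / 1e6, np.zeros(100), np.zeros(100), sampling_rate_hz=1e6
    )
    assert tc.detect_pulses(rec) == []


def test_detect_single_pulse_width(square_recording):
    segs = tc.detect_pulses(square_recording)
    assert len(segs) == 1
    assert abs((segs[0].end - segs[0].start) - 100) <= 2


def test_detect_threshold_domain(square_recording):
    with pytest.raises(DomainError):
        tc.detect_pulses(square_recording, threshold_fraction=1.5)


def test_detect_discards_narrow_glitches(square_recording):
    from dataclasses import replace

    v = square_recording.voltage_v.copy()
    v[900] = 1.0  # single-sample glitch
    segs = tc.detect_pulses(replace(square_recording, voltage_v=v), min_width_samples=5)
    assert len(segs) == 1


# -- plateau estimation ------------------------------------------------------


def test_plateau_of_constant_pulse(square_recording):
    seg = tc.detect_pulses(square_recording)[0]
    v, i = tc.plateau_stats(seg, square_recording)
    assert v == 1.0
    assert i == 5e-3


def test_plateau_excludes_edge_ramps():
    fs = 1e6
    n = 600
    v = np.zeros(n)
    # 100-sample pulse with first/last 10 samples ramped
    v[200:210] = np.linspace(0.6, 1.0, 10)
    v[210:290] = 1.0
    v[290:300] = np.linspace(1.0, 0.6, 10)
    rec = tc.PulseRecording(np.arange(n) / fs, v, v * 1e-3, sampling_rate_hz=fs)
    seg = tc.detect_pulses(rec)[0]
    vp, _ = tc.plateau_stats(seg, rec, central_fraction=0.5)
    assert vp == 1.0


def test_plateau_robust_to_spike(square_recording):
    from dataclasses import replace

    v = square_recording.voltage_v.copy()
    v[450] = 1.4  # corrupted sample inside the plateau
    rec = replace(square_recording, voltage_v=v)
    seg = tc.detect_pulses(rec)[0]
    vp, _ = tc.plateau_stats(seg, rec)
    assert vp == 1.0


def test_plateau_empty_window_rejected(square_recording):
    seg = tc.PulseSegment(pulse_index=0, start=400, end=410)
    with pytest.raises(SegmentationError):
        tc.plateau_stats(seg, square_recording, central_fraction=0.01)


def test_pulse_table_schema(square_recording):
    segs = characterize_segments(square_recording, tc.detect_pulses(square_recording))
    table = pulse_table(segs)
    assert list(table.columns) == ["pulse_index", "v_plateau_V", "i_plateau_A", "resistance_ohm"]
    assert table["resistance_ohm"].iloc[0] == pytest.approx(200.0)


def test_conditioning_neutrality(mold_sample, sigmoid_model):
    """Full conditioning on noiseless input matches raw Ohm's-law values."""
    protocol = tc.PulseProtocol(10, 100e-6, 1.0, tc.FieldStrength.from_v_per_cm(1000))
    rec = tc.synth_pulse_train(sigmoid_model, mold_sample, protocol)
    raw_segs = characterize_segments(rec, tc.detect_pulses(rec))
    cond = tc.smooth(tc.remove_dc_offset(rec, (0, raw_segs[0].start - 4)), cutoff_hz=5e4)
    cond_segs = characterize_segments(cond, tc.detect_pulses(cond))
    for raw, seg in zip(raw_segs, cond_segs):
        assert seg.resistance_ohm == pytest.approx(raw.resistance_ohm, rel=1e-9)
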