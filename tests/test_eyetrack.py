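import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biprkit import eyetrack as et
from biprkit.eyetrack import (
    BlinkEvent,
    EmptyInputError,
    FilterSpec,
    NonMonotonicError,
    PupilTrace,
    StageError,
    TraceTooShortError,
    UnsupportedRateError,
    bandpass_filter,
    detect_blinks,
    downsample_100hz,
    interpolate_blinks,
    parse_asc_samples,
    resample_to_1khz,
)


# ---------------------------------------------------------------------------
# parsing


def _sample_text(n, missing_at=(), dt=1):
    lines = []
    for i in range(n):
        p = 0.0 if i in missing_at else 1500.0 + i
        lines.append(f"{1000 + i * dt}\t640.0\t360.0\t{p:.1f}")
    return "\n".join(lines)


def test_parse_ignores_event_lines():
    text = "\n".join([
        "MSG 999 RECORD_START",
        "1000\t640.0\t360.0\t1500.0",
        "EBLINK R 1001 1002 2",
        "1001\t640.0\t360.0\t1501.0",
        "SSACC R 1001",
        "1002\t640.0\t360.0\t1502.0",
    ])
    trace = parse_asc_samples(text)
    assert trace.n == 3
    assert not trace.missing.any()


def test_parse_empty_input_error():
    with pytest.raises(EmptyInputError):
        parse_asc_samples("MSG 1 hello\nEND\n")


def test_parse_ten_line_fixture_with_three_missing():
    trace = parse_asc_samples(_sample_text(10, missing_at=(2, 5, 6)))
    assert trace.n == 10
    assert trace.missing.sum() == 3
    assert (trace.pupil[trace.missing] == 0.0).all()


def test_parse_non_monotonic_names_line():
    text = "1000\t0\t0\t1.0\n1001\t0\t0\t1.0\n1001\t0\t0\t1.0\n"
    with pytest.raises(NonMonotonicError, match="line 3"):
        parse_asc_samples(text)


def test_parse_unparseable_pupil_is_missing():
    trace = parse_asc_samples("1000\t0\t0\t1500.0\n1001\t0\t0\t.\n1002\t0\t0\t1500.0")
    assert trace.missing.tolist() == [False, True, False]


def test_parse_500hz_rate_detected():
    trace = parse_asc_samples(_sample_text(10, dt=2))
    assert trace.sampling_hz == 500.0


def test_roundtrip_write_parse(make_trace):
    import io

    trace = make_trace(1500.0 + np.arange(20.0), missing=[i in (4, 5) for i in range(20)])
    buf = io.StringIO()
    et.write_asc_samples(trace, buf)
    back = parse_asc_samples(buf.getvalue())
    assert back.n == trace.n
    assert (back.missing == trace.missing).all()
    ok = ~trace.missing
    np.testing.assert_allclose(back.pupil[ok], trace.pupil[ok], atol=0.05)
    assert (back.pupil[back.missing] == 0.0).all()


# ---------------------------------------------------------------------------
# resampling


def test_resample_1khz_identity(make_trace):
    trace = make_trace(np.arange(100.0))
    out = resample_to_1khz(trace)
    assert out.sampling_hz == 1000.0
    assert out.stage == "upsampled"
    np.testing.assert_array_equal(out.pupil, trace.pupil)


def test_resample_500hz_linear_midpoints(make_trace):
    ramp = np.arange(0.0, 20.0, 2.0)  # 10 samples at 500 Hz
    out = resample_to_1khz(make_trace(ramp, fs=500.0))
    assert out.n == 2 * 10 - 1
    np.testing.assert_allclose(out.pupil, np.arange(0.0, 19.0))


def test_resample_mask_conservative(make_trace):
    missing = [False, True, False, False]
    out = resample_to_1khz(make_trace([1.0, 0.0, 3.0, 4.0], missing, fs=500.0))
    # midpoints flanking the missing source sample are missing too
    assert out.missing.tolist() == [False, True, True, True, False, False, False]
    assert (out.pupil[out.missing] == 0.0).all()


def test_resample_rejects_wrong_stage(make_trace):
    trace = make_trace(np.ones(10), stage="interpolated")
    with pytest.raises(StageError):
        resample_to_1khz(trace)


# ---------------------------------------------------------------------------
# blink / closure detection


def _upsampled(make_trace, n, gaps):
    missing = np.zeros(n, dtype=bool)
    for start, length in gaps:
        missing[start:start + length] = True
    pupil = np.where(missing, 0.0, 1500.0)
    return make_trace(pupil, missing, stage="upsampled")


def test_single_100ms_gap_is_blink(make_trace):
    blinks, closures = detect_blinks(_upsampled(make_trace, 5000, [(1000, 100)]))
    assert len(blinks) == 1 and len(closures) == 0
    assert blinks[0].onset_ms == 1000.0
    assert blinks[0].duration_ms == 100.0


def test_short_and_long_gaps_are_closures(make_trace):
    blinks, closures = detect_blinks(
        _upsampled(make_trace, 5000, [(100, 30), (2000, 800)]))
    assert len(blinks) == 0 and len(closures) == 2
    assert [c.duration_ms for c in closures] == [30.0, 800.0]


def test_boundary_durations():
    # 40 and 400 ms are blinks (inclusive); 39 and 401 are closures
    assert BlinkEvent(0.0, 40.0) and BlinkEvent(0.0, 400.0)
    with pytest.raises(et.EyetrackError):
        BlinkEvent(0.0, 401.0)
    with pytest.raises(et.EyetrackError):
        et.ClosureEvent(0.0, 400.0)


def test_clean_trace_empty_lists(make_trace):
    blinks, closures = detect_blinks(_upsampled(make_trace, 1000, []))
    assert blinks == [] and closures == []


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 600)), max_size=5))
def test_detection_is_exhaustive_and_exclusive(gaps):
    """#blinks + #closures equals the number of maximal lost intervals."""
    n = 5000
    missing = np.zeros(n, dtype=bool)
    pos = 0
    for skip, length in gaps:
        pos += skip + 700  # keep intervals separated
        if pos + length >= n:
            break
        missing[pos:pos + length] = True
        pos += length
    trace = PupilTrace(0.0, 1000.0, np.where(missing, 0.0, 1.0), missing,
                       stage="upsampled")
    blinks, closures = detect_blinks(trace)
    padded = np.concatenate([[False], missing, [False]]).astype(np.int8)
    n_runs = int((np.diff(padded) == 1).sum())
    assert len(blinks) + len(closures) == n_runs


# ---------------------------------------------------------------------------
# interpolation


def test_interpolate_constant_signal_exact(make_trace):
    n = 2000
    missing = np.zeros(n, bool)
    missing[900:1100] = True
    trace = make_trace(np.where(missing, 0.0, 42.0), missing, stage="upsampled")
    blinks, _ = detect_blinks(trace)
    out = interpolate_blinks(trace, blinks)
    np.testing.assert_allclose(out.pupil, 42.0, atol=1e-8)
    assert not out.missing.any()
    assert out.stage == "interpolated"


def test_interpolate_reproduces_cubic(make_trace):
    n = 2000
    t = np.arange(n) / 1000.0
    cubic = 3.0 + 2.0 * t - 5.0 * t ** 2 + 1.5 * t ** 3
    missing = np.zeros(n, bool)
    missing[1000:1200] = True
    pupil = np.where(missing, 0.0, cubic)
    trace = make_trace(pupil, missing, stage="upsampled")
    blinks, _ = detect_blinks(trace)
    out = interpolate_blinks(trace, blinks)
    np.testing.assert_allclose(out.pupil[1000:1200], cubic[1000:1200], atol=1e-6)


def test_interpolate_clears_blink_mask_only(make_trace):
    n = 5000
    missing = np.zeros(n, bool)
    missing[1000:1200] = True   # 200 ms blink
    missing[3000:3800] = True   # 800 ms closure
    trace = make_trace(np.where(missing, 0.0, 10.0), missing, stage="upsampled")
    blinks, closures = detect_blinks(trace)
    out = interpolate_blinks(trace, blinks)
    assert not out.missing[1000:1200].any()
    assert out.missing[3000:3800].all()


def test_interpolate_edge_blink_falls_back_with_warning(make_trace):
    n = 1000
    missing = np.zeros(n, bool)
    missing[:100] = True
    trace = make_trace(np.where(missing, 0.0, 7.0), missing, stage="upsampled")
    blinks, _ = detect_blinks(trace)
    with pytest.warns(UserWarning):
        out = interpolate_blinks(trace, blinks)
    assert not out.missing.any()
    np.testing.assert_allclose(out.pupil[:100], 7.0, atol=1e-6)


# ---------------------------------------------------------------------------
# filtering


FS = 1000.0
N_FILT = 200_000  # 200 s: longer than the 150001-tap trend filter


def _interp_trace(values):
    return PupilTrace(0.0, FS, values, np.zeros(values.size, bool),
                      stage="interpolated")


def _amp(x):
    core = x[x.size // 4: -x.size // 4]
    return np.sqrt(2.0) * core.std()


def test_filter_dc_removed():
    out = bandpass_filter(_interp_trace(np.full(N_FILT, 1000.0)))
    assert np.abs(out.pupil).max() < 1e-3 * 1000.0


def test_filter_passband_1hz():
    t = np.arange(N_FILT) / FS
    out = bandpass_filter(_interp_trace(np.sin(2 * np.pi * 1.0 * t)))
    assert abs(_amp(out.pupil) - 1.0) < 0.05


def test_filter_stopband_10hz():
    t = np.arange(N_FILT) / FS
    out = bandpass_filter(_interp_trace(np.sin(2 * np.pi * 10.0 * t)))
    atten_db = 20 * np.log10(1.0 / max(_amp(out.pupil), 1e-12))
    assert atten_db >= 20.0


def test_filter_zero_phase_symmetry():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(N_FILT)
    fwd = bandpass_filter(_interp_trace(x)).pupil
    rev = bandpass_filter(_interp_trace(x[::-1])).pupil[::-1]
    assert np.abs(fwd - rev).max() < 1e-8


def test_filter_mean_near_zero():
    rng = np.random.default_rng(1)
    x = 1500.0 + 50.0 * rng.standard_normal(N_FILT)
    out = bandpass_filter(_interp_trace(x))
    assert abs(out.pupil.mean()) < 0.5


def test_filter_too_short_error_states_minimum():
    with pytest.raises(TraceTooShortError, match="150001"):
        bandpass_filter(_interp_trace(np.zeros(10_000)))


def test_filter_rejects_wrong_stage(make_trace):
    with pytest.raises(StageError):
        bandpass_filter(make_trace(np.zeros(N_FILT), stage="raw"))


# ---------------------------------------------------------------------------
# downsampling


def test_downsample_length_and_rate(make_trace):
    trace = make_trace(np.zeros(60_000), stage="filtered")
    out = downsample_100hz(trace)
    assert out.n == 6000
    assert out.sampling_hz == 100.0
    assert out.stage == "downsampled"


def test_downsample_mask_or(make_trace):
    missing = np.zeros(100, bool)
    missing[13] = True  # second block contains one missing sample
    out = downsample_100hz(make_trace(np.zeros(100), missing, stage="filtered"))
    assert out.missing.tolist() == [False, True] + [False] * 8


def test_downsample_preserves_1hz_sine():
    t = np.arange(100_000) / 1000.0
    x = np.sin(2 * np.pi * t)
    trace = PupilTrace(0.0, 1000.0, x, np.zeros(x.size, bool), stage="filtered")
    out = downsample_100hz(trace)
    assert abs(_amp(out.pupil) - 1.0) < 0.01


def test_downsample_rejects_wrong_rate(make_trace):
    with pytest.raises(UnsupportedRateError):
        downsample_100hz(make_trace(np.zeros(100), fs=500.0, stage="filtered"))


# ---------------------------------------------------------------------------
# pipeline order / ground-truth agreement


def test_detected_events_match_ground_truth(standard_run):
    trace, truth = standard_run
    up = resample_to_1khz(trace)
    blinks, closures = detect_blinks(up)
    assert [(b.onset_ms, b.duration_ms) for b in blinks] == \
        [(b.onset_ms, b.duration_ms) for b in truth.blinks]
    assert [(c.onset_ms, c.duration_ms) for c in closures] == \
        [(c.onset_ms, c.duration_ms) for c in truth.closures]


def test_stage_order_enforced(make_trace):
    raw = make_trace(np.ones(1000))
    with pytest.raises(StageError):
        detect_blinks(raw)  # needs upsampled
    with pytest.raises(StageError):
        downsample_100hz(make_trace(np.ones(1000), stage="interpolated"))
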