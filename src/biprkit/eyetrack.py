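"""Raw eye-tracking ingestion and the pupil preprocessing chain.

The pipeline is a fixed sequence of stages, each of which checks the
stage tag of its input and produces the next tag::

    parse -> resample(1 kHz) -> detect blinks -> interpolate -> filter -> downsample(100 Hz)

Pupil-loss intervals of 40-400 ms are blinks; anything else is an eye
closure.  Blinks are cubic-interpolated and become valid data; closures
are only ever bridged transiently for filtering and stay missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, List, Tuple, Union

import numpy as np
from scipy.signal import fftconvolve, firwin

STAGES = ("raw", "upsampled", "interpolated", "filtered", "downsampled")

BLINK_MIN_MS = 40.0
BLINK_MAX_MS = 400.0


class EyetrackError(ValueError):
    """Base class for preprocessing errors."""


class EmptyInputError(EyetrackError):
    pass


class NonMonotonicError(EyetrackError):
    pass


class StageError(EyetrackError):
    pass


class UnsupportedRateError(EyetrackError):
    pass


class TraceTooShortError(EyetrackError):
    pass


@dataclass
class PupilTrace:
    """Uniformly sampled pupil time series with a missingness mask.

    Parameters
    ----------
    start_time_ms : float
        Timestamp of the first sample.
    sampling_hz : float
        Sampling rate; one of 500, 1000 (raw/intermediate) or 100 (final).
    pupil : ndarray of float
        Pupil size in arbitrary units.  In raw/upsampled stages the value
        is exactly 0.0 wherever ``missing`` is True.
    missing : ndarray of bool
        True where the tracker did not detect the pupil.
    stage : str
        One of ``raw, upsampled, interpolated, filtered, downsampled``.
    """

    start_time_ms: float
    sampling_hz: float
    pupil: np.ndarray
    missing: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.pupil.shape != self.missing.shape or self.pupil.ndim != 1:
            raise EyetrackError("pupil and missing must be equal-length 1-D arrays")
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if self.sampling_hz not in (100.0, 500.0, 1000.0):
            raise UnsupportedRateError(
                f"sampling rate {self.sampling_hz} Hz not supported (500/1000/100)"
            )

    @property
    def n(self) -> int:
        return self.pupil.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_hz

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_hz

    def times_ms(self) -> np.ndarray:
        return self.start_time_ms + np.arange(self.n) * self.dt_ms

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"expected trace at stage {'/'.join(stages)}, got {self.stage!r}"
            )

    def to_tsv(self, handle: IO[str]) -> None:
        """Write a ``time_ms\tpupil\tmissing`` table."""
        handle.write("time_ms\tpupil\tmissing\n")
        for t, v, m in zip(self.times_ms(), self.pupil, self.missing):
            handle.write(f"{t:.3f}\t{v:.6g}\t{int(m)}\n")


@dataclass(frozen=True)
class BlinkEvent:
    """A pupil-loss interval of blink-compatible duration (40-400 ms)."""

    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if not (BLINK_MIN_MS <= self.duration_ms <= BLINK_MAX_MS):
            raise EyetrackError(
                f"blink duration {self.duration_ms} ms outside [40, 400] ms"
            )


@dataclass(frozen=True)
class ClosureEvent:
    """Any pupil-loss interval that is not a blink (<40 ms or >400 ms)."""

    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if BLINK_MIN_MS <= self.duration_ms <= BLINK_MAX_MS:
            raise EyetrackError(
                f"closure duration {self.duration_ms} ms is in the blink range"
            )


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: zero-phase Hamming-window FIR low-pass plus
    subtraction of a very-low-frequency trend (the high-pass leg).

    Tap counts follow ``order = factor * fs / cutoff`` rounded up to odd.
    The defaults (0.02-4 Hz, factor 3) give 751 low-pass taps and 150001
    trend taps at 1 kHz; a run must be longer than the trend filter for
    the high-pass to be realizable.
    """

    low_cutoff_hz: float = 0.02
    high_cutoff_hz: float = 4.0
    lp_order_factor: float = 3.0
    hp_order_factor: float = 3.0

    def lp_ntaps(self, fs: float) -> int:
        return _next_odd(int(round(self.lp_order_factor * fs / self.high_cutoff_hz)))

    def hp_ntaps(self, fs: float) -> int:
        return _next_odd(int(round(self.hp_order_factor * fs / self.low_cutoff_hz)))


def _next_odd(n: int) -> int:
    return n + 1 if n % 2 == 0 else n


# ---------------------------------------------------------------------------
# Stage (i): ASC sample parsing


def parse_asc_samples(source: Union[str, IO[str], Iterable[str]]) -> PupilTrace:
    """Parse EyeLink-ASC-dialect sample lines into a raw :class:`PupilTrace`.

    Sample lines start with a numeric timestamp and carry
    ``time, gaze_x, gaze_y, pupil`` columns.  Event/message lines (MSG,
    EBLINK, SSACC, ...) are skipped: vendor blink labels are discarded and
    blinks are re-derived from pupil loss downstream.  A pupil field of
    ``0.0`` — or an unparseable one — is recorded as missing.

    Raises
    ------
    EmptyInputError
        If the stream contains no sample lines.
    NonMonotonicError
        If sample timestamps do not strictly increase (reports the first
        offending line number).
    UnsupportedRateError
        If the timestamp spacing is not 1 ms or 2 ms.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source

    times: List[float] = []
    pupils: List[float] = []
    miss: List[bool] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            t = float(tokens[0])
        except ValueError:
            continue  # event / message line
        if times and t <= times[-1]:
            raise NonMonotonicError(
                f"non-monotonic timestamp at line {lineno}: {t} after {times[-1]}"
            )
        value = np.nan
        if len(tokens) >= 4:
            try:
                value = float(tokens[3])
            except ValueError:
                value = np.nan
        missing = not np.isfinite(value) or value == 0.0
        times.append(t)
        pupils.append(0.0 if missing else value)
        miss.append(missing)

    if not times:
        raise EmptyInputError("no sample lines found in input")

    t_arr = np.asarray(times)
    if t_arr.size < 2:
        dt = 1.0
    else:
        dt = float(np.median(np.diff(t_arr)))
    if not (np.isclose(dt, 1.0) or np.isclose(dt, 2.0)):
        raise UnsupportedRateError(f"timestamp spacing {dt} ms implies unsupported rate")
    if t_arr.size >= 2:
        bad = np.flatnonzero(~np.isclose(np.diff(t_arr), dt))
        if bad.size:
            raise EyetrackError(
                f"non-uniform timestamp spacing near sample {int(bad[0]) + 1}"
            )
    return PupilTrace(
        start_time_ms=float(t_arr[0]),
        sampling_hz=1000.0 / dt,
        pupil=np.asarray(pupils),
        missing=np.asarray(miss),
        stage="raw",
    )


def write_asc_samples(trace: PupilTrace, handle: IO[str],
                      gaze_x: float = 640.0, gaze_y: float = 360.0) -> None:
    """Emit the tab-separated ASC sample dialect (missing pupil as 0.0)."""
    for t, v, m in zip(trace.times_ms(), trace.pupil, trace.missing):
        p = 0.0 if m else v
        handle.write(f"{t:.0f}\t{gaze_x:.1f}\t{gaze_y:.1f}\t{p:.1f}\n")


# ---------------------------------------------------------------------------
# Stage (ii): resampling to 1 kHz


def resample_to_1khz(trace: PupilTrace) -> PupilTrace:
    """Up-sample a raw 500 Hz trace to 1 kHz (linear midpoints, 2n-1 samples).

    A 1 kHz input passes through unchanged apart from the stage tag.  An
    inserted midpoint is missing if either flanking source sample is
    missing; missing samples keep the 0.0 value convention.
    """
    trace.require_stage("raw")
    if trace.sampling_hz == 1000.0:
        return replace(trace, pupil=trace.pupil.copy(),
                       missing=trace.missing.copy(), stage="upsampled")
    if trace.sampling_hz != 500.0:
        raise UnsupportedRateError(f"cannot resample {trace.sampling_hz} Hz input")

    n = trace.n
    if n < 2:
        raise EyetrackError("need at least 2 samples to up-sample")
    out = np.empty(2 * n - 1)
    out[0::2] = trace.pupil
    out[1::2] = 0.5 * (trace.pupil[:-1] + trace.pupil[1:])
    mask = np.zeros(2 * n - 1, dtype=bool)
    mask[0::2] = trace.missing
    mask[1::2] = trace.missing[:-1] | trace.missing[1:]
    out[mask] = 0.0
    return PupilTrace(trace.start_time_ms, 1000.0, out, mask, stage="upsampled")


# ---------------------------------------------------------------------------
# Stage (iii): blink / closure detection


def _missing_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal contiguous True runs as (start, length) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_blinks(trace: PupilTrace) -> Tuple[List[BlinkEvent], List[ClosureEvent]]:
    """Classify every maximal pupil-loss interval of a 1 kHz trace.

    Intervals lasting 40-400 ms (inclusive) are blinks, with the onset at
    the first lost sample; everything else is a closure.  The two lists
    together cover every lost interval exactly once, in time order.
    """
    trace.require_stage("upsampled")
    if trace.sampling_hz != 1000.0:
        raise UnsupportedRateError("blink detection requires a 1 kHz trace")
    blinks: List[BlinkEvent] = []
    closures: List[ClosureEvent] = []
    dt = trace.dt_ms
    for start, length in _missing_runs(trace.missing):
        onset = trace.start_time_ms + start * dt
        dur = length * dt
        if BLINK_MIN_MS <= dur <= BLINK_MAX_MS:
            blinks.append(BlinkEvent(onset, dur))
        else:
            closures.append(ClosureEvent(onset, dur))
    return blinks, closures


# ---------------------------------------------------------------------------
# Stage (iv): cubic interpolation of blink gaps


def interpolate_blinks(trace: PupilTrace, blinks: List[BlinkEvent],
                       anchor_ms: float = 100.0) -> PupilTrace:
    """Replace blink-gap samples by a cubic fit to flanking anchor windows.

    Anchors are the valid samples within ``anchor_ms`` on each side of the
    gap.  If one side has no valid anchors (blink at a trace edge, or
    hemmed in by closures) the fill falls back to a linear fit on the
    available side, with a warning.  Closure intervals are left missing.
    """
    trace.require_stage("upsampled")
    pupil = trace.pupil.copy()
    mask = trace.missing.copy()
    dt = trace.dt_ms
    w = max(2, int(round(anchor_ms / dt)))

    for ev in blinks:
        i0 = int(round((ev.onset_ms - trace.start_time_ms) / dt))
        length = int(round(ev.duration_ms / dt))
        i1 = i0 + length
        left = np.arange(max(0, i0 - w), i0)
        right = np.arange(i1, min(trace.n, i1 + w))
        left = left[~mask[left]] if left.size else left
        right = right[~mask[right]] if right.size else right
        gap = np.arange(i0, i1)
        anchors = np.concatenate([left, right])
        if left.size >= 2 and right.size >= 2 and anchors.size >= 4:
            poly = np.polynomial.Polynomial.fit(anchors, pupil[anchors], deg=3)
            pupil[gap] = poly(gap)
        elif anchors.size >= 2:
            warnings.warn(
                "blink at trace edge: linear one-sided fill", stacklevel=2)
            poly = np.polynomial.Polynomial.fit(anchors, pupil[anchors], deg=1)
            pupil[gap] = poly(gap)
        elif anchors.size == 1:
            warnings.warn("blink with single anchor: constant fill", stacklevel=2)
            pupil[gap] = pupil[anchors[0]]
        else:
            warnings.warn("blink with no valid anchors left missing", stacklevel=2)
            continue
        mask[gap] = False
    return PupilTrace(trace.start_time_ms, trace.sampling_hz, pupil, mask,
                      stage="interpolated")


# ---------------------------------------------------------------------------
# Stage (v): zero-phase FIR band-pass


def _zero_phase_fir(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward application of a symmetric odd-length FIR filter.

    Odd-reflection padding of length = filter order suppresses the onset
    transient; the kernel is applied twice (|H|^2 response), which for a
    symmetric kernel is exactly the forward-backward result.
    """
    ntaps = b.size
    pad = ntaps - 1
    n = x.size
    if n < ntaps:
        raise TraceTooShortError(
            f"trace of {n} samples shorter than the {ntaps}-tap filter; "
            f"minimum length is {ntaps} samples"
        )
    pad = min(pad, n - 1)
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-2 - pad:-1]
    xp = np.concatenate([left, x, right])
    y = fftconvolve(xp, b, mode="same")
    y = fftconvolve(y, b, mode="same")
    return y[pad:pad + n]


def _bridge_missing(pupil: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linearly bridge masked samples (nearest-value extension at edges)."""
    if not mask.any():
        return pupil.copy()
    if mask.all():
        raise EyetrackError("cannot filter a fully missing trace")
    idx = np.arange(pupil.size)
    out = pupil.copy()
    out[mask] = np.interp(idx[mask], idx[~mask], pupil[~mask])
    return out


def bandpass_filter(trace: PupilTrace, spec: FilterSpec = FilterSpec()) -> PupilTrace:
    """Zero-phase 0.02-4 Hz band-pass of an interpolated 1 kHz trace.

    Realized as a Hamming-window FIR low-pass at the upper cutoff minus a
    same-family low-pass trend at the lower cutoff (the high-pass leg),
    both applied forward-backward.  Closure intervals are bridged linearly
    beforehand and re-masked afterwards; they remain missing data.

    Raises
    ------
    TraceTooShortError
        If the run is shorter than the trend filter (message states the
        minimum length).
    """
    trace.require_stage("interpolated")
    fs = trace.sampling_hz
    hp_ntaps = spec.hp_ntaps(fs)
    if trace.n < hp_ntaps:
        raise TraceTooShortError(
            f"run of {trace.n} samples too short for the {hp_ntaps}-tap "
            f"{spec.low_cutoff_hz} Hz high-pass; need >= {hp_ntaps} samples "
            f"({hp_ntaps / fs:.1f} s at {fs:.0f} Hz)"
        )
    bridged = _bridge_missing(trace.pupil, trace.missing)
    b_lp = firwin(spec.lp_ntaps(fs), spec.high_cutoff_hz, fs=fs)
    b_trend = firwin(hp_ntaps, spec.low_cutoff_hz, fs=fs)
    low = _zero_phase_fir(b_lp, bridged)
    trend = _zero_phase_fir(b_trend, bridged)
    return PupilTrace(trace.start_time_ms, fs, low - trend,
                      trace.missing.copy(), stage="filtered")


# ---------------------------------------------------------------------------
# Stage (vi): decimation to 100 Hz


def downsample_100hz(trace: PupilTrace) -> PupilTrace:
    """Keep every 10th sample of a filtered 1 kHz trace (4 Hz low-pass is
    the anti-alias filter); masks are OR-reduced over each 10-sample block."""
    trace.require_stage("filtered")
    if trace.sampling_hz != 1000.0:
        raise UnsupportedRateError("downsampling expects a 1 kHz trace")
    n = trace.n
    values = trace.pupil[::10].copy()
    n_out = values.size
    padded = np.zeros(n_out * 10, dtype=bool)
    padded[:n] = trace.missing
    mask = padded.reshape(n_out, 10).any(axis=1)
    return PupilTrace(trace.start_time_ms, 100.0, values, mask, stage="downsampled")


def preprocess(trace: PupilTrace, spec: FilterSpec = FilterSpec()):
    """Run the full chain on a raw trace.

    Returns
    -------
    (trace_100hz, interpolated_1khz, blinks, closures)
        The 100 Hz filtered trace for epoching, the interpolated but
        unfiltered 1 kHz trace (mean pupil size is computed on this one:
        the 0.02 Hz high-pass removes the mean), and the event lists.
    """
    up = resample_to_1khz(trace)
    blinks, closures = detect_blinks(up)
    interp = interpolate_blinks(up, blinks)
    filtered = bandpass_filter(interp, spec)
    down = downsample_100hz(filtered)
    return down, interp, blinks, closures
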