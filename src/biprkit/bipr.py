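"""Blink-locked epoching and the nine per-run eye measures.

Each blink yields a -2 s ... +3 s epoch of the 100 Hz filtered pupil
trace, baselined to the -200...0 ms pre-blink mean.  Valid epochs are
averaged into a per-run profile from which the D (dilation) and C
(constriction) peaks are read off, giving six waveform parameters; blink
rate, mean blink duration and mean pupil size complete the set of nine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from biprkit.eyetrack import BlinkEvent, ClosureEvent, PupilTrace

EPOCH_PRE_S = 2.0
EPOCH_POST_S = 3.0
EPOCH_FS = 100.0
EPOCH_LEN = int((EPOCH_PRE_S + EPOCH_POST_S) * EPOCH_FS)  # 500 samples
BASELINE_MS = 200.0

#: Names of the nine per-run measures, in report order.
MEASURE_NAMES = (
    "blink_rate", "blink_duration", "pupil_size",
    "d_peak_time", "d_peak_amp", "c_peak_time", "c_peak_amp",
    "dc_time_diff", "dc_magnitude_drop",
)


def epoch_times_ms() -> np.ndarray:
    """Epoch timebase: 500 samples from -2000 ms to +2990 ms."""
    return (np.arange(EPOCH_LEN) - EPOCH_PRE_S * EPOCH_FS) * (1000.0 / EPOCH_FS)


@dataclass
class BIPREpoch:
    """One blink-locked pupil segment (NaN marks missing samples)."""

    values: np.ndarray
    valid: bool
    missing_fraction_post: float
    onset_ms: float


@dataclass
class BIPRProfile:
    """Per-run average blink-locked waveform."""

    values: np.ndarray
    n_epochs: int


@dataclass
class EyeMeasures:
    """The nine per-run scalars; NaN encodes a missing field."""

    blink_rate: float = math.nan
    blink_duration: float = math.nan
    pupil_size: float = math.nan
    d_peak_time: float = math.nan
    d_peak_amp: float = math.nan
    c_peak_time: float = math.nan
    c_peak_amp: float = math.nan
    dc_time_diff: float = math.nan
    dc_magnitude_drop: float = math.nan
    n_epochs: int = 0

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


def extract_epochs(trace: PupilTrace, blinks: Sequence[BlinkEvent],
                   max_missing_post: float = 0.40) -> List[BIPREpoch]:
    """Cut one epoch per blink whose full -2...+3 s window fits in the run.

    Out-of-bounds windows are dropped, not padded.  An epoch is valid when
    the whole pre-window is present and at most ``max_missing_post`` of
    the 0-3 s samples are missing.  Values are baselined to the mean of
    the -200...0 ms window.
    """
    trace.require_stage("downsampled")
    pre = int(EPOCH_PRE_S * EPOCH_FS)
    post = int(EPOCH_POST_S * EPOCH_FS)
    base = int(BASELINE_MS / 1000.0 * EPOCH_FS)
    epochs: List[BIPREpoch] = []
    for ev in blinks:
        idx = int(round((ev.onset_ms - trace.start_time_ms) / trace.dt_ms))
        lo, hi = idx - pre, idx + post
        if lo < 0 or hi > trace.n:
            continue
        vals = trace.pupil[lo:hi].astype(float).copy()
        mask = trace.missing[lo:hi]
        vals[mask] = np.nan
        pre_ok = not mask[:pre].any()
        frac_post = float(mask[pre:].mean())
        baseline_vals = vals[pre - base:pre]
        finite = np.isfinite(baseline_vals)
        if finite.any():
            vals = vals - np.nanmean(baseline_vals)
        epochs.append(BIPREpoch(
            values=vals,
            valid=pre_ok and frac_post <= max_missing_post,
            missing_fraction_post=frac_post,
            onset_ms=ev.onset_ms,
        ))
    return epochs


def average_bipr(epochs: Sequence[BIPREpoch],
                 min_epochs: int = 5) -> Optional[BIPRProfile]:
    """Pointwise mean over valid epochs, ignoring missing samples.

    Returns None when fewer than ``min_epochs`` epochs are valid; the
    BIPR fields then stay missing downstream.
    """
    good = [e for e in epochs if e.valid]
    if len(good) < min_epochs:
        return None
    stacked = np.vstack([e.values for e in good])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return BIPRProfile(values=mean, n_epochs=len(good))


def find_bipr_peaks(profile: BIPRProfile,
                    d_window_ms: Tuple[float, float] = (50.0, 900.0),
                    c_window_ms: Tuple[float, float] = (300.0, 2500.0)
                    ) -> Tuple[float, float, float, float]:
    """Locate the dilation (D) and constriction (C) peaks of a profile.

    D is the maximum within the D window, required positive; C is the
    minimum within the C window at a time strictly after D, required
    negative.  A peak failing its sign constraint yields NaN for both its
    time and amplitude.  Times are ms after blink onset.
    """
    t = epoch_times_ms()
    v = profile.values
    d_time = d_amp = c_time = c_amp = math.nan

    d_sel = (t >= d_window_ms[0]) & (t <= d_window_ms[1]) & np.isfinite(v)
    if d_sel.any():
        i = np.flatnonzero(d_sel)[np.nanargmax(v[d_sel])]
        if v[i] > 0:
            d_time, d_amp = float(t[i]), float(v[i])

    c_lo = c_window_ms[0] if math.isnan(d_time) else max(c_window_ms[0], d_time)
    c_sel = (t > c_lo) & (t <= c_window_ms[1]) & np.isfinite(v)
    if c_sel.any():
        i = np.flatnonzero(c_sel)[np.nanargmin(v[c_sel])]
        if v[i] < 0:
            c_time, c_amp = float(t[i]), float(v[i])

    return d_time, d_amp, c_time, c_amp


def compute_eye_measures(interp_trace: PupilTrace,
                         blinks: Sequence[BlinkEvent],
                         closures: Sequence[ClosureEvent],
                         profile: Optional[BIPRProfile],
                         d_window_ms: Tuple[float, float] = (50.0, 900.0),
                         c_window_ms: Tuple[float, float] = (300.0, 2500.0)
                         ) -> EyeMeasures:
    """Assemble the nine scalars for a run.

    blink_rate is blinks per minute of eyes-open time (run duration minus
    total closure time); blink_duration is the mean blink length in ms;
    pupil_size is the mean of the interpolated *unfiltered* trace over
    non-missing samples (the band-pass removes the mean, so this is the
    only self-consistent stage for it).
    """
    interp_trace.require_stage("interpolated", "upsampled", "raw")
    m = EyeMeasures()
    eyes_open_min = (interp_trace.duration_s
                     - sum(c.duration_ms for c in closures) / 1000.0) / 60.0
    if eyes_open_min <= 0:
        return m
    m.blink_rate = len(blinks) / eyes_open_min
    if blinks:
        m.blink_duration = float(np.mean([b.duration_ms for b in blinks]))
    valid = ~interp_trace.missing
    if valid.any():
        m.pupil_size = float(interp_trace.pupil[valid].mean())
    if profile is not None:
        m.n_epochs = profile.n_epochs
        d_t, d_a, c_t, c_a = find_bipr_peaks(profile, d_window_ms, c_window_ms)
        m.d_peak_time, m.d_peak_amp = d_t, d_a
        m.c_peak_time, m.c_peak_amp = c_t, c_a
        if not math.isnan(d_t) and not math.isnan(c_t):
            m.dc_time_diff = c_t - d_t
            m.dc_magnitude_drop = d_a - c_a
    return m


def iqr_keep_mask(values: np.ndarray, multiplier: float = 2.0) -> np.ndarray:
    """Boolean keep-mask under the Q1 - m*IQR ... Q3 + m*IQR rule.

    NaNs are kept (they pass through untouched); with fewer than 4 finite
    values everything is kept.  Quartiles use linear interpolation between
    order statistics.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    keep = np.ones(values.shape, dtype=bool)
    if finite.sum() < 4:
        return keep
    q1, q3 = np.percentile(values[finite], [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    keep[finite] = (values[finite] >= lo) & (values[finite] <= hi)
    return keep


def remove_outliers(values: Sequence[float], multiplier: float = 2.0) -> np.ndarray:
    """Drop values outside 2 IQR beyond the quartiles; NaNs pass through."""
    values = np.asarray(values, dtype=float)
    return values[iqr_keep_mask(values, multiplier)]
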