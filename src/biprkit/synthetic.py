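"""Ground-truth generators: pupil runs, twin cohorts, reliability tables.

Every generator is a pure function of its spec (which embeds the seed),
so downstream stages get a parameter-recovery test surface with exactly
known blink lists, closure lists, kernels and variance components.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import IO, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from biprkit.eyetrack import (
    BLINK_MAX_MS,
    BLINK_MIN_MS,
    BlinkEvent,
    ClosureEvent,
    PupilTrace,
    write_asc_samples,
)


class SimulationError(ValueError):
    """Raised when a requested simulation is infeasible."""


@dataclass(frozen=True)
class BIPRKernel:
    """Blink-locked response: a positive Gaussian bump (dilation, D)
    followed by a negative one (constriction, C), timed from blink onset.

    The published waveform peaks around 500 ms (D) and 1 s (C) but is
    never parameterized; Gaussian bumps make peak times and amplitudes
    analytically known for recovery tests.  Amplitudes are free
    parameters in au and make no claim to match any real recording.
    """

    d_time_ms: float = 500.0
    d_amp: float = 30.0
    d_width_ms: float = 120.0
    c_time_ms: float = 1000.0
    c_amp: float = 25.0
    c_width_ms: float = 180.0

    def __post_init__(self) -> None:
        if self.c_time_ms <= self.d_time_ms:
            raise SimulationError("c_time_ms must exceed d_time_ms")
        if min(self.d_width_ms, self.c_width_ms) <= 0:
            raise SimulationError("kernel widths must be positive")
        if self.d_amp <= 0 or self.c_amp <= 0:
            raise SimulationError("kernel amplitudes must be positive")

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Kernel value at times (ms) relative to blink onset."""
        d = self.d_amp * np.exp(-0.5 * ((t_ms - self.d_time_ms) / self.d_width_ms) ** 2)
        c = self.c_amp * np.exp(-0.5 * ((t_ms - self.c_time_ms) / self.c_width_ms) ** 2)
        return d - c


@dataclass(frozen=True)
class SimRunParams:
    """Parameters for one simulated eye-tracking run."""

    duration_s: float = 300.0
    sampling_hz: int = 1000
    baseline_pupil: float = 1500.0
    drift_amplitude: float = 100.0
    drift_period_s: float = 60.0
    blink_rate_per_min: float = 12.0
    blink_duration_range_ms: Tuple[float, float] = (80.0, 300.0)
    closure_target_fraction: float = 0.0
    closure_duration_range_s: Tuple[float, float] = (0.5, 4.0)
    kernel: BIPRKernel = field(default_factory=BIPRKernel)
    noise_sd: float = 5.0
    seed: int = 0
    clean_tail_fraction: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.blink_duration_range_ms
        if not (BLINK_MIN_MS <= lo <= hi <= BLINK_MAX_MS):
            raise SimulationError("blink durations must lie in [40, 400] ms")
        clo, chi = self.closure_duration_range_s
        if not (0.4 < clo <= chi):
            raise SimulationError("closure durations must exceed 0.4 s")
        if self.sampling_hz not in (500, 1000):
            raise SimulationError("sampling_hz must be 500 or 1000")
        if not (0.0 <= self.closure_target_fraction < 1.0):
            raise SimulationError("closure_target_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Exact event lists and kernel used to build a simulated run."""

    blinks: List[BlinkEvent]
    closures: List[ClosureEvent]
    kernel: BIPRKernel

    def to_json(self, handle: IO[str]) -> None:
        payload = {
            "blinks": [asdict(b) for b in self.blinks],
            "closures": [asdict(c) for c in self.closures],
            "kernel": asdict(self.kernel),
        }
        json.dump(payload, handle, indent=1)


def _place_interval(rng: np.random.Generator, free: np.ndarray, length: int,
                    margin: int, n: int, attempts: int = 200) -> int:
    """Pick a start index such that [start, start+length) is free.

    ``free`` already excludes a margin zone around existing events, so any
    placement inside it keeps events separated.  Random rejection sampling
    is tried first; at high occupancy it falls back to choosing among the
    free gaps that still fit.  No gap fitting -> explicit failure.
    """
    for _ in range(attempts):
        start = int(rng.integers(0, n - length))
        if free[start:start + length].all():
            return start
    # first-fit fallback: enumerate maximal free gaps
    padded = np.concatenate([[False], free, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    fitting = [(s, e) for s, e in zip(starts, ends) if e - s >= length]
    if not fitting:
        raise SimulationError(
            "could not place a loss interval without overlap; "
            "requested event density is too high"
        )
    s, e = fitting[int(rng.integers(0, len(fitting)))]
    return int(rng.integers(s, e - length + 1))


def _largest_free_gap(free: np.ndarray) -> int:
    padded = np.concatenate([[False], free, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max()) if starts.size else 0


def simulate_pupil_run(params: SimRunParams) -> Tuple[PupilTrace, GroundTruth]:
    """Simulate one raw pupil run with known blinks, closures and kernel.

    The signal is baseline + slow sinusoidal drift + white noise, with the
    BIPR kernel added after every blink.  Blinks follow a Poisson process
    thinned to forbid overlaps; a ``clean_tail_fraction`` share of blinks
    reserves a 3 s event-free tail so some epochs are valid by
    construction.  Long closures are placed until the realized closure
    fraction is within +-0.05 of the target.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    fs = float(p.sampling_hz)
    dt_ms = 1000.0 / fs
    n = int(round(p.duration_s * fs))
    if n < 10:
        raise SimulationError("run too short")

    blink_occupancy = (p.blink_rate_per_min / 60.0) * (
        np.mean(p.blink_duration_range_ms) / 1000.0)
    if blink_occupancy + p.closure_target_fraction > 0.95:
        raise SimulationError(
            f"requested loss occupancy {blink_occupancy + p.closure_target_fraction:.2f} "
            "infeasible (blink rate x duration plus closure target too high)"
        )

    free = np.ones(n, dtype=bool)
    margin = int(round(0.05 * fs))  # 50 ms gap so events never merge

    # closures first (they dominate occupancy)
    closures: List[ClosureEvent] = []
    target_samples = int(round(p.closure_target_fraction * n))
    placed = 0
    min_len = int(round(max(0.401, p.closure_duration_range_s[0]) * fs))
    while placed < target_samples:
        dur_s = rng.uniform(*p.closure_duration_range_s)
        length = int(round(dur_s * fs))
        remaining = target_samples - placed
        if length > remaining:
            length = max(min_len, remaining)
        # cap at the largest free gap so fragmentation cannot stall placement
        gap = _largest_free_gap(free)
        if gap < min_len:
            raise SimulationError(
                "no free gap can hold a closure: closure target too high "
                "for the requested durations"
            )
        length = min(length, gap)
        start = _place_interval(rng, free, length, margin, n)
        free[max(0, start - margin):start + length + margin] = False
        closures.append(ClosureEvent(onset_ms=start * dt_ms, duration_ms=length * dt_ms))
        placed += length

    # blinks: a Poisson-drawn count, every one placed at a free position
    # (placement failure raises rather than silently truncating the count)
    n_blinks = rng.poisson(p.blink_rate_per_min * p.duration_s / 60.0)
    tail = int(round(3.0 * fs))
    blinks: List[BlinkEvent] = []
    for _ in range(n_blinks):
        length = int(round(rng.uniform(*p.blink_duration_range_ms) / dt_ms))
        length = max(length, int(np.ceil(BLINK_MIN_MS / dt_ms)))
        start = _place_interval(rng, free, length, margin, n)
        free[max(0, start - margin):start + length + margin] = False
        if rng.random() < p.clean_tail_fraction:
            free[start + length:start + length + tail] = False
        blinks.append(BlinkEvent(onset_ms=start * dt_ms, duration_ms=length * dt_ms))

    t_s = np.arange(n) / fs
    signal = (p.baseline_pupil
              + p.drift_amplitude * np.sin(2.0 * np.pi * t_s / p.drift_period_s)
              + p.noise_sd * rng.standard_normal(n))

    kernel_span = int(round(4.0 * fs))
    for b in blinks:
        start = int(round(b.onset_ms / dt_ms))
        hi = min(n, start + kernel_span)
        rel_ms = (np.arange(start, hi) - start) * dt_ms
        signal[start:hi] += p.kernel.evaluate(rel_ms)

    mask = np.zeros(n, dtype=bool)
    for ev in list(blinks) + list(closures):
        i0 = int(round(ev.onset_ms / dt_ms))
        i1 = i0 + int(round(ev.duration_ms / dt_ms))
        mask[i0:i1] = True
    signal[mask] = 0.0

    trace = PupilTrace(start_time_ms=0.0, sampling_hz=fs, pupil=signal,
                       missing=mask, stage="raw")
    blinks.sort(key=lambda b: b.onset_ms)
    closures.sort(key=lambda c: c.onset_ms)
    return trace, GroundTruth(blinks=blinks, closures=closures, kernel=p.kernel)


def write_run(trace: PupilTrace, truth: GroundTruth, asc: IO[str],
              sidecar: Optional[IO[str]] = None) -> None:
    """Emit a run as ASC samples plus an optional JSON ground-truth sidecar."""
    write_asc_samples(trace, asc)
    if sidecar is not None:
        truth.to_json(sidecar)


# ---------------------------------------------------------------------------
# Twin cohorts


MODELS = ("ACE", "ADE", "AE", "CE", "E")


@dataclass(frozen=True)
class TwinCohortSpec:
    """Generator spec for a twin cohort under known variance components.

    ``a2``/``c2_or_d2``/``e2`` are standardized fractions that must sum
    to 1; ``c2_or_d2`` is the C share for ACE/CE models and the D share
    for ADE.  Covariate coding follows the phenotype convention:
    sex 1/2, vigilance 1/2.
    """

    n_mz_pairs: int
    n_dz_pairs: int
    model: str = "ACE"
    a2: float = 0.5
    c2_or_d2: float = 0.0
    e2: float = 0.5
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_vig: float = 0.0
    mean: float = 0.0
    age_range: Tuple[float, float] = (22.0, 36.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise SimulationError(f"unknown model {self.model!r}")
        fracs = (self.a2, self.c2_or_d2, self.e2)
        if min(fracs) < 0:
            raise SimulationError("variance fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise SimulationError("variance fractions must sum to 1")
        if self.model in ("CE", "E") and self.a2 != 0.0:
            raise SimulationError(f"a2 must be 0 under model {self.model}")
        if self.model in ("AE", "E") and self.c2_or_d2 != 0.0:
            raise SimulationError(f"c2/d2 must be 0 under model {self.model}")


def simulate_twin_cohort(spec: TwinCohortSpec) -> pd.DataFrame:
    """Simulate twin pairs under the spec's variance components.

    Cross-twin correlations of the latent factors: A is 1 in MZ and 0.5
    in DZ (DZ twins draw ``sqrt(.5)*common + sqrt(.5)*unique``); C is 1 in
    both; D is 1 in MZ and 0.25 in DZ; E is independent.  Twins share
    age; MZ twins share sex.  The vigilance covariate is drawn once per
    pair row.

    Returns a DataFrame with columns ``family_id, zygosity, y1, y2,
    age1, age2, sex1, sex2, vig1, vig2, u1, u2`` where u1/u2 are the
    covariate-free phenotype parts (for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    a = np.sqrt(spec.a2)
    e = np.sqrt(spec.e2)
    cd = np.sqrt(spec.c2_or_d2)
    is_ade = spec.model == "ADE"

    rows = []
    fam = 0
    for zyg, n_pairs in (("MZ", spec.n_mz_pairs), ("DZ", spec.n_dz_pairs)):
        for _ in range(n_pairs):
            fam += 1
            if zyg == "MZ":
                A = np.full(2, rng.standard_normal())
            else:
                Ac = rng.standard_normal()
                A = np.sqrt(0.5) * Ac + np.sqrt(0.5) * rng.standard_normal(2)
            if is_ade:
                if zyg == "MZ":
                    CD = np.full(2, rng.standard_normal())
                else:
                    Dc = rng.standard_normal()
                    CD = np.sqrt(0.25) * Dc + np.sqrt(0.75) * rng.standard_normal(2)
            else:
                CD = np.full(2, rng.standard_normal())  # shared env: r=1 both
            E = rng.standard_normal(2)
            u = a * A + cd * CD + e * E

            age = rng.uniform(*spec.age_range)
            if zyg == "MZ":
                sex = np.full(2, rng.integers(1, 3))
            else:
                sex = rng.integers(1, 3, size=2)
            vig = int(rng.integers(1, 3))
            y = (spec.mean + spec.beta_age * age + spec.beta_sex * sex
                 + spec.beta_vig * vig + u)
            rows.append({
                "family_id": fam, "zygosity": zyg,
                "y1": y[0], "y2": y[1],
                "age1": age, "age2": age,
                "sex1": int(sex[0]), "sex2": int(sex[1]),
                "vig1": vig, "vig2": vig,
                "u1": u[0], "u2": u[1],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reliability tables


@dataclass(frozen=True)
class ReliabilitySpec:
    """Two-way random-effects generator: y_ij = s_i + r_j + e_ij."""

    n_subjects: int
    runs_per_subject: Union[int, Sequence[int]] = 4
    var_subject: float = 1.0
    var_run: float = 0.1
    var_error: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.var_subject, self.var_run, self.var_error) < 0:
            raise SimulationError("variances must be nonnegative")
        counts = self.run_counts()
        if len(counts) != self.n_subjects or min(counts) < 2:
            raise SimulationError("runs_per_subject must be >= 2 for every subject")

    def run_counts(self) -> List[int]:
        if isinstance(self.runs_per_subject, int):
            return [self.runs_per_subject] * self.n_subjects
        return list(self.runs_per_subject)

    def population_icc2k(self) -> float:
        """Closed-form population ICC(2,k) at the mean run count."""
        k = float(np.mean(self.run_counts()))
        return self.var_subject / (
            self.var_subject + (self.var_run + self.var_error) / k)


def simulate_reliability_matrix(spec: ReliabilitySpec) -> pd.DataFrame:
    """Subject x run table under the two-way random-effects model
    (NaN where a subject has fewer runs than the widest subject)."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.run_counts()
    k_max = max(counts)
    s = np.sqrt(spec.var_subject) * rng.standard_normal(spec.n_subjects)
    r = np.sqrt(spec.var_run) * rng.standard_normal(k_max)
    table = np.full((spec.n_subjects, k_max), np.nan)
    for i, k_i in enumerate(counts):
        eps = np.sqrt(spec.var_error) * rng.standard_normal(k_i)
        table[i, :k_i] = s[i] + r[:k_i] + eps
    return pd.DataFrame(
        table,
        index=[f"subj_{i + 1}" for i in range(spec.n_subjects)],
        columns=[f"run_{j + 1}" for j in range(k_max)],
    )
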