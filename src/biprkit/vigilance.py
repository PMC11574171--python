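"""Per-run vigilance staging from the fraction of pupil-loss time.

Runs are labelled Vigilant (<10% loss), Drowsy (10-40%), VeryDrowsy
(40-75%) or Discarded (>75%).  The published interval endpoints overlap;
the convention here is left-closed at 0.10 and 0.40 and right-closed at
0.75, i.e. 0.10 -> Drowsy, 0.40 -> VeryDrowsy, 0.75 -> VeryDrowsy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

from biprkit.eyetrack import PupilTrace

VIGILANT = "Vigilant"
DROWSY = "Drowsy"
VERY_DROWSY = "VeryDrowsy"
DISCARDED = "Discarded"
ALL_DROWSY = "AllDrowsy"

LABELS = (VIGILANT, DROWSY, VERY_DROWSY, DISCARDED)

DEFAULT_THRESHOLDS = (0.10, 0.40, 0.75)


@dataclass(frozen=True)
class VigilanceState:
    label: str
    loss_fraction: float

    def __post_init__(self) -> None:
        if self.label not in LABELS + (ALL_DROWSY,):
            raise ValueError(f"unknown vigilance label {self.label!r}")
        if not (0.0 <= self.loss_fraction <= 1.0):
            raise ValueError("loss_fraction must be in [0, 1]")


def pupil_loss_fraction(trace: PupilTrace) -> float:
    """Fraction of samples with no detected pupil, on the pre-interpolation
    trace (blink gaps count as loss)."""
    trace.require_stage("raw", "upsampled")
    if trace.n == 0:
        raise ValueError("empty trace")
    return float(trace.missing.mean())


def classify_run(loss_fraction: float,
                 thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS
                 ) -> VigilanceState:
    """Map a loss fraction to one of the four vigilance labels."""
    if not (0.0 <= loss_fraction <= 1.0):
        raise ValueError(f"loss fraction {loss_fraction} outside [0, 1]")
    lo, mid, hi = thresholds
    if loss_fraction < lo:
        label = VIGILANT
    elif loss_fraction < mid:
        label = DROWSY
    elif loss_fraction <= hi:
        label = VERY_DROWSY
    else:
        label = DISCARDED
    return VigilanceState(label, loss_fraction)


def merge_drowsy(states: Iterable[VigilanceState]) -> List[VigilanceState]:
    """Collapse Drowsy and VeryDrowsy into a single AllDrowsy label."""
    out = []
    for s in states:
        if s.label in (DROWSY, VERY_DROWSY):
            out.append(VigilanceState(ALL_DROWSY, s.loss_fraction))
        else:
            out.append(s)
    return out


def merge_label(label: str) -> str:
    """Single-label version of :func:`merge_drowsy`."""
    return ALL_DROWSY if label in (DROWSY, VERY_DROWSY) else label
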