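"""Stance-phase extraction from vertical GRF traces, with inclusion filtering.

A stance phase is the interval during which a foot loads the platform: it opens at
the first sample strictly above the onset threshold following a sub-threshold
sample and closes at the first subsequent sample at or below the threshold
(the "force returns to zero" rule, with a small noise gate because real platforms
never read exactly 0 N).  Indices are 0-based and half-open ``[start, end)``;
contact time is computed from the sample count on the uniform grid, not from
timestamps.

Inclusion criteria: the field practice of discarding steps taken above or below
amble speed cannot be reproduced from a single platform, so it is proxied by a
contact-time window; phases touching either end of the trace are truncated and
never valid; tiny supra-threshold blips are gated by a minimum peak force.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .io import ForceRecording

#: Exclusion reasons attached to invalid phases.
REASON_EDGE = "edge_truncated"
REASON_TOO_SHORT = "too_short"
REASON_TOO_LONG = "too_long"
REASON_LOW_PEAK = "below_threshold_peak"


@dataclass(frozen=True)
class SegConfig:
    """Segmentation and inclusion parameters.

    onset_threshold
        Noise gate in newtons; ~1 %BW of a 55 kg sheep.  Samples strictly above
        it open a phase, samples at or below it close one.
    min_peak
        Minimum peak force (N) for a phase to count as a real step.
    t_c_bounds
        Inclusive contact-time window (s) standing in for the amble-speed
        inclusion criterion.
    """

    onset_threshold: float = 5.0
    min_peak: float = 20.0
    t_c_bounds: tuple[float, float] = (0.15, 1.20)

    def __post_init__(self) -> None:
        if self.onset_threshold < 0:
            raise ValidationError("onset_threshold must be >= 0")
        lo, hi = self.t_c_bounds
        if not lo < hi:
            raise ValidationError("t_c_bounds must be ordered (min, max)")


@dataclass(frozen=True)
class StancePhase:
    """One contiguous foot-contact segment of a recording."""

    start_index: int
    end_index: int
    sampling_rate: float
    forces: np.ndarray
    valid: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValidationError("end_index must exceed start_index")
        object.__setattr__(self, "forces", np.asarray(self.forces, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def t_c(self) -> float:
        """Contact time in seconds, from the sample count."""
        return self.n_samples / self.sampling_rate

    @property
    def start_time(self) -> float:
        return self.start_index / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.end_index / self.sampling_rate

    @property
    def peak_force(self) -> float:
        return float(self.forces.max())


def detect_stance_phases(
    recording: ForceRecording, config: SegConfig | None = None
) -> list[StancePhase]:
    """Split a recording into supra-threshold runs.

    Returns phases in temporal order, non-overlapping, covering every run of
    samples strictly above the onset threshold.  Phases touching the first or
    last sample are flagged ``edge_truncated`` immediately (their true extent is
    unknown); all other validity flags are left to
    :func:`apply_inclusion_filters`.
    """
    config = config or SegConfig()
    above = recording.forces > config.onset_threshold
    if not above.any():
        return []
    # Transitions of the boolean mask give phase boundaries.
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    n = recording.n_samples
    phases = []
    for s, e in zip(starts, ends):
        truncated = s == 0 or e == n
        phases.append(
            StancePhase(
                start_index=int(s),
                end_index=int(e),
                sampling_rate=recording.sampling_rate,
                forces=recording.forces[s:e],
                valid=False,
                exclusion_reason=REASON_EDGE if truncated else None,
            )
        )
    return phases


def apply_inclusion_filters(
    phases: list[StancePhase], config: SegConfig | None = None
) -> list[StancePhase]:
    """Set validity flags: not edge-truncated, peak >= min_peak, t_c in bounds."""
    config = config or SegConfig()
    lo, hi = config.t_c_bounds
    out = []
    for p in phases:
        if p.exclusion_reason == REASON_EDGE:
            out.append(replace(p, valid=False, exclusion_reason=REASON_EDGE))
        elif p.peak_force < config.min_peak:
            out.append(replace(p, valid=False, exclusion_reason=REASON_LOW_PEAK))
        elif p.t_c < lo:
            out.append(replace(p, valid=False, exclusion_reason=REASON_TOO_SHORT))
        elif p.t_c > hi:
            out.append(replace(p, valid=False, exclusion_reason=REASON_TOO_LONG))
        else:
            out.append(replace(p, valid=True, exclusion_reason=None))
    return out


def exclusion_counts(phases: list[StancePhase]) -> Counter:
    """Tally of exclusion reasons over a phase list (valid phases not counted)."""
    return Counter(p.exclusion_reason for p in phases if not p.valid)


def segment_recording(
    recording: ForceRecording, config: SegConfig | None = None
) -> list[StancePhase]:
    """Detect phases and apply inclusion filters in one call."""
    config = config or SegConfig()
    return apply_inclusion_filters(detect_stance_phases(recording, config), config)
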