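"""Stimulus schedules for tilt-in-place calcium imaging.

Two stimulus protocols are modelled, both 65 s long and imaged at a fixed
frame rate (3 frames/s by default):

* the *tonic* protocol — horizontal baseline (5 s at 0°), nose-down tilt
  (15 s at −19°), horizontal imaging (15 s), nose-up tilt (15 s at +19°),
  horizontal imaging (15 s); and
* the *impulse* protocol — horizontal baseline (20 s), a 10 ms angular
  impulse, horizontal imaging (30 s), a second 10 ms impulse, horizontal
  imaging (15 s).

Because the microscope images only at horizontal, responses are read out in
the first second of each restoration to horizontal.  The schedule object
converts those stimulus times into frame-index windows for the scoring code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidConfigError

SEGMENT_LABELS = ("baseline", "nose_down_tilt", "horizontal", "nose_up_tilt", "impulse")

TONIC_TOTAL_S = 65.0
IMPULSE_TOTAL_S = 65.0
DEFAULT_FRAME_RATE = 3.0
TILT_ANGLE_DEG = 19.0
IMPULSE_DURATION_S = 0.010


@dataclass(frozen=True)
class Segment:
    label: str
    duration: float  # seconds
    angle: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise InvalidConfigError(f"unknown segment label: {self.label!r}")
        if self.duration <= 0:
            raise InvalidConfigError("segment duration must be positive")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus segments plus the imaging frame rate."""

    segments: tuple[Segment, ...]
    frame_rate: float = DEFAULT_FRAME_RATE
    kind: str = "tonic"  # "tonic" | "impulse"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidConfigError("frame_rate must be positive")
        if self.kind not in ("tonic", "impulse"):
            raise InvalidConfigError(f"unknown schedule kind: {self.kind!r}")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def n_frames(self) -> int:
        return round(self.total_duration * self.frame_rate)

    def segment_onsets(self) -> tuple[float, ...]:
        t, out = 0.0, []
        for s in self.segments:
            out.append(t)
            t += s.duration
        return tuple(out)

    def frame_at(self, t: float) -> int:
        """Nearest frame index to stimulus time ``t`` (frames at k/rate)."""
        return int(round(t * self.frame_rate))

    def window(self, t_start: float, duration: float) -> slice:
        """Frame slice covering [t_start, t_start + duration).

        A one-second window is always ceil(frame_rate) frames so that at
        3 frames/s "the first second" is exactly 3 frames.
        """
        start = self.frame_at(t_start)
        n = math.ceil(duration * self.frame_rate)
        return slice(start, start + n)

    # -- windows used by the scoring module ---------------------------------
    def impulse_onsets(self) -> tuple[float, ...]:
        return tuple(
            t for t, s in zip(self.segment_onsets(), self.segments) if s.label == "impulse"
        )

    def impulse_onset_frames(self) -> tuple[int, ...]:
        return tuple(self.frame_at(t) for t in self.impulse_onsets())


def tonic_schedule(frame_rate: float = DEFAULT_FRAME_RATE) -> StimulusSchedule:
    """The 65-s tonic pitch-tilt protocol (5/15/15/15/15 s at 0/−19/0/+19/0°)."""
    return StimulusSchedule(
        segments=(
            Segment("baseline", 5.0, 0.0),
            Segment("nose_down_tilt", 15.0, -TILT_ANGLE_DEG),
            Segment("horizontal", 15.0, 0.0),
            Segment("nose_up_tilt", 15.0, TILT_ANGLE_DEG),
            Segment("horizontal", 15.0, 0.0),
        ),
        frame_rate=frame_rate,
        kind="tonic",
    )


def impulse_schedule(frame_rate: float = DEFAULT_FRAME_RATE) -> StimulusSchedule:
    """The 65-s impulse protocol: 20 s baseline, 10 ms impulse, 30 s
    horizontal, 10 ms impulse, ~15 s horizontal."""
    # Final segment trimmed by the two impulse durations so the total stays 65 s.
    tail = IMPULSE_TOTAL_S - (20.0 + 30.0 + 2 * IMPULSE_DURATION_S)
    return StimulusSchedule(
        segments=(
            Segment("baseline", 20.0, 0.0),
            Segment("impulse", IMPULSE_DURATION_S),
            Segment("horizontal", 30.0, 0.0),
            Segment("impulse", IMPULSE_DURATION_S),
            Segment("horizontal", tail, 0.0),
        ),
        frame_rate=frame_rate,
        kind="impulse",
    )


# Scoring windows for the tonic protocol, in stimulus time (seconds).
TONIC_BASELINE_DOWN = (0.0, 5.0)     # initial baseline preceding nose-down
TONIC_RESPONSE_DOWN_T = 20.0         # restoration after nose-down tilt
TONIC_BASELINE_UP = (32.0, 35.0)     # last 3 s of the post-nose-down horizontal
TONIC_RESPONSE_UP_T = 50.0           # restoration after nose-up tilt
IMPULSE_BASELINE = (0.0, 20.0)       # 20-s pre-impulse baseline
RESPONSE_WINDOW_S = 1.0              # "first second" read-out
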