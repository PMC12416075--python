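"""Stimulus schedules and well geometry.

A screening run presents each larva with a fixed 3-hour program of
visual and acoustic stimuli divided into consecutive periods.  The
reference protocol used throughout this package is eighteen 10-minute
periods: an unstimulated first hour, two cycles of moving colored
lines (red-slow, green-slow, blue-slow, red-fast), a resting period
(period 15, minutes 140-150) used as the baseline for the acoustic
measures, two periods of acoustic taps at 1-second intervals, and a
final period of taps at 20-second intervals.  Schedules are plain data
and fully configurable; nothing downstream assumes the reference
layout beyond the presence of the periods it needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .errors import ConfigurationError

#: Camera frame interval, seconds.  One image of every well every 6 s.
FRAME_INTERVAL_S = 6.0

VISUAL_COLORS = ("red", "green", "blue")
VISUAL_SPEEDS = ("slow", "fast")
ACOUSTIC_ISIS = (1, 20)
PERIOD_KINDS = ("rest", "visual", "acoustic")

#: Visual stimulus classes scored as separate optomotor features.
VISUAL_CLASSES = (("red", "slow"), ("green", "slow"), ("blue", "slow"), ("red", "fast"))


@dataclass(frozen=True)
class Period:
    """One contiguous block of the presentation.

    Parameters
    ----------
    index
        1-based ordinal within the schedule.
    t_start_min, t_end_min
        Span in minutes from the start of imaging.
    kind
        ``"rest"``, ``"visual"`` (moving colored lines) or
        ``"acoustic"`` (taps at a fixed inter-stimulus interval).
    visual_color, visual_speed, motion_direction_deg
        Required iff ``kind == "visual"``.
    isi_s
        Inter-stimulus interval in seconds, required iff
        ``kind == "acoustic"``; 1 s drives habituation, 20 s probes
        the undiminished startle response.
    """

    index: int
    t_start_min: float
    t_end_min: float
    kind: str
    visual_color: str | None = None
    visual_speed: str | None = None
    motion_direction_deg: float | None = None
    isi_s: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in PERIOD_KINDS:
            raise ConfigurationError(f"unknown period kind {self.kind!r}")
        if not self.t_end_min > self.t_start_min:
            raise ConfigurationError(
                f"period {self.index}: t_end_min must exceed t_start_min"
            )
        visual_fields = (self.visual_color, self.visual_speed, self.motion_direction_deg)
        if self.kind == "visual":
            if any(v is None for v in visual_fields):
                raise ConfigurationError(
                    f"period {self.index}: visual periods need color, speed and direction"
                )
            if self.visual_color not in VISUAL_COLORS:
                raise ConfigurationError(f"unknown visual color {self.visual_color!r}")
            if self.visual_speed not in VISUAL_SPEEDS:
                raise ConfigurationError(f"unknown visual speed {self.visual_speed!r}")
            if not 0.0 <= self.motion_direction_deg < 360.0:
                raise ConfigurationError("motion_direction_deg must lie in [0, 360)")
        elif any(v is not None for v in visual_fields):
            raise ConfigurationError(
                f"period {self.index}: visual fields only allowed on visual periods"
            )
        if self.kind == "acoustic":
            if self.isi_s not in ACOUSTIC_ISIS:
                raise ConfigurationError(
                    f"period {self.index}: isi_s must be one of {ACOUSTIC_ISIS}"
                )
        elif self.isi_s is not None:
            raise ConfigurationError(
                f"period {self.index}: isi_s only allowed on acoustic periods"
            )

    @property
    def span_s(self) -> tuple[float, float]:
        return self.t_start_min * 60.0, self.t_end_min * 60.0

    @property
    def visual_class(self) -> tuple[str, str] | None:
        if self.kind != "visual":
            return None
        return (self.visual_color, self.visual_speed)


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, contiguous periods covering ``[0, total_duration_min)``."""

    periods: tuple[Period, ...]
    total_duration_min: float

    def __post_init__(self) -> None:
        if not self.periods:
            raise ConfigurationError("schedule has no periods")
        expected_start = 0.0
        for ordinal, period in enumerate(self.periods, start=1):
            if period.index != ordinal:
                raise ConfigurationError(
                    f"period indices must be 1-based and consecutive; "
                    f"got {period.index} at position {ordinal}"
                )
            if period.t_start_min != expected_start:
                raise ConfigurationError(
                    f"period {period.index} starts at {period.t_start_min} min, "
                    f"expected {expected_start} (gap or overlap)"
                )
            expected_start = period.t_end_min
        if expected_start != self.total_duration_min:
            raise ConfigurationError(
                f"periods cover [0, {expected_start}) min but total_duration_min "
                f"is {self.total_duration_min}"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_min * 60.0 / FRAME_INTERVAL_S))

    def period(self, index: int) -> Period:
        for p in self.periods:
            if p.index == index:
                return p
        raise ConfigurationError(f"schedule has no period {index}")

    def period_at(self, t_s: float) -> Period:
        """Period containing time ``t_s`` (seconds, half-open spans)."""
        for p in self.periods:
            start, end = p.span_s
            if start <= t_s < end:
                return p
        raise ConfigurationError(f"t={t_s} s outside schedule")

    def visual_periods(self) -> list[Period]:
        return [p for p in self.periods if p.kind == "visual"]

    def acoustic_periods(self, isi_s: int | None = None) -> list[Period]:
        out = [p for p in self.periods if p.kind == "acoustic"]
        if isi_s is not None:
            out = [p for p in out if p.isi_s == isi_s]
        return out


def default_schedule(
    motion_direction_deg: float = 0.0, period_min: float = 10.0
) -> StimulusSchedule:
    """The reference 18-period protocol (10-minute periods, 3 h total).

    Periods 1-6 rest (unstimulated first hour), 7-14 two cycles of
    red-slow / green-slow / blue-slow / red-fast moving lines, 15 rest
    (the acoustic baseline at minutes 140-150), 16-17 acoustic taps at
    1-s intervals, 18 acoustic taps at 20-s intervals.

    ``period_min`` shortens or stretches every period uniformly; the
    reference protocol uses 10-minute periods.
    """
    cycle = list(VISUAL_CLASSES)
    periods: list[Period] = []
    for i in range(1, 7):
        periods.append(Period(i, (i - 1) * period_min, i * period_min, "rest"))
    for j, (color, speed) in enumerate(cycle + cycle):
        idx = 7 + j
        periods.append(
            Period(
                idx,
                (idx - 1) * period_min,
                idx * period_min,
                "visual",
                visual_color=color,
                visual_speed=speed,
                motion_direction_deg=motion_direction_deg,
            )
        )
    periods.append(Period(15, 14 * period_min, 15 * period_min, "rest"))
    periods.append(Period(16, 15 * period_min, 16 * period_min, "acoustic", isi_s=1))
    periods.append(Period(17, 16 * period_min, 17 * period_min, "acoustic", isi_s=1))
    periods.append(Period(18, 17 * period_min, 18 * period_min, "acoustic", isi_s=20))
    return StimulusSchedule(tuple(periods), 18 * period_min)


@dataclass(frozen=True)
class WellGeometry:
    """Circular well, coordinates centered at the origin.

    The length unit is the well radius by convention (``radius=1.0``).
    A frame counts as "edge" when its distance from the center exceeds
    ``edge_fraction * radius``; the default 2/3 makes the outer third
    of the radius the edge annulus.
    """

    radius: float = 1.0
    edge_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("well radius must be positive")
        if not 0.0 < self.edge_fraction < 1.0:
            raise ConfigurationError("edge_fraction must lie in (0, 1)")

    @property
    def edge_radius(self) -> float:
        return self.edge_fraction * self.radius


# -- schedule config file (YAML) ------------------------------------------

def schedule_to_dict(schedule: StimulusSchedule) -> dict:
    periods = []
    for p in schedule.periods:
        d = {
            "index": p.index,
            "t_start_min": p.t_start_min,
            "t_end_min": p.t_end_min,
            "kind": p.kind,
        }
        if p.kind == "visual":
            d.update(
                visual_color=p.visual_color,
                visual_speed=p.visual_speed,
                motion_direction_deg=p.motion_direction_deg,
            )
        if p.kind == "acoustic":
            d["isi_s"] = p.isi_s
        periods.append(d)
    return {"total_duration_min": schedule.total_duration_min, "periods": periods}


def schedule_from_dict(data: dict) -> StimulusSchedule:
    try:
        periods = tuple(Period(**block) for block in data["periods"])
        total = float(data["total_duration_min"])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"bad schedule config: {exc}") from exc
    return StimulusSchedule(periods, total)


def save_schedule(schedule: StimulusSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=False)


def load_schedule(path) -> StimulusSchedule:
    with open(path) as fh:
        return schedule_from_dict(yaml.safe_load(fh))
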