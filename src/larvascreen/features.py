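"""Behavioral parameters computed from a trajectory and its schedule.

The extracted vector has 21 named entries:

======== ==========================================================
label    meaning
======== ==========================================================
act_1h   % of frames moving during the first hour (unstimulated)
P15      % of frames moving during period 15 (minutes 140-150)
Hab      activity in the late 1-s tap period minus P15-period
         activity (habituated response), percentage points
S        activity in the 20-s tap period minus P15-period activity
         (undiminished startle), percentage points
E        activity over all 1-s tap periods minus P15-period
         activity (excitability), percentage points
R,G,B,FR optomotor response per visual class (red/green/blue slow,
         red fast): % of moving frames displacing within +-90 deg
         of the line motion direction, minus 50 (0 = no response)
RGB      mean of R, G and B
Sc_1h    % of first-hour frames in scoot (short-step) movement
Sc_V     same over the union of visual periods
Bu_1h    % of first-hour frames in burst (long-step) movement
Bu_V     same over the union of visual periods
Ed_1h    % of first-hour frames in the edge annulus of the well
Ed_V     same over the union of visual periods
Cw_1h    % of first-hour frames turning clockwise (negative heading
         change in math convention, y up)
Cw_V     same over the union of visual periods
Or       % of frames with upward heading, i.e. in (0, 180) deg
Turn_1h  mean signed per-frame heading change, deg/frame, first hour
Tabs_1h  mean absolute per-frame heading change, deg/frame
======== ==========================================================

Percent-type values live in [0, 100]; Hab/S/E and the optomotor
features are signed percentage points; Turn is signed degrees/frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, SchemaError
from .protocol import StimulusSchedule, VISUAL_CLASSES, WellGeometry
from .tracks import LarvaTrack

logger = logging.getLogger(__name__)

BEHAVIOR_LABELS = (
    "act_1h", "P15", "Hab", "S", "E",
    "R", "G", "B", "FR", "RGB",
    "Sc_1h", "Sc_V", "Bu_1h", "Bu_V",
    "Ed_1h", "Ed_V", "Cw_1h", "Cw_V",
    "Or", "Turn_1h", "Tabs_1h",
)

OPTOMOTOR_LABELS = {"R": ("red", "slow"), "G": ("green", "slow"),
                    "B": ("blue", "slow"), "FR": ("red", "fast")}


@dataclass(frozen=True)
class Thresholds:
    """Kinematic thresholds, in well radii per frame.

    A frame moves when its displacement exceeds ``move``; a moving
    frame is a burst when the displacement exceeds ``burst``, else a
    scoot.
    """

    move: float = 0.02
    burst: float = 0.10


def _wrap180(deg: np.ndarray) -> np.ndarray:
    return -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)


def step_lengths(track: LarvaTrack) -> np.ndarray:
    """Per-frame displacement; frame 0 inherits frame 1's value."""
    if track.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames")
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    return np.concatenate([[d[0]], d])


def moving_mask(track: LarvaTrack, move_threshold: float = Thresholds.move) -> np.ndarray:
    """Boolean per-frame movement mask (frame 0 inherits frame 1)."""
    return step_lengths(track) > move_threshold


def heading_changes(track: LarvaTrack, mask: np.ndarray) -> np.ndarray:
    """Signed heading change on the shortest arc, (-180, 180], for the
    masked frames.

    The change at frame i is measured from frame i-1 (which may lie
    just outside the window); frame 0 has no predecessor and is
    dropped, so the statistics are means over actual transitions.
    """
    if track.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames")
    idx = np.flatnonzero(mask)
    idx = idx[idx >= 1]
    if idx.size == 0:
        raise InsufficientDataError("window has no heading transitions")
    return _wrap180(track.heading_deg[idx] - track.heading_deg[idx - 1])


def window_mask(track: LarvaTrack, window) -> np.ndarray:
    """Frame mask for a window.

    ``window`` is either a half-open ``(t0_s, t1_s)`` pair or an
    explicit boolean mask over frames.
    """
    if isinstance(window, np.ndarray) and window.dtype == bool:
        mask = window
    else:
        t0, t1 = window
        mask = (track.t_s >= t0) & (track.t_s < t1)
    if not mask.any():
        raise InsufficientDataError("window contains no frames")
    return mask


def activity_pct(
    track: LarvaTrack, window, move_threshold: float = Thresholds.move
) -> float:
    """% of window frames on which the larva moved."""
    mask = window_mask(track, window)
    moving = moving_mask(track, move_threshold)
    return 100.0 * float(moving[mask].mean())


def scoot_burst_pct(
    track: LarvaTrack, window, thresholds: Thresholds = Thresholds()
) -> tuple[float, float]:
    """(scoot %, burst %) of window frames.

    Moving frames are partitioned by step length at ``thresholds.burst``;
    each class is expressed as a percentage of all window frames, so
    scoot + burst equals the window's overall moving percentage.
    """
    mask = window_mask(track, window)
    steps = step_lengths(track)[mask]
    moving = steps > thresholds.move
    burst = moving & (steps > thresholds.burst)
    scoot = moving & ~burst
    n = mask.sum()
    return 100.0 * scoot.sum() / n, 100.0 * burst.sum() / n


def occupancy_orientation(
    track: LarvaTrack, window, well: WellGeometry
) -> tuple[float, float, float, float, float]:
    """(Ed %, Cw %, Or %, Turn deg/frame, Tabs deg/frame) over a window.

    Clockwise means a negative heading change in standard math
    convention with y pointing up; image-coordinate data with y down
    must be flipped before ingestion.  "Up" is heading in (0, 180)
    with 90 degrees straight up.
    """
    mask = window_mask(track, window)
    r = np.hypot(track.x, track.y)[mask]
    ed = 100.0 * float((r > well.edge_radius).mean())
    delta = heading_changes(track, mask)
    cw = 100.0 * float((delta < 0.0).mean())
    h = track.heading_deg[mask]
    orient = 100.0 * float(((h > 0.0) & (h < 180.0)).mean())
    return ed, cw, orient, float(delta.mean()), float(np.abs(delta).mean())


def _class_window(track: LarvaTrack, schedule: StimulusSchedule, cls) -> np.ndarray:
    mask = np.zeros(track.n_frames, dtype=bool)
    for p in schedule.visual_periods():
        if p.visual_class == cls:
            t0, t1 = p.span_s
            mask |= (track.t_s >= t0) & (track.t_s < t1)
    return mask


def visual_window(track: LarvaTrack, schedule: StimulusSchedule) -> np.ndarray:
    """Union of all visual periods as a frame mask."""
    mask = np.zeros(track.n_frames, dtype=bool)
    for p in schedule.visual_periods():
        t0, t1 = p.span_s
        mask |= (track.t_s >= t0) & (track.t_s < t1)
    return mask


def optomotor_features(
    track: LarvaTrack,
    schedule: StimulusSchedule,
    move_threshold: float = Thresholds.move,
) -> dict[str, float]:
    """Chance-centered alignment scores R, G, B, FR and their mean RGB.

    For each visual class the score is the percentage of *moving*
    frames whose displacement direction lies within +-90 degrees of
    the lines' motion direction, minus 50.  Zero therefore means no
    optomotor response, +50 perfect following, -50 counter-swimming.
    Scored on displacement, not body heading.
    """
    moving = moving_mask(track, move_threshold)
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    disp_dir = np.degrees(np.arctan2(dy, dx))
    disp_dir = np.concatenate([[disp_dir[0]], disp_dir])

    out: dict[str, float] = {}
    for label, cls in OPTOMOTOR_LABELS.items():
        mask = _class_window(track, schedule, cls)
        if not mask.any():
            continue
        sel = mask & moving
        if not sel.any():
            logger.warning("no moving frames in visual class %s; scoring 0", label)
            out[label] = 0.0
            continue
        direction = None
        for p in schedule.visual_periods():
            if p.visual_class == cls:
                direction = p.motion_direction_deg
                break
        aligned = np.abs(_wrap180(disp_dir[sel] - direction)) <= 90.0
        out[label] = 100.0 * float(aligned.mean()) - 50.0
    if all(k in out for k in ("R", "G", "B")):
        out["RGB"] = (out["R"] + out["G"] + out["B"]) / 3.0
    return out


def acoustic_features(
    track: LarvaTrack,
    schedule: StimulusSchedule,
    move_threshold: float = Thresholds.move,
) -> tuple[float, float, float]:
    """(Hab, S, E): tap-evoked activity changes vs the period-15 baseline.

    With A(w) the moving percentage over window w:
    E = A(all 1-s periods) - A(period 15); Hab = A(last 1-s period)
    - A(period 15); S = A(20-s period) - A(period 15).  All in
    percentage points.
    """
    try:
        baseline_period = schedule.period(15)
    except ConfigurationError as exc:
        raise ConfigurationError("schedule lacks the period-15 baseline") from exc
    fast = schedule.acoustic_periods(isi_s=1)
    slow = schedule.acoustic_periods(isi_s=20)
    if not fast or not slow:
        raise ConfigurationError(
            "schedule must define 1-s and 20-s interval acoustic periods"
        )
    a_base = activity_pct(track, baseline_period.span_s, move_threshold)

    fast_mask = np.zeros(track.n_frames, dtype=bool)
    for p in fast:
        fast_mask |= window_mask(track, p.span_s)
    e = activity_pct(track, fast_mask, move_threshold) - a_base
    hab = activity_pct(track, fast[-1].span_s, move_threshold) - a_base
    slow_mask = np.zeros(track.n_frames, dtype=bool)
    for p in slow:
        slow_mask |= window_mask(track, p.span_s)
    s = activity_pct(track, slow_mask, move_threshold) - a_base
    return hab, s, e


def behavior_vector(
    track: LarvaTrack,
    schedule: StimulusSchedule,
    well: WellGeometry,
    thresholds: Thresholds = Thresholds(),
) -> pd.Series:
    """Assemble the full 21-entry behavioral parameter vector."""
    hour = (0.0, 3600.0)
    vmask = visual_window(track, schedule)
    p15 = schedule.period(15).span_s

    values: dict[str, float] = {}
    values["act_1h"] = activity_pct(track, hour, thresholds.move)
    values["P15"] = activity_pct(track, p15, thresholds.move)
    hab, s, e = acoustic_features(track, schedule, thresholds.move)
    values["Hab"], values["S"], values["E"] = hab, s, e
    values.update(optomotor_features(track, schedule, thresholds.move))
    values["Sc_1h"], values["Bu_1h"] = scoot_burst_pct(track, hour, thresholds)
    values["Sc_V"], values["Bu_V"] = scoot_burst_pct(track, vmask, thresholds)
    ed1, cw1, _, turn1, tabs1 = occupancy_orientation(track, hour, well)
    edv, cwv, _, _, _ = occupancy_orientation(track, vmask, well)
    full = np.ones(track.n_frames, dtype=bool)
    _, _, orient, _, _ = occupancy_orientation(track, full, well)
    values["Ed_1h"], values["Ed_V"] = ed1, edv
    values["Cw_1h"], values["Cw_V"] = cw1, cwv
    values["Or"] = orient
    values["Turn_1h"], values["Tabs_1h"] = turn1, tabs1
    return pd.Series([values.get(k, np.nan) for k in BEHAVIOR_LABELS],
                     index=list(BEHAVIOR_LABELS), name=f"{track.arm_id}/{track.well_id}")


def features_table(
    tracks: list[LarvaTrack],
    schedule: StimulusSchedule,
    well: WellGeometry,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """One row per larva: arm_id, well_id and the 21 feature columns."""
    rows = []
    for track in tracks:
        vec = behavior_vector(track, schedule, well, thresholds)
        rows.append({"arm_id": track.arm_id, "well_id": track.well_id,
                     **vec.to_dict()})
    return pd.DataFrame(rows, columns=["arm_id", "well_id", *BEHAVIOR_LABELS])


def write_features(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    if "arm_id" not in table.columns or "well_id" not in table.columns:
        raise SchemaError("feature table needs arm_id and well_id columns")
    return table
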