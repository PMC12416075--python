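"""Larval trajectories and treatment arms, with flat-file round-trip IO.

A :class:`LarvaTrack` is the per-larva time series the tracker emits:
position and heading sampled every 6 s in well-centered coordinates.
Tracks are exchanged as a single comma-delimited table with the header
``arm_id,well_id,t_s,x,y,heading_deg``, one row per larva per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MalformedTrackError, SchemaError, ConfigurationError
from .protocol import FRAME_INTERVAL_S

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ("arm_id", "well_id", "t_s", "x", "y", "heading_deg")

ARM_ROLES = ("vehicle_control", "single", "combination")


@dataclass
class LarvaTrack:
    """One larva's trajectory: frames at t = 0, 6, 12, ... seconds."""

    arm_id: str
    well_id: str
    t_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading_deg: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading_deg = np.asarray(self.heading_deg, dtype=float)
        n = len(self.t_s)
        if not (len(self.x) == len(self.y) == len(self.heading_deg) == n):
            raise MalformedTrackError(
                f"track {self.arm_id}/{self.well_id}: ragged columns"
            )

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    def validate(self, radius: float | None = None) -> None:
        """Enforce the track invariants; raise with the well named."""
        label = f"{self.arm_id}/{self.well_id}"
        if self.n_frames < 1:
            raise MalformedTrackError(f"track {label}: empty")
        if self.t_s[0] != 0.0:
            raise MalformedTrackError(f"track {label}: must start at t=0")
        steps = np.diff(self.t_s)
        if self.n_frames > 1 and not np.allclose(steps, FRAME_INTERVAL_S):
            raise MalformedTrackError(
                f"track {label}: non-uniform {FRAME_INTERVAL_S:g}-s time step"
            )
        if np.any(self.heading_deg < 0.0) or np.any(self.heading_deg >= 360.0):
            raise MalformedTrackError(f"track {label}: heading outside [0, 360)")
        if radius is not None:
            r = np.hypot(self.x, self.y)
            if np.any(r > radius * (1.0 + 1e-9)):
                raise MalformedTrackError(f"track {label}: position outside well")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm_id": self.arm_id,
                "well_id": self.well_id,
                "t_s": self.t_s,
                "x": self.x,
                "y": self.y,
                "heading_deg": self.heading_deg,
            }
        )


@dataclass(frozen=True)
class TreatmentArm:
    """A treatment group on the plate.

    ``components`` holds (drug name, dose in uM) pairs; the vehicle
    control arm has none.  Exactly one arm per experiment must carry
    ``role="vehicle_control"``.
    """

    name: str
    role: str
    components: tuple[tuple[str, float], ...] = ()
    n_larvae: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ARM_ROLES:
            raise ConfigurationError(f"arm {self.name!r}: unknown role {self.role!r}")
        if self.role == "combination" and len(self.components) < 2:
            raise ConfigurationError(
                f"arm {self.name!r}: combination arms need >=2 components"
            )
        if self.role == "vehicle_control" and self.components:
            raise ConfigurationError(
                f"arm {self.name!r}: vehicle control carries no drug components"
            )


def vehicle_arm(arms: list[TreatmentArm]) -> TreatmentArm:
    vehicles = [a for a in arms if a.role == "vehicle_control"]
    if len(vehicles) != 1:
        raise ConfigurationError(
            f"exactly one vehicle_control arm required, found {len(vehicles)}"
        )
    return vehicles[0]


# -- trajectory table IO ---------------------------------------------------

def write_tracks(tracks: list[LarvaTrack], path) -> None:
    """Write tracks as one delimited table (see module docstring)."""
    if not tracks:
        pd.DataFrame(columns=list(TRACK_COLUMNS)).to_csv(path, index=False)
        return
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(
        path, index=False
    )


def tracks_from_frame(table: pd.DataFrame) -> list[LarvaTrack]:
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trajectory table missing columns: {missing}")
    if table.empty:
        logger.warning("trajectory table is empty; returning no tracks")
        return []
    tracks: list[LarvaTrack] = []
    for (arm_id, well_id), group in table.groupby(
        ["arm_id", "well_id"], sort=True
    ):
        group = group.sort_values("t_s")
        track = LarvaTrack(
            arm_id=str(arm_id),
            well_id=str(well_id),
            t_s=group["t_s"].to_numpy(),
            x=group["x"].to_numpy(),
            y=group["y"].to_numpy(),
            heading_deg=group["heading_deg"].to_numpy(),
        )
        track.validate()
        tracks.append(track)
    return tracks


def read_tracks(path) -> list[LarvaTrack]:
    """Read a trajectory table; validates the 6-s frame grid per track."""
    table = pd.read_csv(path, float_precision="round_trip")
    return tracks_from_frame(table)
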