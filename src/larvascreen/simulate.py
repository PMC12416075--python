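"""Generative model of larval swimming under the stimulus schedule.

The simulator stands in for raw tracking data.  Each larva is a
discrete-time random walker in a circular well, one state update per
6-s frame:

* Movement: with probability ``p_move`` (plus a decaying startle
  boost during acoustic periods) the larva displaces this frame;
  a moving frame is a *burst* (long step) with probability
  ``burst_given_move``, else a *scoot* (short step).  Step lengths are
  fixed per class so the downstream scoot/burst thresholds partition
  frames exactly.
* Heading: wrapped-normal noise, a constant clockwise bias, a pull of
  strength ``optomotor_gain`` toward the motion direction of the
  moving lines during visual periods, and an ``up_bias`` pull toward
  90 degrees.
* Position: displacement along the heading, blended radially outward
  by ``edge_attraction``, reflected at the wall.
* Acoustic startle: each tap adds ``startle_boost`` to the movement
  probability for one frame.  Under 1-s inter-stimulus intervals the
  boost decays geometrically by ``habituation_rate`` per tap
  (habituation); under 20-s intervals it does not (undiminished
  startle).

Drug exposure is modeled as additive offsets on these parameters
(:class:`DrugEffect`); combination arms sum their components' offsets,
optionally scaled by a per-pair interaction multiplier, so synergy in
the downstream report is an emergent measurement rather than an input.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .errors import ConfigurationError
from .protocol import FRAME_INTERVAL_S, StimulusSchedule, WellGeometry
from .tracks import LarvaTrack, TreatmentArm

logger = logging.getLogger(__name__)

_UNBOUNDED = (-math.inf, math.inf)

#: Valid range per parameter; offsets are clamped back into these.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "p_move": (0.0, 1.0),
    "burst_given_move": (0.0, 1.0),
    "scoot_step_mean": (1e-9, math.inf),
    "burst_step_mean": (1e-9, math.inf),
    "turn_sd_deg": (0.0, math.inf),
    "cw_bias": _UNBOUNDED,
    "optomotor_gain": (0.0, 1.0),
    "startle_boost": (0.0, 1.0),
    "habituation_rate": (0.0, 1.0),
    "edge_attraction": (0.0, 1.0),
    "up_bias": (-1.0, 1.0),
}


@dataclass(frozen=True)
class BehaviorParams:
    """Per-larva behavioral parameters (units: well radii, degrees, frames)."""

    p_move: float = 0.25
    burst_given_move: float = 0.30
    scoot_step_mean: float = 0.05
    burst_step_mean: float = 0.15
    turn_sd_deg: float = 35.0
    cw_bias: float = 0.0
    optomotor_gain: float = 0.35
    startle_boost: float = 0.45
    habituation_rate: float = 0.002
    edge_attraction: float = 0.15
    up_bias: float = 0.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            lo, hi = PARAM_RANGES[f.name]
            v = getattr(self, f.name)
            if not lo <= v <= hi:
                raise ConfigurationError(
                    f"{f.name}={v} outside valid range [{lo}, {hi}]"
                )


PARAM_FIELDS = tuple(f.name for f in dc_fields(BehaviorParams))


@dataclass(frozen=True)
class DrugEffect:
    """Additive parameter offsets for one drug.

    ``reference_dose_uM`` makes the offsets dose-scalable: at dose d
    the applied offset is ``offset * d / reference_dose_uM``.  With
    the default ``None`` the offsets apply as-is at any dose.
    """

    name: str
    offsets: dict[str, float] = field(default_factory=dict)
    reference_dose_uM: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.offsets) - set(PARAM_FIELDS)
        if unknown:
            raise ConfigurationError(
                f"effect {self.name!r} names unknown parameters: {sorted(unknown)}"
            )

    def scaled(self, dose_uM: float) -> "DrugEffect":
        if self.reference_dose_uM is None:
            return self
        factor = dose_uM / self.reference_dose_uM
        return DrugEffect(
            name=f"{self.name}@{dose_uM:g}uM",
            offsets={k: v * factor for k, v in self.offsets.items()},
        )


def apply_effects(
    base: BehaviorParams, effects: list[DrugEffect]
) -> BehaviorParams:
    """Sum effect offsets field-wise onto ``base``, clamped to valid ranges."""
    values = {f: getattr(base, f) for f in PARAM_FIELDS}
    for eff in effects:
        for key, delta in eff.offsets.items():
            values[key] += delta
    for key, v in values.items():
        lo, hi = PARAM_RANGES[key]
        clamped = min(max(v, lo), hi)
        if clamped != v:
            logger.warning(
                "parameter %s=%g clamped to %g after drug offsets", key, v, clamped
            )
            values[key] = clamped
    return BehaviorParams(**values)


# -- schedule precomputation ----------------------------------------------

def _frame_context(schedule: StimulusSchedule) -> dict[str, np.ndarray]:
    """Per-frame stimulus context.

    Frame i (i >= 1) is attributed to the period containing its
    capture time t_i; taps are counted over the interval
    (t_{i-1}, t_i].  Contiguous 1-s-interval periods share one
    habituation clock, so the decay carries across their boundary.
    """
    n = schedule.n_frames
    t = np.arange(n) * FRAME_INTERVAL_S
    is_visual = np.zeros(n, dtype=bool)
    motion_dir = np.zeros(n, dtype=float)
    gain_on = np.zeros(n, dtype=bool)
    tap_count = np.zeros(n, dtype=int)   # taps since 1-s block start, 0 = none
    tap20 = np.zeros(n, dtype=bool)

    # start times of contiguous 1-s acoustic blocks
    block_start: dict[int, float] = {}
    current_start = None
    for p in schedule.periods:
        if p.kind == "acoustic" and p.isi_s == 1:
            if current_start is None:
                current_start = p.span_s[0]
            block_start[p.index] = current_start
        else:
            current_start = None

    for i in range(1, n):
        period = schedule.period_at(t[i])
        if period.kind == "visual":
            is_visual[i] = True
            gain_on[i] = True
            motion_dir[i] = period.motion_direction_deg
        elif period.kind == "acoustic":
            start = period.span_s[0]
            if period.isi_s == 1:
                tap_count[i] = int(t[i] - block_start[period.index])
            else:
                isi = float(period.isi_s)
                # a tap falls in (t_{i-1}, t_i] iff a multiple of isi
                # past the period start does
                k_lo = math.floor((t[i - 1] - start) / isi)
                k_hi = math.floor((t[i] - start) / isi)
                tap20[i] = k_hi > k_lo and k_hi >= 1
    return {
        "t": t,
        "is_visual": is_visual,
        "motion_dir": motion_dir,
        "gain_on": gain_on,
        "tap_count": tap_count,
        "tap20": tap20,
    }


def _wrap180(deg: np.ndarray) -> np.ndarray:
    """Wrap angles to the shortest signed arc in (-180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def _simulate_cohort(
    params_list: list[BehaviorParams],
    schedule: StimulusSchedule,
    well: WellGeometry,
    rngs: list[np.random.Generator],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Simulate one cohort; vectorized over larvae, sequential in time.

    Each larva consumes only its own generator, in a fixed draw order,
    so a larva's trajectory does not depend on who shares the plate.
    """
    ctx = _frame_context(schedule)
    n_frames = schedule.n_frames
    m = len(params_list)
    R = well.radius

    def vec(name: str) -> np.ndarray:
        return np.array([getattr(p, name) for p in params_list])

    p_move = vec("p_move")
    bgm = vec("burst_given_move")
    scoot = vec("scoot_step_mean")
    burst_step = vec("burst_step_mean")
    turn_sd = vec("turn_sd_deg")
    cw_bias = vec("cw_bias")
    gain = vec("optomotor_gain")
    sboost = vec("startle_boost")
    hab = vec("habituation_rate")
    edge = vec("edge_attraction")
    up = vec("up_bias")

    # per-larva random streams, fixed draw order
    init = np.stack([rng.random(3) for rng in rngs])          # r, phi, heading
    u_move = np.stack([rng.random(n_frames) for rng in rngs], axis=1)
    u_burst = np.stack([rng.random(n_frames) for rng in rngs], axis=1)
    z_turn = np.stack([rng.standard_normal(n_frames) for rng in rngs], axis=1)

    # startle boost per (frame, larva)
    boost = np.zeros((n_frames, m))
    ones = ctx["tap_count"] > 0
    if ones.any():
        expo = (ctx["tap_count"][ones] - 1)[:, None]
        boost[ones] = sboost[None, :] * (1.0 - hab[None, :]) ** expo
    boost[ctx["tap20"]] = sboost[None, :]

    r0 = 0.7 * R * np.sqrt(init[:, 0])
    phi0 = 2.0 * np.pi * init[:, 1]
    pos = np.stack([r0 * np.cos(phi0), r0 * np.sin(phi0)], axis=1)
    theta = 360.0 * init[:, 2]

    xs = np.empty((n_frames, m))
    ys = np.empty((n_frames, m))
    hs = np.empty((n_frames, m))
    xs[0], ys[0], hs[0] = pos[:, 0], pos[:, 1], theta

    is_visual = ctx["is_visual"]
    motion_dir = ctx["motion_dir"]
    for i in range(1, n_frames):
        d_theta = z_turn[i] * turn_sd - cw_bias
        if is_visual[i]:
            d_theta = d_theta + gain * _wrap180(motion_dir[i] - theta)
        d_theta = d_theta + up * _wrap180(90.0 - theta)
        theta = (theta + d_theta) % 360.0

        p_eff = np.clip(p_move + boost[i], 0.0, 1.0)
        moving = u_move[i] < p_eff
        is_burst = u_burst[i] < bgm
        step = np.where(is_burst, burst_step, scoot) * moving

        rad = np.radians(theta)
        u_head = np.stack([np.cos(rad), np.sin(rad)], axis=1)
        r = np.hypot(pos[:, 0], pos[:, 1])
        safe_r = np.where(r > 1e-12, r, 1.0)
        u_rad = np.where(r[:, None] > 1e-12, pos / safe_r[:, None], u_head)
        d = (1.0 - edge[:, None]) * u_head + edge[:, None] * u_rad
        norm = np.hypot(d[:, 0], d[:, 1])
        bad = norm < 1e-12
        d[bad] = u_head[bad]
        norm[bad] = 1.0
        pos = pos + step[:, None] * d / norm[:, None]

        # reflect at the circular wall
        rn = np.hypot(pos[:, 0], pos[:, 1])
        out = rn > R
        if out.any():
            scale = (2.0 * R - rn[out]) / rn[out]
            pos[out] *= scale[:, None]
            rn = np.hypot(pos[:, 0], pos[:, 1])
            still_out = rn > R
            if still_out.any():
                pos[still_out] *= (R / rn[still_out])[:, None]

        xs[i], ys[i], hs[i] = pos[:, 0], pos[:, 1], theta

    return [(xs[:, j], ys[:, j], hs[:, j]) for j in range(m)]


def simulate_track(
    params: BehaviorParams,
    schedule: StimulusSchedule,
    well: WellGeometry,
    seed: int,
    arm_id: str = "arm",
    well_id: str = "w000",
) -> LarvaTrack:
    """Simulate one larva; bit-reproducible from ``seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    (x, y, h), = _simulate_cohort([params], schedule, well, [rng])
    t = np.arange(schedule.n_frames) * FRAME_INTERVAL_S
    track = LarvaTrack(arm_id, well_id, t, x, y, h)
    track.validate(radius=well.radius)
    return track


# -- plates ----------------------------------------------------------------

#: Relative jitter (lognormal sigma) applied per larva to rate/scale
#: parameters; additive jitter for the signed biases.
_JITTER_SIGMA = 0.08
_JITTER_ADDITIVE = {"cw_bias": 0.3, "up_bias": 0.02}


def _jittered(params: BehaviorParams, rng: np.random.Generator) -> BehaviorParams:
    values = {}
    for name in PARAM_FIELDS:
        v = getattr(params, name)
        if name in _JITTER_ADDITIVE:
            v = v + rng.normal(0.0, _JITTER_ADDITIVE[name])
        else:
            v = v * math.exp(rng.normal(0.0, _JITTER_SIGMA))
        lo, hi = PARAM_RANGES[name]
        values[name] = min(max(v, lo), hi)
    return BehaviorParams(**values)


def _larva_seed_seq(seed: int, arm_name: str, index: int) -> np.random.SeedSequence:
    # stable across arm ordering: keyed by arm name hash, not position
    key = zlib.crc32(arm_name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence(seed, spawn_key=(key, index))


def combined_effect(
    arm: TreatmentArm,
    effect_library: dict[str, DrugEffect],
    interaction: dict[frozenset, float] | None = None,
) -> DrugEffect:
    """Dose-scaled, summed (and optionally interaction-scaled) arm effect."""
    offsets: dict[str, float] = {}
    for drug, dose in arm.components:
        if drug not in effect_library:
            raise ConfigurationError(
                f"arm {arm.name!r}: drug {drug!r} missing from effect library"
            )
        eff = effect_library[drug].scaled(dose)
        for k, v in eff.offsets.items():
            offsets[k] = offsets.get(k, 0.0) + v
    mult = 1.0
    if interaction and len(arm.components) >= 2:
        key = frozenset(d for d, _ in arm.components)
        mult = interaction.get(key, 1.0)
    if mult != 1.0:
        offsets = {k: v * mult for k, v in offsets.items()}
    return DrugEffect(name=arm.name, offsets=offsets)


def simulate_plate(
    arms: list[TreatmentArm],
    effect_library: dict[str, DrugEffect],
    base: BehaviorParams,
    schedule: StimulusSchedule,
    well: WellGeometry,
    n_per_arm: int,
    seed: int,
    interaction: dict[frozenset, float] | None = None,
) -> list[LarvaTrack]:
    """Simulate every arm of a plate.

    Per-larva seeds derive from (seed, arm name, larva index), and
    per-larva heterogeneity is a small seeded jitter on the arm's
    parameters, so results do not depend on arm order and adding an
    arm never perturbs the others.
    """
    t = np.arange(schedule.n_frames) * FRAME_INTERVAL_S
    tracks: list[LarvaTrack] = []
    for arm in arms:
        arm_params = apply_effects(base, [combined_effect(arm, effect_library, interaction)])
        n = arm.n_larvae if arm.n_larvae is not None else n_per_arm
        cohort_params: list[BehaviorParams] = []
        rngs: list[np.random.Generator] = []
        for j in range(n):
            children = _larva_seed_seq(seed, arm.name, j).spawn(2)
            cohort_params.append(
                _jittered(arm_params, np.random.default_rng(children[0]))
            )
            rngs.append(np.random.default_rng(children[1]))
        for j, (x, y, h) in enumerate(
            _simulate_cohort(cohort_params, schedule, well, rngs)
        ):
            tracks.append(LarvaTrack(arm.name, f"w{j:03d}", t, x, y, h))
    return tracks
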