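"""Simulate one larva under the reference protocol and extract its
behavioral parameter vector.

The printed vector has 21 entries: percent-of-time measures (activity,
scoot/burst, edge occupancy, clockwise turning, upward orientation),
tap-evoked activity changes vs the resting baseline (Hab, S, E, in
percentage points) and chance-centered optomotor scores (R/G/B/FR/RGB,
0 = no following of the moving lines, +50 = perfect following).
"""

from larvascreen import (
    BehaviorParams,
    WellGeometry,
    behavior_vector,
    default_schedule,
    simulate_track,
)

schedule = default_schedule()
well = WellGeometry()
params = BehaviorParams()  # an untreated, vehicle-like larva

track = simulate_track(params, schedule, well, seed=1)
print(f"simulated {track.n_frames} frames ({schedule.total_duration_min:.0f} min)")

vec = behavior_vector(track, schedule, well)
print(vec.round(2).to_string())
print(
    "\nact_1h is this larva's spontaneous activity; E/S show the "
    "tap-evoked activity surge and Hab its habituated remnant; "
    "positive R/G/B/FR mean the larva followed the moving lines."
)
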