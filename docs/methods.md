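# Methods

## The assay being modeled

A screen arm is a set of larvae, one per well, exposed to a compound
(or compound pair) and imaged every 6 s for 3 h — 1800 frames per
larva — while an 18-period stimulus program plays. The reference
protocol uses 10-minute periods: 1–6 rest (so all "first hour"
measures are unstimulated baseline), 7–14 two cycles of moving
colored lines (red-slow, green-slow, blue-slow, red-fast), 15 rest
(the designated baseline for the acoustic measures, minutes 140–150),
16–17 acoustic taps at 1-s intervals, 18 taps at 20-s intervals.
Only period 15's role and span and the 1-s/20-s acoustic blocks are
fixed by the assay design; the placement of the visual blocks and the
20-s block is this package's reference choice, and schedules are
fully configurable (including a uniform `period_min` compression used
by the test suite to run the same layout at 1-minute periods).

Coordinates are continuous and well-centered, with the well radius as
the length unit (radius 1.0); there is no pixel or image model. Time
is 0-based seconds with frames at t = 0, 6, …, 10794.

## Feature definitions

All features derive from three per-frame primitives:

- **displacement** d_i between frames i−1 and i; frame 0 inherits
  frame 1's value so per-window percentages are over all frames.
  A frame *moves* if d_i > 0.02 well radii (configurable); a moving
  frame is a *burst* if d_i > 0.10, else a *scoot*. The two
  thresholds match the simulator's fixed step-length classes so the
  scoot/burst partition is exactly recoverable.
- **heading change** δ_i, the shortest signed arc between successive
  headings in (−180°, 180°]. Turning statistics (Cw, Turn, Tabs) are
  means over actual transitions (frame 0, having no predecessor, is
  excluded); this makes Turn exactly antisymmetric under time
  reversal. Clockwise = δ < 0 in standard math convention with y up;
  image-coordinate data (y down) must be flipped before ingestion.
- **radial distance**; a frame is "edge" if r > edge_fraction ×
  radius, default edge_fraction 2/3 (the outer third of the radius;
  under a uniform spatial distribution that annulus holds 5/9 of
  frames, so vehicle Ed values near 55% are expected, not a bug).

Windows: "-1h" features use minutes 0–60; "-V" features the union of
all visual periods; P15 uses period 15. Acoustic features compare
tap-period activity A(w) (percent of frames moving) with the period-15
baseline: E = A(all 1-s periods) − A(P15), Hab = A(last 1-s period) −
A(P15) (the habituated, late-block response), S = A(20-s period) −
A(P15). Optomotor scores are computed on **displacement direction**
(not body heading): per visual class, the percentage of moving frames
displacing within ±90° of the lines' motion direction, minus 50, so 0
means no response and +50 perfect following; RGB = mean(R, G, B).
Whether a published optomotor metric is displacement- or
orientation-based is often unstated, so cross-dataset comparisons of
these scores should be made by sign and ranking, not absolute scale.
Or ("upward orientation") counts headings strictly inside (0°, 180°)
and is computed over the whole track.

## Statistics

Each treatment arm is compared to the single vehicle arm per behavior
with Welch's unequal-variance t-test (two-sided,
Welch–Satterthwaite df; scipy's implementation behind a thin wrapper
that handles the zero-variance degenerate cases explicitly: equal
means → p = 1, unequal means → the p → 0 limit, flagged). Behaviors
may have different effective n (missing entries are dropped
pairwise). Significance is reported in three Bonferroni tiers with
family levels 0.05, 0.01, 0.001 divided by m = the number of
treatment arms (30 in the reference screen) — deliberately *not*
treatments × behaviors; m is a parameter. The test is parametric; no
rank-based alternative is provided.

Synergy uses the mean form of the profile magnitude (mean |delta|
across behaviors) as primary, with the raw sum exposed; the two
differ by the constant n_behaviors, so the percent change is
identical under either. Significant-behavior counts default to tier 1
(p < 0.05/m); the tier is a parameter. Percent changes are reported
at one decimal; internal math is full precision.

Clustering is agglomerative complete linkage on Euclidean distances
between raw delta rows — no standardization, since profile values
already share a percentage-point scale. Ties are broken
lexicographically by the smallest member label, making the tree
deterministic; the implementation is the direct O(n³) algorithm
(ample at screen scale, tens of rows) and is tested for exact height
agreement against an independent brute-force oracle and scipy.
A subtree's "correlation value" is defined here as the mean of all
pairwise Pearson correlations among its leaves — a transparent,
testable cohesion score; desktop clustering tools annotate node
correlations by their own (often undocumented) conventions, so those
numbers are comparable in ranking, not digit-for-digit.

## The generative model

The simulator produces study-shaped data, not a biophysical model.
Each larva is a discrete-time random walker (one update per 6-s
frame) with parameters:

| parameter | unit | default | role |
|---|---|---|---|
| p_move | prob/frame | 0.25 | spontaneous movement rate |
| burst_given_move | prob | 0.30 | burst vs scoot split |
| scoot_step_mean / burst_step_mean | well radii | 0.05 / 0.15 | fixed step lengths bracketing the 0.02/0.10 thresholds |
| turn_sd_deg | deg/frame | 35 | wrapped-normal heading noise |
| cw_bias | deg/frame | 0 | clockwise turning bias |
| optomotor_gain | [0,1] | 0.35 | fraction of heading error toward line motion corrected per frame (visual periods) |
| startle_boost | prob | 0.45 | added to p_move for one frame per tap |
| habituation_rate | per tap | 0.002 | geometric decay of the boost under 1-s intervals (≈600 taps per 10-min period ⇒ the boost decays to ~30% by the end of the first 1-s period; 20-s-interval taps do not decay) |
| edge_attraction | [0,1] | 0.15 | outward radial blend of the displacement direction |
| up_bias | [−1,1] | 0 | pull toward 90° heading |

Positions reflect at the circular wall. The habituation clock runs
continuously across contiguous 1-s periods, so late-block activity
(Hab) is genuinely lower than early-block activity (E) — the contrast
the assay is designed to read out.

Drugs are additive offsets on these parameters, clamped to valid
ranges, defined at a 10 µM reference dose and scaled linearly with
dose; combination arms sum their components' scaled offsets, with an
optional per-pair interaction multiplier (default 1.0). Synergy in
the downstream report is therefore an emergent measurement of the
pipeline, never an input. Per-larva heterogeneity is a small seeded
jitter (lognormal σ = 0.08 on rates/scales; additive on the signed
biases). Reproducibility: per-larva random streams are derived from
(master seed, arm-name hash, larva index), so results are independent
of arm order and adding an arm never perturbs existing ones.

The reference screen preset (31 arms × 30 larvae: vehicle, 14 heart
drugs at 10 µM, their 5 µM combinations with 5 µM CsA, CsA at
5/10 µM; 30 is the smallest per-arm n of the screen it emulates)
assigns CsA the calcineurin-inhibitor signature — raised activity and
excitability, slowed habituation, blunted optomotor response, more
burst movement — and each heart drug a scaled, perturbed variant of
it: strong scaling for the drugs reported to phenocopy CsA, weak for
the rest. These presets are illustrative; no public effect-size
ground truth exists to calibrate them, so tests assert recovery of
*injected* effects (directions, orderings, co-clustering), never
specific published magnitudes.

What the generator does **not** emulate — and hence what passing
tests cannot show about real data: body-shape/keypoint detail and
tracking noise, inter-larva variability beyond parameter jitter,
non-additive pharmacology (unless injected via the interaction
multiplier), circadian or handling effects, and the four additional
measures some published 25-column tables carry beyond the 21
trajectory-level features computed here (e.g. eye-angle measures,
which need keypoints).

## Numerical and design choices

- Windows are half-open `[t0, t1)`; a frame belongs to the period
  containing its capture time; taps are counted over `(t−6, t]`.
- Optomotor classes with no moving frames score 0 with a warning
  rather than NaN, keeping downstream matrices dense.
- Zero-variance profile rows have undefined correlations; they are
  emitted as missing with a warning, and the correlation matrix keeps
  an exact unit diagonal for well-defined rows.
- CSV readers use round-trip float parsing, so write→read is
  bit-exact and pipeline runs are byte-reproducible under a fixed
  seed (verified by manifest content hashes).
- The test suite runs the statistical calibration and recovery suites
  at reduced problem sizes chosen for CI practicality (1-minute
  periods for the null calibration's 1000 arm pairs; n = 200/arm on
  the full protocol for monotone recovery); the full-size reference
  screen itself is run end to end.

## Known limitations

- The Welch test is applied to percent-type features that are bounded
  and mildly discrete; at n = 20–30 per arm its type-I rate is
  empirically nominal (tested), but very small arms may miscalibrate.
- Complete-linkage heights are tested for exact oracle agreement, but
  merge *partners* under exact distance ties depend on the documented
  lexicographic rule and may differ from other tools' trees.
- The simulator's wall reflection preserves step direction, not
  incidence angle, which slightly inflates edge dwell for fast
  movers; edge statistics are therefore compared between arms, not
  interpreted absolutely.
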