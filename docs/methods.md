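# Methods

This note documents the models, conventions and numerical choices behind
`tubeswarm`, and what the synthetic tests do and do not establish about
real tracking data.

## Geometry and region partition

A tube is a simple trapezoid bounded by two straight walls plus the
entrance and exit openings. The tube x-axis is the unit vector from the
entrance midpoint to the exit midpoint (the direction fish leave); the
y-axis follows the right-hand rule. Wall angles are stored signed, measured
*from the wall to the x-axis*, so a symmetric converging tube with opening
angle φ has `theta_l = +φ/2` and `theta_r = −φ/2`; the opening (included)
angle is always `|theta_r − theta_l|` and must lie in [0°, 90°). With this
convention the inward unit normal of the left wall is
`(−sin θ_l, −cos θ_l)` in tube-local coordinates and that of the right wall
is `(sin θ_r, cos θ_r)`; the implementation computes normals geometrically
from the wall segments (rotate the wall direction, orient toward the
trapezoid centroid), which reduces to those closed forms and stays correct
for tubes in arbitrary ambient placement.

The middle region is the exit opening swept along the axis to the entrance
line; the two residual triangles are the left/right edge regions. The three
polygons tile the trapezoid exactly (shapely intersection/difference of the
trapezoid with the mid band), and point classification checks middle first,
then left edge, then right edge, so boundary points deterministically get
the middle label.

The experimental study never published wall coordinates — only each tube's
opening angle — so the eight named fixtures (`tube_fixture("A")` … `"H"`)
are symmetric trapezoids built from the published angles with a default
120 px exit opening and 600 px height, the order of magnitude of the video
setup. Only the opening angle enters any quantitative law, so this choice
affects no fitted or predicted number; it does set the middle-region area
fraction used as the occupancy baseline.

## Frame tables and anomaly handling

Frame tables follow the tracking-export schema: `number, x, y, speed_x,
speed_y, speed, frame` with `speed_x` a magnitude, `speed_y` signed, and
`speed = hypot(speed_x, speed_y)`, all in pixels and pixels/frame. CSV
round trips are lossless at the declared 2-dp precision; full precision is
kept in memory and rounding happens only at serialization.

Trackers occasionally emit self-contradictory rows (the bundled measured
frame contains one: components 641/525 with combined speed 0). A row is
flagged when its recomputed combined speed differs from the stored one by
more than 0.01 after 2-dp rounding, or when a component exceeds a
configurable 100 px/frame ceiling (an order of magnitude above observed
swim speeds). Flagged rows are excluded from region averages, never
repaired: the intended correction is unknowable. Parked lost-track fish
(frozen at an out-of-tube position) are excluded naturally because they
classify as outside.

## Region statistics

Per frame, `ratio_s = V_middle/V_edge` and `ratio_n = N_middle/N_edge`,
with the convention that an empty or zero-mean-speed denominator gives a
ratio of 0 — the convention the measured tables use. Tube summaries average
the *per-frame ratios* over a selected frame window. This mean-of-ratios
choice is pinned by the data: over the measured window {28, 37, 46} it
reproduces the published 1.42, while the ratio of mean speeds gives 1.34.
The frame window is an explicit input (the published analysis chose windows
by inspecting the videos, an inherently manual step); the default is all
frames.

`kde_1d` uses Gaussian kernels with Silverman's rule
(`0.9·min(sd, IQR/1.34)·n^(−1/5)`) when the bandwidth is "auto", matching
the default behaviour of common kernel-density routines. The evaluation
grid pads the data range by six bandwidths so the truncated trapezoidal
integral equals 1 to ~1e-6; degenerate all-equal samples fall back to a
fixed 1 px bandwidth.

## Angle–ratio laws

The linear speed-ratio law is fitted by ordinary least squares of `ratio_s`
on `cos θ`; the exponential count-ratio law by OLS of `ln ratio_n` on
`cos θ` (deterministic, and exactly the model's log-linear form), with
non-positive ratios excluded and reported. The MSE of the exponential law
is computed on the linear ratio scale by default (configurable to the log
scale): the scale used for the published 0.0035 is not recoverable, and
neither is that value itself — the published summary table prints only six
of the eight tubes, so the reference coefficients (1.5033/0.1545 and
3.5971/2.0173) cannot be re-derived from printed data. They are therefore
treated as *reference constants* for prediction, and fitting is validated
by recovery tests on synthetic summaries: noiseless data drawn from the
laws must return the coefficients to 1e-9, and log-normal/Gaussian noise of
σ = 0.05 over 50 angles must recover them within ±0.1. The correlation
r = 0.98 between `ratio_s` and the cosine column *is* reproducible from the
six printed rows and is asserted at 2 dp.

## Movement model

Synchronous discrete-time update with dt = 1 frame:

```
v_i(t+1) = v0·x̂ + v_s,i(t) + v_n,i(t) + v_w,i(t),   p_i(t+1) = p_i(t) + v_i(t+1)
```

- **Field of view**: circular sector of radius `fov_range` and half-angle
  `fov_half_angle` (default 90°, i.e. a 180° field) about the fish's
  heading (normalized velocity; the tube axis when at rest). Front members
  are those not behind the fish along the tube axis.
- **Following** `v_s = 0.5·k·(p_c − p_i)` toward the centroid `p_c` of
  front-of-view members; zero when none.
- **Nearest neighbour** `v_n`: repulsion `−k·(p_n − p_i)` when the nearest
  perceived fish is closer than `d1`, attraction `+k·(p_n − p_i)` beyond
  `d2`, zero in between (`d1 < d2`; the equation's zone layout is used
  where prose and equation disagree). Ties in nearest distance break to
  the lowest id; an empty field of view contributes nothing.
- **Wall avoidance** `v_w`: when the perpendicular distance `d_w` to the
  nearer wall is ≤ `d3`, a push of magnitude `b·d_w` along that wall's
  inward normal. The printed right-wall direction vector is not orthogonal
  to the wall under the signed-angle convention (its x-component's sign is
  inconsistent with the accompanying description of a normal, away-from-
  wall push); the implementation uses the exact inward normal, which both
  printed vectors equal once the wall-tilt magnitude is used. Note the
  push *weakens* as the wall gets closer (it is proportional to `d_w`);
  this is implemented as specified, and containment in practice comes from
  the push acting over the whole 18 px band.

Fish whose tube-local x reaches the exit are marked passed: they stop
influencing and receiving dynamics and stay in the emitted frames frozen at
their crossing position with zero speed (mirroring how trackers park lost
fish, and keeping the per-frame row count constant).

### Parameters

| name | default | unit | origin |
|------|---------|------|--------|
| `v0` | 3 | px/frame | free; matches observed swim speeds (~5–12 px/frame combined) |
| `k`  | 0.1 | 1/frame | free; keeps interaction velocities bounded at tube scales |
| `b`  | 0.8 | 1/frame | published |
| `d1`, `d2` | 12, 36 | px | free; ~3 and ~9 body-heights, `d1 < d2` required |
| `d3` | 18 | px | published |
| `fov_half_angle` | 90 | deg | published 180° field |
| `fov_range` | 200 | px | free; a body-lengths-scale perception radius |
| `n_fish` | 30 | – | published simulation size |
| `init_wall_margin` | 5 | px | free; see below |

Initialization divides the `n_fish` between middle and edge regions
according to the count-ratio law at the tube's angle (rounded to the
nearest integer split, edges split evenly with the odd fish on the left),
places them uniformly in the assigned polygons by rejection sampling, and
draws headings down-tube with 15° Gaussian spread; edge fish start at speed
`v0` and middle fish faster by the speed-ratio law. Because the wall push
vanishes as `d_w → 0`, a fish initialized essentially touching a converging
wall near the exit can be carried across it by the forward drive before the
push acts; initial placement therefore keeps `init_wall_margin` (about one
body width — fish are not points) of wall clearance. With that margin, runs
of 1000 steps at `v0 ≤ 5` never cross a wall across the seeds and angles
exercised in the tests.

## Synthetic data

`generate_frames` realizes an exact integer middle/edge split every frame
(counts are noise-free by construction — count ratios recover exactly) and
draws speeds per region from a zero-truncated normal whose means are in the
requested `target_ratio_s` proportion. `generate_summary_dataset` draws
tube summaries from the two laws with additive Gaussian noise on the linear
law and log-scale Gaussian noise on the exponential one, matching each
law's fitting model.

What passing these tests shows: the arithmetic, classification, averaging
and fitting chain is correct, and the movement model's emergent occupancy
exceeds the uniform baseline. What they do not show: robustness to real
tracking pathologies beyond the single glitch pattern modelled (identity
swaps, missed detections, lens distortion), nor that the movement model's
free parameters are calibrated to any particular species.

## Problem sizes

The test suite simulates 30 fish for up to 1000 steps over 5 seeds at three
angles (the containment/occupancy property), checks field-of-view
membership against a brute-force oracle on 10^4 random configurations, and
uses 10^5 Monte-Carlo points for the area oracle — sizes at which the
stochastic checks are decisive while the whole suite stays fast. The
acceptance script uses the same sizes.
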