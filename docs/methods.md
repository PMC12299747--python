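# Methods

This note records the models, conventions and design choices behind
`seggrade`, in the spirit of a package reference manual: what is
computed, under which assumptions, and where the edges are.

## Morphometry

**Rectangle model.** Each class (cap, stalk) is reduced to its largest
8-connected component — smaller satellites are treated as segmentation
speckle, though their presence feeds broken detection — and fitted with
the minimum-area *rotated* rectangle. An axis-aligned box would carry no
orientation and could not drive the upright alignment step, so the
rotated rectangle is the only self-consistent choice. The fit models the
rasterized object as the convex hull of its pixel centers dilated by a
half-pixel **disk**: at every orientation this adds exactly 1 px to each
rectangle side, so an object 40 rasterized pixels wide measures 40 px
whether it lies axis-aligned or diagonal. The alternative pixel-square
(corner) model is rotation-*variant*: it inflates diagonal objects by an
extra ~0.4 px per side, which at stalk scale (~20 px diameter) pushes
the RLDS error to the tolerance edge at 45° poses. Implementation:
`scipy.spatial.ConvexHull` for the hull, `shapely.buffer(0.5)` for the
dilation, `shapely.minimum_rotated_rectangle` for the fit; tests check
it against an independent rotating-calipers sweep in 0.1° steps.

**Angle convention.** Degrees in `[-90, 90)`, measured from the image
x-axis to the rectangle's long side; origin top-left, y down. One
convention everywhere, enforced by `normalize_angle` and exercised by
fixtures at known poses.

**Orientation inference.** The cap of this species is reliably wider
than tall, so the cap rectangle's long side is the diameter `D1` and the
short side the height `H`; the short-side axis deviates from image
vertical by exactly the long side's angle from horizontal, which is the
mushroom's tilt. When `|D1 − H| < 1 px` the rule cannot orient the cap;
the stalk rectangle's long axis is used as the vertical reference
instead and a warning is recorded.

**Stalk measurement in the upright frame.** The stalk's length is
defined directionally, not by magnitude: after upright alignment, the
rectangle side whose axis is closer to vertical is `L`, the
perpendicular side `D2` (a squat stalk with `L < D2` is legal). At an
exact 45° tie, `L` is taken as the long side — the anatomically common
case — with a warning. The upright stalk rectangle is obtained by
*transforming* the rectangle fitted on the original mask (rotating its
orientation by the negative tilt), not by re-fitting on a rotated
raster. The two are mathematically equivalent for a rigid rotation, but
the raster route resamples labels nearest-neighbor and jags the stalk
edges at diagonal tilts, inflating `D2` by 1–2 px; the transform route
is exact. `rotate_upright` (nearest-neighbor, canvas-expanding) remains
available for visualization and is property-tested for label and
pixel-count conservation.

**Units.** All dimensions are pixels. The grading indexes are ratios,
so the pipeline needs no mm-per-pixel calibration; a fixed camera
distance on the line plays the same role.

## Grading

Bands are half-open `[lo, hi)` so boundary ownership is deterministic
(1.5 belongs to the band it opens). RLDS bands must tile `(0, ∞)`
because RLDS settles every decision; RDHP bands may stop short — the
default top band ends at 2.5, and values beyond it yield `rdhp_grade =
None`, which the conflict rule resolves to the RLDS grade. Criteria
round-trip through YAML and are validated for gaps, overlaps and
coverage on load.

Broken detection is a three-test rule on the label mask: cap absent,
stalk absent, or either class splitting into ≥ 2 connected components
that each hold at least 10% (configurable) of the class's pixels.
Smaller fragments are speckle, not breakage. A label map carries no
instance identities, so a second mushroom in frame is indistinguishable
from a fragmented one; the pipeline assumes single-file feeding (one
specimen per frame) and the fragmentation test catches violations as
`BROKEN`.

## Synthetic fixtures

The renderer replaces belt photography plus a trained segmenter with an
analytic model: cap = half-ellipse of width `D1` and height `H` (flat
side down), stalk = `D2 × L` rectangle attached beneath the cap's
midpoint, tucked 2 px under the cap rim (stalk takes label priority in
the overlap) so the classes stay contiguous while the stalk's drawn
length is exactly `L`. Pixel membership is evaluated in the upright
local frame after inverse rotation, so arbitrary poses introduce no
resampling noise into the ground truth. Optional Gaussian blur and
brightness shifts degrade the *image* only, emulating motion blur and
uneven lighting; the ground-truth mask is rendered before noise.

Dataset sampling defaults: cap height 26–40 px, stalk diameter
14–22 px, pose uniform over 360°, and index values drawn inside each
grade's band with a 0.1 inset from the edges, so a fixture's true grade
is robust to the ~1 px rasterization uncertainty of the measured
dimensions. Grade-3 fixtures keep `D1 ≥ H` (RDHP sampled from 1.1–1.6):
in this species the third grade is defined by its elongated stalk, which
the RLDS-prevails rule captures — not by an inverted cap. Grade counts
are apportioned largest-remainder, exact to ±1. One top-level seed
drives all sampling; identical specs render byte-identical files.

What passing on fixtures does *not* show: robustness to real-world
segmentation failure modes (occlusion, soil, touching specimens,
textured caps) or to a trained network's boundary errors. The fixtures
validate the measurement geometry and the decision logic, and the
reference color segmenter validates the mask contract, on inputs whose
truth is known exactly.

## Metrics

Pixel metrics take a `(k+1)×(k+1)` confusion matrix over k object
classes plus background (included by default, excludable by flag): PA =
trace/total, MPA = mean row accuracy, MIoU = mean of
`p_ii / (row_i + col_i − p_ii)`. Precision/recall/F1 accept instance or
pixel counts (same arithmetic; the mode flag documents provenance).
Grading accuracy is the unweighted mean of per-grade correct rates,
reported to 2 decimals with round-half-up — matching how grading tables
are conventionally printed. Note that a mean of *printed* 2-decimal
group accuracies can differ from the mean of unrounded rates in the last
digit; `mean_reported_accuracy` performs the former deliberately.
Aggregation across images is micro (summed confusion) with per-image
macro available by averaging caller-side.

## Sorting kinematics

Parameters (SI): pump pressure `P` (default 0.80 MPa), tube radius `r`
(4 mm), belt friction coefficient `μ` (0.10), mushroom mass `m` (30 g,
a typical specimen), `g` = 9.80 m/s², blow duration `Δt0` (1 ms),
initial lateral speed `Vy0` (0), belt speed `Vx` (0.10 m/s) and belt
width `W` (0.20 m). `π` defaults to 3.14 — engineering worked examples
for this rig round π, and reproducing their printed digits requires the
same rounding; `"exact"` selects full precision. The belt width is
named `W` to avoid colliding with the tube cross-section `S`.

The impulse is `F·Δt0` with `F = P·S` (the only dimensionally consistent
reading — a pressure times a time is not a momentum). Crossing starts at
belt center (lateral travel `W/2`) under constant friction acceleration
of magnitude `a = μg`. Two sign conventions are provided:
`friction_decelerates` (default; physically, friction opposes the slide)
with stall detection when `Vy1² < 2a·W/2`, and `as_printed`, where
friction adds speed, retained to reproduce worked examples using that
convention. Closed forms are verified against a `dt = 10⁻⁵ s` step
integrator to better than 0.1%.

A consequence worth stating because intuition inverts it: the along-belt
displacement `X = Δt1·Vx` *decreases* with `Vy1` and *increases* with
`μ` and with mass — a harder blow (or lighter mushroom, or slicker belt)
crosses the belt faster and therefore rides it a shorter distance. The
displacement envelope over a mass range evaluates both extremes and
returns them sorted; with fixed impulse the heaviest mushroom lands
farthest along the belt.

## Problem sizes and numerical choices

The acceptance script and tests use a 300-fixture balanced set for
round-trip recovery, 100 random convex blobs (≤ 64×64 px) for the
rectangle oracle, a 100-point parameter sweep for the integrator check,
and 10⁴ random ratio pairs for the grading properties — sizes at which
every rate of interest is stable to well under a percentage point across
seeds. Hypothesis property tests run derandomized. Tolerances: rectangle
sides to ±1–2 px against generating parameters, ratios to 5% relative,
oracle areas to 1%, kinematics to 0.1%.

## Known limitations

* Caps are modelled as convex half-ellipses; strongly irregular or
  concave cap silhouettes would loosen the `D1`/`H` readout.
* The color reference segmenter assumes a near-black background and
  saturated class colors; it is a fixture instrument, not a field
  segmenter.
* The kinematics ignore aerodynamic drag, jet spreading, tumbling and
  actuator delays; it is the same rigid-body, constant-friction
  idealization used to size collection boxes, not a CFD model.
* No mm calibration: absolute sizes are reported in pixels only.
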