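# Methods

## The device being modelled

The package targets a robotic extrusion-bioprinting printhead that cures
a photocurable hydrogel ink (reference formulation: 5% w/v GelMA +
0.5% w/v LAP) *during* deposition. Eight 405 nm LEDs are wired as four
couples (two LEDs in parallel per couple, ≈30 mW each, 60 mW per couple)
mounted at the cardinal azimuths 0°, 90°, 180°, 270° around the needle,
10.6 mm from its axis, on a slider that sets the LED–substrate distance
anywhere between 1 and 15 mm. The control convention throughout is the
machine (printer-bed) frame: polar angle θ measured counterclockwise from
the +x axis.

## Direction-aware scheduling

For every path segment the XY projection of the displacement defines a
unit versor and its angle θ. The plane is divided into eight 45° sectors
**centred** on the principal directions k·45° (k = 0…7), with half-open
boundaries `[k·45° − 22.5°, k·45° + 22.5°)`; a boundary angle belongs to
the sector whose lower boundary it is. Centred sectors make cardinal and
diagonal behaviour symmetric: a segment within ±22.5° of an axis is
treated as axis-aligned. Sector k maps to code k+1 by default; the map is
a configurable bijection (`SectorConvention.code_map`) because the
sector↔wiring assignment is a property of how a particular head is
cabled, not of the algorithm.

The active couples are those *behind* the motion: an even (cardinal)
sector lights the single couple at `(k·45° + 180°) mod 360°`; an odd
(diagonal) sector lights the two cardinal couples adjacent to the
opposite direction. This guarantees, for every active azimuth *a* and
direction θ in the sector, `cos(a − θ) ≤ cos(112.5°)` — active light
always comes from the trailing half-plane.

Scheduling policy for moves without a usable direction: travel moves and
degenerate segments (pure-Z, zero XY length) **hold** the previous LED
state rather than switching off, avoiding mid-layer flicker and
needless switching between strands; segments before the first directed
print move get code 0 (off). An `off_on_travel` option switches the LEDs
off during travels instead. Two dialect extensions exist for codes:
0 = all off and 9 = all on (the control configuration). A trailing
`M102 P0` is emitted at path end by default so a finished print never
leaves LEDs on.

## G-code dialect

Only linear motion is accepted (`G0`/`G1` with `X Y Z F E`), absolute
coordinates, `;` comments, and `M102 P<n>`; arcs and relative mode raise
a parse error naming the line, because the upstream planner emits linear
segments only and silent linearization would change the schedule. Feeds
are mm/min on the wire and mm/s in memory. A move is a print move iff it
is a `G1` whose `E` word advances the extruder axis. The `M102` for a
move precedes its motion line (the controller must switch LEDs before
the motion starts; the alternative — after — would lag by one segment),
and consecutive duplicate codes are suppressed. Coordinates are written
with three decimals, so round trips are exact to 5·10⁻⁴ mm.

## Cure-depth model

Curing follows the photopolymerization working curve

    C_d = D_p · ln(E / E_c),

with defaults `D_p = 0.61 mm`, `E_c = 0.48 mJ/mm²` for the reference
ink. The exposure delivered by a spot of diameter `w_0` (mm) and power
`P_L` (mW) scanning at `v_s` (mm/s) is modelled as

    E = κ · P_L / (w_0 · v_s)   [mJ/mm²],

where the dimensionless prefactor κ absorbs the irradiance profile and
dwell geometry of the real optics. Rather than asserting a profile we do
not know, κ is **calibrated** from one measured operating point of the
device (`calibrate_kappa` inverts the working curve); the package default
κ ≈ 1.397 reproduces a cure depth of 0.34 mm at the device's
shallowest-curing condition — one 60 mW couple, `w_0 = 20 mm` (maximum
slider distance), `v_s = 5 mm/s`. With κ = 1 the same expression gives
0.136 mm; any user with their own calibration point can re-derive κ for
their optics.

The spot diameter is interpolated linearly between the two measured
endpoints, 10 mm at 1 mm slider distance and 20 mm at 15 mm; no other
points are available, and a cone-beam model would add parameters without
data to fit them. Cure depths below gelation (`E ≤ E_c`) are clamped to
0 and flagged `no cure` instead of raising, so a batch report over a
whole path stays total.

`check_cure_path` verifies `C_d ≥ layer thickness` per print segment,
using the segment's feed as `v_s` and doubling `P_L` on diagonal
segments (two couples in parallel — the couples are electrically
independent, so powers add). It reports the worst segment; since
`C_d` is monotone decreasing in speed and spot size, the slowest check
to pass is always the fastest segment at the largest distance.

## Exposure simulation

Each active couple illuminates a uniform (top-hat) disk of diameter
`w_0` on the substrate; irradiance `P/(π(w_0/2)²)`. Top-hat keeps the
closed-form checks (a stationary dwell deposits exactly `I·t` on interior
cells); a Gaussian profile is not modelled.

**Spot-centre geometry.** The LEDs sit 10.6 mm from the needle, but they
are aimed at the deposition zone — if each spot were centred vertically
under its LED, no light would ever reach either the fresh strand at the
nozzle or the needle (spot radius ≤ 10 mm < 10.6 mm offset), which
contradicts both the device's purpose and its observed failure mode
(immediate clogging with all LEDs on). The spot centre is therefore
placed a small configurable distance — default 3 mm — from the needle
toward the active couple's azimuth: the spot covers the just-deposited
strand behind the needle, and the needle itself lies inside the spot,
which is exactly why lighting fewer couples matters. The 10.6 mm
mechanical offset remains in the hardware config for users who want the
strict under-the-LED geometry (under it, all needle-exposure totals are
zero).

**Deposition numerics.** A segment's sweep is discretized into nodes
spaced half a grid cell apart; each node deposits its dwell share over
the disk's *exact* per-cell overlap areas, computed from the closed-form
circle–rectangle intersection (corner-area decomposition). Because every
node's areas sum to exactly `π(w_0/2)²`, the grid conserves emitted
energy to machine precision whenever spots stay inside the grid, for any
node spacing; refinement only sharpens the spatial distribution. Cells
geometrically disjoint from a disk receive exactly zero. The grid export
formats are a CSV matrix and a plain-text (P2) PGM grayscale image.

**Needle exposure.** The needle is a point on the nozzle axis (optionally
a cylinder radius). Since the spots ride with the nozzle, a couple
exposes the needle iff the spot-centre offset is within the spot radius;
the incident energy integrates irradiance over each move's dwell
(travels included — the LEDs stay on between strands under the default
policy). `compare_schedules` reports the A/B energy ratio, flagging a
zero denominator as infinite. On axis-aligned paths the directional
schedule yields exactly ¼ of the all-on control's needle energy; with
diagonals it rises toward ½, always strictly below 1.

## Characterization analyses

Swelling percent is `100·(W_i − W_0)/W_0` (scale-invariant; negative =
deswelling). Replicate series sharing a time grid are summarized as
mean ± sd per time point; the plateau time is the first time point after
which the mean drifts slower than 0.5 percent-points/hour on **every**
later interval. The 0.5 %/h default separates the rise (several %/h at
the typical time constant ≈1 h) from the plateau (<0.2 %/h) of saturating
curves on the usual 0.5–24 h sampling grid.

The elastic modulus is the least-squares slope (scipy `linregress`) of
stress (kPa) vs strain (fraction, validated to the 0–30% test range)
over a linear window. When no window is given, it is chosen
automatically as the **widest contiguous run with r² ≥ 0.99**, ties
broken toward higher strain so a contact toe is excluded; this rule is a
documented stand-in for the usual by-eye selection of the "linear
portion". Strain may be supplied in percent with an explicit unit flag.

## Synthetic paths

The generators emulate the slicer output the device consumes, not real
anatomy:

* `gen_grid_monolayer` — one-layer crosshatch (x-serpentine then
  y-serpentine) filling the bounding box, the parameter-optimization
  geometry (default 20 × 20 × 0.2 mm).
* `gen_multilayer_square` — N layers of rectilinear infill alternating
  0°/90°, the characterization sample (default 6 layers, 20 × 20 mm,
  0.2 mm layers, 50% infill).
* `gen_spherical_cap_infill` — the planar pattern draped over a
  spherical cap (strands subdivided ≈ every 1 mm, Z following the
  surface; layers offset vertically, an approximation to constant normal
  offset valid for the gentle curvatures involved), a stand-in for
  non-planar anatomical-defect paths. Depths beyond the 15 mm the LED
  slider can follow set `meta["depth_warning"]`.

Infill spacing is `line_width / infill_fraction` (0.4 mm nominal strand
width from the 0.4 mm needle → 0.8 mm at 50%); row-end connectors are
print moves (continuous extrusion); every path starts with a travel from
the machine origin so G-code serialization is lossless. What the
fixtures do **not** emulate: extrusion dynamics (die swell, strand
collapse), surface scanning/reconstruction, or real defect geometry —
passing tests demonstrate correctness of scheduling, curing arithmetic
and exposure bookkeeping, not print fidelity on tissue.

## Problem sizes and defaults used in the shipped checks

The test suite and the acceptance script run the 20 × 20 mm fixtures at
grid cells of 1.0 and 0.5 mm and sub-segment node spacing of half a
cell; the six-layer cure check covers ~300 segments. These sizes keep
the raster sums well-resolved (spot radius ≥ 10 cells) while the whole
suite runs in seconds.

## Known limitations

* No photon transport: no scattering, reflection, shadowing by the
  needle, or absorption by added dyes; exposure maps are geometric.
* κ is a lumped calibration constant; it silently absorbs any systematic
  error in the linear spot-size model.
* Cure check treats segments independently — no accumulation of exposure
  from neighbouring strands or layers (conservative for overlap,
  optimistic for very sparse infill at the gelation threshold).
* The scheduler is purely geometric; LED switching latency and the
  controller's command pipeline are not modelled.
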