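# Methods

## The measurement model

The sagittal bow of the femoral shaft is modeled as a plane curve — the
central line of either the cortical outline or the medullary canal on a
lateral radiograph — summarized by circle fits: one radius for the whole
measured span and one per equal-arc-length third (proximal, middle,
distal). The model assumes the traced borders are roughly parallel curves
bounding a simply connected strip (no crossings, no forks), that the bone's
projection onto the detector plane is the quantity of interest (no
out-of-plane correction), and that a circle is an adequate local summary of
each third — the fit's RMS orthogonal residual is reported so users can
judge that adequacy per case.

## Endpoint construction

The measured span is delimited anatomically. Distally, the line through the
two operator-marked shaft/condyle junctions cuts the canal borders; when a
wiggly border crosses it more than once, the most distal crossing is taken.
Proximally, the cut through the lesser-trochanter point is the direction
making equal acute angles with the local tangents of the two cortical
borders. This is solved by scanning candidate directions in 0.5° steps over
±60° around the perpendicular to the lower border's tangent, then bisecting
each sign change of the signed acute-angle difference to ≤ 0.05°; among
multiple roots the one nearest the perpendicular is kept. Two degenerate
regimes are handled explicitly: with locally parallel borders every
direction qualifies and the perpendicular itself is returned; on noisy
hand-traced borders the tangent estimates fluctuate by more than the solver
tolerance, so the nearest-perpendicular crossing is kept and the residual
logged rather than raised. Border tangents are total-least-squares line
fits over a window of 21 vertex spacings (configurable) — wide enough to
average vertex jitter, short relative to the bone's curvature.

## Central-line extraction

The two trimmed borders act as seed sets on a raster with `supersample`
grid cells per image pixel (default 2) and grow at the same speed into the
strip they bound; the meeting locus is the central line. Equal-speed
isotropic growth is realized as the nearest-seed partition under the exact
Euclidean distance transform: a cell belongs to territory 1 iff it is
nearer to border 1, exact ties form the boundary. This is mathematically
the same meeting condition as iterative equal-rate dilation but
deterministic and order-independent; a chamfer (4/8-connected) metric was
rejected because its anisotropy biases fitted curvature by several percent.
The domain is the interior of the ring formed by the rasterized borders
(8-connected Bresenham curves) closed by the two straight end lines, filled
with 4-connected hole filling (which cannot leak through an 8-connected
boundary).

Meeting points are the midpoints of opposing 4-neighbor cell pairs plus
exact-tie cells. They are ordered by greedy nearest-neighbor chaining,
started from the point closest to the proximal end line, with a 3-grid-cell
jump tolerance; leftover points farther than the tolerance from the chain
indicate a disconnected locus and abort the extraction. The chained points
are smoothed with a 5-point moving average (the raster boundary is
stair-stepped) and mapped back to pixel coordinates. Each midline carries
its equidistance residual — the maximum over points of the difference
between exact distances to the two borders — as a per-case quality figure
(≤ 1 px at supersample 2 on clean phantoms).

## Circle fitting and units

Radii come from an algebraic least-squares (Kåsa) circle fit followed by a
geometric refinement minimizing orthogonal distances (Levenberg–Marquardt,
started from the algebraic solution, on centroid-centered and scaled
coordinates for conditioning). An all-points fit was chosen over a
three-point circle because the latter is noise-fragile. Collinear input
(rank-deficient normal system) raises a straight-segment error naming the
segment; finite but huge radii (> 1e5 px) are flagged "near-straight"
instead. The midline is resampled to 300 uniform arc-length intervals
before fitting, and the thirds are cut by arc length (robust to the
non-uniform spacing of raster meeting points), sharing their boundary
points. Millimetre radii are pixel radii × pixel spacing ÷ magnification;
magnification defaults to 1.0 (no correction) since radiographic projection
enlargement is usually uncalibrated — users who calibrate can pass their
factor.

## Reliability statistics

The reliability metric is the coefficient of variation of each repeat
group: sample SD (n−1 denominator, verified against the published
per-subject table, which only reproduces with n−1) over the mean, computed
per (subject, structure, part) and summarized by min/max/mean. Group
summaries are sample mean ± SD; with equal repeat counts per subject the
mean of per-subject means equals the mean of raw repeats, so aggregating
the per-subject table reproduces the pooled statistics. Two-group
comparisons use Welch's unequal-variance t-test, two-sided — no test is
canonical for this design and Welch is the safer default; it is labeled as
such in output. In the packaged transcription of the published per-subject
table, the proximal/distal column labels are stored in the reconciled
(swapped) form because the pooled means only match the published grouped
summary under the swap; the as-printed labeling remains available.

## Synthetic phantoms

The generators emulate the *annotations* the method consumes — border
polylines and operator points — not radiograph intensities, since the
pipeline never touches pixels' gray values. The hockey-stick phantom's
centerline is three tangent-continuous circular arcs of equal arc length;
borders are normal offsets, hence exactly concentric arcs, so each
segment's true midline radius equals the requested one in closed form.
Defaults are the study-like conditions: per-segment radii (752, 1379, 599)
mm, 110 mm measured segment length (≈ 330 mm shaft), cortical width 27 mm
and canal width 13 mm (typical adult mid-shaft diameters), 0.15 mm/px
pixel spacing. Tracing noise is isotropic Gaussian jitter on border
vertices; repeat sets re-jitter borders *and* the three operator points
(snapped back onto the traced curves, as a user clicks on what they drew)
and run the full pipeline per repeat. What passing phantom tests does not
show about real radiographs: borders there are not exact parallel offsets,
tracing error is not i.i.d. Gaussian (observers err systematically at
overlapping anatomy), and the true bow is not piecewise-circular — so
phantom recovery bounds method error, not total clinical error.

## Numerical choices and problem sizes

- Resampling to uniform arc length iterates to the equal-chord fixed point
  (≤ 8 passes, 1e-9 relative tolerance) so resampling is idempotent.
- Point-to-polyline distances use a KD-tree on vertices with an exact
  segment-distance check over a ±12-segment window — exact for the smooth,
  densely sampled curves used here.
- Line–polyline intersection counts a vertex lying on the line once
  (tolerance 1e-9 × coordinate scale) and interior crossings by strict sign
  change.
- Exact distance ties in the territory partition are assigned to the
  boundary set, not to either territory.
- Validation problem sizes: the noiseless recovery grid runs 15 full-scale
  phantoms (radii 300–2000 mm × widths 20–40 mm; worst-case error 1.3%,
  within the 2% bound), and the reliability simulation runs 100 phantoms ×
  3 repeats at full scale with 1 px jitter, measuring the cortical outline.
  Per-phantom reliability is summarized as the mean CV over the four parts.
  Short-arc circle fits are resolution-limited: at coarser-than-native
  pixel spacing the correlated raster residue biases the middle-third
  radius by several percent, which is why recovery claims are made at the
  study's native 0.15 mm/px.

## Known limitations

- The measured CV under pure 1 px vertex jitter (mean ≈ 0.014) sits near
  the low end of the range observed with human observers, whose re-tracing
  error includes correlated, larger-scale deviations; the simulation shows
  the observed range is attainable, not that it is reproduced.
- The equal-angle construction assumes a single sensible crossing of the
  candidate line with the upper border near the cut; grossly folded
  tracings violate this.
- Euclidean (straight-line) distance stands in for geodesic distance
  within the strip; for anatomically plausible, gently curved strips the
  nearest border point is always visible, so the two coincide.
- No 3-D reconstruction: out-of-plane rotation of the femur shortens the
  apparent bow and is not corrected.
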