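# Methods

This note records how each metric is computed, the defaults and why, what
the synthetic surfaces do and do not emulate, and the numerical choices
made where the underlying protocol is open to interpretation.

## Model preparation

Meshes arrive as geometry-only Wavefront OBJ (`v`/`f` records; `v/vt/vn`
face syntax accepted, texture and material data discarded; polygons
fan-triangulated). Coordinates are metres after `scale_to_reference`, which
applies one isotropic factor derived from a single reference length
(quadrat corner-to-corner = 2√2 m for a 2 m quadrat). Anisotropic scaling
is refused: one scalar reference cannot determine per-axis factors.
`orient_to_plane` applies a rigid rotation + translation so the quadrat
lies in the X–Y plane, one corner at the origin, edges along +X/+Y
(right-handed, Z up). Rigidity is testable: areas and pairwise distances
are preserved to 1e-9 relative.

## Linear rugosity

A transect is a segment in the X–Y plane; the contour is the intersection
of the mesh with the vertical plane through it, reduced to its **upper
envelope**: where the surface is multi-valued over a station (overhangs),
only the highest branch is kept, because nadir-view photogrammetry cannot
reconstruct overhangs anyway and a height-surface contour keeps the chain
well defined. Intersection gaps are bridged by straight chords. Vertical
walls appear as exact vertical jumps in the polyline.

Chain laying is chord marching: from the current node, the next node is
the *first* point forward along the polyline at straight-line distance
exactly one link (2 cm default) — the geometry of rigid links, not
arc-length spacing. Tangential ties resolve to the farther parameter.
The extendible chain covers the whole contour; its draped length counts
full links plus the *exact* terminal chord to the contour endpoint rather
than rounding to whole links, removing a ±2 cm quantisation bias. The
fixed-length chain lays exactly `chain_length / link_length` links (1 m /
2 cm default) from the contour start (the minimum along the cutting
direction — a deterministic stand-in for a diver's choice of start point)
and errors if it runs off the contour. Both report R = draped/undraped
≥ 1, the classic rugosity orientation; the quadrat summary lays 3 chains
per direction at ¼, ½, ¾ of the side (6 chains) and averages, and the
chain-and-tape comparison helper averages a transect with parallel offsets
at ±4 cm.

Accuracy of the marcher is checked against an independent scan-and-bisect
oracle on 10⁵-segment analytic polylines (semicircle, sinusoid) at 1e-6,
and against closed forms in the small-link limit (semicircle R → π/2).

## Fractal dimension

`project_height_grid` drops a blanket of δ-spaced points: nodes sit at
integer multiples of δ from the analysis region's min corner, and each
records the highest intersection of a vertical line with the mesh (NaN
over holes). `quilt_area` joins each complete cell's corners into two
triangles along the SW→NE diagonal and sums their areas. The diagonal is
fixed because its choice moves rough-cell areas in the 4th decimal; fixing
it makes results bit-reproducible.

All resolutions are evaluated over one common region, and S(δ) is
normalised to it: quilt area / planar footprint of complete cells ×
region area. Two reasons. First, grid registration makes a coarse lattice
cover less of the region (δ = 1.2 m covers 1.44 m² of a 4 m² quadrat), so
raw areas would confound roughness with footprint. Second, cells touching
a hole are excluded from numerator *and* denominator, so missing data do
not bias the area ratio downward. With this normalisation S(δ) is
non-increasing in δ on single-valued surfaces, and a plane gives S = the
region area at every δ.

Band dimension: D = 2 − (log S_fine − log S_coarse)/(log δ_fine −
log δ_coarse) over adjacent resolution pairs ordered coarse→fine
(1.20–0.60 … 0.05–0.01). The sign convention is the one for which a plane
gives D = 2 and surfaces lie in [2, 3]; out-of-range values are returned
as computed (they flag a band that is not power-law-like), never clamped.
A δ larger than the region extent is dropped with a warning; a δ between
extent/2 and extent rests on a single cell and is kept with a warning —
the 1.2 m resolution on a 2 m quadrat necessarily works this way.

## Vector dispersion

The 1 cm height grid is triangulated with the same SW→NE rule; each
triangle contributes the directional cosines of its unit normal, flipped
to cos_z ≥ 0 (a height surface has a well-defined up; unoriented normals
cancel spuriously). Triangles are unweighted — on an equal-spacing grid
areas are nearly equal and the statistic's plain sums match. Zero-area
triangles are dropped with a warning and the count decremented.
1/k = (i − R₁)/(i − 1) ∈ [0, 1], 0 iff all normals coincide.

The default analysis window is a centred 1.6 × 1.0 m rectangle along X
(area 1.6 m²). The averaging region's exact shape is a protocol detail the
upstream method leaves open; the window is a plain argument and is echoed
in the result so no run is ambiguous.

Symmetry caveat: rotating a surface by 180° about Z maps grid nodes and
cell diagonals onto themselves, so 1/k is invariant to 1e-9. A 90°
rotation maps the fixed SW→NE diagonal onto the other diagonal; on rough
terrain this shifts 1/k at the ~1e-2 level. That is the cost of the
bit-reproducible diagonal choice, not an arithmetic error.

## Accuracy and precision statistics

Linear accuracy: 100·(1 − |m − t|/t). Fractal accuracy: 100·(1 − |m − t|/
(t − 1)), because surface D only varies over [2, 3] and errors should be
scored against that one-unit range. Neither is clamped below zero.
Summaries are mean ± sample SD (n − 1): the sample denominator is the one
that reproduces the published ±SD figures from per-structure accuracy
triples. Comparisons with printed 2-decimal values use round-half-even.

Replicate precision: CV = 100 · mean(per-quadrat sample SD) / mean(all
measurements). By this formula the CV of perfectly repeatable quadrats is
0 regardless of between-quadrat differences.

The bundled reference dataset (`REFERENCE_VALIDATION_PAIRS`) carries the
(ground truth, underwater model) D and 1/k pairs for three concrete-cast
validation structures. One published digit is not recoverable from it: the
0.15–0.05 m band's printed spread is ±2.01, but the printed pairs imply a
sample SD of 2.0175 → 2.02 under every standard convention; the published
value was evidently computed on unrounded D values the printed table no
longer carries. Tests assert the recomputed 2.02 and say why.

## Synthetic surfaces

Generators are pure functions of (parameters, seed) and emit single-valued
surfaces — no overhangs, matching what nadir photogrammetry can capture.
They emulate geometry only: no reconstruction noise, texture artefacts,
water-column blur, or mesh holes (holes are exercised separately through
constructed grids). A green test on them establishes that the *metrics*
are computed correctly, not that any particular camera protocol is
accurate.

The fractal generator is diamond-square on a (2ⁿ + 1)² lattice with
level-l displacement SD `relief · side · 2^(−H·l)`: halving the lateral
scale shrinks the vertical scale by 2^H, the scaling of fractional
Brownian relief whose graph has dimension 3 − H. Defaults were fixed by a
regime study *before* the recovery tests were written, varying relief
∈ {0.5, 0.75, 1.0, 1.5}·side and n_levels ∈ {7, 8}: the area-based
estimator recovers 3 − H only where roughness is self-similar (vertical
increments comparable to lateral scale across the band), and the finest
recovery band (0.15–0.05 m) needs a lattice step well under 0.05 m.
`relief = 0.75` and `n_levels = 8` (lattice step 7.8 mm) put H ∈
{0.2, 0.5, 0.8} at mid-band errors of −0.10, −0.07, +0.00 respectively;
the residual negative bias at low H is the estimator's, not the
generator's (the surface gradient at band scale is finite, so the measured
slope undershoots the asymptotic one). These defaults are the stated test
world; analyses wanting reef-like relief should pass `relief ≈ 0.05–0.15`.

Block scenes emboss cuboids on a plane: top faces plus vertical walls,
giving exact point-to-point ground truths and rectangular-step contours
whose draped length is span + 2 × height up to link discretisation.

## Known limitations

- Overhangs are reduced to their highest surface; metrics on genuinely
  multi-valued terrain (ledges, caves) describe the visible-from-above
  envelope only.
- Chain marching and cross-sectioning are exact for the polyline geometry
  but O(n) per link in the contour size; 10⁵-point contours are fine,
  10⁷-point contours are not the intended use.
- The fixed-chain start point and the six-chain grid offsets are
  deterministic conventions; field protocols that position chains by eye
  will differ within the precision the replicate CV quantifies.
- Fractal-dimension recovery on synthetic terrain is band-averaged and
  seed-averaged; single bands on single seeds scatter by ~±0.1.
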