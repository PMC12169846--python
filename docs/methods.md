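# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gliamorph`. It is the design record for the package; the
numbers it mentions are all recomputed by the test suite or by
`scripts/acceptance.py`, never asserted from memory.

## Scientific setting

Microglia — the brain's resident macrophages — remodel developing neural
circuits, in part by physically engulfing axon terminals. In the developing
hypothalamus, maternal high-fat diet confined to lactation (MHFD-L) has been
reported to transform microglia in the paraventricular nucleus (PVH) of
postnatal day 16 (P16) mice toward a larger, more ramified state (+44% Sholl
branching complexity, +87% total process length, roughly doubled cell volume
and convex-hull territory) while the arcuate nucleus (ARH) and the bed
nucleus of the stria terminalis (BST) are comparatively resistant (ARH:
+67% process length from P16 to P30 under normal chow; BST: +61% increase
in AgRP terminal density over the same interval; microglial density roughly
halves with age in all three regions). These printed group contrasts are
the quantitative targets the synthetic study embeds and the measurement
chain must recover.

`gliamorph` reimplements the measurement chain of such studies as an open,
tested pipeline: per-cell 3D morphometry (Sholl profile, process length,
cell volume, convex-hull territory, density), Mexican-hat (LoG) terminal
detection, distance-rule engulfment classification (contact ≤ 1 µm from the
microglial surface; internalized > 0.5 µm inside), intracellular CD68
volume, and per-animal group statistics. Because the underlying animal data
cannot be regenerated from a manuscript, validation rests on a synthetic
confocal-volume generator with complete ground truth.

## Coordinate conventions

All physical quantities are micrometres, axis order `(z, y, x)`, 0-based
voxel indices, and the centre of voxel `i` at `(i + 0.5) · voxel_size`.
The default rendering voxel size mirrors a 40× confocal stack at 0.1 µm
z-step, (0.1, 0.155, 0.155) µm; the simulation studies below use coarser
isotropic 0.4 µm voxels (see *Problem sizes*).

## The cell growth model

A microglial cell is a rooted tree grown from a soma of radius 3.2 µm:

| parameter | default | meaning |
|---|---|---|
| `n_primary_processes` | 6 | trunks leaving the soma (Fibonacci-spread directions, randomly rotated) |
| `segment_length_mean` | 6.0 µm | mean arc length of one branch segment (Gamma, CV 0.25, truncated to [0.5, 1.5]× mean) |
| `branch_probability` | 0.95 | chance a branch end bifurcates (while below `max_branch_order`) |
| `max_branch_order` | 3 | depth of bifurcation |
| `tortuosity` | 0.2 | direction-diffusion rate per 1 µm growth step |
| `process_radius` | 0.6 µm | proximal tube radius, tapering ×0.85 per order |
| `soma_radius` | 3.2 µm | soma ball radius |

The defaults give total process lengths of ≈230 µm with ≈10% cell-to-cell
CV and arbor radii of ≈25 µm — a compact, reliably ramified arbor. Real
P16 microglia branch more variably; the tighter spread was chosen so that
group means are informative at the study's per-group n of 8 animals, and is
a stated idealization of the generator, not a claim about biology.

Randomness is *path-keyed*: every branch owns an RNG substream keyed by
(cell seed, path from soma), and each branch draws its bifurcation uniform
and unit-Gamma length before any direction noise. Consequences that the
package exploits deliberately:

* total ground-truth length is exactly linear in `segment_length_mean` at
  fixed seed (branch topology and unit lengths are unchanged), and
* two presets compared under the same seeds form a paired (common random
  numbers) simulation design, so embedded contrasts are realized with very
  small sampling error at 8 scenes per group.

Sholl complexity is controlled by `tortuosity`: the area under the Sholl
profile equals the total radial variation of the arbor, which is bounded by
total length and decreases as paths become more tangential. Increasing
tortuosity therefore lowers Sholl AUC at fixed length — the lever used to
decouple the +44% complexity contrast from the +87% length contrast.

## Preset calibration

`calibrate_presets` performs deterministic 1-D bisection per printed
contrast: `segment_length_mean` for length targets (converges essentially
immediately because of exact linearity), `tortuosity` for the Sholl-AUC
target at the already-calibrated length, and `spot_density` for terminal
density, where the statistic *is* the parameter. Ground-truth statistics
are evaluated on 48 paired seeds; tolerance ±5% relative. Unreachable
targets raise an error naming the parameter stuck at its bound. The MHFD-L
tube radius is then scaled analytically so cell volume (≈ soma + π r² L)
doubles. Calibration is validated out-of-sample on 200 fresh cells.

Parameters the study does not print are chosen once as plausible values:
microglial density 4000 cells/mm³ at P16 (halved at P30). This is below
typical in-vivo Iba1 densities; it was set so whole arbors fit the
simulated ROI without pervasive overlap, which is what per-cell morphometry
assumes. Terminal spot densities are ~1–2.6 puncta per 1000 µm³ (countable
at the 0.8 µm spot scale), contact/engulfed fractions 10–15%/3–5%, CD68
15–30 µm³ per cell.

## Scene rendering

Four channels (microglia, terminals, CD68, nuclei) are rendered as:
tube-and-soma rasterization of skeletons into an int label volume (lower
cell id wins at overlaps); terminals as Gaussian blobs of FWHM =
`spot_diameter` (default 0.8 µm); CD68 as hard spheres placed inside somas;
nuclei at somas plus cosmetic background nuclei. Each channel is convolved
with a separable anisotropic Gaussian PSF (σ = (0.35, 0.12, 0.12) µm —
typical confocal anisotropy; exact optics are out of scope) on a 0.03
background, then Poisson noise at `photon_scale` (default 60 photons at
unit intensity) and Gaussian read noise (σ 0.01) are applied. Rendering is
bit-deterministic given (preset, shape, voxel size, seed); a master seed
spawns per-scene substreams by fixed arithmetic.

Spot ground truth is placed by rejection sampling against the same signed
distance field the classifier uses (positive outside, negative inside,
half-voxel surface convention): engulfed at depth ≥ 0.8 µm (margin over the
0.5 µm rule; with 0.6 µm tubes, only somata are deep enough, which matches
the biology of somatic lysosomal digestion), contacts in the band
[−0.40, +0.90] µm, free beyond 1.3 µm — every band keeps a margin from the
classification thresholds so labels are unambiguous on the voxel grid.
Spots respect a 1.1 µm minimum separation (resolvable at the LoG scale)
and a 1.25 µm ROI margin (keeps blob mass inside the volume). Ground-truth
per-cell length is the generative arc length clipped to the ROI box.

## Measurement chain

**Segmentation.** Otsu threshold per channel within the ROI (override
available), floored at median + 8·1.4826·MAD of the channel — with sparse
foreground, plain Otsu can split the Poisson-skewed background mode and
flood the mask. After 3³ closing and removal of components < 30 µm³,
soma markers (distance-transform peaks ≥ 1.5 µm deep, ≥ 8 µm apart) drive
a watershed split of components containing multiple somas; components with
no soma marker are dropped as debris. Cells whose soma lies inside the ROI
are kept even if processes exit (unbiased counting without edge
correction).

**Skeletonization.** 3D thinning (scikit-image) of each cell mask; if
thinning deletes a symmetric even-width object outright (an implementation
hazard of the thinning algorithm), the mask is re-thinned after a 2³
dilation, which flips the width parity at a ≤ half-voxel centreline shift.
Skeleton voxels are linked over 26-connectivity with physical edge lengths,
reduced to a minimum spanning tree and spurs < 1 µm pruned. Two geometry
levels are then measured: total process length on the voxel path after a
*single* Laplacian relaxation pass (one pass removes grid roughness —
which would otherwise let noise inflate the length — without straightening
genuine curvature, to which tortuous cells are differentially sensitive),
and Sholl/territory on the fully relaxed polyline (three passes; residual
zigzag inflates crossing counts). Soma and tips stay fixed during
relaxation. The soma node is the skeleton voxel nearest the interior
distance-map maximum; node radii are distance-map values. Total process
length excludes the part of the tree inside the estimated soma ball,
matching the generative definition.

**Sholl analysis.** Exact transversal segment–sphere crossings per radius
(quadratic roots on each edge, half-open parameter interval so shared
endpoints are not double counted; tangencies do not count), radius step
1 µm. Because the scalar "ramification complexity" of commercial software
is not further specified, both the profile AUC (trapezoidal) and the peak
intersection count are reported; AUC is the headline.

**Territory.** Convex hull (Qhull) of skeleton nodes; degenerate
(collinear/coplanar) node sets return volume 0 with a flag rather than an
error. Cell volume is mask voxel count × voxel volume (soma included), and
`territory ≥ volume` is deliberately not asserted — thin voxelized cells
can violate it.

**Spot detection.** Scale-normalized LoG at σ = diameter/(2√3) per axis in
voxel units (anisotropy-aware); 26-connected local maxima above a two-stage
adaptive threshold: noise level from the signal-free negative response
side, then Otsu over responses above 6× that level (plain Otsu fails when
puncta are sparse). Plateau maxima collapse to the lowest flattened index;
centroids are refined by per-axis quadratic fits clamped to ±0.5 voxel.
Puncta closer than about half a diameter merge into one detection — the
resolution limit of the filter, demonstrated in the tests.

**Engulfment classification.** Signed distances are interpolated from
anisotropic inside/outside distance transforms. Labels: engulfed
< −0.5 µm, contact in [−0.5, +1.0] µm, free beyond. The contact rule is
one-sided in the original description; shallow-interior spots (0 to 0.5 µm
deep) are assigned to contact so the distance axis is partitioned without
an unlabeled gap. Distance is centre-to-surface by default;
edge-to-surface (centre distance minus spot radius) is a flag. Ownership
goes to the cell with the nearest surface, ties to the lower cell id.

**CD68.** Otsu threshold computed within a 1 µm cell-dilated neighbourhood
(background otherwise dominates the histogram), intersected with each cell
mask, × voxel volume.

**Statistics.** Cells are averaged per animal before testing ("each point
is one animal"); SEM is across animals. Two groups: unpaired two-sided
Student t-test (pooled variance; Welch by flag); zero-variance degeneracy
handled explicitly (equal means → t=0, p=1; unequal → flagged). 2×2
designs: two-way ANOVA with Type-II sums of squares (the common default for
main effects when no interaction priority is stated), Tukey HSD on the four
cell means using the studentized-range distribution with the harmonic mean
of cell sizes when unbalanced. Stars: *p<0.05, **p<0.005, ***p<0.0005.
Both tests are calibrated under the null (type-I error within [0.04, 0.06]
at α=0.05 over 2000 simulations) in the test suite.

## Problem sizes

The recovery studies use 8 scenes (≙ animals) per condition: 64×80×80 µm
ROIs at isotropic 0.4 µm voxels for morphometry (≈1–2 cells per scene at
the P16 density) and 40×56×56 µm ROIs for terminal density (≈200 puncta
per scene). These sizes keep a full acceptance run in minutes on one CPU
while leaving every stage of the measurement chain non-trivial; the
generator itself supports the full 0.1 µm-z acquisition geometry.

## What the synthetic validation does and does not show

Passing recovery tests show that the measurement chain is unbiased enough,
at realistic SNR and geometry, to recover group contrasts of the reported
magnitude through segmentation, thinning, graph extraction, LoG detection
and distance classification — including the systematic errors those steps
introduce (boundary clipping, skeleton digitization, watershed splits,
detection merges). They do not certify performance on real tissue: the
generator has no bleed-through, no vasculature or autofluorescence, no
tissue deformation, soma-homogeneous CD68, spherical somas, and
non-overlapping arbors by construction. Density presets are deliberately
sparse (see above). Manual steps of the original workflow (ROI drawing on
the nuclear channel, manual AgRP soma counting) are inputs here, not
reimplemented claims.

## Other design notes

* Interior spots can only be "deep" inside somata given 0.6 µm process
  radii; engulfed ground truth therefore concentrates at somata.
* `segment_microglia` exposes `exclude_boundary` (default off) for
  workflows that drop boundary-touching components; the default follows the
  soma-inside rule used for density.
* The pipeline manifest contains no timestamps, so rerunning an identical
  config/seed reproduces its hash bit-for-bit; stage timing goes to logs.
* The two-stage LoG threshold can admit false positives on volumes that
  contain no true puncta at all (the tail Otsu then splits noise); pass an
  absolute `response_threshold` for such blank-field applications.
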