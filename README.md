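# gliamorph

Open, tested 3D image-analysis pipeline for microglial morphometry and
microglia–axon-terminal interaction in developing brain tissue, together
with a synthetic confocal-volume generator that makes every stage of the
pipeline verifiable against ground truth without any imaging data.

## Who this is for

Studies of developmental synaptic pruning quantify, from multichannel
confocal stacks of hypothalamic nuclei (PVH, ARH, BST): microglial shape —
Sholl branching complexity, total process length, cell volume, convex-hull
territory, cell density — and microglial handling of AgRP axon terminals —
punctum density, contacts, engulfment, lysosomal CD68 content. Those
measurements are usually locked inside commercial software (filament
tracing, spot detection, surface rendering). `gliamorph` reimplements the
chain as an inspectable Python library with a validation harness.

## The measurements

* **Sholl profile** `n(r)`: exact transversal crossings of the skeleton
  tree with concentric spheres of radius `r = k·Δr` about the soma
  (segment–sphere quadratics, not voxel sampling); summarized as the
  profile AUC `∫ n(r) dr` and the peak `max_r n(r)`.
* **Total process length** `L = Σ edge lengths` of the pruned skeleton
  tree (µm; soma ball excluded), after 3D thinning, MST graph extraction
  and spur pruning.
* **Cell volume** (mask voxels × voxel volume) and **territory** (convex
  hull volume of skeleton nodes); **density** in cells/mm³.
* **Terminal detection**: scale-normalized 3D Laplacian-of-Gaussian
  (Mexican hat) at σ = d/(2√3) per axis for puncta of diameter d
  (default 0.8 µm), sub-voxel centroids at local maxima.
* **Engulfment rule** on the signed distance `s` from a punctum centre to
  the nearest microglial surface (negative inside): engulfed `s < −0.5 µm`,
  contact `−0.5 ≤ s ≤ 1 µm`, free otherwise; per-cell intracellular CD68
  volume by thresholded-mask intersection.
* **Statistics** on per-animal means: unpaired Student t-tests, 2×2
  two-way ANOVA (Type-II SS) with Tukey HSD (studentized range), stars at
  p<0.05 / 0.005 / 0.0005.

The generator grows stochastic branching-tree microglia, renders 4-channel
stacks (microglia / terminals / CD68 / nuclei) with anisotropic Gaussian
PSF and Poisson + read noise, and emits complete ground truth. Condition
presets are *calibrated* so the embedded group contrasts match the reported
biology: +87% process length and +44% Sholl complexity in the PVH at P16
under maternal high-fat diet during lactation, +67% ARH process length and
+61% BST terminal density from P16 to P30, and microglial density halving
with age. See `docs/methods.md` for the model and every default.

## Worked example

Render two scenes per condition, measure them, and compare groups (the
numbered drivers under `analysis/` run exactly this):

```bash
python analysis/01_simulate_scenes.py --n-scenes 2 --seed 1
python analysis/02_microglia_morphometry.py
python analysis/03_terminal_engulfment.py
python analysis/04_group_statistics.py
```

`02` prints, for the 2-scene demo (11 cells total):

```
per-condition means (measured):
              total_process_length  sholl_auc  cell_volume  territory_volume
condition
arh_p16_ncd                  211.9      158.3        378.4           10410.6
arh_p30_ncd                  368.9      237.5        543.1           21245.4
pvh_p16_mhfd                 404.8      235.2        589.7           21124.4
pvh_p16_ncd                  211.9      157.3        377.9           10378.1

PVH P16 MHFD-L vs NCD: length +91% (embedded +87%), Sholl AUC +50% (embedded +44%)
```

i.e. the full measurement chain (segment → skeletonize → measure) applied
to rendered volumes recovers the contrasts the generator embedded; lengths
are µm, volumes µm³. `03` reports terminal densities (puncta per 1000 µm³)
and engulfed fractions per condition, ending with
`BST terminal density P30 vs P16: +62% (embedded +61%)`, and `04` runs the
per-animal t-tests:

```
PVH P16: MHFD-L vs NCD [total_process_length]: +93%  t=26.96, p=0.0014
PVH P16: MHFD-L vs NCD [sholl_auc]: +52%  t=8.41, p=0.014
ARH NCD: P30 vs P16 [total_process_length]: +75%  t=12.07, p=0.0068
```

(2 scenes per group is a demo; the dispersion around the embedded values
shrinks at the 8-scene design used below.) Tables land in `results/`,
volumes in `scratch/scenes/`. A `gliamorph` CLI with `simulate / morpho /
spots / interact / stats / run` subcommands wraps the same stages for
file-based use, driven by a YAML config with a deterministic hash and a
reproducible run manifest.

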