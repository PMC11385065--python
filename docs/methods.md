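# Methods

This note documents the models, parameters and numerical choices behind
`renalmorph`, and what the synthetic-data tests do and do not establish.

## Physical calibration

All lengths in configuration are micrometers; conversion to pixels happens
in exactly one place, `microns_to_pixels`, using round-half-away-from-zero.
This convention is load-bearing: a 50 µm window at the x20 pixel size of
0.5056 µm/px is 50/0.5056 = 98.89 px and must come out as 99 px so that
window and tile geometry agree across magnifications (x40: 0.2519 µm/px).
Coordinates are 0-based; boxes and intervals are half-open `[x0, x1)`,
which removes off-by-one ambiguity in tiling, clipping and merging.

## Pipeline model and assumptions

1. **Tissue detection.** A pixel is tissue iff its luminance (Rec. 601-style
   weights as implemented by `skimage.color.rgb2gray`, scaled to 0–255) is
   below a threshold (default 230; Otsu optional). Assumes a bright,
   near-white background, as in scanned H&E slides.
2. **Sliding-window segmentation.** Windows of `window_um` (50 µm) tile the
   tissue bounding box at 50 % overlap. The stride guarantees that any
   object smaller than half a window is interior to some window, so
   fragments discarded at a window border (area < `border_discard_area_um2`,
   default 100 µm² — fragments whose class a segmenter cannot determine
   reliably) reappear intact in a neighboring window.
3. **Merging.** Two same-class instances intersect "strongly" when their
   intersection over the *smaller* area (IoMin) reaches `merge_iou_min`
   (0.5). IoMin rather than IoU is deliberate: structures larger than the
   window (every glomerulus, at 100–150 µm) are always fragmented, and two
   adjacent-window fragments of one structure have IoU ≈ 1/3 at 50 %
   overlap but IoMin ≥ 0.5 by construction. Merging is transitive
   (connected components via union–find over the pairwise graph of the
   original instances), which makes the result order-independent and
   idempotent; merged scores take the max over parents, and the output is
   sorted canonically by (class, y0, x0).
4. **Stroma derivation.** Stroma = tissue ∖ structures, clipped to the ROI.
   The proper stromal space is the rim of `proper_stroma_width_um` around
   the structure union, computed with a Euclidean distance transform so the
   ring is isotropic and calibration-independent. The default width is
   15 µm, the lower bound of the physiologic 15–20 µm range; it is
   configurable because the literature gives only the range. Everything
   else of the stroma is the fibrosis-eligible compartment.
5. **Cell detection.** Candidates are dark pixels inside stroma ∪ proper
   rim (configurable to exclude the rim), below min(Otsu-within-stroma,
   180). The 180 cap prevents the threshold from drifting into the stromal
   background tone when few dark objects are present. Touching cells are
   split by watershed on the distance transform with markers at local
   maxima (min separation 3 µm). Per object, a moment-based ellipse gives
   the semi-axes; classification: *lymphocyte* iff axis ratio < 2 AND mean
   gray < 95 AND equivalent diameter in 4–10 µm; otherwise *nucleus* if the
   equivalent diameter is in 4–15 µm; otherwise discarded. The size gates
   are package defaults (the classification is stated to use size and
   color, but no printed sizes exist to adopt).
6. **Infiltration.** A fixed (non-sliding) grid of `infiltration_tile_um`
   (50 µm) tiles, anchored at the ROI bounding-box origin, is scanned by
   cell centroid counts: a tile is infiltrated iff it holds
   ≥ 2 lymphocytes and ≥ 20 detected cells. "20 nuclei" is read as 20
   nuclei of any kind — a lymphocyte nucleus is a nucleus — with the strict
   reading (20 non-lymphocyte nuclei) available as
   `count_lymphocytes_as_nuclei=False`. The infiltration mask is the union
   of flagged tiles intersected with the fibrosis-eligible stroma, so
   infiltration ⊆ fibrosis always holds, matching the clinical observation
   that fibrosis area bounds infiltration area.

## Evaluation metrics

* Dice uses the confusion-count form 2TP/(2TP+FN+FP); two empty masks score
  1.0 by convention (flagged in the docstring). Bands: > 0.8 good, 0.6–0.8
  acceptable, < 0.6 bad.
* The confusion matrix is pixel-level (columns = ground truth, rows =
  predicted, column-normalizable). Instance-level accounting was
  considered and rejected as under-specified; pixel accounting is the
  reproducible default.
* AP matches predictions to truths greedily in descending score (ties:
  larger IoU first, then input order) at each IoU threshold
  0.50:0.05:0.95, with the all-point interpolated PR curve (the precision
  envelope), and averages over thresholds; mAP averages over classes,
  excluding classes absent from both prediction and truth (recorded as
  undefined). Empty truth with predictions scores 0.

## ROC analysis

Positives are slides with score ≥ 2. The curve sweeps all distinct feature
thresholds with the decision rule value ≥ cutoff → positive; AUC is the
trapezoid area, which the tests verify equals the Mann–Whitney
concordant-pair fraction (ties ½). The Youden-optimal cutoff maximizes
sens + spec − 1; because "Youden's J" is sometimes reported in feature
units and sometimes as the dimensionless statistic, `RocResult` carries
both under distinct names (`optimal_cutoff`, `youden_j_max`) and never
conflates them. Cohorts scanned at different magnifications are pooled —
features are relative areas, which are calibration-free.

## Synthetic slide generator

The generator emulates what the pipeline measures, not what a pathologist
sees. A slide (default 1280 px at x20, ~0.42 mm² of tissue) contains:

* **Glomeruli** — ovals of 100–150 µm including a rendered Bowman capsule
  ring, so "true borders include tuft and capsule" is morphologically
  honored. Count and diameter are chosen, then once rescaled, to hit the
  40:3:2 tubuli:glomeruli:arteries volume ratio within 20 %.
* **Tubules** — shrunk Voronoi cells of a jittered point grid (spacing
  ≈ mean tubule size + 10 µm inter-tubule gap), clipped away from the
  larger structures: a densely packed polygonal collection, 30–50 µm. The
  10 µm gap keeps all inter-tubule stroma inside the 15 µm proper rim, so
  a slide with fibrosis target 0 measures ≈ 0 % fibrosis.
* **Arteries** — near-circular, ≥ 100 µm, wall plus pale lumen.
* **Fibrosis** — clusters of tubules are replaced by stroma (as connective
  tissue replaces parenchyma in real fibrosis), patch by patch around
  random foci, until the realized fibrosis-eligible fraction reaches the
  target; the realization is accepted within the generator's stated ±3
  percentage points, else `InfeasibleTargetsError`.
* **Infiltration** — 50 µm grid-aligned clusters of stroma-rich tiles are
  populated with 12 lymphocytes + 12 nuclei each; a tile is only marked
  infiltrated in the ground truth when enough cells actually fit (rule
  margin +1 lymphocyte / +2 cells), so the truth label and the counting
  rule cannot disagree by construction. Normal stroma receives ~4 nuclei
  and ~0.2 lymphocytes per tile — enough to exercise detection, far below
  the 20-cell rule, making the rule attainable only in infiltrates.
* **Cells** — lymphocytes are near-circular (axis ratio ≤ 1.15) disks of
  5–7.5 µm with constant gray 50–90; nuclei are ellipses (ratio 1.3–2.2,
  5.5–7.5 µm equivalent diameter) with gray 100–160. Only the 95-gray
  boundary is externally fixed; the sampled ranges leave ≥ 5 gray levels
  of margin on either side. Cell colors are computed so their
  `rgb2gray` luminance equals the intended gray exactly (bluish tint
  solved against the luminance weights). Cells are placed on a 7×7 slot
  grid per tile and only where a distance transform shows the whole cell
  fits inside stroma.

Default fibrosis/infiltration targets (24 % / 6 %) correspond to a mildly
fibrotic specimen, the middle of the clinically interesting range. The
default truth percentages are computed from the generated label map by the
same `area_fraction` definition the pipeline uses.

Determinism: all randomness flows from one `SeedSequence`; the same
parameters yield byte-identical rasters.

**What a green test establishes — and what it does not.** The generator's
infiltrates are grid-aligned with the pipeline's tile grid, its background
is noise-free by default, its cells never overlap structures, and its
staining is flat color. Recovery within ±3 points on this material
validates the *bookkeeping* — tiling, merging, rim geometry, counting
rules, area accounting — not robustness to stain variation, blur, touching
real nuclei, or segmentation error of a trained model. Segmentation-error
sensitivity is exercised separately via `corrupt_segmentation`
(dropout/jitter), which degrades Dice and mAP as expected.

## Degenerate inputs and tie-breaks

* Otsu on a single-gray image → `DegenerateHistogramError`.
* ROI ∩ tissue empty → `EmptyRegionError`; empty tissue in morphometry →
  `ZeroDivisionError`.
* ROC with one score group → `DegenerateLabelsError`; constant vectors in
  Spearman → `ValueError`.
* `predict_score_group`: value = cutoff classifies as *high* (boundary
  convention stated, not derivable).
* Instances eroded to nothing by jitter are dropped.

## Known limitations

* The stride/overlap of the original sliding-window analysis is not
  published; 50 % overlap is this package's choice and is required for the
  border-discard recovery argument above.
* Whether instance merging happened before or after stroma derivation in
  the original workflow is unstated; this package merges first.
* Lymphocyte search includes the proper stromal rim by default (flag to
  exclude); the source material implies but does not state this.
* Real-cohort quantities (per-class Dice of a trained network, cohort
  AUCs, Spearman of measured areas across 110 biopsies) depend on private
  patient data and a trained segmenter and are out of scope; the package
  reproduces the measurement machinery and validates it on synthetic
  ground truth.
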