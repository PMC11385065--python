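# renalmorph

Morphometry of renal-transplant biopsy whole-slide images (WSI).

Grading kidney-transplant biopsies with the Banff classification requires a
pathologist to estimate, by eye, the relative cortical areas of two lesions:
interstitial fibrosis (the **ci** score, 0–3) and interstitial inflammatory
infiltration (the **i** score, 0–3). These estimates drive treatment decisions
— distinguishing borderline changes from T-cell–mediated rejection can hinge
on i = 1 vs i = 2 — yet they suffer from substantial interobserver
variability. `renalmorph` replaces the mental arithmetic with measured
quantities: given an H&E image, its pixel calibration (µm/px) and an instance
segmentation of the renal structures (from any segmenter honoring a simple
contract, or from ground truth), it derives the stromal compartment, detects
nuclei and lymphocytes, maps fibrosis and infiltration, and turns the
measured relative areas into ROC-based score-group predictions.

## What it computes

**Pipeline.** Tissue is found by grayscale thresholding (background is
near-white). A 50 µm sliding window (99 px at the x20 pixel size of
0.5056 µm/px) covers the tissue at 50 % overlap; within each window a
pluggable segmenter emits instances of the three structure classes —
*glomeruli*, *tubuli*, *arteries* — and small fragments touching the window
border are discarded as unstable. Same-class fragments with a strong
intersection are merged transitively. Everything not assigned to a structure
is **stroma**; the thin physiologic rim (15–20 µm) hugging each structure is
split off as **proper stromal space** by Euclidean-distance dilation and
excluded from fibrosis accounting. Nuclei and lymphocytes are detected in the
stroma by thresholding plus watershed; a fitted ellipse classifies each
object — a lymphocyte has semi-axis ratio < 2, mean gray brightness < 95
(0–255) and lymphocyte size. A fixed 50 µm grid tile is **infiltration** when
it holds ≥ 2 lymphocytes and ≥ 20 detected cells. Reported per ROI:

* fibrosis relative area = |stroma ∖ proper rim| / |tissue| · 100 %
* infiltration relative area = |flagged tiles ∩ eligible stroma| / |tissue| · 100 %

**Evaluation.** Dice = 2TP/(2TP+FN+FP) with the qualitative bands
(> 0.8 good, 0.6–0.8 acceptable, < 0.6 bad), column-normalized confusion
matrices, and COCO-style mAP@[0.5:0.95] = (1/N)Σᵢ APᵢ with greedy matching
over IoU thresholds 0.50:0.05:0.95.

**Score discrimination.** For a cohort of slides with expert scores, ROC
analysis of score group 0–1 vs 2–3 per measured feature: trapezoid AUC
(equal to the Mann–Whitney pair statistic), Youden-optimal cutoff
(max sens + spec − 1) with its sensitivity/specificity, and tie-aware
Spearman correlation.

**Synthetic cortex.** A built-in generator renders H&E-like renal cortex
with exhaustive ground truth: oval glomeruli (100–150 µm, capsule included),
Voronoi-packed polygonal tubules (30–50 µm), arteries (≥ 100 µm) at the
normal 40:3:2 tubuli:glomeruli:arteries volume ratio, tunable fibrosis and
infiltration fractions, and cells that satisfy the detection rules by
construction — so every stage is testable without patient data.

## Worked example

```python
from renalmorph import run_full_pipeline
from renalmorph.synthetic import SynthParams, generate_slide, make_oracle_segmenter

params = SynthParams(seed=3)          # 1280 px at x20, fibrosis 24 %, infiltration 6 %
slide = generate_slide(params)
report, label_map = run_full_pipeline(
    slide.rgb_image, make_oracle_segmenter(slide),
    params.calibration, params.pipeline_config,
)
```

prints (via `examples/analyze_slide.py`):

```
tissue area:        0.388 mm²
fibrosis area:      24.06%   (ground truth 24.06%)
infiltration area:  6.26%   (ground truth 6.26%)
cells: 132 lymphocytes, 407 nuclei, 10 infiltrated 50 µm tiles
```

The fibrosis figure is the fraction of tissue occupied by stroma beyond the
proper rim — the compartment where connective tissue has replaced
parenchyma; the infiltration figure is the fraction occupied by 50 µm tiles
dense in lymphocytes. On oracle segmentation both recover the generator's
ground truth within 3 percentage points.

The other scripts in `examples/` walk through slide synthesis
(`synthesize_slide.py`), segmentation scoring (`evaluate_segmentation.py`)
and cohort-level ROC discrimination (`score_discrimination.py`); each prints
the numbers it computes and a line on what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a six-slide synthetic cohort spanning mild to severe disease,
runs the full pipeline on each slide, evaluates segmentation quality under
corruption (mAP), and performs the ROC score-group analysis on the measured
areas, printing every figure it computes along the way and writing the
results file to `--out`.

## Scope

No neural-network training or inference (the segmenter is a contract), no
stain normalization, no pyramidal WSI decoding, no tubulitis/arteritis
scoring, and no beta-regression/ANOVA statistics — per-slide measurements
export to CSV for any stats package.
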