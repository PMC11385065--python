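"""Generate a synthetic renal-cortex slide and inspect its ground truth.

Builds an H&E-like image with glomeruli, tubules, arteries, stroma,
fibrotic expansion and lymphocyte infiltrates, then prints the truth the
generator guarantees: class areas near the 40:3:2 volume ratio, and
fibrosis/infiltration relative areas near the requested targets.
"""

from pathlib import Path

from renalmorph import ClassLabel, write_annotations, write_image, write_label_map_png
from renalmorph.synthetic import SynthParams, generate_slide

out = Path("example_output")
out.mkdir(exist_ok=True)

params = SynthParams(seed=7, fibrosis_fraction_target=0.24, infiltration_fraction_target=0.06)
slide = generate_slide(params)

areas = slide.ground_truth.class_areas_um2()
tub, glom, art = (areas[c] for c in (ClassLabel.tubuli, ClassLabel.glomeruli, ClassLabel.arteries))
print(f"instances: {len(slide.instances)}, cells: {len(slide.cells)}")
print(f"class volume ratio tubuli:glomeruli:arteries = "
      f"{tub / glom * 3:.1f}:3:{art / glom * 3:.1f}  (target 40:3:2)")
print(f"true fibrosis:     {slide.true_fibrosis_pct:6.2f}%  (target 24%)")
print(f"true infiltration: {slide.true_infiltration_pct:6.2f}%  (target 6%)")
print("-> the percentages are relative areas over all tissue pixels; the")
print("   pipeline is expected to recover them within 3 percentage points.")

write_image(out / "slide.png", slide.rgb_image)
write_label_map_png(out / "slide_truth.png", slide.ground_truth)
write_annotations(out / "slide_truth.geojson", slide.instances, calibration=params.calibration)
print(f"wrote {out}/slide.png, slide_truth.png, slide_truth.geojson")
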