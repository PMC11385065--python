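import numpy as np
import pytest

from renalmorph import (
    PipelineConfig,
    detect_tissue,
    derive_stroma,
    merge_instances,
    scan_slide,
)
from renalmorph.synthetic import SynthParams, generate_slide, make_oracle_segmenter


@pytest.fixture(scope="session")
def slide7():
    """One default synthetic slide, shared by all tests that read it."""
    return generate_slide(SynthParams(seed=7))


@pytest.fixture(scope="session")
def analysis7(slide7):
    """Oracle-segmented pipeline products for slide7 (tissue, merged, labels)."""
    cfg = slide7.params.pipeline_config
    calib = slide7.params.calibration
    tissue = detect_tissue(slide7.rgb_image, cfg.tissue_threshold)
    raw = scan_slide(
        slide7.rgb_image, tissue, make_oracle_segmenter(slide7), cfg, calib
    )
    merged = merge_instances(raw, cfg.merge_iou_min)
    label_map = derive_stroma(tissue, merged, None, cfg, calib)
    return {
        "tissue": tissue,
        "raw": raw,
        "merged": merged,
        "label_map": label_map,
        "config": cfg,
        "calibration": calib,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_blob_mask(rng, shape=(24, 24), p=0.35):
    """A random binary mask (possibly with holes/islands) for property tests."""
    m = rng.random(shape) < p
    if not m.any():
        m[shape[0] // 2, shape[1] // 2] = True
    return m
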