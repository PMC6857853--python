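"""Shared fixtures: small synthetic scenes and pre-segmented ROI sets.

Session-scoped fixtures keep the rendering cost paid once; every test that
mutates ROIs works on its own segmentation output.
"""

from __future__ import annotations

import math

import pytest

from oralcyto.pipeline import _match_roi_label
from oralcyto.qc import apply_qc
from oralcyto.segmentation import segment_field
from oralcyto.synthetic import SceneSpec, generate_field_image


def small_scene(**kw) -> SceneSpec:
    """A quick-to-render field: 800x600, FOV radius 280, modest cells."""
    defaults = dict(image_width=800, image_height=600, fov_radius=280,
                    n_cells=12, cell_diameter_range=(22.0, 40.0), seed=3)
    defaults.update(kw)
    return SceneSpec(**defaults)


@pytest.fixture(scope="session")
def default_field():
    """One small field with its ground truth."""
    return generate_field_image(small_scene())


@pytest.fixture(scope="session")
def segmented_field(default_field):
    img, gt = default_field
    return img, gt, segment_field(img)


@pytest.fixture(scope="session")
def labelled_rois():
    """QC-passed ROIs paired with ground-truth atypia labels, 6 fields."""
    out = []
    for s in range(6):
        img, gt = generate_field_image(small_scene(atypical_fraction=0.5,
                                                   seed=100 + s))
        rois = segment_field(img)
        passing, _ = apply_qc(rois)
        for roi in passing:
            lab = _match_roi_label(roi, gt)
            if lab is not None:
                out.append((roi, lab))
    return out


def match_count(gt_cells, rois, tol=5.0):
    """How many ground-truth centroids have a segmented ROI within ``tol``."""
    used = set()
    matched = 0
    for c in gt_cells:
        best, best_d = None, tol
        for i, r in enumerate(rois):
            if i in used:
                continue
            d = math.hypot(c.centroid[0] - r.centroid[0],
                           c.centroid[1] - r.centroid[1])
            if d < best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            matched += 1
    return matched
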