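"""Per-cell quality-control cascade run before atypia scoring.

Four checks are applied in a fixed order with short-circuiting, mirroring how
clump fragments, shadow artifacts, unstained debris and anucleate fragments
are weeded out of segmented cytology fields:

1. ``size_aspect`` — area within plausible squamous-cell bounds and aspect
   ratio not clump-like;
2. ``shadow`` — mean red / mean green intensity ratio at most a threshold
   (shadows and out-of-focus smudges are red-dominant relative to stain);
3. ``hematoxylin_area`` — at least a minimum fraction of the ROI is
   hematoxylin-stained (blue-dominant and dark), i.e. the ROI is stained
   at all;
4. ``nucleus`` — thresholding the red channel inside the ROI reveals at
   least one particle of nuclear size; the largest is kept as the nucleus
   mask for morphometric scoring.

All numeric thresholds are deliberate defaults chosen from typical squamous
cell dimensions (20–70 um diameter) at 1.9 px/um; every one is overridable
through :class:`QCCriteria`.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .segmentation import CellROI

__all__ = [
    "QCCriteria",
    "QCResult",
    "CHECK_ORDER",
    "check_size_aspect",
    "check_shadow",
    "check_hematoxylin_area",
    "check_nucleus",
    "apply_qc",
]

CHECK_ORDER = ("size_aspect", "shadow", "hematoxylin_area", "nucleus")


@dataclass(frozen=True)
class QCCriteria:
    min_cell_area_um2: float = 150.0
    max_cell_area_um2: float = 4000.0
    max_aspect_ratio: float = 3.0
    max_red_green_ratio: float = 1.15  # inclusive upper bound for passing
    min_hematoxylin_fraction: float = 0.05  # inclusive lower bound
    min_nucleus_area_um2: float = 10.0
    min_contrast: float = 30.0  # grey-level spread under which an ROI is flat

    def __post_init__(self):
        if not (0 < self.min_cell_area_um2 < self.max_cell_area_um2):
            raise ValueError("cell area bounds must satisfy 0 < min < max")
        if self.max_aspect_ratio < 1.0:
            raise ValueError("max_aspect_ratio must be >= 1")
        if not (0.0 < self.min_hematoxylin_fraction < 1.0):
            raise ValueError("min_hematoxylin_fraction must lie in (0, 1)")
        if self.min_nucleus_area_um2 <= 0:
            raise ValueError("min_nucleus_area_um2 must be > 0")


@dataclass
class QCResult:
    """Verdicts of the four checks; short-circuited checks are ``None``."""

    size_aspect: bool | None = None
    shadow: bool | None = None
    hematoxylin_area: bool | None = None
    nucleus: bool | None = None
    passed: bool = False
    failure_reason: str | None = None


def check_size_aspect(roi: CellROI, c: QCCriteria = QCCriteria()) -> bool:
    """Pass iff area in [min, max] um^2 (inclusive) and aspect <= max."""
    if roi.area_um2 is None or roi.aspect_ratio is None:
        raise ValueError("ROI is missing area or aspect ratio")
    return (c.min_cell_area_um2 <= roi.area_um2 <= c.max_cell_area_um2
            and roi.aspect_ratio <= c.max_aspect_ratio)


def check_shadow(roi: CellROI, c: QCCriteria = QCCriteria()) -> bool:
    """Pass iff mean_red / mean_green <= threshold (inclusive); a zero green
    mean is degenerate and fails."""
    r, g, _ = roi.channel_means
    if g == 0:
        return False
    return (r / g) <= c.max_red_green_ratio


def _stained_fraction(roi: CellROI, c: QCCriteria) -> float:
    """Fraction of mask pixels that look hematoxylin-stained.

    Rule: blue >= red and luminance below the ROI's Otsu split.  A flat ROI
    (spread below ``min_contrast``) has no stained/unstained structure and
    scores 0 — this is what rejects unstained debris.
    """
    if roi.crop is None:
        raise ValueError("ROI crop is required for the hematoxylin check")
    crop = roi.crop.astype(np.float64)
    m = roi.mask
    lum = crop.mean(axis=2)
    vals = lum[m]
    if vals.size == 0:
        return 0.0
    if float(np.percentile(vals, 99) - np.percentile(vals, 1)) < c.min_contrast:
        return 0.0
    thr = threshold_otsu(vals)
    stained = m & (crop[:, :, 2] >= crop[:, :, 0]) & (lum < thr)
    return float(stained.sum()) / float(m.sum())


def check_hematoxylin_area(roi: CellROI, c: QCCriteria = QCCriteria()) -> bool:
    return _stained_fraction(roi, c) >= c.min_hematoxylin_fraction


def check_nucleus(roi: CellROI, c: QCCriteria = QCCriteria()) -> bool:
    """Threshold the red channel inside the ROI; pass iff a particle of at
    least nuclear size appears.  The largest qualifying particle is stored as
    ``roi.nucleus_mask``."""
    if roi.crop is None:
        raise ValueError("ROI crop is required for the nucleus check")
    red = roi.crop[:, :, 0].astype(np.float64)
    m = roi.mask
    vals = red[m]
    if vals.size == 0:
        return False
    if float(np.percentile(vals, 99) - np.percentile(vals, 1)) < c.min_contrast:
        return False  # flat red channel: anucleate fragment
    thr = threshold_otsu(vals)
    nuc = m & (red < thr)
    lab = sk_label(nuc, connectivity=2)
    if lab.max() == 0:
        return False
    min_px = c.min_nucleus_area_um2 * roi.pixel_scale ** 2
    best, best_area = None, 0
    for k in range(1, lab.max() + 1):
        area = int((lab == k).sum())
        if area >= min_px and area > best_area:
            best, best_area = k, area
    if best is None:
        return False
    roi.nucleus_mask = lab == best
    return True


_CHECKS = {
    "size_aspect": check_size_aspect,
    "shadow": check_shadow,
    "hematoxylin_area": check_hematoxylin_area,
    "nucleus": check_nucleus,
}


def run_qc(roi: CellROI, c: QCCriteria = QCCriteria()) -> QCResult:
    """Run the four checks in order on one ROI, short-circuiting on the first
    failure.  The result is attached to ``roi.qc`` and returned."""
    res = QCResult()
    for name in CHECK_ORDER:
        verdict = _CHECKS[name](roi, c)
        setattr(res, name, verdict)
        if not verdict:
            res.passed = False
            res.failure_reason = name
            break
    else:
        res.passed = True
    roi.qc = res
    return res


def apply_qc(rois: list[CellROI], c: QCCriteria = QCCriteria()
             ) -> tuple[list[CellROI], dict[str, int]]:
    """Filter ROIs through the cascade; return survivors and a per-check tally.

    The tally maps each check name to the number of ROIs it rejected, plus
    ``"passed"`` for the survivor count.
    """
    tally: Counter[str] = Counter()
    passing: list[CellROI] = []
    for roi in rois:
        res = run_qc(roi, c)
        if res.passed:
            passing.append(roi)
        else:
            tally[res.failure_reason] += 1
    tally["passed"] = len(passing)
    return passing, dict(tally)
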