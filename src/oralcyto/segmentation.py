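"""Circular-FOV estimation and cell segmentation for stained cytology fields.

The stage sequence mirrors how tablet-microscope oral-cytology fields are
processed in practice:

1. find three pixels on the boundary of the bright circular field of view
   (FOV) and fit their circumcircle;
2. trim the frame to that circle (everything outside goes to black);
3. threshold the green channel (the channel with the best stain contrast,
   Otsu, inverted so dark stained pixels are foreground) to get cell mass;
4. clear the background outside the detected mass and drop sub-speck debris;
5. split touching cells along distance-transform watershed ridges;
6. emit one :class:`CellROI` per connected component with geometry and
   per-channel statistics.

Coordinates are 0-based with ``x`` = column, ``y`` = row; bounding boxes are
half-open ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "CircleFOV",
    "FieldImage",
    "CellMask",
    "CellROI",
    "EdgePoints",
    "SegmentationParams",
    "FOVNotDetectedError",
    "DegenerateCircleError",
    "find_fov_edge_points",
    "circumcircle",
    "trim_to_fov",
    "threshold_cell_mass",
    "clear_background",
    "split_clumps",
    "extract_cell_rois",
    "segment_field",
]


class FOVNotDetectedError(RuntimeError):
    """No bright circular field of view could be found in the frame."""


class DegenerateCircleError(ValueError):
    """The three edge points are (near-)collinear; no unique circle exists."""


@dataclass(frozen=True)
class CircleFOV:
    """Circular field of view: centre ``(cx, cy)`` and ``radius`` in pixels."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    def contains(self, x, y, slack: float = 0.0) -> np.ndarray:
        return (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2 \
            <= (self.radius + slack) ** 2

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
        return self.contains(xx, yy)


@dataclass
class FieldImage:
    """One RGB microscope field.

    ``pixels`` is ``H x W x 3`` uint8 in (R, G, B) order; ``pixel_scale`` is
    pixels per micrometre (1.9 for the target acquisition).  ``origin`` is the
    (x, y) offset of this (possibly cropped) frame in its parent frame, so ROI
    coordinates can always be mapped back to the raw field.
    """

    pixels: np.ndarray
    pixel_scale: float = 1.9
    source_id: str = ""
    fov: CircleFOV | None = None
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError("image must be at least 3 x 3")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel (uint8)")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class CellMask:
    """Binary foreground mask with a provenance tag for the producing stage."""

    data: np.ndarray
    provenance: str = "thresholded"  # thresholded | background_cleared | watershed

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)


@dataclass
class CellROI:
    """One segmented candidate cell.

    Bounding box is half-open in field coordinates; ``mask`` and ``crop`` are
    local to the box.  ``qc`` is filled by the quality-control stage and
    ``nucleus_mask`` by its nucleus check.
    """

    roi_id: int
    x0: int
    y0: int
    x1: int
    y1: int
    mask: np.ndarray
    area_px: int
    area_um2: float
    aspect_ratio: float
    channel_means: tuple[float, float, float]
    centroid: tuple[float, float]
    crop: np.ndarray | None = None
    pixel_scale: float = 1.9
    nucleus_mask: np.ndarray | None = None
    qc: "object | None" = None

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("bounding box must be non-empty and half-open")
        if self.mask is not None and not self.mask.any():
            raise ValueError("ROI mask must contain at least one pixel")


@dataclass(frozen=True)
class EdgePoints:
    """Three (x, y) points on the FOV boundary; ``low_confidence`` is set when
    no vignette was found and the points sit on the image border."""

    points: tuple[tuple[float, float], ...]
    low_confidence: bool = False

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, i):
        return self.points[i]

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation stages (values in comments are the
    reasoning, none is dictated by the imaging hardware)."""

    min_contrast: float = 30.0  # grey-level spread below which a frame/ROI is flat
    speck_area_px: int = 25  # components smaller than this are debris
    marker_min_separation_um: float = 10.0  # watershed marker spacing
    n_edge_rays: int = 6
    fov_margin_px: float = 4.0  # guard band inside the fitted circle; the
    # vignette transition is blurred, so a ~1 px dark ring can survive at the
    # circle boundary and would otherwise threshold as a giant ring component


def _luminance(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float64).mean(axis=2)


def find_fov_edge_points(image: FieldImage,
                         params: SegmentationParams = SegmentationParams()
                         ) -> EdgePoints:
    """Locate three pixels on the boundary of the bright circular FOV.

    Rays are cast inward from the image border toward the centre along
    ``n_edge_rays`` equally spaced directions; the first above-background
    pixel on each ray is an edge candidate.  Of the candidates, the triple
    maximising the minimum pairwise angular separation is returned.  A frame
    with no dark surround yields border points flagged ``low_confidence``.
    """
    lum = _luminance(image.pixels)
    h, w = lum.shape
    spread = float(np.percentile(lum, 99) - np.percentile(lum, 1))
    if spread < params.min_contrast:
        if float(lum.mean()) < 128:
            raise FOVNotDetectedError("FOV not detected: frame has no bright region")
        # uniformly bright frame: degenerate, no vignette to find
        pts = ((w - 1.0, h / 2.0), (0.0, h / 2.0), (w / 2.0, 0.0))
        return EdgePoints(points=pts, low_confidence=True)
    thr = threshold_otsu(lum)
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    candidates = []
    border_hits = 0
    for k in range(params.n_edge_rays):
        ang = 2.0 * math.pi * k / params.n_edge_rays + math.pi / params.n_edge_rays
        dx, dy = math.cos(ang), math.sin(ang)
        # start where the ray from the centre exits the frame
        tmax = np.inf
        if dx > 0:
            tmax = min(tmax, (w - 1 - cx0) / dx)
        elif dx < 0:
            tmax = min(tmax, -cx0 / dx)
        if dy > 0:
            tmax = min(tmax, (h - 1 - cy0) / dy)
        elif dy < 0:
            tmax = min(tmax, -cy0 / dy)
        found = None
        for t in np.arange(tmax, -1.0, -1.0):
            x, y = cx0 + t * dx, cy0 + t * dy
            if lum[int(round(y)), int(round(x))] > thr:
                found = (x, y, t, tmax)
                break
        if found is not None:
            x, y, t, texit = found
            if texit - t < 2.0:
                border_hits += 1
            candidates.append((x, y))
    if len(candidates) < 3:
        raise FOVNotDetectedError("FOV not detected: fewer than 3 edge candidates")
    best, best_sep = None, -1.0
    for tri in itertools.combinations(candidates, 3):
        try:
            _check_not_collinear(*tri)
        except DegenerateCircleError:
            continue
        angs = [math.atan2(p[1] - cy0, p[0] - cx0) for p in tri]
        seps = []
        for a, b in itertools.combinations(angs, 2):
            d = abs(a - b) % (2 * math.pi)
            seps.append(min(d, 2 * math.pi - d))
        if min(seps) > best_sep:
            best_sep, best = min(seps), tri
    if best is None:
        raise FOVNotDetectedError("FOV not detected: all edge-point triples collinear")
    return EdgePoints(points=tuple((float(x), float(y)) for x, y in best),
                      low_confidence=border_hits >= params.n_edge_rays)


def _check_not_collinear(p1, p2, p3, tol: float = 1e-9):
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    scale = max(abs(x1) + abs(y1), abs(x2) + abs(y2), abs(x3) + abs(y3), 1.0)
    if abs(d) <= tol * scale * scale:
        raise DegenerateCircleError("degenerate circle: points are collinear")
    return d


def circumcircle(p1, p2, p3) -> CircleFOV:
    """Closed-form circle through three non-collinear points."""
    d = _check_not_collinear(p1, p2, p3)
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    s1, s2, s3 = x1 * x1 + y1 * y1, x2 * x2 + y2 * y2, x3 * x3 + y3 * y3
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = math.hypot(x1 - ux, y1 - uy)
    return CircleFOV(cx=ux, cy=uy, radius=r)


def trim_to_fov(image: FieldImage, fov: CircleFOV) -> FieldImage:
    """Zero everything outside the circle and crop to its bounding box."""
    h, w = image.shape
    x0 = max(0, int(math.floor(fov.cx - fov.radius)))
    x1 = min(w, int(math.ceil(fov.cx + fov.radius)) + 1)
    y0 = max(0, int(math.floor(fov.cy - fov.radius)))
    y1 = min(h, int(math.ceil(fov.cy + fov.radius)) + 1)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("FOV circle lies entirely outside the image")
    crop = image.pixels[y0:y1, x0:x1].copy()
    yy, xx = np.mgrid[y0:y1, x0:x1]
    crop[~fov.contains(xx, yy)] = 0
    new_fov = CircleFOV(fov.cx - x0, fov.cy - y0, fov.radius)
    return FieldImage(pixels=crop, pixel_scale=image.pixel_scale,
                      source_id=image.source_id, fov=new_fov,
                      origin=(image.origin[0] + x0, image.origin[1] + y0))


def threshold_cell_mass(image: FieldImage,
                        params: SegmentationParams = SegmentationParams()
                        ) -> CellMask:
    """Binary cell-mass mask from the green channel (best stain contrast).

    Otsu's threshold is estimated over in-FOV pixels only and inverted so that
    dark (stained) pixels are foreground.  A flat FOV (no cells) yields an
    empty mask with a warning rather than thresholding pure noise.
    """
    green = image.pixels[:, :, 1].astype(np.float64)
    if image.fov is not None:
        f = image.fov
        guarded = CircleFOV(f.cx, f.cy, max(f.radius - params.fov_margin_px, 1.0))
        inside = guarded.mask(image.shape)
    else:
        inside = np.ones(image.shape, dtype=bool)
    vals = green[inside]
    if vals.size == 0:
        warnings.warn("empty FOV: no in-circle pixels", stacklevel=2)
        return CellMask(np.zeros(image.shape, dtype=bool))
    spread = float(np.percentile(vals, 99.5) - np.percentile(vals, 0.5))
    if spread < params.min_contrast:
        warnings.warn("empty FOV: green channel is flat, no cell mass detected",
                      stacklevel=2)
        return CellMask(np.zeros(image.shape, dtype=bool))
    thr = threshold_otsu(vals)
    mask = (green < thr) & inside
    return CellMask(mask, provenance="thresholded")


def clear_background(mask: CellMask, image: FieldImage,
                     params: SegmentationParams = SegmentationParams()
                     ) -> tuple[CellMask, FieldImage]:
    """Drop sub-speck components and black out the image outside the mass."""
    if mask.data.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    lab = sk_label(mask.data, connectivity=2)
    areas = np.bincount(lab.ravel())
    small = np.flatnonzero(areas < params.speck_area_px)
    kept = mask.data & ~np.isin(lab, small[small > 0])
    cleared = image.pixels.copy()
    cleared[~kept] = 0
    out_img = replace(image, pixels=cleared)
    return CellMask(kept, provenance="background_cleared"), out_img


def split_clumps(mask: CellMask,
                 params: SegmentationParams = SegmentationParams(),
                 pixel_scale: float = 1.9) -> CellMask:
    """Split touching cells along distance-transform watershed ridges.

    Markers are local maxima of the Euclidean distance transform separated by
    at least ``marker_min_separation_um``; every input component is guaranteed
    at least one marker, so the component count never decreases and no
    foreground appears outside the input mask.
    """
    m = mask.data
    if not m.any():
        return CellMask(m.copy(), provenance="watershed")
    dist = ndi.distance_transform_edt(m)
    comp = sk_label(m, connectivity=2)
    min_dist = max(1, int(round(params.marker_min_separation_um * pixel_scale)))
    coords = peak_local_max(dist, min_distance=min_dist, labels=comp,
                            exclude_border=False)
    markers = np.zeros(m.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # guarantee one marker per component
    have = set(np.unique(comp[markers > 0]))
    nxt = int(markers.max()) + 1
    for region in regionprops(comp):
        if region.label in have:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        k = int(np.argmax(dist[rr, cc]))
        markers[rr[k], cc[k]] = nxt
        nxt += 1
    labels = watershed(-dist, markers, mask=m, watershed_line=True)
    return CellMask(labels > 0, provenance="watershed")


def extract_cell_rois(mask: CellMask, image: FieldImage) -> list[CellROI]:
    """One :class:`CellROI` per connected component, ordered by (y0, x0)."""
    lab = sk_label(mask.data, connectivity=2)
    rois: list[CellROI] = []
    ox, oy = image.origin
    scale = image.pixel_scale
    for region in regionprops(lab):
        y0, x0, y1, x1 = region.bbox
        rmask = region.image
        crop = image.pixels[y0:y1, x0:x1]
        means = tuple(float(crop[:, :, c][rmask].mean()) for c in range(3))
        minor = region.axis_minor_length
        aspect = float(region.axis_major_length / minor) if minor > 0 else math.inf
        cy, cx = region.centroid
        rois.append(CellROI(
            roi_id=0,
            x0=x0 + ox, y0=y0 + oy, x1=x1 + ox, y1=y1 + oy,
            mask=rmask.copy(),
            area_px=int(region.area),
            area_um2=float(region.area / scale ** 2),
            aspect_ratio=max(aspect, 1.0),
            channel_means=means,
            centroid=(float(cx + ox), float(cy + oy)),
            crop=crop.copy(),
            pixel_scale=scale,
        ))
    rois.sort(key=lambda r: (r.y0, r.x0))
    for i, roi in enumerate(rois):
        roi.roi_id = i
    return rois


def segment_field(image: FieldImage,
                  params: SegmentationParams = SegmentationParams()
                  ) -> list[CellROI]:
    """Full pipeline: FOV fit, trim, threshold, clear, split, extract.

    ROI coordinates are reported in the raw field's frame.  Stage failures
    are re-raised with the stage name prepended.
    """
    stage = "find_fov_edge_points"
    try:
        pts = find_fov_edge_points(image, params)
        stage = "circumcircle"
        fov = circumcircle(*pts.points)
        stage = "trim_to_fov"
        trimmed = trim_to_fov(image, fov)
        stage = "threshold_cell_mass"
        mask = threshold_cell_mass(trimmed, params)
        stage = "clear_background"
        mask, cleared = clear_background(mask, trimmed, params)
        stage = "split_clumps"
        mask = split_clumps(mask, params, pixel_scale=image.pixel_scale)
        stage = "extract_cell_rois"
        rois = extract_cell_rois(mask, cleared)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    logger.info("segment_field %s: fov r=%.1f, %d ROIs",
                image.source_id, fov.radius, len(rois))
    return rois
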