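"""Seeded synthetic oral-cytology data: field images with ground truth, and
per-patient score cohorts.

Two independent generators live here:

``generate_field_image`` / ``generate_slide``
    Render microscope-like RGB fields: a bright circular field of view (FOV)
    on a dark vignette, containing stained squamous cells (cytoplasm ellipse
    plus a darker, blue-dominant nucleus), optional touching-cell clumps and
    shadow artifacts.  Every rendered object is returned as pixel-exact
    ground truth so segmentation and QC can be scored against a known answer.

``generate_score_cohort``
    Draw per-cell atypia scores for a cohort of patients from a two-component
    truncated-normal mixture (normal cells below 0.5, atypical cells above),
    calibrated so each diagnostic class reproduces its published
    fraction-atypical and mean atypical-cell score.

All randomness flows through ``numpy.random.Generator`` seeded from the spec;
the same spec yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .segmentation import CircleFOV, FieldImage
from .aggregation import PatientRecord

__all__ = [
    "StainPalette",
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "ClassScoreSpec",
    "CohortSpec",
    "DEFAULT_CLASS_SPECS",
    "generate_field_image",
    "generate_slide",
    "generate_score_cohort",
]


class SpecValidationError(ValueError):
    """A generator spec violated one of its invariants."""


# ---------------------------------------------------------------------------
# field-image generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StainPalette:
    """Per-channel (low, high) 8-bit intensity ranges for each scene component.

    Chosen to mimic a Papanicolaou-type stain: cytoplasm is pinkish (green is
    the darkest channel, giving cell mass its contrast there), nuclei are dark
    and blue-dominant (hematoxylin), the in-FOV background is near-white and
    the surround outside the FOV is near-black.
    """

    cytoplasm: tuple[tuple[int, int], ...] = ((128, 152), (118, 142), (168, 190))
    nucleus: tuple[tuple[int, int], ...] = ((55, 85), (60, 90), (115, 145))
    background: tuple[tuple[int, int], ...] = ((228, 240), (226, 238), (230, 242))
    shadow: tuple[tuple[int, int], ...] = ((140, 165), (95, 115), (95, 115))
    outside: tuple[int, int, int] = (8, 8, 8)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic microscope field.

    Defaults follow the acquisition geometry of tablet-microscope oral
    cytology fields: 2592x1936 px, 24-bit RGB, 1.9 px/um, with a circular
    illuminated FOV centred in the frame.
    """

    image_width: int = 2592
    image_height: int = 1936
    fov_center: tuple[float, float] | None = None  # default: image centre
    fov_radius: float = 900.0
    n_cells: int = 25
    n_clumps: int = 0
    n_shadow_artifacts: int = 0
    cell_diameter_range: tuple[float, float] = (25.0, 55.0)  # um
    nucleus_fraction_range: tuple[float, float] = (0.08, 0.18)  # of cell area
    atypical_nucleus_fraction_range: tuple[float, float] = (0.35, 0.60)
    atypical_fraction: float = 0.25
    stain_palette: StainPalette = field(default_factory=StainPalette)
    pixel_scale: float = 1.9  # px per um
    noise_sigma: float = 5.0 / 255.0  # Gaussian pixel noise, fraction of range
    seed: int = 0

    def center(self) -> tuple[float, float]:
        if self.fov_center is not None:
            return self.fov_center
        return (self.image_width / 2.0, self.image_height / 2.0)

    def validate(self) -> None:
        if self.image_width < 3 or self.image_height < 3:
            raise SpecValidationError("image_width/image_height must be >= 3")
        if self.fov_radius <= 0:
            raise SpecValidationError("fov_radius must be > 0")
        cx, cy = self.center()
        if (cx - self.fov_radius < 0 or cx + self.fov_radius > self.image_width
                or cy - self.fov_radius < 0 or cy + self.fov_radius > self.image_height):
            raise SpecValidationError("fov_radius: FOV circle must fit inside the image")
        if self.n_cells < 0:
            raise SpecValidationError("n_cells must be >= 0")
        if self.n_clumps < 0 or self.n_shadow_artifacts < 0:
            raise SpecValidationError("n_clumps/n_shadow_artifacts must be >= 0")
        lo, hi = self.nucleus_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise SpecValidationError("nucleus_fraction_range must lie inside (0, 1)")
        lo, hi = self.atypical_nucleus_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise SpecValidationError("atypical_nucleus_fraction_range must lie inside (0, 1)")
        if not (0.0 <= self.atypical_fraction <= 1.0):
            raise SpecValidationError("atypical_fraction must lie in [0, 1]")
        lo, hi = self.cell_diameter_range
        if not (0 < lo <= hi):
            raise SpecValidationError("cell_diameter_range must be positive and ordered")
        if self.pixel_scale <= 0:
            raise SpecValidationError("pixel_scale must be > 0")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    centroid: tuple[float, float]  # (x, y) px
    area_px: int
    aspect_ratio: float
    label: str  # 'normal' | 'atypical'
    nucleus_area_px: int
    clump_id: int | None = None
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # x0, y0, x1, y1 half-open


@dataclass
class GroundTruth:
    """Pixel-exact rendering record for one field."""

    fov: CircleFOV
    cells: list[CellTruth]
    cell_labels: np.ndarray  # int32 HxW, 0 = background, k = cell_id
    nucleus_labels: np.ndarray  # int32 HxW
    artifact_mask: np.ndarray  # bool HxW

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id


def _ellipse_patch(shape, cx, cy, a, b, theta, boundary_amp=0.0,
                   boundary_waves=0, phase=0.0):
    """Boolean patch of a (possibly radially perturbed) filled ellipse.

    Returns ``(mask, (ys, xs))`` where ``mask`` covers only the ellipse's
    bounding box and the slices place it in the full frame.  ``boundary_amp``
    adds a sinusoidal perturbation of the radius, used to give atypical
    nuclei an irregular membrane.
    """
    h, w = shape
    half = int(math.ceil(max(a, b) * (1.0 + boundary_amp))) + 2
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return np.zeros((0, 0), dtype=bool), (slice(0, 0), slice(0, 0))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    r = np.hypot(u / a, v / b)
    if boundary_amp > 0.0 and boundary_waves > 0:
        ang = np.arctan2(v / b, u / a)
        limit = 1.0 + boundary_amp * np.sin(boundary_waves * ang + phase)
    else:
        limit = 1.0
    return r <= limit, (slice(y0, y1), slice(x0, x1))


def _draw_color(rng: np.random.Generator, ranges) -> np.ndarray:
    # one shared brightness draw across channels keeps channel ratios stable
    # from cell to cell (stain hue varies much less than stain density)
    t = rng.uniform()
    base = np.array([lo + t * (hi - lo) for lo, hi in ranges], dtype=np.float64)
    return base + rng.uniform(-3.0, 3.0, size=base.size)


def _place_centers(rng, spec: SceneSpec, radii_px, margin=3.0, max_tries=4000):
    """Rejection-sample non-overlapping cell centres fully inside the FOV."""
    cx, cy = spec.center()
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii_px:
        ok = False
        for _ in range(max_tries):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = math.sqrt(rng.uniform(0.0, 1.0)) * max(
                spec.fov_radius - r - margin, 0.0)
            x = cx + rad * math.cos(ang)
            y = cy + rad * math.sin(ang)
            if all((x - px) ** 2 + (y - py) ** 2 > (r + pr + margin) ** 2
                   for (px, py), pr in zip(centers, placed_r)):
                centers.append((x, y))
                placed_r.append(r)
                ok = True
                break
        if not ok:
            raise SpecValidationError(
                "n_cells: could not place all objects without overlap inside the FOV")
    return centers


def generate_field_image(spec: SceneSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its pixel-exact ground truth.

    Cells are anti-aliased by a light Gaussian blur after hard-ellipse
    rasterisation; ground-truth masks are the unblurred ellipses.  Atypical
    cells get a larger, irregular nucleus so that morphometric scoring has
    signal.  Identical spec (including seed) gives byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.image_height, spec.image_width
    cx, cy = spec.center()
    fov = CircleFOV(cx, cy, spec.fov_radius)
    pal = spec.stain_palette

    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = pal.outside
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.fov_radius ** 2
    bg = _draw_color(rng, pal.background)
    img[inside] = bg

    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    artifact_mask = np.zeros((h, w), dtype=bool)
    cells: list[CellTruth] = []

    # plan the population: singles, then clump members (pairs), then shadows
    n_singles = spec.n_cells
    n_clump_members = 2 * spec.n_clumps
    d_lo, d_hi = spec.cell_diameter_range
    # effective placement radius per object (major semi-axis in px)
    all_n = n_singles + spec.n_clumps + spec.n_shadow_artifacts
    diam_um = rng.uniform(d_lo, d_hi, size=max(all_n + n_clump_members, 1))
    radii_px = diam_um * spec.pixel_scale / 2.0

    # placement slots: each single cell, each clump (as one bigger slot),
    # each shadow artifact.  Clump slot radius covers both members.
    slot_radii = []
    for i in range(n_singles):
        slot_radii.append(radii_px[i] * 1.1)
    for j in range(spec.n_clumps):
        r1 = radii_px[n_singles + j]
        slot_radii.append(r1 * 2.4)
    for k in range(spec.n_shadow_artifacts):
        slot_radii.append(radii_px[n_singles + spec.n_clumps + k] * 1.6)
    centers = _place_centers(rng, spec, slot_radii) if slot_radii else []

    next_id = 1

    def draw_cell(x, y, semi_major, label, clump_id=None):
        nonlocal next_id
        aspect = rng.uniform(1.0, 1.6)
        a, b = semi_major, semi_major / aspect
        theta = rng.uniform(0.0, math.pi)
        cmask, csl = _ellipse_patch((h, w), x, y, a, b, theta)
        cmask &= inside[csl]
        # nucleus: fraction of cell area, offset toward the centre
        if label == "atypical":
            frac = rng.uniform(*spec.atypical_nucleus_fraction_range)
            amp, waves = 0.25, int(rng.integers(4, 8))
        else:
            frac = rng.uniform(*spec.nucleus_fraction_range)
            amp, waves = 0.05, int(rng.integers(3, 6))
        scale = math.sqrt(frac)
        na, nb = a * scale, b * scale
        off = rng.uniform(-0.15, 0.15, size=2) * semi_major
        nmask, nsl = _ellipse_patch((h, w), x + off[0], y + off[1], na, nb,
                                    theta, boundary_amp=amp,
                                    boundary_waves=waves,
                                    phase=rng.uniform(0.0, 2.0 * math.pi))
        cyto_color = _draw_color(rng, pal.cytoplasm)
        nuc_color = _draw_color(rng, pal.nucleus)
        img[csl][cmask] = cyto_color  # slice indexing yields views
        cell_labels[csl][cmask] = next_id
        nmask &= cell_labels[nsl] == next_id  # clip nucleus to this cell
        img[nsl][nmask] = nuc_color
        nucleus_labels[nsl][nmask] = next_id
        own = cell_labels[csl] == next_id
        ys, xs = np.nonzero(own)
        if xs.size == 0:
            next_id += 1
            return
        y0g, x0g = csl[0].start, csl[1].start
        cells.append(CellTruth(
            cell_id=next_id,
            centroid=(float(xs.mean()) + x0g, float(ys.mean()) + y0g),
            area_px=int(own.sum()),
            aspect_ratio=float(aspect),
            label=label,
            nucleus_area_px=int(nmask.sum()),
            clump_id=clump_id,
            bbox=(int(xs.min()) + x0g, int(ys.min()) + y0g,
                  int(xs.max()) + 1 + x0g, int(ys.max()) + 1 + y0g),
        ))
        next_id += 1

    slot = 0
    for i in range(n_singles):
        x, y = centers[slot]
        label = "atypical" if rng.uniform() < spec.atypical_fraction else "normal"
        draw_cell(x, y, radii_px[i], label)
        slot += 1
    for j in range(spec.n_clumps):
        x, y = centers[slot]
        r1 = radii_px[n_singles + j]
        r2 = radii_px[all_n + 2 * j] if all_n + 2 * j < radii_px.size else r1
        ang = rng.uniform(0.0, 2.0 * math.pi)
        sep = 0.85 * (r1 + r2) / 2.0 + r1 * 0.4
        label1 = "atypical" if rng.uniform() < spec.atypical_fraction else "normal"
        label2 = "atypical" if rng.uniform() < spec.atypical_fraction else "normal"
        draw_cell(x - sep / 2 * math.cos(ang), y - sep / 2 * math.sin(ang),
                  r1, label1, clump_id=j + 1)
        draw_cell(x + sep / 2 * math.cos(ang), y + sep / 2 * math.sin(ang),
                  r2, label2, clump_id=j + 1)
        slot += 1
    for k in range(spec.n_shadow_artifacts):
        x, y = centers[slot]
        r = radii_px[n_singles + spec.n_clumps + k] * 1.3
        aspect = rng.uniform(1.1, 2.2)
        theta = rng.uniform(0.0, math.pi)
        amask, asl = _ellipse_patch((h, w), x, y, r, r / aspect, theta,
                                    boundary_amp=0.15, boundary_waves=5,
                                    phase=rng.uniform(0.0, 2.0 * math.pi))
        amask &= inside[asl] & (cell_labels[asl] == 0)
        img[asl][amask] = _draw_color(rng, pal.shadow)
        artifact_mask[asl][amask] = True
        slot += 1

    # light blur for anti-aliasing, then pixel noise; vignette stays dark
    img = ndi.gaussian_filter(img, sigma=(0.8, 0.8, 0.0))
    img += (rng.standard_normal(size=img.shape, dtype=np.float32)
            * np.float32(spec.noise_sigma * 255.0))
    np.clip(img, 0, 255, out=img)
    pixels = img.astype(np.uint8)

    truth = GroundTruth(fov=fov, cells=cells, cell_labels=cell_labels,
                        nucleus_labels=nucleus_labels, artifact_mask=artifact_mask)
    fimg = FieldImage(pixels=pixels, pixel_scale=spec.pixel_scale,
                      source_id=f"synthetic-{spec.seed}", fov=None)
    return fimg, truth


def field_seed(master_seed: int, index: int) -> int:
    """Deterministic per-field seed: SeedSequence((master, index)) folded to 31 bits."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2 ** 31))


def generate_slide(spec: SceneSpec, n_fields: int) -> list[tuple[FieldImage, GroundTruth]]:
    """Render ``n_fields`` independent fields, seeds split from the master seed."""
    if n_fields < 1:
        raise SpecValidationError("n_fields must be >= 1")
    out = []
    for i in range(n_fields):
        sub = replace(spec, seed=field_seed(spec.seed, i))
        out.append(generate_field_image(sub))
    return out


# ---------------------------------------------------------------------------
# score-cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassScoreSpec:
    """Score-distribution parameters for one diagnostic class.

    Per-cell scores follow a two-component truncated-normal mixture: normal
    cells on (0, 0.5], atypical cells on (0.5, 1].  Patient-level heterogeneity
    comes from drawing each patient's atypical fraction and component means
    around the class values.  ``mean_all``/``sd_all`` set the class
    distribution of the per-patient mean score of all cells; the normal-cell
    component mean is derived from it so the mixture is internally consistent.
    """

    n_patients: int
    atypical_fraction: float
    atypical_fraction_sd: float
    mean_atypical: float
    sd_atypical: float
    mean_all: float
    sd_all: float
    cells_per_patient: float = 200.0
    cell_sd_normal: float = 0.08
    cell_sd_atypical: float = 0.08
    #: Published patient-level correlation between the mean all-cell score and
    #: the atypical fraction; fixes how much of ``sd_all`` is independent of
    #: the fraction (the printed per-class SDs alone are inconsistent with
    #: this correlation, and the correlation wins — see the methods note).
    feature_correlation: float = 0.992

    def validate(self, name: str = "") -> None:
        tag = f"{name}: " if name else ""
        if self.n_patients < 0:
            raise SpecValidationError(tag + "n_patients must be >= 0")
        if not (0.0 <= self.atypical_fraction <= 1.0):
            raise SpecValidationError(tag + "atypical_fraction must lie in [0, 1]")
        if self.atypical_fraction > 0.0 and self.mean_atypical <= 0.5:
            raise SpecValidationError(
                tag + "mean_atypical must exceed 0.5 (atypical component lies above 0.5)")
        if self.cells_per_patient < 1:
            raise SpecValidationError(tag + "cells_per_patient must be >= 1")
        if self.atypical_fraction < 1.0:
            mu_n = self.normal_mean()
            if not (0.0 <= mu_n <= 0.5):
                raise SpecValidationError(
                    tag + f"infeasible mean_all={self.mean_all}: implied normal-cell "
                          f"mean {mu_n:.3f} outside [0, 0.5]")

    def normal_mean(self) -> float:
        """Class normal-component mean implied by mean_all and the mixture."""
        f = self.atypical_fraction
        if f >= 1.0:
            return 0.0
        return (self.mean_all - f * self.mean_atypical) / (1.0 - f)

    def normal_sd(self) -> float:
        """Patient-level SD of the normal-component mean.

        The fraction-independent share of Var(mean_all) is pinned by the
        published feature correlation: sd_indep = sqrt(1 - rho^2) * sd_all.
        """
        f = self.atypical_fraction
        if f >= 1.0:
            return 0.0
        rho = min(max(abs(self.feature_correlation), 0.0), 1.0)
        return math.sqrt(1.0 - rho * rho) * self.sd_all / (1.0 - f)


#: Published class-conditional score statistics: fraction of atypical cells
#: (text values 14/16/39% with the caption SDs), mean atypical-cell score and
#: per-patient mean-of-all-cells distribution.  BNG shares the LGD parameters
#: (the source lumps benign with LGD at 14%).  Cohort composition n=60
#: reconstructed from the holdout denominators (15 OSCC, ~12 HGD, 3 LGD/BNG
#: in the 30-patient test half).
DEFAULT_CLASS_SPECS: dict[str, ClassScoreSpec] = {
    "OSCC": ClassScoreSpec(n_patients=30, atypical_fraction=0.39,
                           atypical_fraction_sd=0.11, mean_atypical=0.71,
                           sd_atypical=0.02, mean_all=0.40, sd_all=0.08),
    "HGD": ClassScoreSpec(n_patients=24, atypical_fraction=0.16,
                          atypical_fraction_sd=0.09, mean_atypical=0.76,
                          sd_atypical=0.03, mean_all=0.21, sd_all=0.08),
    "LGD": ClassScoreSpec(n_patients=4, atypical_fraction=0.14,
                          atypical_fraction_sd=0.09, mean_atypical=0.78,
                          sd_atypical=0.03, mean_all=0.17, sd_all=0.09),
    "BNG": ClassScoreSpec(n_patients=2, atypical_fraction=0.14,
                          atypical_fraction_sd=0.09, mean_atypical=0.78,
                          sd_atypical=0.03, mean_all=0.17, sd_all=0.09),
}


@dataclass(frozen=True)
class CohortSpec:
    classes: dict[str, ClassScoreSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECS))
    seed: int = 0

    def validate(self) -> None:
        if not self.classes:
            raise SpecValidationError("classes must not be empty")
        for name, cs in self.classes.items():
            cs.validate(name)


def _trunc_draw(rng, mean, sd, lo, hi, size):
    """Mean-corrected truncated-normal draws on (lo, hi].

    The location parameter is solved so the *truncated* mean equals ``mean``
    (plain truncation would bias component means toward the interval centre,
    breaking the contract that component means match the spec).  A degenerate
    sd collapses to the mean.
    """
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    mean = float(np.clip(mean, lo + 0.02 * sd, hi - 0.02 * sd))

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    from scipy.optimize import brentq

    lo_loc, hi_loc = lo - 12.0 * sd, hi + 12.0 * sd
    try:
        loc = brentq(trunc_mean, lo_loc, hi_loc, xtol=1e-10)
    except ValueError:  # target unreachable within bracket; fall back
        loc = mean
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size,
                               random_state=rng)


def generate_score_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a seeded cohort of patients with per-cell atypia scores.

    For each patient the atypical fraction, atypical-component mean and
    normal-component mean are drawn around the class values, cell count is
    Poisson around ``cells_per_patient``, and per-cell scores are truncated
    normals on (0, 0.5] / (0.5, 1].  All draws are clipped to [0, 1] by
    construction.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    records: list[PatientRecord] = []
    pid = 0
    for cls in sorted(spec.classes):
        cs = spec.classes[cls]
        mu_n_cls = cs.normal_mean()
        sd_n = cs.normal_sd()
        for _ in range(cs.n_patients):
            pid += 1
            f_i = float(np.clip(rng.normal(cs.atypical_fraction,
                                           cs.atypical_fraction_sd), 0.0, 1.0))
            if cs.atypical_fraction in (0.0, 1.0):
                f_i = cs.atypical_fraction
            mu_a_i = float(np.clip(rng.normal(cs.mean_atypical, cs.sd_atypical),
                                   0.52, 0.98))
            mu_n_i = float(np.clip(rng.normal(mu_n_cls, sd_n), 0.02, 0.48))
            n_cells = max(1, int(rng.poisson(cs.cells_per_patient)))
            n_atyp = int(rng.binomial(n_cells, f_i))
            scores = np.empty(n_cells, dtype=np.float64)
            if n_atyp:
                scores[:n_atyp] = _trunc_draw(rng, mu_a_i, cs.cell_sd_atypical,
                                              0.5, 1.0, n_atyp)
            if n_cells - n_atyp:
                scores[n_atyp:] = _trunc_draw(rng, mu_n_i, cs.cell_sd_normal,
                                              0.0, 0.5, n_cells - n_atyp)
            rng.shuffle(scores)
            records.append(PatientRecord(patient_id=f"P{pid:03d}", label=cls,
                                         scores=scores.tolist()))
    return records
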