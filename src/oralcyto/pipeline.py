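"""Pipeline driver, file adapters and configuration.

``run_pipeline`` chains the whole workflow — simulate (or ingest) → segment →
QC → score → aggregate → stratify → evaluate — and writes per-stage artifacts
plus a machine-readable run manifest into a run directory.  Artifacts are
deterministic for a given (config, seed): timings go to the log, never into
compared files.

Config is a single YAML file; every numeric default that is a package choice
rather than an acquisition constant lives in the dataclasses it mirrors and
is annotated there.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import PatientRecord
from .cascade import CascadeRiskModel, features_frame
from .evaluation import ConfusionCounts, metrics_from_counts
from .qc import QCCriteria, apply_qc
from .scoring import ScorerSpec, score_cells, train_reference_scorer
from .segmentation import (CellROI, FieldImage, SegmentationParams,
                           segment_field)
from .synthetic import (ClassScoreSpec, CohortSpec, SceneSpec,
                        generate_field_image, generate_slide, field_seed)

logger = logging.getLogger(__name__)

MANIFEST_VERSION = 1

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "SchemaError",
    "run_pipeline",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "read_manifest",
    "write_manifest",
    "evaluate_predictions",
    "TABLE_SCHEMAS",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input id."""

    def __init__(self, stage: str, message: str, input_id: str = ""):
        self.stage = stage
        self.input_id = input_id
        super().__init__(f"stage {stage!r}"
                         + (f" (input {input_id})" if input_id else "")
                         + f": {message}")


class SchemaError(ValueError):
    """A table or manifest did not match its declared schema."""


# ---------------------------------------------------------------------------
# adapters
# ---------------------------------------------------------------------------

def write_image(path, pixels: np.ndarray) -> None:
    """Write an 8-bit RGB image as PNG or TIFF, by extension."""
    import imageio.v3 as iio

    path = Path(path)
    if pixels.dtype != np.uint8 or pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("images must be 8-bit-per-channel RGB")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, pixels)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, pixels)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_image(path, pixel_scale: float = 1.9) -> FieldImage:
    """Read a PNG/TIFF field image; anything but 8-bit RGB is an error."""
    import imageio.v3 as iio

    path = Path(path)
    px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha only if fully opaque
        if np.all(px[:, :, 3] == 255):
            px = px[:, :, :3]
    if px.dtype != np.uint8 or px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"{path}: expected 8-bit RGB, got "
                         f"dtype={px.dtype}, shape={px.shape}")
    return FieldImage(pixels=px, pixel_scale=pixel_scale, source_id=path.stem)


TABLE_SCHEMAS = {
    "cohort_scores": ["patient_id", "class", "cell_id", "score"],
    "features": ["patient_id", "class", "n_cells", "pct_atypical",
                 "mean_all", "mean_atypical"],
    "predictions": ["patient_id", "stratum", "test1_margin", "mean_atypical"],
    "scores": ["patient_id", "roi_id", "score", "atypical", "bin"],
    "qc_report": ["roi_id", "size_aspect", "shadow", "hematoxylin_area",
                  "nucleus", "passed", "failure_reason"],
    "truth": ["patient_id", "class"],
}


def write_table(path, df: pd.DataFrame, schema: str) -> None:
    cols = TABLE_SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table {schema!r} is missing column {missing[0]!r}")
    df[cols].to_csv(path, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in TABLE_SCHEMAS[schema]:
        if c not in df.columns:
            raise SchemaError(f"{path}: table {schema!r} is missing column {c!r}")
    return df


def write_manifest(path, payload: dict) -> None:
    payload = {"version": MANIFEST_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    d = json.loads(Path(path).read_text())
    v = d.get("version")
    if v != MANIFEST_VERSION:
        raise SchemaError(f"{path}: unsupported manifest version {v!r} "
                          f"(expected {MANIFEST_VERSION})")
    return d


def roi_manifest_entry(patient_id: str, field_id: str, roi: CellROI) -> dict:
    e = {
        "patient_id": patient_id, "field_id": field_id, "roi_id": roi.roi_id,
        "box": [roi.x0, roi.y0, roi.x1, roi.y1],
        "area_px": roi.area_px, "area_um2": roi.area_um2,
        "aspect_ratio": roi.aspect_ratio,
        "channel_means": list(roi.channel_means),
        "centroid": list(roi.centroid),
    }
    if roi.qc is not None:
        e["qc_passed"] = roi.qc.passed
        e["qc_failure_reason"] = roi.qc.failure_reason
    return e


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML.

    ``mode`` selects the input source: ``"cohort"`` simulates per-cell score
    tables directly (fast, cohort-scale), ``"images"`` renders small synthetic
    fields per patient and runs the full image path (segment → QC → train
    scorer → score).
    """

    mode: str = "images"
    seed: int = 0
    scene: SceneSpec = field(default_factory=lambda: SceneSpec(
        image_width=512, image_height=512, fov_radius=240, n_cells=10,
        cell_diameter_range=(22.0, 40.0)))
    cohort: CohortSpec = field(default_factory=CohortSpec)
    qc: QCCriteria = field(default_factory=QCCriteria)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    scorer_kind: str = "reference_morphometric"
    split_fraction: float = 0.5
    stratify: bool = True
    svm_C: float = 1.0
    rounding_decimals: int = 0
    log_level: str = "INFO"
    # images-mode cohort shape (kept small: the image path is a demonstration
    # of the full chain, not the statistical study, which uses cohort mode)
    images_patients_per_class: int = 4
    images_fields_per_patient: int = 2
    images_atypical_fraction: dict = field(default_factory=lambda: {
        "BNG": 0.05, "LGD": 0.15, "HGD": 0.35, "OSCC": 0.55})
    images_training_fields: int = 4

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = {
            "seed": self.cohort.seed,
            "classes": {k: dataclasses.asdict(v)
                        for k, v in self.cohort.classes.items()},
        }
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d:
            s = dict(d["scene"])
            if s.get("stain_palette") is not None:
                from .synthetic import StainPalette
                s["stain_palette"] = StainPalette(**{
                    k: _listlike_to_tuple(v) for k, v in s["stain_palette"].items()})
            for key in ("fov_center", "cell_diameter_range",
                        "nucleus_fraction_range",
                        "atypical_nucleus_fraction_range"):
                if s.get(key) is not None:
                    s[key] = tuple(s[key])
            d["scene"] = SceneSpec(**s)
        if "cohort" in d:
            c = d["cohort"]
            d["cohort"] = CohortSpec(
                classes={k: ClassScoreSpec(**v) for k, v in c["classes"].items()},
                seed=c.get("seed", 0))
        if "qc" in d:
            d["qc"] = QCCriteria(**d["qc"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _listlike_to_tuple(v):
    if isinstance(v, (list, tuple)):
        return tuple(_listlike_to_tuple(x) for x in v)
    return v


# ---------------------------------------------------------------------------
# evaluation of prediction tables
# ---------------------------------------------------------------------------

def evaluate_predictions(pred: pd.DataFrame, truth: pd.DataFrame,
                         decimals: int = 0) -> dict:
    """Diagnostic metrics of a predictions table against a truth table.

    Reports Test 1 (OSCC vs rest), Test 2 (HGD vs LGD/BNG among Test-1
    negatives) and overall (OSCC/HGD vs LGD/BNG) sensitivity/specificity/
    accuracy as percents (half-up) with raw fractions alongside.
    """
    merged = pred.merge(truth, on="patient_id", how="inner", validate="1:1")
    if len(merged) == 0:
        raise ValueError("predictions and truth share no patient ids")
    out: dict = {"n": int(len(merged))}

    def block(pred_pos, truth_pos, name):
        counts = ConfusionCounts.from_predictions(list(pred_pos),
                                                  list(truth_pos), positive=True)
        m = metrics_from_counts(counts)
        out[name] = {
            "counts": {"tp": counts.tp, "fn": counts.fn,
                       "tn": counts.tn, "fp": counts.fp},
            "percent": m.percent(decimals=decimals),
            "fractions": {k: getattr(m, k) for k in
                          ("sensitivity", "specificity", "accuracy", "ppv", "npv")},
        }

    t1_pred = merged["stratum"] == "OSCC_risk"
    block(t1_pred, merged["class"] == "OSCC", "test1")
    neg = ~t1_pred
    sub = merged.loc[neg]
    keep = sub["class"].isin(["HGD", "LGD", "BNG"])
    if keep.any():
        block(sub.loc[keep, "stratum"] == "HGD_risk",
              sub.loc[keep, "class"] == "HGD", "test2")
    block(merged["stratum"] != "LGD_or_benign",
          merged["class"].isin(["OSCC", "HGD"]), "overall")
    return out


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _match_roi_label(roi: CellROI, truth) -> str | None:
    """Ground-truth atypia label of the cell a segmented ROI lands on."""
    x, y = int(round(roi.centroid[0])), int(round(roi.centroid[1]))
    h, w = truth.cell_labels.shape
    if not (0 <= y < h and 0 <= x < w):
        return None
    cid = int(truth.cell_labels[y, x])
    if cid == 0:
        return None
    for cell in truth.cells:
        if cell.cell_id == cid:
            return cell.label
    return None


def _images_mode_records(cfg: PipelineConfig, out: Path, counts: dict
                         ) -> tuple[list[PatientRecord], ScorerSpec]:
    import dataclasses as dc

    if cfg.scorer_kind != "reference_morphometric":
        raise PipelineStageError(
            "score", f"unknown or missing scorer {cfg.scorer_kind!r}")
    fields_dir = out / "fields"
    fields_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x1A)))

    # train the reference scorer on dedicated, GT-labelled training fields
    train_scene = dc.replace(cfg.scene, atypical_fraction=0.5,
                             seed=field_seed(cfg.seed, 9000))
    labelled = []
    for i in range(cfg.images_training_fields):
        scn = dc.replace(train_scene, seed=field_seed(cfg.seed, 9000 + i))
        img, gt = generate_field_image(scn)
        rois = segment_field(img, cfg.segmentation)
        passing, _ = apply_qc(rois, cfg.qc)
        for roi in passing:
            lab = _match_roi_label(roi, gt)
            if lab is not None:
                labelled.append((roi, lab))
    if not labelled:
        raise PipelineStageError("score", "no labelled training ROIs; "
                                          "cannot build the scorer")
    scorer = train_reference_scorer(labelled, seed=cfg.seed)
    counts["scorer_training_rois"] = len(labelled)

    records: list[PatientRecord] = []
    roi_entries, qc_rows, score_rows = [], [], []
    pid = 0
    for cls in ("BNG", "LGD", "HGD", "OSCC"):
        for _ in range(cfg.images_patients_per_class):
            pid += 1
            patient_id = f"P{pid:03d}"
            scores: list[float] = []
            for f in range(cfg.images_fields_per_patient):
                scn = dc.replace(
                    cfg.scene,
                    atypical_fraction=cfg.images_atypical_fraction[cls],
                    seed=field_seed(cfg.seed, pid * 100 + f))
                img, gt = generate_field_image(scn)
                field_id = f"{patient_id}_f{f}"
                write_image(fields_dir / f"{field_id}.png", img.pixels)
                rois = segment_field(img, cfg.segmentation)
                passing, tally = apply_qc(rois, cfg.qc)
                for roi in rois:
                    roi_entries.append(roi_manifest_entry(patient_id, field_id, roi))
                    qc_rows.append({
                        "roi_id": f"{field_id}:{roi.roi_id}",
                        **{k: getattr(roi.qc, k) for k in
                           ("size_aspect", "shadow", "hematoxylin_area",
                            "nucleus", "passed", "failure_reason")}})
                cell_scores = score_cells(passing, scorer)
                for cs in cell_scores:
                    score_rows.append({"patient_id": patient_id,
                                       "roi_id": f"{field_id}:{cs.roi_id}",
                                       "score": cs.score,
                                       "atypical": cs.atypical, "bin": cs.bin})
                scores.extend(cs.score for cs in cell_scores)
            if not scores:  # degenerate patient: keep the record scoreable
                scores = [0.0]
            records.append(PatientRecord(patient_id=patient_id, label=cls,
                                         scores=scores))
    write_manifest(out / "roi_manifest.json", {"rois": roi_entries})
    write_table(out / "qc_report.csv", pd.DataFrame(qc_rows), "qc_report")
    write_table(out / "scores.csv", pd.DataFrame(score_rows), "scores")
    (out / "scorer.json").write_text(json.dumps(scorer.to_dict(), indent=2,
                                                sort_keys=True))
    counts["fields"] = pid * cfg.images_fields_per_patient
    counts["rois"] = len(roi_entries)
    counts["scored_cells"] = len(score_rows)
    del rng
    return records, scorer


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute the configured workflow; returns the run directory.

    Stage failures are wrapped in :class:`PipelineStageError` with the stage
    name.  Re-running with the same config and seed reproduces every CSV/JSON
    artifact byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    t0 = time.perf_counter()

    stage = "simulate"
    try:
        if cfg.mode == "images":
            records, _scorer = _images_mode_records(cfg, out, counts)
        elif cfg.mode == "cohort":
            from .synthetic import generate_score_cohort

            cohort_spec = dataclasses.replace(cfg.cohort, seed=cfg.seed)
            records = generate_score_cohort(cohort_spec)
            rows = [{"patient_id": r.patient_id, "class": r.label,
                     "cell_id": i, "score": s}
                    for r in records for i, s in enumerate(r.scores)]
            write_table(out / "cohort_scores.csv", pd.DataFrame(rows),
                        "cohort_scores")
            counts["scored_cells"] = len(rows)
        else:
            raise PipelineStageError("simulate", f"unknown mode {cfg.mode!r}")
        counts["patients"] = len(records)
        timings["simulate"] = time.perf_counter() - t0

        stage = "aggregate"
        t = time.perf_counter()
        feats = features_frame(records)
        fcsv = feats.rename(columns={"label": "class"})
        write_table(out / "features.csv", fcsv, "features")
        timings["aggregate"] = time.perf_counter() - t

        stage = "stratify"
        t = time.perf_counter()
        model = CascadeRiskModel(feats)
        res = model.fit(train_fraction=cfg.split_fraction, seed=cfg.seed,
                        stratify=cfg.stratify, C=cfg.svm_C)
        (out / "model.json").write_text(json.dumps(res.to_dict(), indent=2,
                                                   sort_keys=True) + "\n")
        pred = res.predict(feats)
        write_table(out / "predictions.csv", pred, "predictions")
        timings["stratify"] = time.perf_counter() - t

        stage = "evaluate"
        t = time.perf_counter()
        truth = feats[["patient_id", "label"]].rename(columns={"label": "class"})
        heldout_pred = res.predictions
        heldout_truth = truth[truth["patient_id"].isin(res.test["patient_id"])]
        metrics = evaluate_predictions(heldout_pred, heldout_truth,
                                       decimals=cfg.rounding_decimals)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2,
                                                     sort_keys=True) + "\n")
        (out / "summary.txt").write_text(res.summary() + "\n")
        timings["evaluate"] = time.perf_counter() - t
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    write_manifest(out / "run_manifest.json", {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "counts": counts,
    })
    for name, secs in timings.items():
        logger.info("stage %s: %.2f s", name, secs)
    return out
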