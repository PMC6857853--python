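"""Per-cell atypia scoring.

The scoring contract is a single number in [0, 1] per cell (0 = most likely
normal, 1 = most likely atypical); cells scoring strictly above 0.5 are
atypical.  Deployed screening systems fill this contract with a
transfer-learned convolutional network (Inception V3 class, trained for 4000
epochs at learning rate 0.01 with a 90/10 train/validation split — recorded
here as provenance metadata only).  This package ships a trainable
morphometric reference scorer with the same contract: a regularised logistic
model on cell geometry and stain features, which is deterministic, desk-scale
and has signal on the synthetic generator because atypia is rendered
morphologically (enlarged, irregular nuclei).

Score bins follow the conventional reporting ranges: [0, 0.3), [0.3, 0.5),
[0.5, 0.7), [0.7, 0.9), [0.9, 1] — half-open, closed on the left, top bin
closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.measure import regionprops
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .aggregation import ATYPIA_THRESHOLD
from .segmentation import CellROI

__all__ = [
    "BIN_LABELS",
    "CellScore",
    "ScorerSpec",
    "assign_bin",
    "score_cells",
    "roi_features",
    "FEATURE_NAMES",
    "train_reference_scorer",
]

BIN_LABELS = ("<0.3", "0.3-0.5", "0.5-0.7", "0.7-0.9", ">0.9")
_BIN_EDGES = (0.3, 0.5, 0.7, 0.9)

#: Training settings of the CNN scorers this contract mirrors; provenance
#: metadata only, nothing here consumes them.
CNN_REFERENCE_METADATA = {"architecture": "inception_v3_transfer",
                          "epochs": 4000, "learning_rate": 0.01,
                          "validation_fraction": 0.10}

FEATURE_NAMES = ("area_um2", "aspect_ratio", "nucleus_cell_ratio",
                 "nucleus_irregularity", "mean_red", "mean_green", "mean_blue")


@dataclass(frozen=True)
class CellScore:
    roi_id: int
    score: float
    atypical: bool
    bin: str

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


def assign_bin(score: float) -> str:
    """Reporting bin for one score; raises on scores outside [0, 1]."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    for edge, lab in zip(_BIN_EDGES, BIN_LABELS):
        if score < edge:
            return lab
    return BIN_LABELS[-1]


def roi_features(roi: CellROI) -> np.ndarray:
    """Morphometric + stain feature vector for one QC-passed ROI.

    Nucleus boundary irregularity is the isoperimetric ratio
    perimeter^2 / (4 pi area) of the nucleus mask (1.0 for a circle, larger
    for irregular membranes); it and the nucleus/cell area ratio are purely
    geometric, hence invariant to uniform intensity rescaling.
    """
    if roi.nucleus_mask is not None and roi.nucleus_mask.any():
        nuc_area = float(roi.nucleus_mask.sum())
        props = regionprops(roi.nucleus_mask.astype(np.uint8))[0]
        perim = props.perimeter
        irregularity = (perim ** 2) / (4.0 * math.pi * nuc_area) if nuc_area else 1.0
    else:
        nuc_area, irregularity = 0.0, 1.0
    r, g, b = roi.channel_means
    return np.array([roi.area_um2, roi.aspect_ratio, nuc_area / roi.area_px,
                     irregularity, r, g, b], dtype=np.float64)


@dataclass
class ScorerSpec:
    """A pluggable per-cell scorer.

    ``kind`` is ``"reference_morphometric"`` (a fitted sklearn pipeline in
    ``model``) or ``"external"`` (any callable mapping a list of ROIs to a
    sequence of scores; each score must lie in [0, 1]).
    """

    kind: str = "reference_morphometric"
    model: Pipeline | None = None
    external: Callable[[Sequence[CellROI]], Sequence[float]] | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Serialisable form (linear coefficients + standardisation)."""
        if self.kind != "reference_morphometric" or self.model is None:
            raise ValueError("only fitted reference scorers serialise to dict")
        scaler: StandardScaler = self.model.named_steps["scale"]
        clf: LogisticRegression = self.model.named_steps["logit"]
        return {
            "kind": self.kind,
            "feature_names": list(FEATURE_NAMES),
            "scale_mean": scaler.mean_.tolist(),
            "scale_std": scaler.scale_.tolist(),
            "coef": clf.coef_[0].tolist(),
            "intercept": float(clf.intercept_[0]),
            "metadata": {k: v for k, v in self.metadata.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScorerSpec":
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(d["scale_mean"], dtype=np.float64)
        scaler.scale_ = np.asarray(d["scale_std"], dtype=np.float64)
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = scaler.mean_.size
        clf = LogisticRegression()
        clf.coef_ = np.asarray([d["coef"]], dtype=np.float64)
        clf.intercept_ = np.asarray([d["intercept"]], dtype=np.float64)
        clf.classes_ = np.array([0, 1])
        pipe = Pipeline([("scale", scaler), ("logit", clf)])
        return cls(kind=d["kind"], model=pipe, metadata=dict(d.get("metadata", {})))


def train_reference_scorer(labelled: Sequence[tuple[CellROI, str]],
                           seed: int = 0,
                           validation_fraction: float = 0.10,
                           C: float = 1.0) -> ScorerSpec:
    """Fit the morphometric reference scorer on labelled ROIs.

    ``labelled`` pairs each ROI with ``"normal"`` or ``"atypical"``.  A
    stratified 90/10 train/validation split reports held-out accuracy in the
    returned metadata; the final model is refit on all examples.  Deterministic
    given the seed.
    """
    if len(labelled) < 4:
        raise ValueError("need at least 2 examples per class")
    y = np.array([1 if lab == "atypical" else 0 for _, lab in labelled])
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 examples per class (got a single class)")
    X = np.stack([roi_features(roi) for roi, _ in labelled])

    def make_pipe():
        return Pipeline([
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=C, max_iter=2000, random_state=seed)),
        ])

    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=validation_fraction, random_state=seed, stratify=y)
    probe = make_pipe().fit(X_tr, y_tr)
    val_acc = float((probe.predict(X_val) == y_val).mean()) if len(y_val) else float("nan")

    model = make_pipe().fit(X, y)
    meta = {
        "n_normal": int((y == 0).sum()),
        "n_atypical": int((y == 1).sum()),
        "seed": seed,
        "validation_fraction": validation_fraction,
        "validation_accuracy": val_acc,
        "cnn_reference": dict(CNN_REFERENCE_METADATA),
    }
    return ScorerSpec(kind="reference_morphometric", model=model, metadata=meta)


def score_cells(rois: Sequence[CellROI], scorer: ScorerSpec) -> list[CellScore]:
    """Score each ROI, preserving order; fill the atypical flag and bin."""
    if scorer.kind == "reference_morphometric":
        if scorer.model is None:
            raise ValueError("reference scorer has no fitted model")
        if not rois:
            return []
        X = np.stack([roi_features(r) for r in rois])
        raw = scorer.model.predict_proba(X)[:, 1]
    elif scorer.kind == "external":
        if scorer.external is None:
            raise ValueError("external scorer has no callable")
        raw = list(scorer.external(rois))
        if len(raw) != len(rois):
            raise ValueError("external scorer returned wrong number of scores")
    else:
        raise ValueError(f"unknown scorer kind {scorer.kind!r}")
    out: list[CellScore] = []
    for roi, s in zip(rois, raw):
        s = float(s)
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"scorer emitted score {s} outside [0, 1] "
                             f"for roi_id {roi.roi_id}")
        out.append(CellScore(roi_id=roi.roi_id, score=s,
                             atypical=s > ATYPIA_THRESHOLD, bin=assign_bin(s)))
    return out
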