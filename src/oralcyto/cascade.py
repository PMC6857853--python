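"""Two-test cascade risk stratification of patients.

Patients are stratified sequentially from their aggregate score features:

* **Test 1** — a linear-kernel support-vector machine on the standardized
  pair (mean score of all cells, percentage of atypical cells), trained on a
  random half of the cohort, flags OSCC risk.
* **Test 2** — Test-1 negatives are compared against a scalar cutoff on the
  mean score of atypical cells.  The cutoff is derived by ROC analysis of
  OSCC versus LGD training patients (Youden's J, ties toward the lower
  cutoff) and then applied to delineate HGD from LGD/benign.  A patient with
  no atypical cell has an undefined mean atypical score and is an automatic
  Test-2 negative.

The public surface follows the statsmodels convention: build a
:class:`CascadeRiskModel` from a patient-feature table (or directly
``from_records``), call :meth:`~CascadeRiskModel.fit`, and read estimates,
held-out diagnostics and a ``summary()`` off the returned
:class:`CascadeResults`.  The individual operations (``split_cohort``,
``train_test1``, ``derive_test2_cutoff``, ``cascade_predict``,
``compare_learners``) are module-level functions the results object delegates
to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .aggregation import PatientRecord, aggregate_patient
from .evaluation import (ConfusionCounts, DiagnosticMetrics, ROCResult,
                         metrics_from_counts, roc_analysis)

__all__ = [
    "STRATA",
    "FEATURE_COLUMNS",
    "Test1Model",
    "Test2Cutoff",
    "CascadeModel",
    "CascadeRiskModel",
    "CascadeResults",
    "features_frame",
    "split_cohort",
    "train_test1",
    "derive_test2_cutoff",
    "cascade_predict",
    "compare_learners",
]

#: Mutually exclusive, exhaustive output strata.
STRATA = ("OSCC_risk", "HGD_risk", "LGD_or_benign")

FEATURE_COLUMNS = ("mean_all", "pct_atypical", "mean_atypical")

_POSITIVE_CLASS = "OSCC"


def features_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Aggregate per-cell scores into the canonical patient-feature table.

    Columns: patient_id, label, n_cells, pct_atypical, mean_all,
    mean_atypical (NaN when the patient has no atypical cell).
    """
    rows = []
    for rec in records:
        feats = rec.features or aggregate_patient(rec)
        rows.append({
            "patient_id": rec.patient_id,
            "label": rec.label,
            "n_cells": len(rec.scores),
            "pct_atypical": feats.percentage_atypical,
            "mean_all": feats.mean_score_all,
            "mean_atypical": (math.nan if feats.mean_score_atypical is None
                              else feats.mean_score_atypical),
        })
    return pd.DataFrame(rows)


def split_cohort(df: pd.DataFrame, fraction: float = 0.5, seed: int = 0,
                 stratify: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded, disjoint, exhaustive train/test split, stratified by class.

    With stratification each class contributes ``round(fraction * n_class)``
    patients to training; any class with fewer than 2 members raises.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    train_idx: list[int] = []
    if stratify:
        for cls in sorted(df["label"].dropna().unique()):
            idx = df.index[df["label"] == cls].to_numpy()
            if idx.size < 2:
                raise ValueError(
                    f"class {cls!r} has fewer than 2 members; cannot stratify")
            k = int(math.floor(fraction * idx.size + 0.5))
            k = min(max(k, 1), idx.size - 1)
            picked = rng.choice(idx, size=k, replace=False)
            train_idx.extend(picked.tolist())
    else:
        idx = df.index.to_numpy()
        k = int(math.floor(fraction * idx.size + 0.5))
        train_idx = rng.choice(idx, size=k, replace=False).tolist()
    train_mask = df.index.isin(train_idx)
    return df.loc[train_mask].copy(), df.loc[~train_mask].copy()


@dataclass
class Test1Model:
    """Linear decision rule on standardized (mean_all, pct_atypical)."""

    weights: np.ndarray  # shape (2,)
    intercept: float
    feature_means: np.ndarray
    feature_stds: np.ndarray
    train_ids: list[str]
    seed: int
    C: float = 1.0

    def margin(self, mean_all, pct_atypical) -> np.ndarray:
        x = np.column_stack([np.atleast_1d(mean_all),
                             np.atleast_1d(pct_atypical)]).astype(float)
        z = (x - self.feature_means) / self.feature_stds
        return z @ self.weights + self.intercept

    def predict_positive(self, mean_all, pct_atypical) -> np.ndarray:
        return self.margin(mean_all, pct_atypical) > 0.0

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "intercept": self.intercept,
                "feature_means": self.feature_means.tolist(),
                "feature_stds": self.feature_stds.tolist(),
                "train_ids": list(self.train_ids), "seed": self.seed, "C": self.C}

    @classmethod
    def from_dict(cls, d: dict) -> "Test1Model":
        return cls(weights=np.asarray(d["weights"], float),
                   intercept=float(d["intercept"]),
                   feature_means=np.asarray(d["feature_means"], float),
                   feature_stds=np.asarray(d["feature_stds"], float),
                   train_ids=list(d["train_ids"]), seed=int(d["seed"]),
                   C=float(d.get("C", 1.0)))


def train_test1(train: pd.DataFrame, C: float = 1.0, seed: int = 0) -> Test1Model:
    """Fit the Test-1 linear SVM (positive class OSCC) on the training half."""
    y = (train["label"] == _POSITIVE_CLASS).to_numpy()
    if y.all() or not y.any():
        raise ValueError("Test 1 needs both OSCC and non-OSCC training patients")
    X = train[["mean_all", "pct_atypical"]].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("Test-1 features contain undefined values")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (X - mu) / sd
    svc = SVC(kernel="linear", C=C, random_state=seed)
    svc.fit(z, y.astype(int))
    return Test1Model(weights=svc.coef_[0].astype(float),
                      intercept=float(svc.intercept_[0]),
                      feature_means=mu, feature_stds=sd,
                      train_ids=train["patient_id"].tolist(), seed=seed, C=C)


@dataclass
class Test2Cutoff:
    """ROC-derived scalar cutoff on the mean atypical-cell score."""

    cutoff: float
    roc: ROCResult
    youden_j: float
    non_informative: bool = False

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "youden_j": self.youden_j,
                "non_informative": self.non_informative,
                "roc_auc": self.roc.auc if self.roc is not None else None}


def derive_test2_cutoff(train: pd.DataFrame) -> Test2Cutoff:
    """ROC cutoff on mean_atypical separating OSCC from LGD training patients.

    Patients with an undefined mean atypical score cannot inform the cutoff
    and are dropped from the derivation.
    """
    sub = train[train["label"].isin(["OSCC", "LGD"])].dropna(subset=["mean_atypical"])
    if (sub["label"] == "OSCC").sum() == 0 or (sub["label"] == "LGD").sum() == 0:
        raise ValueError("Test 2 derivation needs OSCC and LGD training patients "
                         "with defined mean atypical scores")
    roc = roc_analysis(sub["mean_atypical"].to_numpy(),
                       sub["label"].to_numpy(), positive="OSCC")
    return Test2Cutoff(cutoff=roc.youden_cutoff, roc=roc, youden_j=roc.youden_j,
                       non_informative=roc.non_informative)


@dataclass
class CascadeModel:
    """Fitted cascade: Test-1 rule, Test-2 cutoff and the label map."""

    test1: Test1Model
    test2: Test2Cutoff
    label_map: dict = dc_field(default_factory=lambda: {
        "positive1": "OSCC_risk", "positive2": "HGD_risk",
        "negative": "LGD_or_benign"})
    # instrumentation: number of Test-2 evaluations, to assert the cascade
    # contract that Test 2 never sees a Test-1 positive
    test2_evaluations: int = 0


def cascade_predict(row, model: CascadeModel) -> str:
    """Stratum for one patient (mapping or dataclass with the feature fields)."""
    mean_all = row["mean_all"] if isinstance(row, (dict, pd.Series)) else row.mean_all
    pct = row["pct_atypical"] if isinstance(row, (dict, pd.Series)) else row.pct_atypical
    ma = row["mean_atypical"] if isinstance(row, (dict, pd.Series)) else row.mean_atypical
    if bool(model.test1.predict_positive(mean_all, pct)[0]):
        return model.label_map["positive1"]
    if ma is None or (isinstance(ma, float) and math.isnan(ma)):
        return model.label_map["negative"]  # no atypical cells: automatic negative
    model.test2_evaluations += 1
    if ma >= model.test2.cutoff:
        return model.label_map["positive2"]
    return model.label_map["negative"]


_LEARNERS = ("SVM", "RandomForest", "LogisticRegression",
             "LinearDiscriminant", "KNN")


def _make_learner(name: str, seed: int):
    if name == "SVM":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "RandomForest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "LogisticRegression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "LinearDiscriminant":
        return LinearDiscriminantAnalysis()
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    raise KeyError(name)


def compare_learners(train: pd.DataFrame, test: pd.DataFrame,
                     seed: int = 0) -> pd.DataFrame:
    """Fit five linear-ish learners on the Test-1 features under one shared
    standardization and report held-out sensitivity/specificity/accuracy
    (percent).  Per-learner failures are recorded in the ``error`` column,
    not raised."""
    ytr = (train["label"] == _POSITIVE_CLASS).to_numpy().astype(int)
    yte = (test["label"] == _POSITIVE_CLASS).to_numpy().astype(int)
    Xtr = train[["mean_all", "pct_atypical"]].to_numpy(float)
    Xte = test[["mean_all", "pct_atypical"]].to_numpy(float)
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Ztr, Zte = (Xtr - mu) / sd, (Xte - mu) / sd
    rows = []
    for name in _LEARNERS:
        row = {"learner": name, "sensitivity": np.nan, "specificity": np.nan,
               "accuracy": np.nan, "error": None}
        try:
            clf = _make_learner(name, seed)
            clf.fit(Ztr, ytr)
            pred = np.asarray(clf.predict(Zte)).astype(int)
            counts = ConfusionCounts.from_predictions(pred, yte, positive=1)
            m = metrics_from_counts(counts)
            row.update(sensitivity=100.0 * m.sensitivity if m.sensitivity is not None else np.nan,
                       specificity=100.0 * m.specificity if m.specificity is not None else np.nan,
                       accuracy=100.0 * m.accuracy if m.accuracy is not None else np.nan)
        except Exception as exc:  # recorded, not fatal
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("learner")


# ---------------------------------------------------------------------------
# statsmodels-style model / results pair
# ---------------------------------------------------------------------------

class CascadeRiskModel:
    """Cascade risk-stratification model over a patient-feature table.

    Parameters
    ----------
    features : DataFrame with columns ``patient_id``, ``label`` (BNG/LGD/
        HGD/OSCC), ``mean_all``, ``pct_atypical``, ``mean_atypical`` (NaN
        when undefined).  Use :meth:`from_records` to build it from
        per-cell scores.
    """

    def __init__(self, features: pd.DataFrame):
        missing = [c for c in ("patient_id", "label", "mean_all",
                               "pct_atypical", "mean_atypical")
                   if c not in features.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        self.features = features.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[PatientRecord]) -> "CascadeRiskModel":
        return cls(features_frame(records))

    def fit(self, train_fraction: float = 0.5, seed: int = 0,
            stratify: bool = True, C: float = 1.0) -> "CascadeResults":
        """Split the cohort, fit Test 1 and derive the Test-2 cutoff."""
        train, test = split_cohort(self.features, train_fraction, seed, stratify)
        t1 = train_test1(train, C=C, seed=seed)
        t2 = derive_test2_cutoff(train)
        model = CascadeModel(test1=t1, test2=t2)
        return CascadeResults(self, model, train, test, seed=seed)


class CascadeResults:
    """Fitted cascade with held-out diagnostics.

    Attributes
    ----------
    model : CascadeModel — Test-1 weights/intercept and Test-2 cutoff.
    train, test : the split halves of the cohort feature table.
    predictions : DataFrame of held-out strata (filled lazily).
    """

    def __init__(self, model_obj: CascadeRiskModel, model: CascadeModel,
                 train: pd.DataFrame, test: pd.DataFrame, seed: int):
        self.model_obj = model_obj
        self.model = model
        self.train = train
        self.test = test
        self.seed = seed
        self.predictions = self.predict(test)

    # -- prediction ---------------------------------------------------------
    def predict(self, df: pd.DataFrame) -> pd.DataFrame:
        """Stratum, Test-1 margin and mean atypical score per patient."""
        strata = [cascade_predict(row, self.model) for _, row in df.iterrows()]
        margins = self.model.test1.margin(df["mean_all"].to_numpy(float),
                                          df["pct_atypical"].to_numpy(float))
        return pd.DataFrame({
            "patient_id": df["patient_id"].to_numpy(),
            "stratum": strata,
            "test1_margin": margins,
            "mean_atypical": df["mean_atypical"].to_numpy(float),
        })

    # -- diagnostics --------------------------------------------------------
    def heldout_metrics(self) -> dict[str, DiagnosticMetrics]:
        """Test-1, Test-2 and overall confusion metrics on the held-out half.

        Test 1: OSCC vs rest.  Test 2: among Test-1 negatives, truth HGD vs
        LGD/BNG (missed OSCC are not part of the Test-2 table).  Overall:
        OSCC/HGD vs LGD/BNG, positive = any risk stratum.
        """
        test = self.test.reset_index(drop=True)
        pred = self.predictions.reset_index(drop=True)
        out: dict[str, DiagnosticMetrics] = {}

        t1_pred = pred["stratum"] == "OSCC_risk"
        t1_truth = test["label"] == "OSCC"
        out["test1"] = metrics_from_counts(ConfusionCounts.from_predictions(
            t1_pred.tolist(), t1_truth.tolist(), positive=True))

        neg = ~t1_pred
        sub_truth = test.loc[neg, "label"]
        keep = sub_truth.isin(["HGD", "LGD", "BNG"])
        if keep.any():
            t2_pred = (pred.loc[neg, "stratum"][keep] == "HGD_risk").tolist()
            t2_truth = (sub_truth[keep] == "HGD").tolist()
            if t2_truth and (any(t2_truth) or not all(t2_truth)):
                out["test2"] = metrics_from_counts(
                    ConfusionCounts.from_predictions(t2_pred, t2_truth,
                                                     positive=True))
        ov_pred = (pred["stratum"] != "LGD_or_benign").tolist()
        ov_truth = test["label"].isin(["OSCC", "HGD"]).tolist()
        out["overall"] = metrics_from_counts(ConfusionCounts.from_predictions(
            ov_pred, ov_truth, positive=True))
        return out

    def compare_learners(self) -> pd.DataFrame:
        return compare_learners(self.train, self.test, seed=self.seed)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        m = self.heldout_metrics()
        t1 = self.model.test1
        lines = [
            "Cascade risk stratification results",
            "===================================",
            f"cohort: {len(self.model_obj.features)} patients "
            f"(train {len(self.train)}, test {len(self.test)}), seed {self.seed}",
            "",
            "Test 1: linear SVM on (mean_all, pct_atypical), positive = OSCC risk",
            f"  weights: mean_all {t1.weights[0]:+.4f}, "
            f"pct_atypical {t1.weights[1]:+.4f}, intercept {t1.intercept:+.4f}",
            "Test 2: cutoff on mean atypical score "
            f"(Youden J = {self.model.test2.youden_j:.3f})",
            f"  cutoff: {self.model.test2.cutoff:.4f}"
            + ("  [non-informative]" if self.model.test2.non_informative else ""),
            "",
            "held-out diagnostics (percent):",
        ]
        for name, dm in m.items():
            pct = dm.percent(decimals=1)
            lines.append(
                f"  {name:8s} sens {pct['sensitivity']!s:>6} "
                f"spec {pct['specificity']!s:>6} acc {pct['accuracy']!s:>6} "
                f"(n={dm.counts.n})")
        counts = self.predictions["stratum"].value_counts()
        lines.append("")
        lines.append("held-out strata: " + ", ".join(
            f"{s}={int(counts.get(s, 0))}" for s in STRATA))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable model state (weights, cutoff, split, seed)."""
        return {
            "version": 1,
            "seed": self.seed,
            "test1": self.model.test1.to_dict(),
            "test2": self.model.test2.to_dict(),
            "train_ids": self.train["patient_id"].tolist(),
            "test_ids": self.test["patient_id"].tolist(),
        }

    # -- plotting -----------------------------------------------------------
    def plot_features(self, ax=None):
        """Scatter of the Test-1 feature plane with the decision boundary."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model_obj.features
        for cls, marker in zip(("BNG", "LGD", "HGD", "OSCC"), "o^sD"):
            sub = df[df["label"] == cls]
            ax.scatter(sub["mean_all"], sub["pct_atypical"], marker=marker,
                       label=cls, alpha=0.7)
        t1 = self.model.test1
        xs = np.linspace(df["mean_all"].min(), df["mean_all"].max(), 50)
        # w0*zx + w1*zy + b = 0 solved for y
        if t1.weights[1] != 0:
            zx = (xs - t1.feature_means[0]) / t1.feature_stds[0]
            zy = -(t1.weights[0] * zx + t1.intercept) / t1.weights[1]
            ys = zy * t1.feature_stds[1] + t1.feature_means[1]
            ax.plot(xs, ys, "k--", label="Test 1 boundary")
        ax.set_xlabel("mean score of all cells")
        ax.set_ylabel("% atypical cells")
        ax.legend()
        return ax

    def plot_roc(self, ax=None):
        """Test-2 derivation ROC with the Youden-optimal point marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        roc = self.model.test2.roc
        order = np.argsort(roc.fpr)
        ax.plot(roc.fpr[order], roc.tpr[order], drawstyle="steps-post")
        k = int(np.argmin(np.abs(roc.thresholds - self.model.test2.cutoff)))
        ax.plot([roc.fpr[k]], [roc.tpr[k]], "ro", label=f"cutoff {self.model.test2.cutoff:.3f}")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
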