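"""The real-time ovulation-day classifier ("student" model).

A gradient-boosted tree ensemble (XGBoost) maps a one- or two-test-day
instance to a probability vector over the nine relative-to-ovulation
classes.  Missing features (no ultrasound, no second day) are consumed
natively by the trees without imputation.  Per-class one-vs-rest monotone
recalibration (isotonic by default, Platt sigmoid optionally) is applied
on a calibration set disjoint from training; the final prediction is the
argmax of the renormalized calibrated probabilities, with exact ties
broken toward the bin closest to ovulation day zero and then toward the
later bin.
"""

from __future__ import annotations

import hashlib
import io
import json
import tempfile
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

from .instances import FEATURE_REGISTRY, features_matrix, labels_vector
from .records import CLASS_ORDER, Instance, OvulationClass

DEFAULT_GRID: tuple[dict, ...] = tuple(
    {"learning_rate": lr, "max_depth": depth, "n_estimators": n}
    for lr in (0.05, 0.1, 0.3) for depth in (3, 5, 7) for n in (100, 300)
)

DEFAULT_PARAMS: dict = {"learning_rate": 0.1, "max_depth": 5, "n_estimators": 300}

#: Tie-break priority: bins closest to ZERO first, later bin on equal distance.
_TIE_ORDER = sorted(
    range(len(CLASS_ORDER)),
    key=lambda i: (abs(CLASS_ORDER[i].representative_int),
                   -CLASS_ORDER[i].representative_int),
)


@dataclass
class _CalibratorStage:
    """One recalibration pass: per-class monotone maps (None = skipped)."""

    method: str
    maps: list[Optional[tuple[np.ndarray, np.ndarray]]]  # (x, y) interpolation knots

    def apply(self, scores: np.ndarray) -> np.ndarray:
        out = scores.copy()
        for c, knots in enumerate(self.maps):
            if knots is None:
                continue
            x, y = knots
            out[:, c] = np.interp(scores[:, c], x, y)
        return out

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "maps": [None if m is None else [m[0].tolist(), m[1].tolist()]
                     for m in self.maps],
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "_CalibratorStage":
        maps = [None if m is None else (np.asarray(m[0], dtype=float),
                                        np.asarray(m[1], dtype=float))
                for m in d["maps"]]
        return cls(method=d["method"], maps=maps)


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _frame(instances: Sequence[Instance]) -> pd.DataFrame:
    return pd.DataFrame(features_matrix(instances), columns=list(FEATURE_REGISTRY))


@dataclass
class StudentModel:
    """Fitted ovulation-class predictor with optional calibration stages."""

    booster: xgb.Booster
    feature_names: tuple[str, ...] = FEATURE_REGISTRY
    class_order: tuple[OvulationClass, ...] = CLASS_ORDER
    present_classes: tuple[int, ...] = tuple(range(len(CLASS_ORDER)))
    calibration_stages: list[_CalibratorStage] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- scoring ----------------------------------------------------------
    def _raw_proba(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.booster.predict(xgb.DMatrix(X))
        if proba.ndim == 1:  # two-class softprob can come back flattened
            proba = np.column_stack([1.0 - proba, proba])
        full = np.zeros((len(X), len(self.class_order)))
        for j, cls_idx in enumerate(self.present_classes):
            full[:, int(cls_idx)] = proba[:, j]
        return full

    def per_class_scores(self, instances: Sequence[Instance]) -> np.ndarray:
        """Calibrated (but unnormalized) one-vs-rest scores, shape (n, 9)."""
        scores = self._raw_proba(_frame(instances))
        for stage in self.calibration_stages:
            scores = stage.apply(scores)
        return scores

    def predict_proba(self, instances: Sequence[Instance]) -> np.ndarray:
        """Probability vectors over the nine classes; each row sums to 1."""
        scores = np.clip(self.per_class_scores(instances), 0.0, None)
        sums = scores.sum(axis=1, keepdims=True)
        uniform = np.full_like(scores, 1.0 / scores.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            proba = np.where(sums > 0, scores / sums, uniform)
        return proba

    def predict_class(self, instance: Instance) -> OvulationClass:
        """Argmax class with the clinically conservative tie-break."""
        return self.predict_classes([instance])[0]

    def predict_classes(self, instances: Sequence[Instance]) -> list[OvulationClass]:
        proba = self.predict_proba(instances)
        return [argmax_class(row) for row in proba]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a single-archive artifact: booster JSON + calibrators + metadata."""
        path = Path(path)
        with tempfile.TemporaryDirectory() as tmp:
            booster_path = Path(tmp) / "booster.json"
            self.booster.save_model(str(booster_path))  # xgboost-native JSON
            booster_bytes = booster_path.read_bytes()
        meta = {
            "feature_names": list(self.feature_names),
            "class_order": [c.name for c in self.class_order],
            "metadata": self.metadata,
            "n_classes": len(self.class_order),
            "present_classes": [int(c) for c in self.present_classes],
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("booster.json", booster_bytes)
            zf.writestr("calibrators.json", json.dumps(
                [s.to_jsonable() for s in self.calibration_stages]))
            zf.writestr("meta.json", json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StudentModel":
        with zipfile.ZipFile(Path(path)) as zf:
            booster_bytes = zf.read("booster.json")
            stages = [_CalibratorStage.from_jsonable(d)
                      for d in json.loads(zf.read("calibrators.json"))]
            meta = json.loads(zf.read("meta.json"))
        booster = xgb.Booster()
        with tempfile.TemporaryDirectory() as tmp:
            p = Path(tmp) / "booster.json"
            p.write_bytes(booster_bytes)
            booster.load_model(str(p))
        present = tuple(int(c) for c in meta["present_classes"])
        return cls(
            booster=booster,
            feature_names=tuple(meta["feature_names"]),
            class_order=tuple(OvulationClass[n] for n in meta["class_order"]),
            present_classes=present,
            calibration_stages=stages,
            metadata=meta["metadata"],
        )


def argmax_class(proba: np.ndarray) -> OvulationClass:
    """Argmax over the nine classes; ties go to the bin nearest ZERO, then later."""
    best = proba.max()
    for idx in _TIE_ORDER:
        if proba[idx] == best:
            return CLASS_ORDER[idx]
    raise AssertionError("unreachable")


def fit_student(train_instances: Sequence[Instance],
                hyperparameters: Optional[dict] = None,
                seed: int = 0) -> StudentModel:
    """Fit the uncalibrated multiclass ensemble on labeled instances."""
    if not train_instances:
        raise ValueError("no training instances")
    X = _frame(train_instances)
    y = labels_vector(train_instances)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("training data contains a single class")
    y_enc = np.searchsorted(present, y)  # xgboost needs contiguous 0..k-1 labels
    params = dict(DEFAULT_PARAMS, **(hyperparameters or {}))
    clf = xgb.XGBClassifier(
        objective="multi:softprob",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **params,
    )
    clf.fit(X, y_enc)
    return StudentModel(
        booster=clf.get_booster(),
        present_classes=tuple(int(c) for c in present),
        metadata={
            "hyperparameters": params,
            "seed": int(seed),
            "n_train": len(train_instances),
            "data_hash": _data_hash(X.to_numpy(), y),
        },
    )


def tune_hyperparameters(train: Sequence[Instance], valcal: Sequence[Instance],
                         grid: Sequence[dict] = DEFAULT_GRID,
                         seed: int = 0) -> dict:
    """Pick the grid point with the best validation accuracy.

    Ties break toward smaller depth, then smaller learning rate, then
    fewer estimators.
    """
    if not train or not valcal:
        raise ValueError("train and validation sets must be non-empty")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y_val = labels_vector(valcal)
    results = []
    for params in grid:
        model = fit_student(train, params, seed=seed)
        pred = np.asarray([int(c) for c in model.predict_classes(valcal)])
        acc = float((pred == y_val).mean())
        results.append((acc, params))
    best_acc = max(acc for acc, _ in results)
    candidates = [p for acc, p in results if acc == best_acc]
    candidates.sort(key=lambda p: (p.get("max_depth", 0),
                                   p.get("learning_rate", 0.0),
                                   p.get("n_estimators", 0)))
    return candidates[0]


def calibrate_one_vs_rest(model: StudentModel,
                          calibration_instances: Sequence[Instance],
                          method: str = "isotonic") -> StudentModel:
    """Append a per-class monotone recalibration stage fitted on held-out data.

    Each class's one-vs-rest score is regressed against the binary class
    indicator (isotonic regression by default; logistic sigmoid if
    requested).  Classes absent from the calibration set keep their
    current score (with a warning).  Scores are renormalized to a
    probability vector only at prediction time, so repeated calibration on
    the same data is a fixed point of the isotonic map.
    """
    if method not in ("isotonic", "sigmoid"):
        raise ValueError(f"unknown calibration method {method!r}")
    if not calibration_instances:
        raise ValueError("empty calibration set")
    scores = model.per_class_scores(calibration_instances)
    y = labels_vector(calibration_instances)
    maps: list[Optional[tuple[np.ndarray, np.ndarray]]] = []
    for c in range(len(model.class_order)):
        target = (y == c).astype(float)
        if target.sum() == 0:
            warnings.warn(
                f"class {model.class_order[c].name} absent from calibration set; "
                f"leaving its score uncalibrated", stacklevel=2)
            maps.append(None)
            continue
        s = scores[:, c]
        if method == "isotonic":
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(s, target)
            maps.append((np.asarray(iso.X_thresholds_, dtype=float),
                         np.asarray(iso.y_thresholds_, dtype=float)))
        else:
            lr = LogisticRegression(C=1e6)
            lr.fit(s.reshape(-1, 1), target.astype(int))
            grid_x = np.linspace(0.0, 1.0, 201)
            grid_y = lr.predict_proba(grid_x.reshape(-1, 1))[:, 1]
            maps.append((grid_x, grid_y))
    stage = _CalibratorStage(method=method, maps=maps)
    return StudentModel(
        booster=model.booster,
        feature_names=model.feature_names,
        class_order=model.class_order,
        calibration_stages=model.calibration_stages + [stage],
        metadata=dict(model.metadata, calibrated=True, calibration_method=method,
                      n_calibration=len(calibration_instances)),
    )


def expected_calibration_error(proba: np.ndarray, labels: np.ndarray,
                               n_bins: int = 10) -> float:
    """One-vs-rest expected calibration error, averaged over the nine classes."""
    eces = []
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for c in range(proba.shape[1]):
        p = proba[:, c]
        target = (labels == c).astype(float)
        ece = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (p >= lo) & (p < hi) if hi < 1.0 else (p >= lo) & (p <= hi)
            if mask.sum() == 0:
                continue
            ece += mask.mean() * abs(target[mask].mean() - p[mask].mean())
        eces.append(ece)
    return float(np.mean(eces))


# ---------------------------------------------------------------------------
# reporting


@dataclass
class ConfusionReport:
    """Predicted-vs-actual confusion with column (per-actual-class) normalization.

    Rows are model-predicted classes, columns are actual classes; the
    percentage matrix normalizes each actual-class column to 100%.
    """

    counts: np.ndarray  # (9, 9) ints, [predicted, actual]
    class_names: tuple[str, ...]

    @property
    def column_percentages(self) -> np.ndarray:
        col = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(col > 0, 100.0 * self.counts / col, 0.0)
        return pct

    @property
    def per_class_accuracy(self) -> np.ndarray:
        col = self.counts.sum(axis=0).astype(float)
        diag = np.diag(self.counts).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, diag / col, np.nan)

    @property
    def overall_accuracy(self) -> float:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts) / total)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))

    def to_jsonable(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "counts": self.counts.tolist(),
            "column_percentages": self.column_percentages.tolist(),
            "per_class_accuracy": [None if np.isnan(a) else a
                                   for a in self.per_class_accuracy],
            "overall_accuracy": self.overall_accuracy,
        }


#: Reporting subsets: a single test day on cycle days 6-10, and two-day
#: instances whose first test day falls after cycle day 6.
REPORT_FILTERS: dict[str, Callable[[Instance], bool]] = {
    "single_day_6_10": lambda i: i.first_day == i.second_day and 6 <= i.second_day <= 10,
    "pair_first_after_6": lambda i: i.second_day > i.first_day and i.first_day > 6,
}


def confusion_report(model: StudentModel, test_instances: Sequence[Instance],
                     filters: Optional[str | Callable[[Instance], bool]] = None,
                     ) -> ConfusionReport:
    """Confusion counts of the model on labeled test instances."""
    if isinstance(filters, str):
        try:
            filters = REPORT_FILTERS[filters]
        except KeyError:
            raise ValueError(f"unknown report filter {filters!r}") from None
    if filters is not None:
        test_instances = [i for i in test_instances if filters(i)]
    if not test_instances:
        raise ValueError("no test instances (after filtering)")
    y = labels_vector(test_instances)
    pred = model.predict_classes(test_instances)
    k = len(model.class_order)
    counts = np.zeros((k, k), dtype=int)
    for p, a in zip(pred, y):
        counts[int(p), int(a)] += 1
    return ConfusionReport(counts=counts,
                           class_names=tuple(c.name for c in model.class_order))


def feature_importance(model: StudentModel) -> list[tuple[str, float]]:
    """Features ranked by total gain (descending; name breaks ties)."""
    gains = model.booster.get_score(importance_type="total_gain")
    full = {name: float(gains.get(name, 0.0)) for name in model.feature_names}
    return sorted(full.items(), key=lambda kv: (-kv[1], kv[0]))


def assert_patient_disjoint(*splits: Sequence[Instance]) -> None:
    """Raise if any patient id appears in more than one split."""
    seen: dict[str, int] = {}
    for idx, split in enumerate(splits):
        for pid in {inst.patient_id for inst in split}:
            if pid in seen and seen[pid] != idx:
                raise ValueError(f"patient {pid!r} appears in splits "
                                 f"{seen[pid]} and {idx}")
            seen[pid] = idx
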