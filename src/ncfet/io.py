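"""File formats, run configuration, and seed plumbing.

Cycles travel either as a pair of CSVs (a long per-test-day table plus a
per-cycle companion) or as a single JSON document; both round-trip
losslessly, with the empty string marking a missing value in CSV.
Instances, confusion matrices, and feature importances are flat CSVs.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .engine import NTMAConfig
from .instances import FEATURE_REGISTRY
from .model import ConfusionReport
from .records import (Baseline, CycleRecord, Instance, OvulationClass,
                      TestDayRecord)
from .simulate import SimulationConfig

TEST_COLUMNS = ("patient_id", "cycle_id", "cycle_day", "lh", "e2", "p4",
                "follicle_mm", "endometrium_mm")
CYCLE_COLUMNS = ("patient_id", "cycle_id", "age", "bmi", "smoker",
                 "ovulation_day", "label_source")


class SchemaError(ValueError):
    """A file violates the documented schema (message names row and column)."""


def companion_path(path: str | Path) -> Path:
    """Per-cycle companion CSV path for a long-format cycles CSV."""
    path = Path(path)
    return path.with_name(path.stem + ".cycles" + path.suffix)


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def _parse_float(text: str, row: int, column: str,
                 required: bool) -> Optional[float]:
    if text == "":
        if required:
            raise SchemaError(f"row {row}: column {column!r} may not be empty")
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"row {row}: column {column!r} is not a number: "
                          f"{text!r}") from None


def write_cycles(cycles: Sequence[CycleRecord], path: str | Path) -> None:
    """Write cycles as CSV (long table + companion) or single-file JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([_cycle_to_obj(c) for c in cycles], indent=1))
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TEST_COLUMNS)
        for c in cycles:
            for t in c.tests:
                w.writerow([c.baseline.patient_id, c.cycle_id, t.cycle_day,
                            _fmt(t.lh_iu_l), _fmt(t.e2), _fmt(t.p4),
                            _fmt(t.follicle_mm), _fmt(t.endometrium_mm)])
    with open(companion_path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CYCLE_COLUMNS)
        for c in cycles:
            w.writerow([c.baseline.patient_id, c.cycle_id,
                        _fmt(c.baseline.age_years), _fmt(c.baseline.bmi_kg_m2),
                        int(c.baseline.smoker),
                        "" if c.ovulation_day is None else c.ovulation_day,
                        c.label_source])


def _cycle_to_obj(c: CycleRecord) -> dict:
    return {
        "patient_id": c.baseline.patient_id,
        "cycle_id": c.cycle_id,
        "age": c.baseline.age_years,
        "bmi": c.baseline.bmi_kg_m2,
        "smoker": c.baseline.smoker,
        "ovulation_day": c.ovulation_day,
        "label_source": c.label_source,
        "tests": [
            {"cycle_day": t.cycle_day, "lh": t.lh_iu_l, "e2": t.e2, "p4": t.p4,
             "follicle_mm": t.follicle_mm, "endometrium_mm": t.endometrium_mm}
            for t in c.tests
        ],
    }


def _cycle_from_obj(obj: dict) -> CycleRecord:
    baseline = Baseline(patient_id=str(obj["patient_id"]),
                        age_years=float(obj["age"]), bmi_kg_m2=float(obj["bmi"]),
                        smoker=bool(obj["smoker"]))
    tests = [TestDayRecord(
        cycle_day=int(t["cycle_day"]), lh_iu_l=float(t["lh"]),
        e2=float(t["e2"]), p4=float(t["p4"]),
        follicle_mm=None if t.get("follicle_mm") is None else float(t["follicle_mm"]),
        endometrium_mm=(None if t.get("endometrium_mm") is None
                        else float(t["endometrium_mm"])))
        for t in obj["tests"]]
    o = obj.get("ovulation_day")
    return CycleRecord(baseline=baseline, tests=tests,
                       cycle_id=str(obj["cycle_id"]),
                       ovulation_day=None if o is None else int(o),
                       label_source=obj.get("label_source", "none"))


def read_cycles(path: str | Path) -> list[CycleRecord]:
    """Read cycles written by :func:`write_cycles` (CSV pair or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return [_cycle_from_obj(o) for o in json.loads(path.read_text())]

    meta: dict[tuple[str, str], dict] = {}
    with open(companion_path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, CYCLE_COLUMNS, companion_path(path))
        for i, row in enumerate(reader, start=2):
            key = (row["patient_id"], row["cycle_id"])
            meta[key] = {
                "age": _parse_float(row["age"], i, "age", required=True),
                "bmi": _parse_float(row["bmi"], i, "bmi", required=True),
                "smoker": row["smoker"] not in ("0", "", "false", "False"),
                "ovulation_day": (None if row["ovulation_day"] == ""
                                  else int(float(row["ovulation_day"]))),
                "label_source": row["label_source"] or "none",
            }
    tests: dict[tuple[str, str], list[TestDayRecord]] = {k: [] for k in meta}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, TEST_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            key = (row["patient_id"], row["cycle_id"])
            if key not in tests:
                raise SchemaError(f"row {i}: cycle {key} missing from the "
                                  f"per-cycle companion file")
            try:
                day = int(row["cycle_day"])
            except ValueError:
                raise SchemaError(f"row {i}: column 'cycle_day' is not an "
                                  f"integer: {row['cycle_day']!r}") from None
            tests[key].append(TestDayRecord(
                cycle_day=day,
                lh_iu_l=_parse_float(row["lh"], i, "lh", required=True),
                e2=_parse_float(row["e2"], i, "e2", required=True),
                p4=_parse_float(row["p4"], i, "p4", required=True),
                follicle_mm=_parse_float(row["follicle_mm"], i, "follicle_mm",
                                         required=False),
                endometrium_mm=_parse_float(row["endometrium_mm"], i,
                                            "endometrium_mm", required=False)))
    cycles = []
    for key, m in meta.items():
        day_list = [t.cycle_day for t in tests[key]]
        if any(b <= a for a, b in zip(day_list, day_list[1:])):
            raise SchemaError(
                f"cycle {key}: column 'cycle_day' not strictly increasing")
        baseline = Baseline(patient_id=key[0], age_years=m["age"],
                            bmi_kg_m2=m["bmi"], smoker=m["smoker"])
        cycles.append(CycleRecord(
            baseline=baseline, tests=tests[key], cycle_id=key[1],
            ovulation_day=m["ovulation_day"], label_source=m["label_source"]))
    return cycles


def _check_header(fieldnames, expected, path) -> None:
    if fieldnames is None or tuple(fieldnames) != tuple(expected):
        raise SchemaError(f"{path}: expected header {list(expected)}, "
                          f"got {fieldnames}")


# ---------------------------------------------------------------------------
# instances


INSTANCE_KEY_COLUMNS = ("patient_id", "cycle_id", "first_day", "second_day")

# feature columns are prefixed so registry names like first_day cannot
# collide with the instance key columns
_FEATURE_COLUMNS = tuple(f"feat_{name}" for name in FEATURE_REGISTRY)


def write_instances(instances: Sequence[Instance], path: str | Path) -> None:
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(INSTANCE_KEY_COLUMNS) + list(_FEATURE_COLUMNS) + ["label"])
        for inst in instances:
            feats = [("" if np.isnan(inst.features.get(n, float("nan")))
                      else repr(inst.features[n])) for n in FEATURE_REGISTRY]
            w.writerow([inst.patient_id, inst.cycle_id, inst.first_day,
                        inst.second_day] + feats
                       + [inst.label.name if inst.label is not None else ""])


def read_instances(path: str | Path) -> list[Instance]:
    out = []
    expected = list(INSTANCE_KEY_COLUMNS) + list(_FEATURE_COLUMNS) + ["label"]
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, expected, path)
        for i, row in enumerate(reader, start=2):
            features = {}
            for name, column in zip(FEATURE_REGISTRY, _FEATURE_COLUMNS):
                v = _parse_float(row[column], i, column, required=False)
                features[name] = float("nan") if v is None else v
            label = row["label"]
            out.append(Instance(
                patient_id=row["patient_id"], cycle_id=row["cycle_id"],
                first_day=int(row["first_day"]), second_day=int(row["second_day"]),
                features=features,
                label=OvulationClass[label] if label else None))
    return out


# ---------------------------------------------------------------------------
# confusion / importance


def write_confusion(report: ConfusionReport, path: str | Path) -> None:
    """Counts matrix CSV: rows = predicted class, columns = actual class."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["predicted\\actual"] + list(report.class_names))
        for name, row in zip(report.class_names, report.counts):
            w.writerow([name] + [int(v) for v in row])


def read_confusion(path: str | Path) -> ConfusionReport:
    with open(Path(path), newline="") as fh:
        rows = list(csv.reader(fh))
    names = tuple(rows[0][1:])
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=int)
    if counts.shape != (len(names), len(names)):
        raise SchemaError(f"{path}: confusion matrix is not square")
    return ConfusionReport(counts=counts, class_names=names)


def write_importance(ranking: Sequence[tuple[str, float]], path: str | Path) -> None:
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["feature", "total_gain"])
        for name, gain in ranking:
            w.writerow([name, repr(float(gain))])


# ---------------------------------------------------------------------------
# run configuration and seeds


@dataclass(frozen=True)
class InstanceSectionConfig:
    fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)
    distribution_tol: float = 0.10
    max_resamples: int = 20
    policy: str = "sparse_then_dense"


@dataclass(frozen=True)
class ModelSectionConfig:
    hyperparameters: dict = field(default_factory=dict)
    calibration_method: str = "isotonic"
    tune: bool = False


@dataclass(frozen=True)
class EvaluationSectionConfig:
    n_samples: int = 10_000
    n_repeats: int = 30
    exact: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Structured run configuration; unknown keys are rejected on load."""

    rng_seed: int = 0
    simulation: SimulationConfig = SimulationConfig()
    instances: InstanceSectionConfig = InstanceSectionConfig()
    model: ModelSectionConfig = ModelSectionConfig()
    ntma: NTMAConfig = NTMAConfig()
    evaluation: EvaluationSectionConfig = EvaluationSectionConfig()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "simulation": SimulationConfig,
            "instances": InstanceSectionConfig,
            "model": ModelSectionConfig,
            "ntma": NTMAConfig,
            "evaluation": EvaluationSectionConfig,
        }
        unknown = set(data) - set(sections) - {"rng_seed"}
        if unknown:
            raise SchemaError(f"unknown config sections {sorted(unknown)}")
        kwargs: dict = {"rng_seed": int(data.get("rng_seed", 0))}
        for name, section_cls in sections.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise SchemaError(f"config section {name!r} must be an object")
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(section) - valid
            if bad:
                raise SchemaError(
                    f"unknown keys {sorted(bad)} in config section {name!r}")
            coerced = dict(section)
            if name == "instances" and "fractions" in coerced:
                coerced["fractions"] = tuple(coerced["fractions"])
            if name == "ntma" and "transfer_classes" in coerced:
                coerced["transfer_classes"] = frozenset(
                    OvulationClass[c] for c in coerced["transfer_classes"])
            if name == "ntma" and "cancel_class" in coerced:
                coerced["cancel_class"] = OvulationClass[coerced["cancel_class"]]
            kwargs[name] = section_cls(**coerced)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_jsonable(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, frozenset):
                return sorted(c.name for c in obj)
            if isinstance(obj, OvulationClass):
                return obj.name
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return convert(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def forked_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-module generator forked from one global seed."""
    digest = hashlib.sha256(stream.encode()).digest()[:4]
    child = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence([seed, child]))
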