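"""Test registry, per-movement scoring and total-score aggregation.

The built-in registry covers 23 upper-limb test movements across six
categories (Shoulder, Elbow, Forearm, Hand, Wrist, Coordination/Speed).
Each movement is rated on the standard three-point clinical scale —

* 0: the movement cannot be performed at all,
* 1: the movement is performed partially,
* 2: the movement is performed faultlessly —

and the per-movement scores are summed into a total that indexes the
subject's level of upper-limb motor function.  Movements outside the
registry (reflex tests and fine-motion items) are reported as
clinician-administered, never scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import yaml

from .errors import ParameterError, ValidationError
from .features import extract_features, recipe_dimension
from .preprocess import PreprocessParams
from .sensor_io import RecordingBundle

CATEGORIES = (
    "Shoulder",
    "Elbow",
    "Forearm",
    "Hand",
    "Wrist",
    "Coordination/Speed",
)


@dataclass(frozen=True)
class TestDefinition:
    """Registry entry for one supported test movement."""

    test_id: str
    category: str
    movement: str
    required_sensors: frozenset
    recipe: tuple
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        unknown = self.required_sensors - {"skeleton", "imu", "glove", "pressure"}
        if unknown:
            raise ValidationError(f"unknown sensors {sorted(unknown)}")
        if recipe_dimension(self.recipe) <= 0:
            raise ValidationError(
                f"test {self.test_id!r}: recipe must have positive dimension"
            )

    @property
    def dimension(self) -> int:
        return recipe_dimension(self.recipe)


def _parse_registry(doc: dict) -> List[TestDefinition]:
    defaults = doc.get("defaults", {}).get("preprocess", {})
    tests = []
    seen = set()
    for entry in doc["tests"]:
        pp = dict(defaults)
        pp.update(entry.get("preprocess", {}))
        tid = entry["test_id"]
        if tid in seen:
            raise ValidationError(f"duplicate test_id {tid!r} in registry")
        seen.add(tid)
        tests.append(
            TestDefinition(
                test_id=tid,
                category=entry["category"],
                movement=entry.get("movement", tid),
                required_sensors=frozenset(entry["required_sensors"]),
                recipe=tuple(dict(e) for e in entry["recipe"]),
                preprocess=PreprocessParams(**pp),
            )
        )
    return tests


def load_registry(path) -> List[TestDefinition]:
    """Load a registry + recipes YAML file (the shipped schema)."""
    with open(path) as fh:
        return _parse_registry(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def _builtin_registry() -> tuple:
    text = resources.files("fmakit.data").joinpath("registry.yaml").read_text()
    return tuple(_parse_registry(yaml.safe_load(text)))


def registry() -> List[TestDefinition]:
    """The built-in test inventory, in stable (shipped) order."""
    return list(_builtin_registry())


def registry_by_id() -> Dict[str, TestDefinition]:
    return {t.test_id: t for t in _builtin_registry()}


def score_movement(bundle: RecordingBundle, model, test=None) -> int:
    """Score one recording with a trained per-test classifier.

    Pure composition of feature extraction and prediction.
    """
    if model.test_id != bundle.test_id:
        raise ValidationError(
            f"model for test {model.test_id!r} cannot score a "
            f"{bundle.test_id!r} recording"
        )
    if test is None:
        test = registry_by_id().get(bundle.test_id)
        if test is None:
            raise ValidationError(f"unknown test {bundle.test_id!r}")
    fv = extract_features(bundle, test)
    return model.predict(fv)


def total_score(scores: Mapping[str, int]) -> int:
    """Sum per-test scores into the overall assessment total."""
    for tid, s in scores.items():
        if s not in (0, 1, 2):
            raise ValidationError(f"test {tid!r}: score {s!r} outside {{0,1,2}}")
    return int(sum(scores.values()))


def score_agreement(auto_total: int, clinician_total: int) -> float:
    """Percentage agreement between automated and clinician totals.

    Defined as (1 − |auto − clinician| / clinician) × 100, reported to two
    decimals; 100.00 iff the totals are equal.
    """
    if clinician_total <= 0:
        raise ParameterError("clinician_total must be > 0")
    return round((1.0 - abs(auto_total - clinician_total) / clinician_total) * 100.0, 2)


@dataclass
class AssessmentReport:
    """Per-test scores and their total for one subject, plus skipped tests."""

    subject_id: str
    scores: Dict[str, int]
    skipped: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.total = total_score(self.scores)

    def to_obj(self) -> dict:
        return {
            "report_version": 1,
            "subject_id": self.subject_id,
            "scores": dict(self.scores),
            "skipped": dict(self.skipped),
            "total": self.total,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_obj(), indent=1, sort_keys=True)

    def to_text(self) -> str:
        by_id = registry_by_id()
        lines = [f"Assessment report for subject {self.subject_id}"]
        for tid, s in self.scores.items():
            t = by_id.get(tid)
            label = f"{t.category}: {t.movement}" if t else tid
            lines.append(f"  {label:<45s} {s}")
        for tid, reason in self.skipped.items():
            lines.append(f"  {tid:<45s} skipped ({reason})")
        lines.append(f"  {'TOTAL':<45s} {self.total}")
        return "\n".join(lines)


def assess_subject(
    bundles: List[RecordingBundle],
    models: Mapping[str, object],
    subject_id: Optional[str] = None,
) -> AssessmentReport:
    """Score every recording of one subject and aggregate the total.

    Registry tests without a recording or a trained model — and recordings of
    movements outside the registry — are reported as clinician-administered.
    """
    by_test = {b.test_id: b for b in bundles}
    if subject_id is None:
        subject_id = bundles[0].subject_id if bundles else "unknown"
    scores: Dict[str, int] = {}
    skipped: Dict[str, str] = {}
    for test in registry():
        bundle = by_test.pop(test.test_id, None)
        if bundle is None:
            skipped[test.test_id] = "no recording; clinician-administered"
            continue
        model = models.get(test.test_id)
        if model is None:
            skipped[test.test_id] = "no trained model; clinician-administered"
            continue
        scores[test.test_id] = score_movement(bundle, model, test)
    for tid in by_test:
        skipped[tid] = "not in registry; clinician-administered"
    return AssessmentReport(subject_id=subject_id, scores=scores, skipped=skipped)
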