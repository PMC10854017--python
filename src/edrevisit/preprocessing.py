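"""Label construction and feature encoding for 30-day revisit prediction.

The prediction target is built from each patient's own visit sequence: for a
patient with ``n > 1`` visits, the last visit is removed from the input data
and the label records whether it occurred within ``window_days`` (default 30,
inclusive) of visit ``n-1``.  Patients with a single visit are labeled 0 and
contribute that one visit as input.  Input windows are truncated to the most
recent ``visit_cap`` visits (default 10).

Features follow the visit schema: age is normalized (z-score by default,
min-max as an alternative) and the four categorical features are one-hot /
multi-hot encoded against vocabularies fitted on training data only.  Codes
unseen at fit time encode to an all-zero block rather than erroring, since
cross-validation folds can hold out rare codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ehr_data import PatientHistory, VisitRecord

__all__ = [
    "PreprocessConfig",
    "LabeledInstance",
    "FeatureSchema",
    "revisit_indicators",
    "build_instance",
    "build_instances",
    "fit_schema",
    "encode_visit",
    "encode_instance",
]


@dataclass(frozen=True)
class PreprocessConfig:
    window_days: int = 30
    visit_cap: int = 10
    window_inclusive: bool = True
    age_norm: str = "zscore"  # or "minmax"

    def __post_init__(self):
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.visit_cap < 1:
            raise ValueError("visit_cap must be >= 1")
        if self.age_norm not in ("zscore", "minmax"):
            raise ValueError("age_norm must be 'zscore' or 'minmax'")


@dataclass(frozen=True)
class LabeledInstance:
    """A patient's capped input-visit window and the binary revisit label."""

    patient_id: str
    input_visits: tuple[VisitRecord, ...]
    label: int

    def __post_init__(self):
        if not self.input_visits:
            raise ValueError("input_visits must be non-empty")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def _gap_within(gap_days: int, cfg: PreprocessConfig) -> bool:
    return gap_days <= cfg.window_days if cfg.window_inclusive else gap_days < cfg.window_days


def revisit_indicators(history: PatientHistory, cfg: PreprocessConfig) -> list[int]:
    """Per-visit 30-day revisit flags.

    Flag ``i`` is 1 iff some later visit falls within the revisit window of
    visit ``i``.  Because visits are date-sorted the nearest later visit is
    visit ``i+1``, so only consecutive gaps need checking; the last visit's
    flag is 0 by construction (single-visit patients get ``[0]``).
    """
    visits = history.visits
    flags = []
    for i in range(len(visits) - 1):
        gap = (visits[i + 1].visit_date - visits[i].visit_date).days
        flags.append(1 if _gap_within(gap, cfg) else 0)
    flags.append(0)
    return flags


def build_instance(history: PatientHistory, cfg: PreprocessConfig) -> LabeledInstance:
    """Turn one history into a labeled training instance.

    For ``n > 1`` the label is the revisit indicator attached to visit
    ``n-1`` — whether the (removed) final visit followed within the window —
    and the input is visits ``1..n-1`` truncated to the last ``visit_cap``.
    A single-visit patient keeps its one visit as input with label 0.
    """
    visits = history.visits
    if len(visits) == 1:
        return LabeledInstance(history.patient_id, (visits[0],), 0)
    gap = (visits[-1].visit_date - visits[-2].visit_date).days
    label = 1 if _gap_within(gap, cfg) else 0
    inputs = visits[:-1][-cfg.visit_cap:]
    return LabeledInstance(history.patient_id, tuple(inputs), label)


def build_instances(histories: Sequence[PatientHistory], cfg: PreprocessConfig) -> list[LabeledInstance]:
    return [build_instance(h, cfg) for h in histories]


@dataclass(frozen=True)
class FeatureSchema:
    """Fitted encoding: per-vocabulary index maps plus age normalization.

    The visit vector layout is
    ``[age] + one-hot(triage) + one-hot(disposition) + one-hot(diagnosis)
    + multi-hot(service)``; ``width`` is the total length.
    """

    triage_index: dict[int, int]
    disposition_index: dict[str, int]
    diagnosis_index: dict[str, int]
    service_index: dict[str, int]
    age_center: float
    age_scale: float

    @property
    def width(self) -> int:
        return (
            1
            + len(self.triage_index)
            + len(self.disposition_index)
            + len(self.diagnosis_index)
            + len(self.service_index)
        )

    @property
    def visit_node_width(self) -> int:
        """Width of the visit-node feature block: age + triage + disposition."""
        return 1 + len(self.triage_index) + len(self.disposition_index)


def fit_schema(instances: Sequence[LabeledInstance], cfg: PreprocessConfig) -> FeatureSchema:
    """Fit vocabularies and age normalization from training instances only.

    Index assignment is deterministic (sorted order per vocabulary).  With a
    degenerate age distribution (all ages equal, or a single visit) the scale
    falls back to 1 so encoding never divides by zero.
    """
    if not instances:
        raise ValueError("cannot fit a schema from zero instances")
    tri, disp, diag, svc = set(), set(), set(), set()
    ages = []
    for inst in instances:
        for v in inst.input_visits:
            tri.add(v.triage_level)
            disp.add(v.disposition_code)
            diag.add(v.diagnosis_code)
            svc.update(v.service_codes)
            ages.append(v.age_years)
    ages = np.asarray(ages, dtype=float)
    if cfg.age_norm == "zscore":
        center = float(ages.mean())
        scale = float(ages.std())
    else:
        center = float(ages.min())
        scale = float(ages.max() - ages.min())
    if scale <= 0.0:
        scale = 1.0
    return FeatureSchema(
        triage_index={c: i for i, c in enumerate(sorted(tri))},
        disposition_index={c: i for i, c in enumerate(sorted(disp))},
        diagnosis_index={c: i for i, c in enumerate(sorted(diag))},
        service_index={c: i for i, c in enumerate(sorted(svc))},
        age_center=center,
        age_scale=scale,
    )


def encode_visit(visit: VisitRecord, schema: FeatureSchema) -> np.ndarray:
    """Encode one visit as ``[age] ⊕ one-hots ⊕ service multi-hot``.

    Unseen codes leave their block all-zero.
    """
    x = np.zeros(schema.width)
    x[0] = (visit.age_years - schema.age_center) / schema.age_scale
    off = 1
    i = schema.triage_index.get(visit.triage_level)
    if i is not None:
        x[off + i] = 1.0
    off += len(schema.triage_index)
    i = schema.disposition_index.get(visit.disposition_code)
    if i is not None:
        x[off + i] = 1.0
    off += len(schema.disposition_index)
    i = schema.diagnosis_index.get(visit.diagnosis_code)
    if i is not None:
        x[off + i] = 1.0
    off += len(schema.diagnosis_index)
    for code in visit.service_codes:
        i = schema.service_index.get(code)
        if i is not None:
            x[off + i] = 1.0
    return x


def encode_instance(instance: LabeledInstance, schema: FeatureSchema) -> np.ndarray:
    """Stack the instance's visit vectors into a (n_visits, width) matrix."""
    return np.stack([encode_visit(v, schema) for v in instance.input_visits])
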