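"""Three-stage preprocessing: cohort imputation, duplicate removal, chest-pain
segregation, plus standard scaling.

Imputation replaces each missing value with the cohort mode (categorical
fields) or cohort mean (continuous fields), where a patient's cohort is the
set of records that agree with them on a quorum of binned similarity fields —
by default the age decade and the quartiles of cholesterol and resting blood
pressure.  When the cohort offers no observation, the global mode/mean is the
fallback.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records_io import (
    CATEGORICAL,
    COLUMNS,
    DomainError,
    FeatureMatrix,
    HeartRecord,
    RecordSet,
)


class ImputationError(ValueError):
    """A field is missing in every record and cannot be imputed."""


class ScalingError(ValueError):
    """A column cannot be standardized (zero variance)."""


@dataclass
class CohortSpec:
    """Controls how patient cohorts are formed for imputation.

    ``match_quorum`` is the fraction of (binned) similarity fields a peer must
    share with the patient to join their cohort.
    """

    age_bin_width: float = 10.0
    similarity_fields: Sequence[str] = ("age", "chol", "trestbps")
    match_quorum: float = 0.5

    def __post_init__(self) -> None:
        if self.age_bin_width <= 0:
            raise DomainError("age_bin_width must be positive")
        if not (0 < self.match_quorum <= 1):
            raise DomainError("match_quorum must be in (0, 1]")


def _quartile_edges(values: np.ndarray) -> np.ndarray:
    return np.quantile(values, [0.25, 0.5, 0.75])


def _bin_value(col: str, value: float, spec: CohortSpec,
               edges: dict[str, np.ndarray]) -> int:
    if col == "age":
        return int(np.floor(value / spec.age_bin_width))
    if col in edges:
        return int(np.searchsorted(edges[col], value, side="right"))
    return int(value)  # categorical similarity field: exact match


def impute_missing(records: RecordSet, spec: CohortSpec | None = None) -> RecordSet:
    """Fill every missing field from the patient's cohort; observed values are
    never altered.

    Raises :class:`ImputationError` if some field is missing in all records.
    """
    spec = spec or CohortSpec()
    recs = [r.copy() for r in records]
    if not recs:
        return RecordSet([], source=records.source)

    # Quartile edges for the continuous similarity fields, over observed values.
    edges: dict[str, np.ndarray] = {}
    for col in spec.similarity_fields:
        if col == "age" or col in CATEGORICAL:
            continue
        observed = np.array([r[col] for r in recs if not r.is_missing(col)], dtype=float)
        if observed.size:
            edges[col] = _quartile_edges(observed)

    def bins_of(rec: HeartRecord) -> list[int | None]:
        out: list[int | None] = []
        for col in spec.similarity_fields:
            out.append(None if rec.is_missing(col)
                       else _bin_value(col, rec[col], spec, edges))
        return out

    all_bins = [bins_of(r) for r in recs]
    n_fields = len(spec.similarity_fields)
    quorum = spec.match_quorum * n_fields

    for col in COLUMNS:
        observed_idx = [i for i, r in enumerate(recs) if not r.is_missing(col)]
        missing_idx = [i for i, r in enumerate(recs) if r.is_missing(col)]
        if not missing_idx:
            continue
        if not observed_idx:
            raise ImputationError(f"field {col!r} is missing in every record")
        observed_vals = [recs[i][col] for i in observed_idx]
        if col in CATEGORICAL:
            global_fill: float = Counter(observed_vals).most_common(1)[0][0]
        else:
            global_fill = float(np.mean(observed_vals))

        for i in missing_idx:
            me = all_bins[i]
            cohort_vals = []
            for j in observed_idx:
                if j == i:
                    continue
                matches = sum(1 for a, b in zip(me, all_bins[j])
                              if a is not None and a == b)
                if matches >= quorum:
                    cohort_vals.append(recs[j][col])
            if cohort_vals:
                if col in CATEGORICAL:
                    fill: float = Counter(cohort_vals).most_common(1)[0][0]
                else:
                    fill = float(np.mean(cohort_vals))
            else:
                fill = global_fill
            recs[i].values[col] = fill
            recs[i].missing_mask[col] = False

    return RecordSet(recs, source=records.source)


def deduplicate(records: RecordSet) -> RecordSet:
    """Drop exact duplicates (all 14 fields equal), keeping first occurrences."""
    seen: set[tuple] = set()
    kept: list[HeartRecord] = []
    for rec in records:
        key = tuple(rec[c] for c in COLUMNS)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return RecordSet(kept, source=records.source)


def segregate_by_chest_pain(records: RecordSet) -> dict[int, RecordSet]:
    """Partition records into the four chest-pain categories.

    1 = classic angina, 2 = atypical angina, 3 = non-anginal pain,
    4 = asymptomatic.  The four groups are disjoint and exhaustive.
    """
    groups: dict[int, list[HeartRecord]] = {1: [], 2: [], 3: [], 4: []}
    for rec in records:
        cp = rec["cp"]
        if cp is None or int(cp) not in groups:
            raise DomainError(f"cp={cp!r} outside {{1..4}}")
        groups[int(cp)].append(rec)
    return {k: RecordSet(v, source=records.source) for k, v in groups.items()}


@dataclass
class ScalerParams:
    """Per-column means and (n-1 denominator) standard deviations; enough to
    invert the transform."""

    means: np.ndarray
    sds: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds <= 0):
            raise ScalingError("standard deviations must be strictly positive")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means) / self.sds

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sds + self.means

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "column_names": self.column_names,
        }, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(np.array(data["means"]), np.array(data["sds"]),
                   data.get("column_names", []))


def fit_scaler(X: FeatureMatrix) -> ScalerParams:
    """Fit column means/SDs (sample SD, n-1 denominator) on training data only."""
    values = X.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0 or not np.isfinite(sd):
            raise ScalingError(f"column {X.column_names[j]!r} has zero variance")
    return ScalerParams(means, sds, list(X.column_names))


def standard_scale(X: FeatureMatrix) -> tuple[FeatureMatrix, ScalerParams]:
    """Center each column to mean 0 and scale to sample SD 1."""
    params = fit_scaler(X)
    scaled = FeatureMatrix(params.transform(X.values), list(X.column_names),
                           list(X.row_ids))
    return scaled, params
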