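"""Readers, writers and domain types for UCI-dialect heart-disease tables.

The UCI heart-disease ``.data`` dialect is a headerless comma-separated file
with 14 fields per row (13 predictors plus the graded ``num`` outcome) and
``?`` marking a missing value.  The Cleveland table — 303 records — is the
canonical instance of this format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

#: Canonical UCI 14-column order.  ``num`` is the graded outcome (0-4).
COLUMNS: tuple[str, ...] = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal", "num",
)

#: The 13 predictor columns (everything but ``num``).
PREDICTORS: tuple[str, ...] = COLUMNS[:-1]

#: Columns treated as categorical (mode-imputed, integer-valued).
CATEGORICAL: frozenset[str] = frozenset(
    {"sex", "cp", "fbs", "restecg", "exang", "slope", "ca", "thal", "num"}
)

#: Columns treated as continuous (mean-imputed).
CONTINUOUS: tuple[str, ...] = ("age", "trestbps", "chol", "thalach", "oldpeak")

#: Legal supports of the bounded categorical fields.
SUPPORTS: dict[str, tuple[int, ...]] = {
    "sex": (0, 1),
    "cp": (1, 2, 3, 4),
    "fbs": (0, 1),
    "restecg": (0, 1, 2),
    "exang": (0, 1),
    "slope": (1, 2, 3),
    "ca": (0, 1, 2, 3),
    "thal": (3, 6, 7),
    "num": (0, 1, 2, 3, 4),
}


class FormatError(ValueError):
    """Malformed line(s) in a UCI-dialect file."""


class DomainError(ValueError):
    """A value outside its declared domain."""


@dataclass
class HeartRecord:
    """One patient row: 13 predictors, graded outcome, per-field missing flags.

    Missing fields hold ``None`` and are flagged in ``missing_mask``; they are
    never silently zero-filled.  ``num`` may not be missing.
    """

    values: dict[str, float | None]
    missing_mask: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in COLUMNS:
            if col not in self.values:
                raise DomainError(f"record lacks field {col!r}")
            self.missing_mask.setdefault(col, self.values[col] is None)
        if self.missing_mask["num"]:
            raise DomainError("outcome field 'num' may not be missing")
        num = self.values["num"]
        if num not in SUPPORTS["num"]:
            raise DomainError(f"num={num!r} outside {{0..4}}")
        cp = self.values["cp"]
        if cp is not None and cp not in SUPPORTS["cp"]:
            raise DomainError(f"cp={cp!r} outside {{1..4}}")

    def __getitem__(self, col: str) -> float | None:
        return self.values[col]

    def is_missing(self, col: str) -> bool:
        return self.missing_mask[col]

    def copy(self) -> "HeartRecord":
        return HeartRecord(dict(self.values), dict(self.missing_mask))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeartRecord):
            return NotImplemented
        return self.values == other.values and self.missing_mask == other.missing_mask


@dataclass
class RecordSet:
    """An ordered collection of :class:`HeartRecord` with provenance."""

    records: list[HeartRecord]
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> HeartRecord:
        return self.records[i]


@dataclass
class FeatureMatrix:
    """Numeric design matrix with named columns and row identifiers.

    Invariant: no missing values (imputation happens upstream) and column
    names are unique.
    """

    values: np.ndarray
    column_names: list[str]
    row_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("FeatureMatrix must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise DomainError("column count does not match column_names")
        if len(set(self.column_names)) != len(self.column_names):
            raise DomainError("column names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("FeatureMatrix may not contain missing/non-finite values")
        if self.row_ids is None:
            self.row_ids = list(range(self.values.shape[0]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _parse_token(token: str, col: str, lineno: int | None = None) -> float | None:
    token = token.strip()
    if token == "?":
        return None
    if token == "":
        where = f" (line {lineno})" if lineno is not None else ""
        raise FormatError(f"empty field {col!r}{where}: only '?' marks missing")
    try:
        value = float(token)
    except ValueError as exc:
        where = f" (line {lineno})" if lineno is not None else ""
        raise FormatError(f"non-numeric token {token!r} in field {col!r}{where}") from exc
    return value


def parse_uci_line(line: str, schema: Sequence[str] = COLUMNS,
                   lineno: int | None = None) -> HeartRecord:
    """Parse one comma-separated UCI-dialect row into a :class:`HeartRecord`.

    ``?`` marks a missing value and sets the corresponding missing flag.
    Raises :class:`FormatError` on a wrong field count or a non-numeric token.
    """
    tokens = line.strip().split(",")
    if len(tokens) != len(schema):
        where = f" (line {lineno})" if lineno is not None else ""
        raise FormatError(
            f"expected {len(schema)} fields, got {len(tokens)}{where}"
        )
    values = {col: _parse_token(tok, col, lineno) for col, tok in zip(schema, tokens)}
    return HeartRecord(values)


def load_dataset(path: str | Path) -> RecordSet:
    """Read a UCI-dialect file: one record per non-empty line, order preserved.

    All malformed lines are collected and reported together in a single
    :class:`FormatError` naming their line numbers.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records: list[HeartRecord] = []
    errors: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            records.append(parse_uci_line(line, COLUMNS, lineno=lineno))
        except (FormatError, DomainError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise FormatError(f"{len(errors)} malformed line(s) in {path}:\n" + "\n".join(errors))
    return RecordSet(records, source=str(path))


def _format_value(value: float | None) -> str:
    if value is None:
        return "?"
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_dataset(records: RecordSet | Iterable[HeartRecord], path: str | Path) -> None:
    """Write records in the UCI ``.data`` dialect (round-trip exact)."""
    lines = []
    for rec in records:
        lines.append(",".join(_format_value(rec[col]) for col in COLUMNS))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def to_csv(records: RecordSet, path: str | Path) -> None:
    """CSV export with a header row (``?`` for missing, as in the .data dialect)."""
    header = ",".join(COLUMNS)
    lines = [header]
    for rec in records:
        lines.append(",".join(_format_value(rec[col]) for col in COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def binarize_target(num: float) -> int:
    """Collapse the 0-4 disease grade to presence/absence: 0 -> 0, 1..4 -> 1."""
    if num not in SUPPORTS["num"]:
        raise DomainError(f"num={num!r} outside {{0..4}}")
    return 0 if num == 0 else 1


def to_matrix(records: RecordSet, binarize: bool = True,
              columns: Sequence[str] = PREDICTORS) -> tuple[FeatureMatrix, np.ndarray]:
    """Assemble the design matrix and label vector from fully-imputed records.

    Raises :class:`DomainError` if any requested predictor is still missing.
    """
    rows = []
    for i, rec in enumerate(records):
        row = []
        for col in columns:
            if rec.is_missing(col):
                raise DomainError(f"record {i} missing {col!r}; impute before to_matrix")
            row.append(rec[col])
        rows.append(row)
    X = FeatureMatrix(np.array(rows, dtype=float).reshape(len(rows), len(columns)),
                      list(columns))
    y = np.array([rec["num"] for rec in records], dtype=int)
    if binarize:
        y = np.array([binarize_target(v) for v in y], dtype=int)
    return X, y


def load_config(path: str | Path) -> dict:
    """Load a pipeline-parameter mapping from YAML or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data
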