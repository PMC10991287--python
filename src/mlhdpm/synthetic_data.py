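"""Synthetic fixtures emulating the Cleveland heart-disease schema and
RR-interval series.

The tabular generator draws the 13 predictors with marginals close to the
real Cleveland table (age ~54±9 years, cholesterol ~246±51 mg/dl, ...),
allocates labels to an exact class ratio (default 164:139, the Cleveland
absence:presence balance), shifts the class-1 mean of each *informative*
continuous column by a standardized effect size, and injects
missing-completely-at-random ``?`` values.  Only marginals, the class ratio
and the informative shifts are emulated — not the real joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records_io import (
    CONTINUOUS,
    PREDICTORS,
    SUPPORTS,
    DomainError,
    HeartRecord,
    RecordSet,
)
from .signal_features import RRSeries


class SpecError(ValueError):
    """Impossible generator specification."""


#: Continuous-column means/SDs loosely matching the Cleveland marginals.
_CONTINUOUS_PARAMS: dict[str, tuple[float, float]] = {
    "age": (54.0, 9.0),
    "trestbps": (131.0, 17.0),
    "chol": (246.0, 51.0),
    "thalach": (149.0, 23.0),
    "oldpeak": (1.0, 1.1),
}

#: Categorical supports and marginal probabilities (class-independent).
_CATEGORICAL_PARAMS: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "sex": ((0, 1), (0.32, 0.68)),
    "cp": ((1, 2, 3, 4), (0.08, 0.17, 0.28, 0.47)),
    "fbs": ((0, 1), (0.85, 0.15)),
    "restecg": ((0, 1, 2), (0.50, 0.01, 0.49)),
    "exang": ((0, 1), (0.67, 0.33)),
    "slope": ((1, 2, 3), (0.47, 0.46, 0.07)),
    "ca": ((0, 1, 2, 3), (0.59, 0.21, 0.13, 0.07)),
    "thal": ((3, 6, 7), (0.55, 0.06, 0.39)),
}

#: Columns that can carry a class signal, in the order they are used.
_INFORMATIVE_ORDER: tuple[str, ...] = ("thalach", "oldpeak", "age", "trestbps", "chol")

#: Severity-grade distribution of the diseased class (num in 1..4).
_GRADE_PROBS: tuple[float, ...] = (0.50, 0.25, 0.15, 0.10)


@dataclass
class TabularSpec:
    """Parameters of the Cleveland-schema generator."""

    n: int = 303
    n_informative: int = 4
    effect_size: float = 2.0
    class_ratio: tuple[int, int] = (164, 139)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise SpecError("missing_rate must be in [0, 1)")
        if self.n_informative > len(_INFORMATIVE_ORDER):
            raise SpecError(
                f"at most {len(_INFORMATIVE_ORDER)} informative columns available")
        if self.n < 2 or min(self.class_ratio) < 0:
            raise SpecError("need n >= 2 and a nonnegative class ratio")


def _allocate_labels(n: int, ratio: tuple[int, int]) -> np.ndarray:
    """Exact label counts: n0 = round(n*r0/(r0+r1)), remainder class 1."""
    r0, r1 = ratio
    total = r0 + r1
    if total == 0:
        raise SpecError("class ratio cannot be 0:0")
    n0 = int(round(n * r0 / total))
    if n0 == 0 or n0 == n:
        raise SpecError(f"ratio {ratio} leaves a class empty at n={n}")
    return np.concatenate([np.zeros(n0, dtype=int), np.ones(n - n0, dtype=int)])


def gen_tabular(spec: TabularSpec | None = None) -> tuple[RecordSet, np.ndarray]:
    """Generate a Cleveland-schema :class:`RecordSet` and the boolean mask of
    truly informative predictor columns (in ``PREDICTORS`` order).

    Bit-identical for a fixed spec (pure function of the seed).
    """
    spec = spec or TabularSpec()
    rng = np.random.default_rng(spec.seed)
    y = _allocate_labels(spec.n, spec.class_ratio)

    informative = set(_INFORMATIVE_ORDER[:spec.n_informative])
    columns: dict[str, np.ndarray] = {}
    for col in CONTINUOUS:
        mu, sd = _CONTINUOUS_PARAMS[col]
        values = rng.normal(mu, sd, size=spec.n)
        if col in informative:
            values = values + spec.effect_size * sd * y
        columns[col] = np.round(values, 1)
    for col, (support, probs) in _CATEGORICAL_PARAMS.items():
        columns[col] = rng.choice(support, size=spec.n, p=probs).astype(float)

    grades = np.zeros(spec.n, dtype=float)
    diseased = np.flatnonzero(y == 1)
    grades[diseased] = rng.choice((1, 2, 3, 4), size=diseased.size, p=_GRADE_PROBS)

    # MCAR missingness over the predictors only; 'num' is always observed
    missing = rng.uniform(size=(spec.n, len(PREDICTORS))) < spec.missing_rate

    records = []
    for i in range(spec.n):
        values: dict[str, float | None] = {}
        for j, col in enumerate(PREDICTORS):
            values[col] = None if missing[i, j] else float(columns[col][i])
        values["num"] = float(grades[i])
        records.append(HeartRecord(values))

    mask = np.array([col in informative for col in PREDICTORS])
    rs = RecordSet(records, source=f"synthetic(seed={spec.seed})")
    return rs, mask


def gen_matrix(n: int, p: int, n_informative: int, effect_size: float,
               seed: int, class_ratio: tuple[int, int] = (1, 1)
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain Gaussian benchmark matrix: unit-variance columns, the first
    ``n_informative`` shifted by ``effect_size`` for class 1, the rest pure
    noise.  Returns (X, y, informative mask)."""
    if n_informative > p:
        raise SpecError("n_informative exceeds p")
    rng = np.random.default_rng(seed)
    y = _allocate_labels(n, class_ratio)
    rng.shuffle(y)
    X = rng.normal(size=(n, p))
    X[:, :n_informative] += effect_size * y[:, None]
    mask = np.zeros(p, dtype=bool)
    mask[:n_informative] = True
    return X, y, mask


@dataclass
class RRSpec:
    """Parameters of the RR-interval generator.

    The positivity margin mean_rr > 3·sd_rr keeps Gaussian draws away from
    zero; the rare residual nonpositive draw is rejected and redrawn.
    """

    n_beats: int = 300
    mean_rr: float = 0.8
    sd_rr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 3 * self.sd_rr:
            raise SpecError("positivity margin violated: need mean_rr > 3*sd_rr")
        if self.n_beats < 1:
            raise SpecError("need at least one beat")


def gen_rr_series(spec: RRSpec | None = None) -> RRSeries:
    """Seeded Gaussian RR series with the requested mean and variability."""
    spec = spec or RRSpec()
    rng = np.random.default_rng(spec.seed)
    rr = rng.normal(spec.mean_rr, spec.sd_rr, size=spec.n_beats)
    bad = rr <= 0
    while bad.any():
        rr[bad] = rng.normal(spec.mean_rr, spec.sd_rr, size=int(bad.sum()))
        bad = rr <= 0
    return RRSeries(rr)
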