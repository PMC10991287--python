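import numpy as np
import pytest

from mlhdpm.records_io import COLUMNS, HeartRecord, RecordSet


def make_record(**overrides) -> HeartRecord:
    """A valid baseline record; pass column=value (or None for missing)."""
    base = {
        "age": 63.0, "sex": 1.0, "cp": 1.0, "trestbps": 145.0, "chol": 233.0,
        "fbs": 1.0, "restecg": 2.0, "thalach": 150.0, "exang": 0.0,
        "oldpeak": 2.3, "slope": 3.0, "ca": 0.0, "thal": 6.0, "num": 0.0,
    }
    base.update(overrides)
    return HeartRecord(dict(base))


@pytest.fixture
def record_set():
    recs = [
        make_record(),
        make_record(age=41.0, cp=2.0, num=1.0),
        make_record(age=57.0, cp=4.0, num=3.0, chol=192.0),
    ]
    return RecordSet(recs, source="fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_records(n: int, seed: int) -> RecordSet:
    """Random valid records over the legal supports (no missing values)."""
    from mlhdpm.records_io import CATEGORICAL, SUPPORTS
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n):
        values = {}
        for col in COLUMNS:
            if col in CATEGORICAL:
                values[col] = float(rng.choice(SUPPORTS[col]))
            else:
                values[col] = float(np.round(rng.uniform(0.5, 200.0), 1))
        recs.append(HeartRecord(values))
    return RecordSet(recs, source=f"random(seed={seed})")
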