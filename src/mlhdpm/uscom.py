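"""USCOM: the under-sampling / clustering / over-sampling resampler.

The procedure balances an imbalanced training problem in four steps:

1. randomly under-sample the majority class (default retention 2/3);
2. cluster the minority class with k-means, choosing K by the elbow of the
   within-cluster sum of squared errors;
3. split the under-sampled majority and each minority cluster 8:1:1 into
   train/validation/test roles and merge per role, so every minority
   subgroup is represented in every role;
4. SMOTE the merged training set until the two class counts are exactly
   equal.  Synthetic rows are confined to the training set; validation and
   test contain only original rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .records_io import DomainError, FeatureMatrix


class ResamplingError(ValueError):
    """A class is absent or too small to resample."""


class ConfigError(ValueError):
    """Invalid resampler configuration."""


@dataclass
class ClusterModel:
    """A fitted k-means model: centroids, assignments and total SSE."""

    K: int
    centroids: np.ndarray
    assignment: np.ndarray
    sse: float


@dataclass
class USCOMConfig:
    """Resampler knobs.

    ``undersample_ratio`` defaults to 2/3 (the majority retention the source
    protocol uses); the split ratio is 8:1:1 and SMOTE uses 5 neighbors.
    """

    undersample_ratio: float = 2.0 / 3.0
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    elbow_threshold: float = 0.10
    smote_k: int = 5
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.undersample_ratio <= 1):
            raise ConfigError("undersample_ratio must be in (0, 1]")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")


@dataclass
class SplitBundle:
    """Balanced train set plus untouched validation/test sets.

    ``provenance`` marks each train row as ``original`` or ``synthetic``;
    validation and test rows are original by construction.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_provenance: list[str]
    column_names: list[str] = field(default_factory=list)
    train_row_ids: list[int] = field(default_factory=list)
    val_row_ids: list[int] = field(default_factory=list)
    test_row_ids: list[int] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        """Three CSV files plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = ",".join(self.column_names + ["label"])
        for role, X, y in (("train", self.X_train, self.y_train),
                           ("validation", self.X_val, self.y_val),
                           ("test", self.X_test, self.y_test)):
            lines = [header]
            for row, lab in zip(X, y):
                lines.append(",".join(repr(float(v)) for v in row) + f",{int(lab)}")
            (outdir / f"{role}.csv").write_text("\n".join(lines) + "\n")
        manifest = {
            "counts": {
                "train": int(len(self.y_train)),
                "validation": int(len(self.y_val)),
                "test": int(len(self.y_test)),
                "train_synthetic": sum(p == "synthetic" for p in self.train_provenance),
            },
            "train_class_counts": {str(c): int(n) for c, n in
                                   zip(*np.unique(self.y_train, return_counts=True))},
            "provenance": self.train_provenance,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def undersample_majority(majority_ids: list[int] | np.ndarray, ratio: float,
                         seed: int) -> list[int]:
    """Uniformly sample round(ratio*n) distinct majority rows without
    replacement."""
    ids = np.asarray(majority_ids)
    if ids.size == 0:
        raise DomainError("majority class is empty")
    if not (0 < ratio <= 1):
        raise DomainError("undersample ratio must be in (0, 1]")
    n_keep = int(round(ratio * ids.size))
    rng = np.random.default_rng(seed)
    return [int(i) for i in rng.choice(ids, size=n_keep, replace=False)]


def kmeans_fit(X: FeatureMatrix | np.ndarray, K: int, seed: int = 0) -> ClusterModel:
    """Lloyd k-means from seeded initial centroids (single init, <=300 iters).

    SSE is the total within-cluster squared Euclidean error
    E = Σ_clusters Σ_{i in cluster} |i - m|².
    """
    Xa = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = Xa.shape[0]
    if not (1 <= K <= n):
        raise DomainError(f"K={K} outside [1, n={n}]")
    km = KMeans(n_clusters=K, n_init=1, max_iter=300, random_state=seed,
                algorithm="lloyd")
    assignment = km.fit_predict(Xa)
    sse = float(((Xa - km.cluster_centers_[assignment]) ** 2).sum())
    return ClusterModel(K=K, centroids=km.cluster_centers_,
                        assignment=assignment, sse=sse)


def choose_k(X: FeatureMatrix | np.ndarray, k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
             elbow_threshold: float = 0.10, seed: int = 0) -> int:
    """Elbow rule on the SSE curve: the smallest K whose SSE improvement over
    K−1, as a fraction of the SSE at the smallest candidate K, falls below
    the threshold; max(k_range) if the curve never flattens.

    Normalizing each drop by the initial SSE (rather than the previous one)
    makes the rule stop once added clusters stop explaining a meaningful
    share of the total scatter — successive-ratio drops decay too slowly on
    unstructured data to ever cross a fixed threshold.
    """
    if not k_range:
        raise ConfigError("k_range must be nonempty")
    ks = list(k_range)
    if ks != sorted(ks):
        raise ConfigError("k_range must be increasing")
    Xa = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    ks = [k for k in ks if k <= Xa.shape[0]]
    if not ks:
        raise ConfigError("all candidate K exceed the sample count")
    sses = [kmeans_fit(Xa, k, seed=seed).sse for k in ks]
    base = sses[0]
    if base <= 0:
        return ks[0]
    for i in range(1, len(ks)):
        improvement = (sses[i - 1] - sses[i]) / base
        if improvement < elbow_threshold:
            return ks[i - 1]
    return ks[-1]


def split_8_1_1(rows: list[int] | np.ndarray, seed: int,
                split: tuple[float, float, float] = (0.8, 0.1, 0.1)
                ) -> tuple[list[int], list[int], list[int]]:
    """Seeded-shuffle split with test = max(1, round(f_test*n)), val likewise,
    train = remainder."""
    rows = list(rows)
    n = len(rows)
    if n < 3:
        raise DomainError(f"need at least 3 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [rows[i] for i in order]
    n_test = max(1, int(round(split[2] * n)))
    n_val = max(1, int(round(split[1] * n)))
    test = shuffled[:n_test]
    val = shuffled[n_test:n_test + n_val]
    train = shuffled[n_test + n_val:]
    return train, val, test


def smote(minority: np.ndarray, n_new: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Interpolated minority over-sampling.

    Each synthetic row is seed_point + u·(neighbor - seed_point) with
    u ~ U(0,1) and the neighbor drawn uniformly from the seed's k nearest
    minority rows (Euclidean; k clamped to n-1).
    """
    minority = np.asarray(minority, dtype=float)
    if n_new == 0:
        return np.empty((0, minority.shape[1]) if minority.ndim == 2 else (0,))
    if minority.shape[0] < 2:
        raise ResamplingError("SMOTE needs at least 2 minority rows")
    if k < 1:
        raise DomainError("k must be at least 1")
    k = min(k, minority.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # first neighbor is the point itself
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, minority.shape[0], size=n_new)
    out = np.empty((n_new, minority.shape[1]))
    for r, s in enumerate(seeds):
        neighbor = minority[idx[s, 1 + rng.integers(0, k)]]
        u = rng.uniform()
        out[r] = minority[s] + u * (neighbor - minority[s])
    return out


def run_uscom(X: FeatureMatrix | np.ndarray, y: np.ndarray,
              cfg: USCOMConfig | None = None) -> SplitBundle:
    """Full resampling pipeline; see the module docstring for the four steps.

    SMOTE distances and interpolation are computed on standard-scaled
    features and synthetic rows are mapped back to the original scale, so
    large-magnitude columns do not dominate the neighbor geometry.
    """
    cfg = cfg or USCOMConfig()
    if isinstance(X, FeatureMatrix):
        Xa, column_names = X.values, list(X.column_names)
    else:
        Xa = np.asarray(X, dtype=float)
        column_names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=int)

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ResamplingError("both classes must be present")
    majority_label = int(classes[np.argmax(counts)])
    minority_label = int(classes[np.argmin(counts)])
    if majority_label == minority_label:  # exact tie: treat class 0 as majority
        majority_label, minority_label = int(classes[0]), int(classes[1])

    maj_ids = np.flatnonzero(y == majority_label)
    min_ids = np.flatnonzero(y == minority_label)

    rng_root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in rng_root.generate_state(4) % (2 ** 31)]

    # (1) under-sample the majority
    kept_maj = undersample_majority(maj_ids, cfg.undersample_ratio, seeds[0])

    # (2) cluster the minority (on scaled features)
    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (Xa - mu) / sd
    K = choose_k(Xs[min_ids], cfg.k_range, cfg.elbow_threshold, seed=seeds[1])
    model = kmeans_fit(Xs[min_ids], K, seed=seeds[1])

    # (3) split majority and each minority cluster 8:1:1, merge per role
    train_ids: list[int] = []
    val_ids: list[int] = []
    test_ids: list[int] = []
    tr, va, te = split_8_1_1(kept_maj, seeds[2], cfg.split)
    train_ids += tr; val_ids += va; test_ids += te
    for c in range(K):
        cluster_rows = [int(min_ids[i]) for i in np.flatnonzero(model.assignment == c)]
        if len(cluster_rows) < 3:
            train_ids += cluster_rows  # too small to cover all roles
            continue
        tr, va, te = split_8_1_1(cluster_rows, seeds[2] + c + 1, cfg.split)
        train_ids += tr; val_ids += va; test_ids += te

    # (4) SMOTE the rarer class in the merged train set to exact balance
    y_tr = y[train_ids]
    n_min = int(np.sum(y_tr == minority_label))
    n_maj = int(np.sum(y_tr == majority_label))
    if n_min <= n_maj:
        smote_label, n_new = minority_label, n_maj - n_min
    else:
        smote_label, n_new = majority_label, n_min - n_maj
    donor_rows = [i for i in train_ids if y[i] == smote_label]
    synth_scaled = smote(Xs[donor_rows], n_new, k=cfg.smote_k, seed=seeds[3])
    synth = synth_scaled * sd + mu if n_new else np.empty((0, Xa.shape[1]))

    X_train = np.vstack([Xa[train_ids], synth]) if n_new else Xa[train_ids].copy()
    y_train = np.concatenate([y[train_ids],
                              np.full(n_new, smote_label, dtype=int)])
    provenance = ["original"] * len(train_ids) + ["synthetic"] * n_new

    return SplitBundle(
        X_train=X_train, y_train=y_train,
        X_val=Xa[val_ids].copy(), y_val=y[val_ids].copy(),
        X_test=Xa[test_ids].copy(), y_test=y[test_ids].copy(),
        train_provenance=provenance, column_names=column_names,
        train_row_ids=[int(i) for i in train_ids],
        val_row_ids=[int(i) for i in val_ids],
        test_row_ids=[int(i) for i in test_ids],
    )
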