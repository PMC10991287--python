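"""End-to-end orchestration: load → preprocess → select features → rebalance
(USCOM) → train the Gaussian network with AEHOM → evaluate.

One global seed deterministically derives every stage seed (selection,
resampling, weight init, herd) through a fixed counter scheme, so an
identical configuration reproduces an identical run report byte for byte
(timings excluded).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import aehom, evaluation, feature_selection, mldcnn, preprocessing, records_io, uscom
from .synthetic_data import TabularSpec, gen_tabular

logger = logging.getLogger("mlhdpm")


class StageError(RuntimeError):
    """Wraps a failure with the stage name and a config snapshot."""

    def __init__(self, stage: str, cause: Exception, cfg: "PipelineConfig"):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause} "
                         f"(config: {json.dumps(asdict(cfg), default=str)})")


def derive_seeds(global_seed: int, n: int = 8) -> list[int]:
    """Fixed counter scheme: stage i gets the i-th child of the global seed."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


@dataclass
class PipelineConfig:
    """Everything one run needs; sub-stage seeds derive from ``seed``.

    The GA here defaults to a lighter configuration than the selector's own
    printed defaults (6 generations of 24 genomes) so that repeated
    cross-validated runs stay fast; both are overridable.
    """

    data_path: str | None = None
    synthetic: TabularSpec | None = None
    use_signal_features: bool = False

    ga_generations: int = 6
    ga_population: int = 24
    ga_elites: int = 12
    ga_randoms: int = 12
    ga_crossover_rate: float = 0.05
    ga_mutation_rate: float = 0.05
    n_keep: int = 4

    undersample_ratio: float = 1.0
    smote_k: int = 5

    hidden_sizes: tuple[int, ...] = (6,)
    alpha: float = 0.05
    aehom_generations: int = 10
    herd_clans: int = 2
    herd_size: int = 8
    backprop_epochs: int = 40

    cv_folds: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            syn = dict(data["synthetic"])
            if "class_ratio" in syn:
                syn["class_ratio"] = tuple(syn["class_ratio"])
            data["synthetic"] = TabularSpec(**syn)
        if "hidden_sizes" in data:
            data["hidden_sizes"] = tuple(data["hidden_sizes"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(records_io.load_config(path))


class MLHDPMClassifier:
    """Estimator-style wrapper: fit runs selection, USCOM resampling and
    AEHOM-assisted training on the training data only; predict applies the
    stored scaler, feature subset and network.

    Suitable for fold-internal use in cross-validation — nothing fit on the
    training rows ever sees the test rows.
    """

    def __init__(self, cfg: PipelineConfig | None = None):
        self.cfg = cfg or PipelineConfig()
        self.selected_: list[int] | None = None
        self.scaler_: preprocessing.ScalerParams | None = None
        self.net_: mldcnn.Network | None = None
        self.bundle_: uscom.SplitBundle | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLHDPMClassifier":
        cfg = self.cfg
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        seeds = derive_seeds(cfg.seed)

        ga_cfg = feature_selection.GAConfig(
            generations=cfg.ga_generations, population=cfg.ga_population,
            elites=cfg.ga_elites, randoms=cfg.ga_randoms,
            crossover_rate=cfg.ga_crossover_rate,
            mutation_rate=cfg.ga_mutation_rate, seed=seeds[0])
        n_keep = min(cfg.n_keep, X.shape[1])
        Xs_all = _standardize_columns(X)
        best, history = feature_selection.ga_select(Xs_all, y, ga_cfg)
        ga_subset = [int(i) for i in np.flatnonzero(best.mask)]
        if n_keep > len(ga_subset):
            raise feature_selection.ConfigError(
                f"n_keep={n_keep} exceeds GA subset size {len(ga_subset)}")
        self.selected_ = feature_selection.rfe_select(
            Xs_all, y, feature_selection.RFEConfig(n_keep=n_keep),
            columns=ga_subset)
        self.selection_history_ = history

        Xsel = X[:, self.selected_]
        us_cfg = uscom.USCOMConfig(undersample_ratio=cfg.undersample_ratio,
                                   smote_k=cfg.smote_k, seed=seeds[1])
        bundle = uscom.run_uscom(Xsel, y, us_cfg)
        self.bundle_ = bundle

        self.scaler_ = preprocessing.fit_scaler(records_io.FeatureMatrix(
            bundle.X_train, [f"f{i}" for i in range(bundle.X_train.shape[1])]))
        X_train = self.scaler_.transform(bundle.X_train)

        net_cfg = mldcnn.NetworkConfig(
            layer_sizes=(len(self.selected_),) + cfg.hidden_sizes + (1,),
            alpha=cfg.alpha, epochs=cfg.backprop_epochs, seed=seeds[2])
        dims = mldcnn.init_network(net_cfg).n_parameters
        herd_cfg = aehom.HerdConfig(
            n_clans=cfg.herd_clans, clan_size=cfg.herd_size, dims=dims,
            p_min=-1.0, p_max=1.0, seed=seeds[3])
        schedule = aehom.TrainingSchedule(
            aehom_generations=cfg.aehom_generations, backprop_every=5,
            backprop_epochs=1, final_backprop_epochs=cfg.backprop_epochs)
        self.net_, self.loss_history_ = aehom.train_network_aehom(
            net_cfg, X_train, bundle.y_train, herd_cfg, schedule)
        self.threshold_ = net_cfg.threshold
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.net_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)[:, self.selected_]
        return mldcnn.predict(self.net_, self.scaler_.transform(X),
                              self.threshold_)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _load_data(cfg: PipelineConfig) -> tuple[records_io.FeatureMatrix, np.ndarray]:
    if cfg.data_path is not None:
        records = records_io.load_dataset(cfg.data_path)
    elif cfg.synthetic is not None:
        records, _ = gen_tabular(cfg.synthetic)
    else:
        raise ValueError("either data_path or a synthetic spec is required")
    if any(rec.is_missing(col) for rec in records for col in records_io.PREDICTORS):
        records = preprocessing.impute_missing(records)
    records = preprocessing.deduplicate(records)
    return records_io.to_matrix(records)


def run_mlhdpm(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and return a JSON-serializable run report
    with the six metrics for train and test, stage timings, seeds and the
    selected features."""
    timings: dict[str, float] = {}
    report: dict = {"config": json.loads(json.dumps(asdict(cfg), default=str)),
                    "seeds": derive_seeds(cfg.seed)}

    t0 = time.perf_counter()
    try:
        X, y = _load_data(cfg)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("load", exc, cfg) from exc
    timings["load"] = time.perf_counter() - t0
    logger.info("loaded %d rows x %d predictors; class counts %s",
                X.shape[0], X.shape[1], np.bincount(y).tolist())

    t0 = time.perf_counter()
    try:
        model = MLHDPMClassifier(cfg)
        model.fit(X.values, y)
    except Exception as exc:
        raise StageError("train", exc, cfg) from exc
    timings["train"] = time.perf_counter() - t0
    bundle = model.bundle_
    logger.info("selected features %s; balanced train class counts %s",
                [X.column_names[i] for i in model.selected_],
                np.bincount(bundle.y_train).tolist())

    t0 = time.perf_counter()
    try:
        X_train_scaled = model.scaler_.transform(bundle.X_train)
        train_pred = mldcnn.predict(model.net_, X_train_scaled, model.threshold_)
        train_rep = evaluation.evaluate_predictions(bundle.y_train, train_pred)
        X_test_scaled = model.scaler_.transform(bundle.X_test)
        test_pred = mldcnn.predict(model.net_, X_test_scaled, model.threshold_)
        test_rep = evaluation.evaluate_predictions(bundle.y_test, test_pred)
    except Exception as exc:
        raise StageError("evaluate", exc, cfg) from exc
    timings["evaluate"] = time.perf_counter() - t0

    report.update({
        "selected_features": [X.column_names[i] for i in model.selected_],
        "selection_history": [float(f) for f in model.selection_history_],
        "train_counts": {str(c): int(n) for c, n in
                         zip(*np.unique(bundle.y_train, return_counts=True))},
        "val_size": int(len(bundle.y_val)),
        "test_size": int(len(bundle.y_test)),
        "n_synthetic_train_rows": sum(p == "synthetic"
                                      for p in bundle.train_provenance),
        "train_metrics": train_rep.as_dict(),
        "test_metrics": test_rep.as_dict(),
        "timings": timings,
    })
    return report


def report_without_timings(report: dict) -> dict:
    """The deterministic part of a run report (drop wall-clock timings)."""
    return {k: v for k, v in report.items() if k != "timings"}
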