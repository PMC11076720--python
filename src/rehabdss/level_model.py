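"""Strength-level improvement submodel.

Whether a patient is ready for the next robot strength level (F1 -> F5) is
learned from the case library as a binary classification task on the
20-statistic session features.  The production pipeline is:

    min-max normalization  ->  chi-square selection (k = 19)  ->
    random forest (54 trees, max depth 16, seed 70)

chosen because that fusion ranks in the top three for accuracy and AUC in
every training mode.  The module also exposes the comparison harness that
established this: five classifiers (logistic regression, random forest,
SVM, AdaBoost, XGBoost) crossed with six feature-processing schemes
(raw/normalized/standardized x variance filter / chi-square filter / PCA),
evaluated per mode on a seeded stratified hold-out split.

Chi-square selection requires non-negative inputs, which the [0, 1]
normalization guarantees; score ties are broken toward the lower feature
index.  A constant feature column normalizes to all zeros with a warning
rather than an error, so a degenerate clinical feature cannot abort
training.
"""

from __future__ import annotations

import enum
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import chi2 as sklearn_chi2
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .case_base import CaseLibrary, CaseRecord
from .exceptions import (
    DegenerateColumnError,
    SchemaMismatchError,
    UnlearnableError,
    WrongModelError,
)
from .metrics import FEATURE_NAMES, Mode, SessionFeatures

__all__ = [
    "Scaler",
    "Selector",
    "Algorithm",
    "PreprocessSpec",
    "ModelConfig",
    "EvaluationReport",
    "LevelModel",
    "minmax_normalize",
    "standardize",
    "variance_score",
    "chi_square_statistic",
    "chi_square_select",
    "default_config",
    "default_preprocess",
    "fit_level_model",
    "fit_level_model_arrays",
    "predict_level_up",
    "evaluate",
    "run_fusion_comparison",
    "save_model",
    "load_model",
    "DECISION_THRESHOLD",
]

#: Predicted probability at or above which a level-up is granted.
DECISION_THRESHOLD = 0.5


class Scaler(str, enum.Enum):
    RAW = "raw"
    NORMALIZE = "normalize"
    STANDARDIZE = "standardize"


class Selector(str, enum.Enum):
    VARIANCE = "variance"
    CHI_SQUARE = "chi_square"
    PCA = "pca"


class Algorithm(str, enum.Enum):
    LOGISTIC_REGRESSION = "logistic_regression"
    RANDOM_FOREST = "random_forest"
    SVM = "svm"
    ADABOOST = "adaboost"
    XGBOOST = "xgboost"


@dataclass(frozen=True)
class PreprocessSpec:
    """Feature-processing scheme: a scaler plus a selection step keeping
    ``k_or_components`` of the 20 features (default 19)."""

    scaler: Scaler = Scaler.NORMALIZE
    selector: Selector = Selector.CHI_SQUARE
    k_or_components: int = 19

    def __post_init__(self) -> None:
        object.__setattr__(self, "scaler", Scaler(self.scaler))
        object.__setattr__(self, "selector", Selector(self.selector))
        if not 1 <= self.k_or_components <= len(FEATURE_NAMES):
            raise ValueError(
                f"k_or_components must be in [1, {len(FEATURE_NAMES)}]"
            )

    @property
    def tag(self) -> str:
        s = {"raw": "RAW", "normalize": "NOR", "standardize": "STA"}[self.scaler.value]
        f = {"variance": "VAR", "chi_square": "CHI", "pca": "PCA"}[self.selector.value]
        return f"{s}+{f}"


@dataclass(frozen=True)
class ModelConfig:
    algorithm: Algorithm
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "algorithm", Algorithm(self.algorithm))
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))


# Tuned hyperparameter defaults for each algorithm in the comparison.
_DEFAULT_HYPERPARAMETERS: dict[Algorithm, dict] = {
    Algorithm.LOGISTIC_REGRESSION: {
        "penalty": "l2",
        "solver": "liblinear",
        "C": 0.1,
        "max_iter": 1000,
    },
    Algorithm.RANDOM_FOREST: {
        "n_estimators": 54,
        "random_state": 70,
        "max_depth": 16,
    },
    Algorithm.SVM: {"kernel": "rbf", "gamma": "auto", "cache_size": 5000},
    Algorithm.ADABOOST: {
        "base_max_depth": 16,
        "n_estimators": 1000,
        "learning_rate": 3.0,
    },
    Algorithm.XGBOOST: {
        "n_estimators": 340,
        "colsample_bytree": 0.6,
        "learning_rate": 0.3,
        "max_depth": 3,
        "subsample": 0.7,
    },
}


def default_config(algorithm: Algorithm | str = Algorithm.RANDOM_FOREST) -> ModelConfig:
    alg = Algorithm(algorithm)
    return ModelConfig(algorithm=alg, hyperparameters=_DEFAULT_HYPERPARAMETERS[alg])


def default_preprocess() -> PreprocessSpec:
    return PreprocessSpec()


# ---------------------------------------------------------------------------
# Preprocessing primitives


def minmax_normalize(
    x: np.ndarray, bounds: tuple[np.ndarray, np.ndarray] | None = None
) -> np.ndarray:
    """Columnwise (x - min) / (max - min), onto [0, 1].

    ``bounds`` applies a previously fitted (min, max) pair (train-set bounds
    at predict time).  A constant column maps to all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    lo, hi = bounds if bounds is not None else (x.min(axis=0), x.max(axis=0))
    span = hi - lo
    constant = span == 0
    if constant.any() and bounds is None:
        warnings.warn(
            f"{int(constant.sum())} constant column(s) mapped to 0 under "
            "min-max normalization",
            stacklevel=2,
        )
    span = np.where(constant, 1.0, span)
    out = (x - lo) / span
    out[:, constant] = 0.0
    return out


def standardize(x: np.ndarray) -> np.ndarray:
    """Columnwise (x - mean) / sd with the sample (n-1) convention."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    if (sigma == 0).any():
        raise DegenerateColumnError("cannot standardize a constant column")
    return (x - mu) / sigma


def variance_score(x: np.ndarray | float) -> float:
    """Bernoulli variance p(1-p) of a two-class feature column.

    Accepts either the class probability ``p`` directly or a binary column,
    in which case ``p`` is the frequency of the larger value.
    """
    if np.isscalar(x):
        p = float(x)
        if not 0.0 <= p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        return p * (1.0 - p)
    arr = np.asarray(x)
    values = np.unique(arr)
    if len(values) > 2:
        raise ValueError("variance_score expects a two-class column")
    p = float(np.mean(arr == values[-1]))
    return p * (1.0 - p)


def chi_square_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """sum((O_i - E_i)^2 / E_i) over the cells of a frequency table."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected shapes differ")
    if (expected <= 0).any():
        raise ValueError("expected frequencies must be positive")
    return float(((observed - expected) ** 2 / expected).sum())


def chi_square_select(x: np.ndarray, labels: np.ndarray, k: int) -> list[int]:
    """Indices of the ``k`` features with largest chi-square statistic
    against the labels; ties broken toward the lower index.

    Inputs must be non-negative (use the [0, 1] normalization first).
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("chi-square selection requires non-negative inputs")
    if not 1 <= k <= x.shape[1]:
        raise ValueError(f"k must be in [1, {x.shape[1]}]")
    scores, _ = sklearn_chi2(x, np.asarray(labels))
    scores = np.nan_to_num(scores, nan=0.0)
    order = sorted(range(x.shape[1]), key=lambda j: (-scores[j], j))
    return sorted(order[:k])


class _VarianceSelector:
    """Keep the k highest-variance columns (tie toward lower index)."""

    def __init__(self, k: int):
        self.k = k
        self.indices_: list[int] | None = None

    def fit(self, x: np.ndarray, y=None) -> "_VarianceSelector":
        var = np.var(np.asarray(x, dtype=float), axis=0)
        order = sorted(range(x.shape[1]), key=lambda j: (-var[j], j))
        self.indices_ = sorted(order[: self.k])
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[:, self.indices_]


class _ChiSquareSelector:
    def __init__(self, k: int):
        self.k = k
        self.indices_: list[int] | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_ChiSquareSelector":
        self.indices_ = chi_square_select(x, y, self.k)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[:, self.indices_]


class _FittedScaler:
    """Scaler fitted on the training matrix, reapplied at predict time."""

    def __init__(self, kind: Scaler):
        self.kind = kind
        self.lo_: np.ndarray | None = None
        self.hi_: np.ndarray | None = None
        self.mu_: np.ndarray | None = None
        self.sigma_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "_FittedScaler":
        x = np.asarray(x, dtype=float)
        if self.kind == Scaler.NORMALIZE:
            self.lo_, self.hi_ = x.min(axis=0), x.max(axis=0)
        elif self.kind == Scaler.STANDARDIZE:
            self.mu_ = x.mean(axis=0)
            self.sigma_ = x.std(axis=0, ddof=1)
            if (self.sigma_ == 0).any():
                raise DegenerateColumnError("constant column under standardization")
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == Scaler.RAW:
            return x
        if self.kind == Scaler.NORMALIZE:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = minmax_normalize(x, bounds=(self.lo_, self.hi_))
            # chi-square downstream needs non-negative values even when a
            # test point falls outside the training range
            return np.clip(out, 0.0, None)
        return (x - self.mu_) / self.sigma_


def _build_classifier(cfg: ModelConfig, seed: int | None):
    hp = dict(cfg.hyperparameters)
    if cfg.algorithm == Algorithm.LOGISTIC_REGRESSION:
        return LogisticRegression(**hp)
    if cfg.algorithm == Algorithm.RANDOM_FOREST:
        hp.setdefault("random_state", seed)
        return RandomForestClassifier(**hp)
    if cfg.algorithm == Algorithm.SVM:
        hp.setdefault("random_state", seed)
        return SVC(probability=True, **hp)
    if cfg.algorithm == Algorithm.ADABOOST:
        depth = hp.pop("base_max_depth", None)
        hp.setdefault("random_state", seed)
        est = DecisionTreeClassifier(max_depth=depth, random_state=hp["random_state"])
        return AdaBoostClassifier(estimator=est, **hp)
    if cfg.algorithm == Algorithm.XGBOOST:
        hp.setdefault("random_state", seed if seed is not None else 0)
        return XGBClassifier(eval_metric="logloss", **hp)
    raise ValueError(f"unknown algorithm {cfg.algorithm}")  # pragma: no cover


@dataclass(frozen=True)
class EvaluationReport:
    """Hold-out metrics for one fitted model: accuracy/recall/F1 in percent,
    AUC (trapezoidal area under the ROC of predicted probabilities) in
    [0, 1]."""

    mode: Mode
    accuracy: float
    auc: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class LevelModel:
    """A fitted level-up classifier: scaler + selected features + classifier,
    bound to one training mode and one feature schema."""

    mode: Mode
    spec: PreprocessSpec
    config: ModelConfig
    seed: int | None
    feature_names: tuple[str, ...]
    scaler: _FittedScaler
    selector: object
    classifier: object
    library_fingerprint: str

    @property
    def selected_features(self) -> list[str]:
        if isinstance(self.selector, PCA):
            return [f"PC{i + 1}" for i in range(self.selector.n_components_)]
        return [self.feature_names[j] for j in self.selector.indices_]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xt = self.selector.transform(self.scaler.transform(np.asarray(X, dtype=float)))
        return self.classifier.predict_proba(Xt)[:, 1]


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=int).tobytes())
    return h.hexdigest()[:16]


def fit_level_model(
    lib: CaseLibrary,
    mode: Mode | str,
    spec: PreprocessSpec | None = None,
    cfg: ModelConfig | None = None,
    seed: int | None = None,
) -> LevelModel:
    """Fit the level-up pipeline on one mode's partition of the library.

    Defaults to the production pipeline (normalize -> chi-square k=19 ->
    random forest with 54 trees, depth 16, seed 70).  Refitting with the
    same library and seed reproduces identical predictions.
    """
    mode = Mode(mode)
    spec = spec or default_preprocess()
    cfg = cfg or default_config()
    X, y, _ = lib.feature_matrix(mode)
    return _fit_arrays(X, y, mode, spec, cfg, seed)


def fit_level_model_arrays(
    X: np.ndarray,
    y: np.ndarray,
    mode: Mode | str,
    spec: PreprocessSpec | None = None,
    cfg: ModelConfig | None = None,
    seed: int | None = None,
) -> LevelModel:
    """Fit the pipeline directly on an (X, y) feature matrix (columns in
    canonical feature order) — the array-level counterpart of
    :func:`fit_level_model`, for explicit train/test protocols."""
    return _fit_arrays(
        np.asarray(X, dtype=float),
        np.asarray(y, dtype=int),
        Mode(mode),
        spec or default_preprocess(),
        cfg or default_config(),
        seed,
    )


def _fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    mode: Mode,
    spec: PreprocessSpec,
    cfg: ModelConfig,
    seed: int | None,
) -> LevelModel:
    if len(np.unique(y)) < 2:
        raise UnlearnableError(
            f"{mode.value} library has a single label class; cannot fit"
        )
    scaler = _FittedScaler(spec.scaler).fit(X)
    Xs = scaler.transform(X)
    if spec.selector == Selector.CHI_SQUARE:
        selector = _ChiSquareSelector(spec.k_or_components).fit(Xs, y)
    elif spec.selector == Selector.VARIANCE:
        selector = _VarianceSelector(spec.k_or_components).fit(Xs)
    else:
        selector = PCA(
            n_components=min(spec.k_or_components, min(Xs.shape) - 1),
            random_state=seed,
        ).fit(Xs)
    Xt = selector.transform(Xs)
    clf = _build_classifier(cfg, seed)
    clf.fit(Xt, y)
    return LevelModel(
        mode=mode,
        spec=spec,
        config=cfg,
        seed=seed,
        feature_names=FEATURE_NAMES,
        scaler=scaler,
        selector=selector,
        classifier=clf,
        library_fingerprint=_fingerprint(X, y),
    )


def predict_level_up(
    model: LevelModel, f: SessionFeatures
) -> tuple[float, bool]:
    """(probability, decision) for one session; decision = p >= 0.5."""
    if f.mode != model.mode:
        raise WrongModelError(
            f"model fitted for {model.mode.value} mode, session is {f.mode.value}"
        )
    if tuple(model.feature_names) != FEATURE_NAMES:
        raise SchemaMismatchError("model feature schema does not match")
    p = float(model.predict_proba(f.as_array()[None, :])[0])
    return p, p >= DECISION_THRESHOLD


def evaluate(
    model: LevelModel,
    test_cases: Sequence[CaseRecord] | tuple[np.ndarray, np.ndarray],
) -> EvaluationReport:
    """Accuracy, AUC, recall and F1 of a fitted model on held-out cases.

    ``test_cases`` is either a sequence of CaseRecords (of the model's
    mode) or an ``(X, y)`` pair.
    """
    if isinstance(test_cases, tuple):
        X, y = test_cases
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
    else:
        X = np.vstack([c.features.as_array() for c in test_cases])
        y = np.array([int(c.level_up) for c in test_cases])
    if len(np.unique(y)) < 2:
        raise UnlearnableError("test set has a single class; AUC undefined")
    p = model.predict_proba(X)
    yhat = (p >= DECISION_THRESHOLD).astype(int)
    return EvaluationReport(
        mode=model.mode,
        accuracy=100.0 * accuracy_score(y, yhat),
        auc=float(roc_auc_score(y, p)),
        recall=100.0 * recall_score(y, yhat),
        f1=100.0 * f1_score(y, yhat),
    )


#: The six feature-processing schemes of the comparison experiment.
COMPARISON_SPECS: tuple[PreprocessSpec, ...] = (
    PreprocessSpec(Scaler.RAW, Selector.VARIANCE),
    PreprocessSpec(Scaler.NORMALIZE, Selector.VARIANCE),
    PreprocessSpec(Scaler.NORMALIZE, Selector.CHI_SQUARE),
    PreprocessSpec(Scaler.RAW, Selector.PCA),
    PreprocessSpec(Scaler.NORMALIZE, Selector.PCA),
    PreprocessSpec(Scaler.STANDARDIZE, Selector.PCA),
)


def run_fusion_comparison(
    lib: CaseLibrary,
    specs: Sequence[PreprocessSpec] | None = None,
    cfgs: Sequence[ModelConfig] | None = None,
    test_size: float = 0.2,
    seed: int = 0,
    modes: Sequence[Mode] | None = None,
) -> pd.DataFrame:
    """Cross every (mode, feature-processing scheme, algorithm) cell and
    report hold-out metrics from a seeded stratified split.

    Chi-square selection is incompatible with scalers that can emit
    negative values; such cells are skipped with a note in the table.
    """
    specs = list(specs) if specs is not None else list(COMPARISON_SPECS)
    cfgs = (
        list(cfgs)
        if cfgs is not None
        else [default_config(a) for a in Algorithm]
    )
    modes = list(modes) if modes is not None else list(Mode)
    rows = []
    for mode in modes:
        X, y, _ = lib.feature_matrix(mode)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_size, random_state=seed, stratify=y
        )
        for spec in specs:
            for cfg in cfgs:
                row = {
                    "mode": mode.value,
                    "processing": spec.tag,
                    "algorithm": cfg.algorithm.value,
                }
                if spec.selector == Selector.CHI_SQUARE and spec.scaler in (
                    Scaler.RAW,
                    Scaler.STANDARDIZE,
                ):
                    row.update(
                        accuracy=np.nan, auc=np.nan, recall=np.nan, f1=np.nan,
                        note="chi-square needs non-negative inputs",
                    )
                    rows.append(row)
                    continue
                model = _fit_arrays(X_tr, y_tr, mode, spec, cfg, seed)
                rep = evaluate(model, (X_te, y_te))
                row.update(
                    accuracy=rep.accuracy, auc=rep.auc,
                    recall=rep.recall, f1=rep.f1, note="",
                )
                rows.append(row)
    return pd.DataFrame(rows)


def save_model(model: LevelModel, path: str | Path) -> None:
    """Persist a fitted model (single joblib artifact with config, seed,
    selected feature names and library fingerprint embedded)."""
    joblib.dump(
        {
            "format": "rehabdss-level-model-v1",
            "mode": model.mode.value,
            "spec": {
                "scaler": model.spec.scaler.value,
                "selector": model.spec.selector.value,
                "k_or_components": model.spec.k_or_components,
            },
            "config": {
                "algorithm": model.config.algorithm.value,
                "hyperparameters": model.config.hyperparameters,
            },
            "seed": model.seed,
            "feature_names": list(model.feature_names),
            "selected_features": model.selected_features,
            "library_fingerprint": model.library_fingerprint,
            "scaler": model.scaler,
            "selector": model.selector,
            "classifier": model.classifier,
        },
        path,
    )


def load_model(path: str | Path) -> LevelModel:
    d = joblib.load(path)
    if d.get("format") != "rehabdss-level-model-v1":
        raise SchemaMismatchError(f"{path} is not a rehabdss level-model artifact")
    names = tuple(d["feature_names"])
    if names != FEATURE_NAMES:
        raise SchemaMismatchError(
            "persisted model was trained on a different feature schema"
        )
    return LevelModel(
        mode=Mode(d["mode"]),
        spec=PreprocessSpec(**d["spec"]),
        config=ModelConfig(**d["config"]),
        seed=d["seed"],
        feature_names=names,
        scaler=d["scaler"],
        selector=d["selector"],
        classifier=d["classifier"],
        library_fingerprint=d["library_fingerprint"],
    )
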