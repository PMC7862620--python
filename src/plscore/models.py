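"""Linear and nonlinear scoring models: published coefficient sets, MLR,
epsilon-insensitive SVR (rbf / Pearson-VII kernels), random forests,
k-fold cross-validation and the one-term-at-a-time ablation protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from .metrics import pearson_r, rmse

__all__ = [
    "LinearCoefficients", "ModelSpec", "TrainedModel", "CrossValResult",
    "AblationResult", "load_coefficients", "available_models",
    "predict_linear", "fit_mlr", "fit_svr", "fit_rf", "kfold_cv",
    "ablation_selection", "puk_kernel", "DEFAULT_GRIDS",
]

SHIPPED_MODELS = ["general-random", "general-all", "protease", "ippi", "ippi-onesolv"]

#: default hyperparameter grids (config-overridable)
DEFAULT_GRIDS = {
    "svr": {"C": [0.1, 1.0, 10.0, 100.0], "epsilon": [0.001, 0.01, 0.1],
            "kernel": ["rbf", "puk"], "gamma": [0.01, 0.1, 1.0],
            "sigma": [0.5, 1.0, 3.0], "omega": [0.5, 1.0, 3.0]},
    "rf": {"numTrees": [100, 500, 1000], "numFeatures": [1, 2, 3, 4, 5, 6]},
}


@dataclass
class LinearCoefficients:
    weights: Dict[str, float]
    intercept: float
    term_set: List[str]
    provenance: str = ""

    def __post_init__(self):
        missing = [t for t in self.term_set if t not in self.weights]
        if missing:
            raise ValueError(f"terms without weights: {missing}")

    @classmethod
    def from_json(cls, path_or_obj) -> "LinearCoefficients":
        if isinstance(path_or_obj, (str,)):
            with open(path_or_obj) as fh:
                obj = json.load(fh)
        else:
            obj = path_or_obj
        return cls(weights=dict(obj["weights"]), intercept=float(obj["intercept"]),
                   term_set=list(obj["term_set"]),
                   provenance=obj.get("provenance", ""))

    def to_json(self, path: str) -> None:
        obj = {"provenance": self.provenance, "term_set": self.term_set,
               "weights": self.weights, "intercept": self.intercept}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")


def available_models() -> List[str]:
    return list(SHIPPED_MODELS)


def load_coefficients(name: str) -> LinearCoefficients:
    """Load one of the shipped coefficient sets by id."""
    if name not in SHIPPED_MODELS:
        raise KeyError(f"unknown model id: {name!r}; choose from {SHIPPED_MODELS}")
    text = resources.files("plscore.data").joinpath(f"{name}.json").read_text()
    return LinearCoefficients.from_json(json.loads(text))


def predict_linear(desc: Union[Mapping[str, float], "object"],
                   coef: LinearCoefficients) -> float:
    """Affine prediction: sum_t w_t * desc_t + intercept (kcal/mol)."""
    if hasattr(desc, "as_dict"):
        desc = desc.as_dict()
    total = coef.intercept
    for term in coef.term_set:
        if term not in desc or desc[term] is None:
            raise KeyError(f"descriptor vector is missing term {term!r}")
        total += coef.weights[term] * float(desc[term])
    return float(total)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    algorithm: str = "mlr"  # mlr | svr | rf
    C: float = 1.0
    epsilon: float = 0.01
    kernel: str = "rbf"     # rbf | puk
    gamma: float = 0.1
    sigma: float = 1.0
    omega: float = 1.0
    numTrees: int = 500
    numFeatures: Optional[int] = None
    bootstrap: bool = True
    seed: int = 0
    standardize: Optional[bool] = None  # default: True for svr, False otherwise

    def wants_standardize(self) -> bool:
        if self.standardize is None:
            return self.algorithm == "svr"
        return self.standardize


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    scaler: object = None
    term_set: Optional[List[str]] = None
    meta: dict = field(default_factory=dict)

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._design(X)), dtype=float)

    def per_tree_predictions(self, X) -> np.ndarray:
        """(n_trees, n_samples) predictions; random-forest models only."""
        if not hasattr(self.estimator, "estimators_"):
            raise AttributeError("per-tree predictions require a forest model")
        Xd = self._design(X)
        return np.stack([t.predict(Xd) for t in self.estimator.estimators_])


def _as_xy(features, targets):
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) != len(y):
        raise ValueError("features and targets length mismatch")
    return X, y


def fit_mlr(features, targets,
            term_names: Optional[Sequence[str]] = None) -> LinearCoefficients:
    """Ordinary least squares with an implicit intercept."""
    X, y = _as_xy(features, targets)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than terms")
    A = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("rank-deficient design matrix (constant or "
                         "collinear columns)")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]
    term_names = list(term_names)
    return LinearCoefficients(weights=dict(zip(term_names, map(float, beta[:p]))),
                              intercept=float(beta[p]), term_set=term_names,
                              provenance="fit_mlr")


def puk_kernel(X, Y, sigma: float = 1.0, omega: float = 1.0) -> np.ndarray:
    """Pearson VII universal kernel; equals 1 at zero distance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    from scipy.spatial.distance import cdist
    d = cdist(X, Y)
    c = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return (1.0 + (c * d) ** 2) ** (-omega)


def fit_svr(features, targets, spec: ModelSpec,
            term_set: Optional[List[str]] = None) -> TrainedModel:
    """Epsilon-insensitive support-vector regression (SMO-style backend)."""
    from sklearn.svm import SVR
    from sklearn.preprocessing import StandardScaler
    if spec.algorithm != "svr":
        raise ValueError("spec.algorithm must be 'svr'")
    X, y = _as_xy(features, targets)
    scaler = None
    if spec.wants_standardize():
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    if spec.kernel == "rbf":
        est = SVR(kernel="rbf", C=spec.C, epsilon=spec.epsilon, gamma=spec.gamma)
    elif spec.kernel == "puk":
        est = SVR(kernel=lambda A, B: puk_kernel(A, B, spec.sigma, spec.omega),
                  C=spec.C, epsilon=spec.epsilon)
    else:
        raise ValueError(f"unknown kernel: {spec.kernel}")
    est.fit(X, y)
    if est.fit_status_ != 0:  # libsvm non-convergence
        raise RuntimeError(f"SVR failed to converge (status {est.fit_status_}, "
                           f"C={spec.C}, epsilon={spec.epsilon})")
    return TrainedModel(spec=spec, estimator=est, scaler=scaler,
                        term_set=term_set, meta={"n": len(y)})


def fit_rf(features, targets, spec: ModelSpec,
           term_set: Optional[List[str]] = None) -> TrainedModel:
    """Bagged regression trees; prediction = mean over trees."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.preprocessing import StandardScaler
    if spec.algorithm != "rf":
        raise ValueError("spec.algorithm must be 'rf'")
    X, y = _as_xy(features, targets)
    n_feat = X.shape[1]
    max_features = spec.numFeatures
    if max_features is not None and max_features > n_feat:
        raise ValueError(f"numFeatures={max_features} exceeds the "
                         f"{n_feat} available terms")
    scaler = None
    if spec.wants_standardize():
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = RandomForestRegressor(
        n_estimators=spec.numTrees,
        max_features=max_features if max_features is not None else 1.0,
        bootstrap=spec.bootstrap,
        random_state=spec.seed,
    )
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, scaler=scaler,
                        term_set=term_set, meta={"n": len(y)})


def _fit_by_spec(spec: ModelSpec) -> Callable:
    def factory(X, y):
        if spec.algorithm == "mlr":
            coef = fit_mlr(X, y)
            w = np.array([coef.weights[t] for t in coef.term_set])
            return lambda Xt: np.asarray(Xt, dtype=float) @ w + coef.intercept
        if spec.algorithm == "svr":
            return fit_svr(X, y, spec).predict
        if spec.algorithm == "rf":
            return fit_rf(X, y, spec).predict
        raise ValueError(f"unknown algorithm: {spec.algorithm}")
    return factory


@dataclass
class CrossValResult:
    per_fold_R: List[float]
    mean_R: float
    per_fold_RMSE: List[float]
    mean_RMSE: float
    fold_assignments: np.ndarray


def kfold_cv(features, targets, spec_or_factory, k: int = 10,
             seed: int = 0) -> CrossValResult:
    """Seeded random k-fold CV; per-fold Pearson R and RMSE on held-out data.

    ``spec_or_factory`` is a :class:`ModelSpec` or a callable
    ``factory(X_train, y_train) -> predict_fn``.
    """
    X, y = _as_xy(features, targets)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    factory = (spec_or_factory if callable(spec_or_factory)
               else _fit_by_spec(spec_or_factory))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    folds = np.array_split(perm, k)
    for fi, idx in enumerate(folds):
        assignments[idx] = fi
    per_R, per_RMSE = [], []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        predict = factory(X[train_idx], y[train_idx])
        pred = np.asarray(predict(X[test_idx]), dtype=float)
        per_R.append(pearson_r(pred, y[test_idx]))
        per_RMSE.append(rmse(pred, y[test_idx]))
    return CrossValResult(per_fold_R=per_R, mean_R=float(np.mean(per_R)),
                          per_fold_RMSE=per_RMSE,
                          mean_RMSE=float(np.mean(per_RMSE)),
                          fold_assignments=assignments)


# ---------------------------------------------------------------------------
# Ablation (one candidate term added to the base at a time)
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    per_variant_R: Dict[str, Dict[str, float]]  # class -> variant -> CV mean R
    best_per_class: Dict[str, str]
    chosen_terms: List[str]


def ablation_selection(base_terms: Mapping[str, Sequence[float]],
                       candidate_variants: Mapping[str, Sequence[str]],
                       features_by_variant: Mapping[str, Sequence[float]],
                       targets, k: int = 10, seed: int = 0) -> AblationResult:
    """Add each candidate variant to the base term set one at a time, score
    with MLR cross-validation, and keep the best variant of each class.

    ``base_terms``: name -> column for the always-present terms.
    ``candidate_variants``: class name -> list of variant column names.
    ``features_by_variant``: variant column name -> column.
    """
    import warnings as _warnings
    base_names = list(base_terms)
    Xbase = np.column_stack([np.asarray(base_terms[t], dtype=float)
                             for t in base_names])
    y = np.asarray(targets, dtype=float)
    per_variant: Dict[str, Dict[str, float]] = {}
    best: Dict[str, str] = {}
    for cls, variants in candidate_variants.items():
        if not variants:
            _warnings.warn(f"candidate class {cls!r} is empty; skipped")
            continue
        scores = {}
        for v in variants:
            col = np.asarray(features_by_variant[v], dtype=float)
            X = np.column_stack([Xbase, col])
            cv = kfold_cv(X, y, ModelSpec(algorithm="mlr"), k=k, seed=seed)
            scores[v] = cv.mean_R
        per_variant[cls] = scores
        best[cls] = max(scores, key=scores.get)
    chosen = base_names + [best[c] for c in candidate_variants if c in best]
    return AblationResult(per_variant_R=per_variant, best_per_class=best,
                          chosen_terms=chosen)
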