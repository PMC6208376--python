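"""GA-selected SVM disease classifier with a calibrated [0, 1] index.

A genetic algorithm searches for the 20-feature subset that maximizes
the repeated stratified k-fold cross-validated ROC AUC of a linear SVM
(standardization and calibration fitted within each training fold only).
The trained model maps a feature vector through a Platt sigmoid to a
disease index in [0, 1]: low values control-like, high values
carrier-like.

Two evaluation protocols are provided.  ``honest`` (nested) repeats the
GA selection inside every training fold — an unbiased but expensive
estimate.  ``paper`` selects one subset on all data and then
cross-validates only the SVM — the optimistically biased single-selection
protocol typical of small pilot studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .ga import GAConfig, ga_optimize

CARRIER_LABEL = 1  # positive class: gene carrier


@dataclass(frozen=True)
class CVConfig:
    folds: int = 10
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"


@dataclass
class ClassifierModel:
    """Selected subset + standardization + SVM + Platt calibration."""

    selected_features: list[str]
    loc: np.ndarray
    scale: np.ndarray
    svm: SVC
    platt: LogisticRegression

    def index(self, X: np.ndarray) -> np.ndarray:
        """Disease index in [0, 1] for rows of the selected-feature matrix."""
        Z = (np.asarray(X, float) - self.loc) / self.scale
        decision = self.svm.decision_function(Z)
        return self.platt.predict_proba(decision[:, None])[:, 1]

    def to_dict(self) -> dict:
        """JSON-serializable form: subset, standardization, SVM dual
        representation and the sigmoid calibration parameters."""
        if self.svm.kernel != "linear":
            raise NotImplementedError("only linear models serialize to JSON")
        return {
            "selected_features": list(self.selected_features),
            "loc": self.loc.tolist(),
            "scale": self.scale.tolist(),
            "svm": {
                "kernel": self.svm.kernel,
                "C": float(self.svm.C),
                "support_vectors": self.svm.support_vectors_.tolist(),
                "dual_coef": self.svm.dual_coef_.tolist(),
                "intercept": self.svm.intercept_.tolist(),
            },
            "platt": {
                "coef": float(self.platt.coef_[0, 0]),
                "intercept": float(self.platt.intercept_[0]),
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LinearIndexModel":
        svm = payload["svm"]
        weights = np.asarray(svm["dual_coef"])[0] @ np.asarray(svm["support_vectors"])
        return LinearIndexModel(
            selected_features=list(payload["selected_features"]),
            loc=np.asarray(payload["loc"], float),
            scale=np.asarray(payload["scale"], float),
            weights=weights,
            bias=float(svm["intercept"][0]),
            platt_coef=float(payload["platt"]["coef"]),
            platt_intercept=float(payload["platt"]["intercept"]),
        )


@dataclass
class LinearIndexModel:
    """A deserialized linear classifier: primal weights + Platt sigmoid."""

    selected_features: list[str]
    loc: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    bias: float
    platt_coef: float
    platt_intercept: float

    def index(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.loc) / self.scale
        decision = Z @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-(self.platt_coef * decision + self.platt_intercept)))


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_point: dict[str, float]      # at index threshold 0.5
    youden_point: dict[str, float]
    oof_index: np.ndarray                  # per-subject out-of-fold index
    group_densities: dict[str, np.ndarray] = field(default_factory=dict)
    selected_features: list[str] | None = None
    fitness_trace: list[float] | None = None


def _validate_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return loc, scale


def _fold_seed(seed: int, repeat: int) -> int:
    return (seed * 1000003 + repeat) % (2**31 - 1)


def _cv_decision_values(
    X: np.ndarray, y: np.ndarray, cv: CVConfig, svm: SVMConfig
) -> np.ndarray:
    """Out-of-fold SVM decision values, one column per repeat."""
    n = len(y)
    out = np.empty((n, cv.repeats))
    for rep in range(cv.repeats):
        skf = StratifiedKFold(cv.folds, shuffle=True, random_state=_fold_seed(cv.seed, rep))
        for train, test in skf.split(X, y):
            if len(np.unique(y[train])) < 2:
                raise ValueError("training fold lost a class; reduce folds")
            loc, scale = _standardize_fit(X[train])
            clf = SVC(kernel=svm.kernel, C=svm.C, gamma=svm.gamma)
            clf.fit((X[train] - loc) / scale, y[train])
            out[test, rep] = clf.decision_function((X[test] - loc) / scale)
    return out


def cv_auc_fitness(
    X: np.ndarray,
    y: np.ndarray,
    subset,
    cv: CVConfig,
    svm: SVMConfig | None = None,
) -> float:
    """Mean out-of-fold ROC AUC of the subset over repeated stratified CV."""
    svm = svm or SVMConfig()
    _validate_classes(y)
    decisions = _cv_decision_values(X[:, list(subset)], y, cv, svm)
    return float(np.mean([roc_auc_score(y, decisions[:, r]) for r in range(cv.repeats)]))


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    ga: GAConfig,
    cv: CVConfig,
    svm: SVMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, ...], list[float]]:
    """GA search for the subset with maximal cross-validated AUC."""
    svm = svm or SVMConfig()
    return ga_optimize(
        X.shape[1],
        lambda subset: cv_auc_fitness(X, y, subset, cv, svm),
        ga,
        rng,
    )


def train_index_model(
    X: np.ndarray,
    y: np.ndarray,
    subset,
    feature_names=None,
    svm: SVMConfig | None = None,
) -> ClassifierModel:
    """Standardize, fit the SVM and the Platt sigmoid on training data only."""
    svm = svm or SVMConfig()
    _validate_classes(y)
    subset = list(subset)
    Xs = X[:, subset]
    loc, scale = _standardize_fit(Xs)
    clf = SVC(kernel=svm.kernel, C=svm.C, gamma=svm.gamma)
    clf.fit((Xs - loc) / scale, y)
    decision = clf.decision_function((Xs - loc) / scale)
    platt = LogisticRegression(C=1e6)  # plain sigmoid fit A*f+B, no shrinkage
    platt.fit(decision[:, None], y)
    names = (
        [feature_names[i] for i in subset]
        if feature_names is not None
        else [str(i) for i in subset]
    )
    return ClassifierModel(names, loc, scale, clf, platt)


def _roc_from_index(y: np.ndarray, index: np.ndarray) -> ROCResult:
    fpr, tpr, thr = roc_curve(y, index)
    auc = float(roc_auc_score(y, index))
    sens = tpr
    spec = 1.0 - fpr

    def _point(threshold: float) -> dict[str, float]:
        pred = (index >= threshold).astype(int)
        pos, neg = y == CARRIER_LABEL, y != CARRIER_LABEL
        return {
            "threshold": float(threshold),
            "sensitivity": float(pred[pos].mean()),
            "specificity": float(1.0 - pred[neg].mean()),
            "accuracy": float((pred == y).mean()),
        }

    youden_thr = thr[np.argmax(tpr - fpr)]
    densities = {}
    grid = np.linspace(0, 1, 201)
    for name, mask in (("control", y != CARRIER_LABEL), ("carrier", y == CARRIER_LABEL)):
        vals = index[mask]
        if len(vals) > 1 and vals.std() > 0:
            densities[name] = gaussian_kde(vals)(grid)
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        operating_point=_point(0.5),
        youden_point=_point(float(min(youden_thr, 1.0))),
        oof_index=index,
        group_densities=densities,
    )


def evaluate_classifier(
    X: np.ndarray,
    y: np.ndarray,
    ga: GAConfig,
    cv: CVConfig,
    svm: SVMConfig | None = None,
    mode: str = "honest",
    feature_names=None,
) -> ROCResult:
    """Repeated stratified k-fold evaluation of the full pipeline.

    ``mode='honest'`` nests the GA selection inside every training fold;
    ``mode='paper'`` selects once on all data, then cross-validates the
    SVM on the fixed subset.
    """
    svm = svm or SVMConfig()
    _validate_classes(y)
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n = len(y)
    selected: list[str] | None = None
    trace: list[float] | None = None

    if mode == "paper":
        subset, trace = ga_select(X, y, ga, cv, svm)
        selected = (
            [feature_names[i] for i in subset] if feature_names is not None else list(map(str, subset))
        )
        oof = np.empty((n, cv.repeats))
        for rep in range(cv.repeats):
            skf = StratifiedKFold(cv.folds, shuffle=True, random_state=_fold_seed(cv.seed, rep))
            for train, test in skf.split(X, y):
                model = train_index_model(X[train], y[train], subset, svm=svm)
                oof[test, rep] = model.index(X[test][:, list(subset)])
    elif mode == "honest":
        oof = np.empty((n, cv.repeats))
        for rep in range(cv.repeats):
            skf = StratifiedKFold(cv.folds, shuffle=True, random_state=_fold_seed(cv.seed, rep))
            for fold, (train, test) in enumerate(skf.split(X, y)):
                fold_ga = GAConfig(**{**ga.__dict__, "seed": _fold_seed(ga.seed, rep * cv.folds + fold)})
                fold_cv = CVConfig(
                    folds=min(cv.folds, int(np.bincount(y[train]).min())),
                    repeats=1,
                    seed=_fold_seed(cv.seed, rep * cv.folds + fold),
                )
                subset, _ = ga_select(X[train], y[train], fold_ga, fold_cv, svm)
                model = train_index_model(X[train], y[train], subset, svm=svm)
                oof[test, rep] = model.index(X[test][:, list(subset)])
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")

    result = _roc_from_index(y, oof.mean(axis=1))
    result.selected_features = selected
    result.fitness_trace = trace
    return result


def auc_mann_whitney(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney U identity (midranks for ties)."""
    from scipy.stats import rankdata

    y = np.asarray(y)
    pos = scores[y == CARRIER_LABEL]
    neg = scores[y != CARRIER_LABEL]
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))
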