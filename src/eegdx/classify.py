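"""Classifier training and evaluation under stratified k-fold CV.

Four model families — SVM (RBF), LDA, a single-hidden-layer MLP, and random
forest — are evaluated with stratified 10-fold cross-validation. Features
are standardized inside each fold using training statistics only. Metrics:
accuracy, sensitivity, specificity, precision, F-score and AUC; for binary
tasks the positive class is the disease (versus control) or the first-listed
class, for multiclass tasks metrics are macro one-vs-rest averages.

Hyperparameter tuning is a small seeded Bayesian optimizer (Gaussian-process
surrogate with expected improvement) over per-family search boxes; the inner
objective is mean accuracy under an inner stratified CV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

FAMILIES = ("svm", "lda", "ann", "rf")

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    tuning_budget: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if self.tuning_budget < 1:
            raise ConfigurationError("tuning_budget must be >= 1")


#: documented family defaults (tuning_budget=1 returns these)
DEFAULTS = {
    "svm": {"C": 1.0, "gamma": "scale"},
    "lda": {"shrinkage": "auto"},
    "ann": {"width": 32, "alpha": 1e-3},
    "rf": {"n_estimators": 200, "max_depth": None, "max_features": "sqrt"},
}

#: tuning search boxes (log10 scales where noted)
SEARCH_SPACES = {
    "svm": {"log10_C": (-2.0, 3.0), "log10_gamma": (-5.0, 0.0)},
    "lda": {"shrinkage": (0.0, 1.0)},
    "ann": {"log2_width": (3.0, 7.0), "log10_alpha": (-5.0, -1.0)},
    "rf": {"n_estimators": (50.0, 400.0), "max_depth": (2.0, 20.0),
           "max_features": (0.05, 1.0)},
}


def _decode(family: str, point: np.ndarray) -> dict:
    names = list(SEARCH_SPACES[family])
    raw = dict(zip(names, point))
    if family == "svm":
        return {"C": 10.0 ** raw["log10_C"], "gamma": 10.0 ** raw["log10_gamma"]}
    if family == "lda":
        return {"shrinkage": float(raw["shrinkage"])}
    if family == "ann":
        return {"width": int(round(2.0 ** raw["log2_width"])),
                "alpha": 10.0 ** raw["log10_alpha"]}
    return {"n_estimators": int(round(raw["n_estimators"])),
            "max_depth": int(round(raw["max_depth"])),
            "max_features": float(raw["max_features"])}


def make_estimator(spec: ModelSpec) -> Pipeline:
    """Standardizer + classifier pipeline for one family."""
    hp = {**DEFAULTS[spec.family], **spec.hyperparameters}
    fam = spec.family
    if fam == "svm":
        clf = SVC(C=hp["C"], gamma=hp["gamma"], kernel="rbf",
                  random_state=spec.seed)
    elif fam == "lda":
        clf = LinearDiscriminantAnalysis(solver="lsqr",
                                         shrinkage=hp["shrinkage"])
    elif fam == "ann":
        clf = MLPClassifier(hidden_layer_sizes=(int(hp["width"]),),
                            alpha=hp["alpha"], max_iter=800,
                            early_stopping=True, n_iter_no_change=20,
                            random_state=spec.seed)
    else:
        clf = RandomForestClassifier(n_estimators=int(hp["n_estimators"]),
                                     max_depth=hp["max_depth"],
                                     max_features=hp["max_features"],
                                     random_state=spec.seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# folds

def stratified_folds(y, k: int = 10, seed: int = 0) -> list:
    """Stratified fold assignment: list of (train_idx, test_idx) pairs."""
    y = np.asarray(y)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        logger.warning("smallest class has %d members; reducing k from %d",
                       counts.min(), k)
        k = int(counts.min())
        if k < 2:
            raise ConfigurationError("a class has fewer than 2 members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


# ---------------------------------------------------------------------------
# metrics

def _positive_index(classes) -> int:
    """Positive class for binary tasks: the disease when control is present,
    else the first-listed class."""
    classes = list(classes)
    if "control" in classes and len(classes) == 2:
        return 1 - classes.index("control")
    return 0


def _binary_counts(confusion: np.ndarray, pos: int) -> tuple:
    neg = 1 - pos
    tp = confusion[pos, pos]
    tn = confusion[neg, neg]
    fp = confusion[neg, pos]
    fn = confusion[pos, neg]
    return tp, tn, fp, fn


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0",
                      stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(confusion, classes, y_true=None, scores=None) -> dict:
    """Metric suite from a class x class confusion matrix.

    *confusion* rows are true classes, columns predicted, ordered as
    *classes*. AUC needs per-sample *scores* (and *y_true*); without them it
    is omitted with a warning. Multiclass metrics are macro one-vs-rest.
    """
    confusion = np.asarray(confusion, float)
    n_cls = len(classes)
    if confusion.shape != (n_cls, n_cls) or confusion.sum() == 0:
        raise ConfigurationError("confusion matrix empty or mis-shaped")
    if np.any(confusion < 0):
        raise ConfigurationError("confusion matrix must be nonnegative")
    total = confusion.sum()
    out = {"accuracy": float(np.trace(confusion) / total)}
    if n_cls == 2:
        pos = _positive_index(classes)
        tp, tn, fp, fn = _binary_counts(confusion, pos)
        out["sensitivity"] = _safe_div(tp, tp + fn, "sensitivity")
        out["specificity"] = _safe_div(tn, tn + fp, "specificity")
        out["precision"] = _safe_div(tp, tp + fp, "precision")
    else:
        sens, spec, prec = [], [], []
        for i in range(n_cls):
            tp = confusion[i, i]
            fn = confusion[i].sum() - tp
            fp = confusion[:, i].sum() - tp
            tn = total - tp - fn - fp
            sens.append(_safe_div(tp, tp + fn, f"sensitivity[{classes[i]}]"))
            spec.append(_safe_div(tn, tn + fp, f"specificity[{classes[i]}]"))
            prec.append(_safe_div(tp, tp + fp, f"precision[{classes[i]}]"))
        out["sensitivity"] = float(np.mean(sens))
        out["specificity"] = float(np.mean(spec))
        out["precision"] = float(np.mean(prec))
    out["f1"] = _safe_div(2 * out["precision"] * out["sensitivity"],
                          out["precision"] + out["sensitivity"], "f1")
    if scores is not None and y_true is not None:
        y_true = np.asarray(y_true)
        if len(np.unique(y_true)) < 2:
            warnings.warn("single-class fold; AUC omitted", stacklevel=2)
        elif n_cls == 2:
            pos = _positive_index(classes)
            s = scores[:, pos] if np.ndim(scores) == 2 else np.asarray(scores)
            out["auc"] = float(roc_auc_score(
                (y_true == classes[pos]).astype(int), s))
        else:
            out["auc"] = float(roc_auc_score(y_true, scores,
                                             multi_class="ovr",
                                             average="macro",
                                             labels=list(classes)))
    else:
        warnings.warn("scores unavailable; AUC omitted", stacklevel=2)
    return out


def _scores_of(model: Pipeline, X: np.ndarray, classes) -> np.ndarray:
    """Per-class score table: probabilities, or softmax-free decision values."""
    clf = model
    if hasattr(clf, "predict_proba"):
        try:
            return clf.predict_proba(X)
        except AttributeError:
            pass
    dv = clf.decision_function(X)
    if dv.ndim == 1:                        # binary decision values
        dv = np.column_stack([-dv, dv])
    # rank-preserving map onto the simplex so the OVR AUC is well defined
    e = np.exp(dv - dv.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# cross-validated evaluation

@dataclass
class CVResult:
    model: ModelSpec
    classes: list
    per_fold: pd.DataFrame                 # fold x metric
    mean_sd: pd.DataFrame                  # metric -> (mean, sd)
    confusion: np.ndarray                  # aggregated over folds

    def to_csv(self, path) -> None:
        self.per_fold.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {m: {"mean": float(self.mean_sd.loc[m, "mean"]),
                    "sd": float(self.mean_sd.loc[m, "sd"])}
                for m in self.mean_sd.index}


def evaluate_cv(X, y, model: ModelSpec, folds=None, k: int = 10) -> CVResult:
    """Fit and score *model* across stratified folds."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if folds is None:
        folds = stratified_folds(y, k=k, seed=model.seed)
    classes = sorted(np.unique(y))
    n_cls = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    agg = np.zeros((n_cls, n_cls))
    rows = []
    for fold_i, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < n_cls:
            raise ConfigurationError(
                f"fold {fold_i}: training split misses a class")
        est = make_estimator(model)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        conf = np.zeros((n_cls, n_cls))
        for truth, hat in zip(y[te], pred):
            conf[cls_index[truth], cls_index[hat]] += 1
        scores = _scores_of(est, X[te], classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = compute_metrics(conf, classes, y_true=y[te],
                                      scores=scores)
        metrics.setdefault("auc", np.nan)
        rows.append({"fold": fold_i, **metrics})
        agg += conf
    per_fold = pd.DataFrame(rows)
    mean_sd = pd.DataFrame({
        "mean": per_fold[list(METRICS)].mean(),
        "sd": per_fold[list(METRICS)].std(ddof=1),
    })
    return CVResult(model=model, classes=classes, per_fold=per_fold,
                    mean_sd=mean_sd, confusion=agg)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter tuning

def _objective(family: str, hp: dict, X, y, seed: int) -> float:
    spec = ModelSpec(family=family, hyperparameters=hp, seed=seed)
    _, counts = np.unique(y, return_counts=True)
    k = max(2, min(3, counts.min()))
    folds = stratified_folds(y, k=k, seed=seed)
    accs = []
    for tr, te in folds:
        est = make_estimator(spec)
        est.fit(X[tr], y[tr])
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def tune(model: ModelSpec, X_train, y_train) -> dict:
    """Bayesian search (GP surrogate + expected improvement) for one family.

    Returns the best hyperparameters found within ``model.tuning_budget``
    objective evaluations; a budget of 1 returns the family defaults.
    """
    if model.tuning_budget <= 1:
        return dict(DEFAULTS[model.family])
    X = np.asarray(X_train, float)
    y = np.asarray(y_train)
    space = SEARCH_SPACES[model.family]
    lo = np.array([b[0] for b in space.values()])
    hi = np.array([b[1] for b in space.values()])
    rng = np.random.default_rng(model.seed)
    n_init = min(max(3, model.tuning_budget // 3), model.tuning_budget)
    pts, vals = [], []

    def evaluate(point):
        hp = _decode(model.family, lo + point * (hi - lo))
        val = _objective(model.family, hp, X, y, model.seed)
        pts.append(point)
        vals.append(val)

    for _ in range(n_init):
        evaluate(rng.uniform(size=lo.size))
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5),
                                  normalize_y=True, alpha=1e-4,
                                  random_state=model.seed)
    while len(vals) < model.tuning_budget:
        gp.fit(np.array(pts), -np.array(vals))       # GP minimizes
        cand = rng.uniform(size=(256, lo.size))
        mu, sd = gp.predict(cand, return_std=True)
        best = -max(vals)
        sd = np.maximum(sd, 1e-9)
        z = (best - mu) / sd
        ei = (best - mu) * spstats.norm.cdf(z) + sd * spstats.norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])
    best_point = pts[int(np.argmax(vals))]
    return _decode(model.family, lo + best_point * (hi - lo))
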