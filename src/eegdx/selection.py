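"""L1-regularized (Lasso) feature selection with a cross-validated lambda grid.

The selector fits an l1-penalized logistic objective c(beta, X) + lambda *
sum|beta_i| and keeps the features with nonzero coefficients. The shrinkage
weight lambda is chosen from a logarithmic grid spanning 0.001-0.05 by
10-fold cross-validated classification loss (ties resolve to the smaller
lambda). For more than two classes the default is one-vs-rest fits whose
supports are unioned; a multinomial l1 model is available by configuration.

sklearn's LogisticRegression stands behind the fit; its per-sample objective
maps lambda to C = 1 / (n * lambda).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError
from .features import FeatureMatrix
from .montage import CHANNELS_1020

#: coefficients below this magnitude count as zero (saga leaves dust)
_COEF_TOL = 1e-6


def default_lambda_grid() -> np.ndarray:
    """25 logarithmically spaced shrinkage values in [0.001, 0.05]."""
    return np.logspace(np.log10(0.001), np.log10(0.05), 25)


@dataclass(frozen=True)
class SelectionConfig:
    lambda_grid: tuple = tuple(default_lambda_grid())
    cv_folds: int = 10
    standardize: bool = True
    multiclass_mode: str = "one_vs_rest_union"
    seed: int = 0
    max_iter: int = 2000

    def validate(self) -> None:
        grid = np.asarray(self.lambda_grid, float)
        if grid.size == 0 or grid.min() <= 0:
            raise ConfigurationError("lambda_grid must be positive")
        if not np.all(np.diff(grid) > 0):
            raise ConfigurationError("lambda_grid must be increasing")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.multiclass_mode not in ("one_vs_rest_union", "multinomial"):
            raise ConfigurationError(
                f"unknown multiclass_mode {self.multiclass_mode!r}")


@dataclass
class SelectionResult:
    lambda_star: float
    beta: np.ndarray                      # (n_classes_or_1, n_features)
    selected: np.ndarray                  # sorted indices of surviving features
    feature_names: list
    per_channel_counts: dict
    cv_loss_curve: dict | None = None     # lambda -> mean CV loss

    @property
    def selected_names(self) -> list:
        return [self.feature_names[i] for i in self.selected]

    def to_json(self, path) -> None:
        payload = {
            "lambda_star": self.lambda_star,
            "selected_indices": [int(i) for i in self.selected],
            "selected_names": self.selected_names,
            "per_channel_counts": self.per_channel_counts,
            "cv_loss_curve": ({str(k): v for k, v in
                               self.cv_loss_curve.items()}
                              if self.cv_loss_curve else None),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        coef = np.abs(self.beta).max(axis=0)
        pd.DataFrame({"feature": self.feature_names,
                      "coefficient": coef}).to_csv(path, index=False)


def _as_xy(X, y=None):
    if isinstance(X, FeatureMatrix):
        names = list(X.feature_names)
        mat = X.to_dataframe()[names].to_numpy(float)
        labels = np.asarray(X.labels if y is None else y)
    elif isinstance(X, pd.DataFrame):
        names = [c for c in X.columns if c not in ("subject_id", "group")]
        mat = X[names].to_numpy(float)
        labels = np.asarray(X["group"] if y is None and "group" in X else y)
    else:
        mat = np.asarray(X, float)
        names = [f"f{i}" for i in range(mat.shape[1])]
        labels = np.asarray(y)
    if labels is None or labels.ndim != 1 or len(labels) != mat.shape[0]:
        raise ConfigurationError("labels missing or wrong length")
    bad = np.where(~np.isfinite(mat))
    if bad[0].size:
        raise ConfigurationError(
            f"non-finite value in feature column {names[int(bad[1][0])]!r}")
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("need at least two classes")
    return mat, labels, names


def _fit_l1(mat: np.ndarray, labels: np.ndarray, lam: float,
            cfg: SelectionConfig) -> np.ndarray:
    """Coefficient matrix of the l1 logistic fit at shrinkage *lam*."""
    n = mat.shape[0]
    C = 1.0 / (n * lam)
    classes = np.unique(labels)
    if len(classes) == 2 or cfg.multiclass_mode == "one_vs_rest_union":
        rows = []
        targets = [classes[1]] if len(classes) == 2 else classes
        for cls in targets:
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=cfg.max_iter, tol=1e-8,
                                     random_state=cfg.seed)
            clf.fit(mat, (labels == cls).astype(int))
            rows.append(clf.coef_[0])
        return np.vstack(rows)
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="saga",
                             max_iter=cfg.max_iter, tol=1e-6,
                             random_state=cfg.seed)
    clf.fit(mat, labels)
    return clf.coef_


def select_features(X, y=None, lam: float = 0.001,
                    cfg: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Select the features surviving l1 shrinkage at weight *lam*."""
    cfg.validate()
    if lam <= 0:
        raise ConfigurationError("lambda must be positive")
    mat, labels, names = _as_xy(X, y)
    if cfg.standardize:
        mat = StandardScaler().fit_transform(mat)
    beta = _fit_l1(mat, labels, lam, cfg)
    selected = np.where(np.abs(beta).max(axis=0) > _COEF_TOL)[0]
    if all(n.split("__")[0] in CHANNELS_1020 for n in names):
        counts = channel_counts([names[i] for i in selected])
    else:                       # anonymous columns: no channel bookkeeping
        counts = {}
    return SelectionResult(lambda_star=float(lam), beta=beta,
                           selected=selected, feature_names=names,
                           per_channel_counts=counts)


def choose_lambda(X, y=None,
                  cfg: SelectionConfig = SelectionConfig()) -> tuple:
    """Cross-validated choice of lambda: (lambda_star, {lambda: mean loss}).

    The loss is the mean held-out misclassification rate of the l1 logistic
    model refit at each grid value; ties resolve to the smaller lambda.
    """
    cfg.validate()
    mat, labels, _ = _as_xy(X, y)
    _, counts = np.unique(labels, return_counts=True)
    k = min(cfg.cv_folds, counts.min())
    if k < 2:
        raise ConfigurationError("smallest class too small for CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(mat, labels))
    curve: dict[float, float] = {}
    for lam in cfg.lambda_grid:
        losses = []
        for tr, te in folds:
            Xtr, Xte = mat[tr], mat[te]
            if cfg.standardize:
                scaler = StandardScaler().fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            C = 1.0 / (len(tr) * lam)
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=cfg.max_iter, tol=1e-8,
                                     random_state=cfg.seed)
            clf.fit(Xtr, labels[tr])
            losses.append(float(np.mean(clf.predict(Xte) != labels[te])))
        curve[float(lam)] = float(np.mean(losses))
    lams = list(curve)
    lambda_star = lams[int(np.argmin([curve[l] for l in lams]))]
    return lambda_star, curve


def channel_counts(selected_names, channels=CHANNELS_1020) -> dict:
    """Per-channel tally of selected features; absent channels count 0."""
    counts = {ch: 0 for ch in channels}
    for name in selected_names:
        ch = name.split("__")[0]
        if ch not in counts:
            raise ConfigurationError(
                f"malformed feature name {name!r}: unknown channel {ch!r}")
        counts[ch] += 1
    return counts
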