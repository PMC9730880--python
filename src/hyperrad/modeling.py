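"""HPL prediction models: nested cross-validation with embedded selection.

The learner is a two-stage pipeline: a gradient-boosted tree ensemble is fit
on standardized features and its most important features (total gain) — at
most six per imaging modality — are passed to an L2 logistic regression.
Hyperparameters (boosting shape, feature budget, regularization) are tuned
by random search inside a repeated stratified inner cross-validation; the
outer loop is a stratified group 5-fold split that keeps all lesions of a
patient in one fold.  Redundant features (Kendall tau > 0.90) are pruned on
the training folds only, so no statistic of the held-out lesions reaches
training.  Performance is the ROC AUC per outer fold, reported as mean +/-
SD with a vertically averaged ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from ._rng import derive_seed, substream
from .feature_reduction import kendall_matrix, prune_correlated

__all__ = [
    "CVResult",
    "FittedModel",
    "make_outer_folds",
    "sample_hyperparameters",
    "tune_inner",
    "fit_select_then_logreg",
    "nested_cv_evaluate",
    "modality_columns",
]

MAX_FEATURES_PER_MODALITY = 6
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class FittedModel:
    """Scaler -> boosted-tree selector -> logistic regression."""

    scaler: StandardScaler
    feature_names: list[str]       # columns seen by the scaler
    selected: list[str]            # features retained for the logistic model
    logreg: LogisticRegression
    coefficients: dict[str, float]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Z = pd.DataFrame(self.scaler.transform(X[self.feature_names]),
                         columns=self.feature_names, index=X.index)
        return self.logreg.predict_proba(Z[self.selected])[:, 1]


@dataclass
class CVResult:
    modality: str
    outer_fold_aucs: list[float]
    train_aucs: list[float]
    selected_features: list[list[str]]
    coefficients: list[dict[str, float]]
    hyperparameters: list[dict]
    fpr_grid: np.ndarray = field(default_factory=lambda: FPR_GRID.copy())
    mean_tpr: np.ndarray | None = None

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.outer_fold_aucs))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.outer_fold_aucs))

    @property
    def train_auc_mean(self) -> float:
        return float(np.mean(self.train_aucs))

    @property
    def train_auc_sd(self) -> float:
        return float(np.std(self.train_aucs))

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "outer_fold_aucs": [float(a) for a in self.outer_fold_aucs],
            "auc_mean": self.auc_mean, "auc_sd": self.auc_sd,
            "train_auc_mean": self.train_auc_mean,
            "train_auc_sd": self.train_auc_sd,
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "hyperparameters": self.hyperparameters,
            "roc_fpr": self.fpr_grid.tolist(),
            "roc_mean_tpr": (self.mean_tpr.tolist()
                             if self.mean_tpr is not None else None),
        }


def modality_columns(columns, modality: str) -> list[str]:
    """Feature columns belonging to a modality selection (CT, PET, PETCT)."""
    modality = modality.upper()
    prefixes = {"CT": ("ct_",), "PET": ("pet_",), "PETCT": ("ct_", "pet_")}
    if modality not in prefixes:
        raise ValueError(f"unknown modality {modality!r}")
    return [c for c in columns if c.startswith(prefixes[modality])]


def make_outer_folds(groups, labels, k: int = 5, seed: int = 0
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified group k-fold assignments (train_idx, test_idx) per fold."""
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    if len(np.unique(groups)) < k:
        raise ValueError(f"need >= {k} distinct groups, "
                         f"got {len(np.unique(groups))}")
    cv = StratifiedGroupKFold(n_splits=k, shuffle=True,
                              random_state=derive_seed(seed, "outer-folds"))
    return list(cv.split(np.zeros(len(labels)), labels, groups))


def sample_hyperparameters(rng: np.random.Generator,
                           max_features: int = MAX_FEATURES_PER_MODALITY) -> dict:
    """One draw from the declared random-search space."""
    return {
        "n_estimators": int(rng.choice([25, 50, 100])),
        "max_depth": int(rng.integers(1, 5)),
        "learning_rate": float(np.exp(rng.uniform(np.log(0.03), np.log(0.3)))),
        "subsample": float(rng.uniform(0.6, 1.0)),
        "n_features_per_modality": int(rng.integers(1, max_features + 1)),
        "logreg_C": float(np.exp(rng.uniform(np.log(0.01), np.log(100.0)))),
    }


def _univariate_aucs(Z: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    return np.array([abs(roc_auc_score(y, Z[c]) - 0.5) for c in Z.columns])


def fit_select_then_logreg(X: pd.DataFrame, y, hyperparams: dict,
                           seed: int = 0) -> FittedModel:
    """Fit the selector-then-logistic pipeline on a training subset.

    Features are standardized; a gradient-boosted tree model ranks them by
    total-gain importance; the top ``n_features_per_modality`` per modality
    prefix are kept (ties broken by column order) and fed to an L2 logistic
    regression.  If every importance is zero the ranking falls back to
    univariate AUC with a warning.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset must contain both classes")
    scaler = StandardScaler().fit(X)
    Z = pd.DataFrame(scaler.transform(X), columns=X.columns, index=X.index)
    booster = XGBClassifier(
        n_estimators=hyperparams["n_estimators"],
        max_depth=hyperparams["max_depth"],
        learning_rate=hyperparams["learning_rate"],
        subsample=hyperparams["subsample"],
        importance_type="total_gain",
        tree_method="hist", n_jobs=1, random_state=derive_seed(seed, "xgb"),
        eval_metric="logloss",
    )
    booster.fit(Z, y)
    importance = np.asarray(booster.feature_importances_, dtype=float)
    if not np.any(importance > 0):
        warnings.warn("all boosting importances are zero; "
                      "falling back to univariate AUC ranking")
        importance = _univariate_aucs(Z, y)

    m = int(hyperparams.get("n_features_per_modality",
                            MAX_FEATURES_PER_MODALITY))
    m = min(m, MAX_FEATURES_PER_MODALITY)
    selected: list[str] = []
    for prefix in ("ct_", "pet_"):
        idx = [i for i, c in enumerate(X.columns) if c.startswith(prefix)]
        if not idx:
            continue
        # stable sort: equal importances keep column order
        order = sorted(idx, key=lambda i: (-importance[i], i))
        selected.extend(X.columns[i] for i in order[:m])
    selected = [c for c in X.columns if c in set(selected)]

    logreg = LogisticRegression(C=hyperparams.get("logreg_C", 1.0),
                                max_iter=2000)
    logreg.fit(Z[selected], y)
    coefs = dict(zip(selected, logreg.coef_[0].astype(float)))
    return FittedModel(scaler, list(X.columns), selected, logreg, coefs)


def tune_inner(X: pd.DataFrame, y, n_iter: int = 100, repeats: int = 10,
               k: int = 5, seed: int = 0) -> dict:
    """Random-search hyperparameter tuning on the training subset.

    Each candidate is scored by mean AUC over a ``repeats``-times repeated
    stratified ``k``-fold cross-validation of the full pipeline; ties keep
    the first candidate encountered.  Single-class inner folds are skipped
    with a warning.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset must contain both classes")
    rng = substream(seed, "search")
    k_eff = min(k, int(np.bincount(y).min()))
    if k_eff < k:
        warnings.warn(f"minority class smaller than k={k}; using {k_eff} folds")
    cv = RepeatedStratifiedKFold(n_splits=max(k_eff, 2), n_repeats=repeats,
                                 random_state=derive_seed(seed, "inner-folds"))
    splits = list(cv.split(X, y))
    best_score, best_params = -np.inf, None
    for _ in range(n_iter):
        params = sample_hyperparameters(rng)
        scores = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                warnings.warn("single-class inner fold skipped")
                continue
            model = fit_select_then_logreg(X.iloc[tr], y[tr], params, seed)
            scores.append(roc_auc_score(y[te],
                                        model.predict_proba(X.iloc[te])))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_params = score, params
    if best_params is None:
        raise RuntimeError("no valid inner folds")
    return best_params


def nested_cv_evaluate(table: pd.DataFrame, modality: str = "PETCT",
                       seed: int = 0, k_outer: int = 5,
                       n_iter: int = 100, repeats: int = 10, k_inner: int = 5,
                       tau_threshold: float = 0.90) -> CVResult:
    """Nested cross-validated AUC of the HPL model for one modality.

    ``table`` holds modality-prefixed feature columns plus ``label`` and
    ``patient_id``.  Per outer fold: prune redundant features on training
    data, tune by random search, refit, score the held-out lesions.
    """
    cols = modality_columns(table.columns, modality)
    if not cols:
        raise ValueError(f"no feature columns for modality {modality!r}")
    X_all = table[cols]
    y = table["label"].to_numpy().astype(int)
    groups = table["patient_id"].to_numpy()

    fold_aucs, train_aucs, sel_feats, coefs, hps = [], [], [], [], []
    tprs = []
    for fi, (tr, te) in enumerate(make_outer_folds(groups, y, k_outer, seed)):
        fold_seed = derive_seed(seed, f"fold{fi}")
        kept = prune_correlated(kendall_matrix(X_all.iloc[tr]),
                                threshold=tau_threshold, seed=fold_seed)
        Xtr, Xte = X_all.iloc[tr][kept], X_all.iloc[te][kept]
        params = tune_inner(Xtr, y[tr], n_iter=n_iter, repeats=repeats,
                            k=k_inner, seed=fold_seed)
        model = fit_select_then_logreg(Xtr, y[tr], params, fold_seed)
        train_aucs.append(roc_auc_score(y[tr], model.predict_proba(Xtr)))
        sel_feats.append(model.selected)
        coefs.append(model.coefficients)
        hps.append(params)
        if len(np.unique(y[te])) < 2:
            warnings.warn(f"outer fold {fi}: single-class test set, "
                          "AUC undefined; fold excluded")
            continue
        p = model.predict_proba(Xte)
        fold_aucs.append(roc_auc_score(y[te], p))
        fpr, tpr, _ = roc_curve(y[te], p)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))

    mean_tpr = np.mean(tprs, axis=0) if tprs else None
    if mean_tpr is not None:
        mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return CVResult(modality.upper(), fold_aucs, train_aucs, sel_feats,
                    coefs, hps, FPR_GRID.copy(), mean_tpr)
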