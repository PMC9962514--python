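"""Gradient-boosted PAP regression and cutoff classification with repeated
stratified cross-validation.

Models are depth-3 boosted trees (squared-error or logistic objective);
severity labels come from the clinical cutoffs (mPAP 40 mmHg, sPAP 55 mmHg,
a value at the cutoff counts as severe).  Repeated k-fold CV stratifies
classification folds by class and regression folds by target-quartile bins;
any feature selection is re-fit inside each training fold so held-out data
never leaks into the selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBClassifier, XGBRegressor

from .agreestats import icc_consistency, roc_auc, sensitivity_specificity

#: Clinical severity cutoffs (mmHg).
CUTOFFS = {"mPAP": 40.0, "sPAP": 55.0}

#: Boosting hyperparameters; only the tree depth is externally fixed, the
#: rest are package defaults recorded in every report.
DEFAULT_PARAMS = {
    "max_depth": 3,
    "n_estimators": 200,
    "learning_rate": 0.1,
    "subsample": 1.0,
}


def label_by_cutoff(values, cutoff: float | None = None,
                    which: str = "mPAP") -> tuple[np.ndarray, np.ndarray]:
    """Binary severity labels (1 = severe, value >= cutoff).

    Returns (labels, keep_mask): cases with a missing pressure are excluded
    with a warning and flagged False in ``keep_mask``.
    """
    if cutoff is None:
        cutoff = CUTOFFS[which]
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} case(s) excluded: missing {which}",
                      stacklevel=2)
    return (values[keep] >= cutoff).astype(int), keep


def _check_X_y(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in inputs")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    return X, y


def train_regressor(X, y, params: dict | None = None, seed: int = 0):
    """Depth-3 boosted-tree regressor (squared error), deterministic per seed."""
    X, y = _check_X_y(X, y)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows")
    kw = dict(DEFAULT_PARAMS, **(params or {}))
    model = XGBRegressor(objective="reg:squarederror", random_state=seed,
                         n_jobs=1, **kw)
    model.fit(X, y)
    return model


def train_classifier(X, labels, params: dict | None = None, seed: int = 0):
    """Depth-3 boosted-tree classifier (logistic objective) with
    probability scores via ``predict_proba``."""
    X, labels = _check_X_y(X, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    kw = dict(DEFAULT_PARAMS, **(params or {}))
    model = XGBClassifier(objective="binary:logistic", random_state=seed,
                          n_jobs=1, eval_metric="logloss", **kw)
    model.fit(X, labels.astype(int))
    return model


@dataclass
class CVReport:
    """Out-of-fold predictions of a repeated cross-validation run."""

    task: str
    folds: int
    repeats: int
    seed: int
    params: dict
    y: np.ndarray
    predictions: np.ndarray   # (repeats, n) out-of-fold predictions/scores
    fold_ids: np.ndarray      # (repeats, n) test-fold index per case
    redeal_log: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def mean_prediction(self) -> np.ndarray:
        return self.predictions.mean(axis=0)

    def to_json(self) -> str:
        return json.dumps({
            "task": self.task, "folds": self.folds, "repeats": self.repeats,
            "seed": self.seed, "params": self.params,
            "y": self.y.tolist(),
            "predictions": self.predictions.tolist(),
            "fold_ids": self.fold_ids.tolist(),
            "redeal_log": self.redeal_log,
            "metrics": self.metrics,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CVReport":
        d = json.loads(text)
        return cls(task=d["task"], folds=d["folds"], repeats=d["repeats"],
                   seed=d["seed"], params=d["params"],
                   y=np.asarray(d["y"], dtype=float),
                   predictions=np.asarray(d["predictions"], dtype=float),
                   fold_ids=np.asarray(d["fold_ids"], dtype=int),
                   redeal_log=d.get("redeal_log", []),
                   metrics=d.get("metrics", {}))


def _quartile_bins(y: np.ndarray) -> np.ndarray:
    edges = np.quantile(y, [0.25, 0.5, 0.75])
    return np.searchsorted(edges, y, side="left")


def _deal_folds(y: np.ndarray, task: str, folds: int, rs: int,
                redeal_log: list) -> np.ndarray:
    """Fold index per case; stratified by class (classification) or by
    target-quartile bin (regression); folds == n degenerates to LOO."""
    n = y.shape[0]
    fold_of = np.empty(n, dtype=int)
    if folds == n:
        fold_of[:] = np.arange(n)
        return fold_of
    if task == "classification":
        strata = y.astype(int)
    else:
        strata = _quartile_bins(y)
    for attempt in range(10):
        seed = rs + 1000 * attempt
        counts = np.bincount(strata)
        if counts[counts > 0].min() >= folds:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                       random_state=seed)
            split_arg = strata
        else:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
            split_arg = None
        for f, (_, test) in enumerate(splitter.split(np.zeros((n, 1)),
                                                     split_arg)):
            fold_of[test] = f
        if task != "classification":
            return fold_of
        ok = all(len(np.unique(y[fold_of != f].astype(int))) == 2
                 for f in range(folds))
        if ok:
            return fold_of
        redeal_log.append(f"re-deal: seed {seed} left a single-class "
                          f"training fold")
    raise ValueError("could not deal folds with both classes in every "
                     "training split")


def repeated_cv(X, y, task: str = "regression", folds: int = 10,
                repeats: int = 20, seed: int = 0,
                params: dict | None = None,
                selector_factory=None, feature_frame: pd.DataFrame | None = None,
                target: str | None = None) -> CVReport:
    """Repeated stratified k-fold cross-validation.

    Repeat r uses seed ``seed + r`` for both fold dealing and model fitting.
    When ``selector_factory`` is given (a zero-argument callable returning a
    fresh :class:`~papkit.featsel.SelectionPipeline`), ``feature_frame`` must
    hold the raw named features plus the ``target`` column; the selector is
    fit on each training fold only and applied to the held-out fold.
    Otherwise ``X`` is used as the model input directly.
    """
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < folds:
        raise ValueError(f"need n >= folds, got n={n}, folds={folds}")
    use_selector = selector_factory is not None
    if use_selector:
        if feature_frame is None or target is None:
            raise ValueError("selector_factory requires feature_frame and target")
        frame = feature_frame.reset_index(drop=True)
    else:
        X = np.asarray(X, dtype=float)

    kw = dict(DEFAULT_PARAMS, **(params or {}))
    predictions = np.empty((repeats, n))
    fold_ids = np.empty((repeats, n), dtype=int)
    redeal_log: list = []
    for r in range(repeats):
        rs = seed + r
        fold_of = _deal_folds(y, task, folds, rs, redeal_log)
        fold_ids[r] = fold_of
        for f in np.unique(fold_of):
            test = fold_of == f
            train = ~test
            if use_selector:
                sel = selector_factory()
                sel.fit(frame.loc[train])
                Xtr = sel.transform(frame.loc[train])
                Xte = sel.transform(frame.loc[test])
            else:
                Xtr, Xte = X[train], X[test]
            if task == "regression":
                model = XGBRegressor(objective="reg:squarederror",
                                     random_state=rs, n_jobs=1, **kw)
                model.fit(Xtr, y[train])
                predictions[r, test] = model.predict(Xte)
            else:
                model = XGBClassifier(objective="binary:logistic",
                                      random_state=rs, n_jobs=1,
                                      eval_metric="logloss", **kw)
                model.fit(Xtr, y[train].astype(int))
                predictions[r, test] = model.predict_proba(Xte)[:, 1]
    report = CVReport(task=task, folds=folds, repeats=repeats, seed=seed,
                      params=kw, y=y.copy(), predictions=predictions,
                      fold_ids=fold_ids, redeal_log=redeal_log)
    report.metrics = evaluate(report, y)
    return report


def evaluate(report: CVReport, truth) -> dict:
    """Aggregate metrics recomputed from the stored predictions.

    Regression: MSE over every out-of-fold prediction and the two-way mixed
    consistency ICC between truth and the per-case mean prediction.
    Classification: AUC (with p), sensitivity and specificity at score 0.5
    on the per-case mean score.
    """
    truth = np.asarray(truth, dtype=float)
    if truth.shape[0] != report.y.shape[0]:
        raise ValueError("truth length mismatch")
    mean_pred = report.mean_prediction()
    out: dict = {}
    if report.task == "regression":
        out["mse"] = float(((report.predictions - truth[None, :]) ** 2).mean())
        icc = icc_consistency(np.column_stack([truth, mean_pred]))
        out["icc"] = icc.icc_single
        out["icc_average"] = icc.icc_average
        out["icc_p"] = icc.icc_p
    else:
        auc, p = roc_auc(mean_pred, truth.astype(int))
        out["auc"], out["auc_p"] = auc, p
        sens, spec = sensitivity_specificity((mean_pred >= 0.5).astype(int),
                                             truth.astype(int))
        out["sensitivity"], out["specificity"] = sens, spec
        out["mse"] = float(((report.predictions - truth[None, :]) ** 2).mean())
    return out
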