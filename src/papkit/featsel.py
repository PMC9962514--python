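"""Feature screening, collinearity pruning, standardization and PCA.

The chain: (1) keep features whose Spearman correlation with the target is
significant (two-sided p < alpha); (2) examine feature pairs in descending
absolute pairwise Pearson correlation and, whenever |r| > 0.9 with both
features still kept, drop the one with the lower |Pearson r| to the target;
(3) scale to mean 0, variance 1 (population convention); (4) PCA keeping the
smallest number of components whose cumulative explained variance reaches
the threshold.  Screening uses pairwise-complete rows, PCA listwise-complete
rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreestats import pearson_r, spearman_r


@dataclass
class SelectionReport:
    """Full provenance of a selection run."""

    target: str = ""
    alpha: float = 0.05
    r_thresh: float = 0.9
    var_frac: float = 0.95
    # per-feature screen results: name -> {"r":, "p":, "status":, "reason":}
    screen: dict = field(default_factory=dict)
    kept: list = field(default_factory=list)
    scaler_mean: dict = field(default_factory=dict)
    scaler_sd: dict = field(default_factory=dict)
    loadings: list = field(default_factory=list)       # (n_kept, m) nested lists
    explained_frac: list = field(default_factory=list)
    m: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SelectionReport":
        return cls(**json.loads(text))


def _screen_order(report_screen: dict) -> list:
    """Feature names sorted by |r| descending (report presentation order)."""
    return sorted(report_screen,
                  key=lambda f: (-abs(report_screen[f].get("r") or 0.0), f))


def spearman_screen(df: pd.DataFrame, target: str, features=None,
                    alpha: float = 0.05) -> SelectionReport:
    """Spearman screen of every feature against the target.

    Returns a partial :class:`SelectionReport` with per-feature r, p and
    kept/dropped status; features with fewer than 3 complete pairs are
    flagged unevaluable.  The report's ``screen`` dict is ordered by |r|
    descending.
    """
    if target not in df.columns:
        raise KeyError(f"target column {target!r} not in table")
    if features is None:
        features = [c for c in df.columns
                    if c not in (target, "patient_id")
                    and pd.api.types.is_numeric_dtype(df[c])]
    rep = SelectionReport(target=target, alpha=alpha)
    for f in features:
        entry: dict = {"r": None, "p": None, "status": "dropped",
                       "reason": "insignificant"}
        pair = df[[f, target]].dropna()
        if len(pair) < 3:
            entry["reason"] = "unevaluable"
        else:
            try:
                r, p = spearman_r(pair[f].to_numpy(), pair[target].to_numpy())
            except ValueError:
                entry["reason"] = "unevaluable"
            else:
                entry["r"], entry["p"] = r, p
                if p < alpha:
                    entry["status"], entry["reason"] = "kept", ""
        rep.screen[f] = entry
    rep.screen = {f: rep.screen[f] for f in _screen_order(rep.screen)}
    rep.kept = [f for f, e in rep.screen.items() if e["status"] == "kept"]
    return rep


def pearson_prune(df: pd.DataFrame, target: str, features,
                  r_thresh: float = 0.9,
                  report: SelectionReport | None = None) -> list:
    """Greedy collinearity prune.

    Pairs are visited in descending |pairwise Pearson r| (ties broken by
    feature-name pair, lexicographically); when |r| > ``r_thresh`` and both
    members are still kept, the one with the lower |Pearson r to target| is
    dropped (name-lexicographic tie-break: the later name is dropped).  The
    surviving set has all pairwise |r| <= ``r_thresh``.
    """
    features = list(features)
    if len(features) < 2:
        return features

    def target_r(f):
        pair = df[[f, target]].dropna()
        if len(pair) < 3 or pair[f].nunique() < 2 or pair[target].nunique() < 2:
            return 0.0
        return abs(pearson_r(pair[f].to_numpy(), pair[target].to_numpy())[0])

    tr = {f: target_r(f) for f in features}
    pairs = []
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            sub = df[[a, b]].dropna()
            if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                continue
            r, _ = pearson_r(sub[a].to_numpy(), sub[b].to_numpy())
            pairs.append((abs(r), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    kept = set(features)
    for absr, a, b in pairs:
        if absr <= r_thresh or a not in kept or b not in kept:
            continue
        if tr[a] < tr[b]:
            victim = a
        elif tr[b] < tr[a]:
            victim = b
        else:
            victim = max(a, b)  # lexicographic tie-break: drop the later name
        kept.discard(victim)
        if report is not None and victim in report.screen:
            other = b if victim == a else a
            report.screen[victim]["status"] = "dropped"
            report.screen[victim]["reason"] = f"collinear-with:{other}"
    out = [f for f in features if f in kept]
    if report is not None:
        report.r_thresh = r_thresh
        report.kept = out
    return out


class Standardizer:
    """Column-wise scaling to mean 0, variance 1 (population divisor n)."""

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, df: pd.DataFrame) -> "Standardizer":
        if len(df) < 2:
            raise ValueError("need at least 2 rows to standardize")
        self.mean_ = df.mean()
        self.sd_ = df.std(ddof=0)
        zero = self.sd_[self.sd_ == 0]
        if len(zero):
            raise ValueError(
                f"zero-variance column(s): {list(zero.index)}")
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.mean_.index] - self.mean_) / self.sd_

    def inverse_transform(self, scaled: pd.DataFrame) -> pd.DataFrame:
        return scaled * self.sd_ + self.mean_


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Scale every column to mean 0 / variance 1; returns (table, scaler)."""
    scaler = Standardizer().fit(df)
    return scaler.transform(df), scaler


def pca_reduce(scaled: pd.DataFrame, var_frac: float = 0.95,
               report: SelectionReport | None = None
               ) -> tuple[np.ndarray, SelectionReport]:
    """PCA on a standardized table, keeping the smallest m components whose
    cumulative explained variance reaches ``var_frac``.

    Sign convention: each loading vector's largest-magnitude entry is made
    positive, so the decomposition is deterministic.
    """
    X = scaled.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    # population covariance of already-centered data
    cov = X.T @ X / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    cum = np.cumsum(frac)
    m = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    m = min(m, p)
    L = evecs[:, :m]
    for j in range(m):  # deterministic sign
        idx = np.argmax(np.abs(L[:, j]))
        if L[idx, j] < 0:
            L[:, j] = -L[:, j]
    scores = X @ L
    if report is None:
        report = SelectionReport()
    report.loadings = L.tolist()
    report.explained_frac = frac[:m].tolist()
    report.m = m
    report.var_frac = var_frac
    return scores, report


class SelectionPipeline:
    """Screen → prune → standardize → PCA, fit on training data only.

    If the screen keeps no feature (e.g. permuted-label null runs), the
    single largest-|r| evaluable feature is retained so downstream fits stay
    defined; the report records this fallback.
    """

    def __init__(self, target: str, alpha: float = 0.05,
                 r_thresh: float = 0.9, var_frac: float = 0.95) -> None:
        self.target = target
        self.alpha = alpha
        self.r_thresh = r_thresh
        self.var_frac = var_frac
        self.report: SelectionReport | None = None
        self._scaler: Standardizer | None = None
        self._loadings: np.ndarray | None = None

    def fit(self, df: pd.DataFrame, features=None) -> "SelectionPipeline":
        rep = spearman_screen(df, self.target, features=features,
                              alpha=self.alpha)
        if not rep.kept:
            evaluable = [f for f, e in rep.screen.items() if e["r"] is not None]
            if not evaluable:
                raise ValueError("no evaluable feature")
            best = max(evaluable, key=lambda f: abs(rep.screen[f]["r"]))
            rep.screen[best]["status"] = "kept"
            rep.screen[best]["reason"] = "fallback-best-|r|"
            rep.kept = [best]
        kept = pearson_prune(df, self.target, rep.kept,
                             r_thresh=self.r_thresh, report=rep)
        complete = df[kept].dropna()
        scaled, self._scaler = standardize(complete)
        _, rep = pca_reduce(scaled, var_frac=self.var_frac, report=rep)
        rep.scaler_mean = self._scaler.mean_.to_dict()
        rep.scaler_sd = self._scaler.sd_.to_dict()
        rep.target, rep.alpha = self.target, self.alpha
        self._loadings = np.asarray(rep.loadings)
        self.report = rep
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if self.report is None:
            raise RuntimeError("pipeline not fitted")
        scaled = self._scaler.transform(df[self.report.kept])
        return scaled.to_numpy(dtype=float) @ self._loadings

    def fit_transform(self, df: pd.DataFrame, features=None) -> np.ndarray:
        return self.fit(df, features=features).transform(df)
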