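"""Agreement and association statistics.

Dice overlap, paired t (and its reconstruction from printed summaries),
Bland–Altman bias and limits of agreement, Spearman/Pearson correlation with
exact small-sample permutation p-values, two-way mixed consistency ICC with
its F test and confidence interval, the Spearman–Brown step-up, ROC/AUC via
the rank-sum statistic, and sensitivity/specificity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Sample size at or below which correlation p-values are computed by
#: exhaustive permutation instead of the t approximation.
EXACT_PERM_N = 9


@dataclass
class AgreementReport:
    """Bag of agreement statistics; unused fields stay None."""

    n: int | None = None
    k: int | None = None
    # paired t
    t: float | None = None
    df: float | None = None
    p: float | None = None
    mean_diff: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    # Bland–Altman
    bias: float | None = None
    sd_diff: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    # ICC
    icc_single: float | None = None
    icc_average: float | None = None
    F: float | None = None
    df1: float | None = None
    df2: float | None = None
    icc_p: float | None = None
    icc_single_ci: tuple | None = None
    icc_average_ci: tuple | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for key, val in self.__dict__.items():
            if key == "extra":
                out.update(val)
            elif val is not None:
                out[key] = val
        return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    tot = int(a.sum()) + int(b.sum())
    if tot == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / tot


def summarize_structure_scores(values) -> tuple[float, float]:
    """Mean and population SD (divisor N) of per-structure scores."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty score list")
    return float(values.mean()), float(values.std(ddof=0))


def paired_t(x, y) -> AgreementReport:
    """Paired-samples t test of x against y with a 95% CI of the mean diff."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        raise ValueError(f"need n >= 2 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)
    if se == 0:
        t = 0.0
        p = 1.0
    else:
        t = mean / se
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    q = stats.t.ppf(0.975, n - 1)
    return AgreementReport(n=n, t=float(t), df=n - 1, p=float(p),
                           mean_diff=mean, ci_low=mean - q * se,
                           ci_high=mean + q * se)


def t_from_summary(mean_diff: float, ci_low: float, ci_high: float,
                   n: int) -> float:
    """Reconstruct the paired t statistic from a printed mean and 95% CI."""
    if not ci_low < ci_high:
        raise ValueError("degenerate confidence interval")
    if n < 2:
        raise ValueError("need n >= 2")
    se = (ci_high - ci_low) / (2.0 * stats.t.ppf(0.975, n - 1))
    return float(mean_diff / se)


def bland_altman(x, y) -> AgreementReport:
    """Bias and 95% limits of agreement between two paired measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    if d.size < 2:
        raise ValueError("need n >= 2 complete pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(n=d.size, bias=bias, sd_diff=sd,
                           loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def loa_from_summary(mean_diff: float, t: float, n: int) -> tuple[float, float]:
    """Limits of agreement reconstructed from a printed mean and t statistic.

    sd of the differences follows from t = mean/(sd/sqrt(n)).
    """
    if t == 0:
        raise ValueError("t = 0 carries no scale information")
    sd = abs(mean_diff / t) * math.sqrt(n)
    return mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def _perm_pvalue(x: np.ndarray, y: np.ndarray, statistic) -> float:
    """Exact two-sided permutation p for a correlation statistic."""
    obs = abs(statistic(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(statistic(x, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / total


def _pearson_stat(x, y) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p.

    p from the t approximation for n > 9, exact permutation for n <= 9.
    Constant input raises (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = _pearson_stat(x, y)
    if n <= EXACT_PERM_N:
        p = _perm_pvalue(x, y, _pearson_stat)
    else:
        p = _t_approx_p(r, n)
    return r, p


def spearman_r(x, y) -> tuple[float, float]:
    """Average-rank Spearman correlation with a two-sided p.

    p from the t approximation for n > 9, exact permutation for n <= 9.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = _pearson_stat(rx, ry)
    if n <= EXACT_PERM_N:
        p = _perm_pvalue(rx, ry, lambda a, b: _pearson_stat(a, stats.rankdata(b)))
    else:
        p = _t_approx_p(r, n)
    return r, p


def icc_consistency(data, alpha: float = 0.05) -> AgreementReport:
    """Two-way mixed consistency ICC (subjects random, measures fixed).

    ANOVA without interaction on a complete n×k table: MSR between subjects,
    MSE residual;
    ICC_single  = (MSR − MSE) / (MSR + (k−1)·MSE),
    ICC_average = (MSR − MSE) / MSR = 1 − 1/F with F = MSR/MSE on
    df (n−1, (n−1)(k−1)); the CI is the standard F-bound construction.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n x k matrix")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError(f"need n >= 3 subjects and k >= 2 measures, got {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells; perform listwise deletion first")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    msr = ssr / df1
    mse = max(sse / df2, 0.0)
    if mse == 0:
        icc_s, icc_a, F, p = 1.0, 1.0, float("inf"), 0.0
        ci_s = ci_a = (1.0, 1.0)
    else:
        F = msr / mse
        icc_s = (msr - mse) / (msr + (k - 1) * mse)
        icc_a = (msr - mse) / msr
        p = float(stats.f.sf(F, df1, df2))
        fu = stats.f.ppf(1 - alpha / 2, df1, df2)
        fl = stats.f.ppf(1 - alpha / 2, df2, df1)
        f_low = F / fu
        f_high = F * fl
        ci_s = ((f_low - 1) / (f_low + k - 1), (f_high - 1) / (f_high + k - 1))
        ci_a = (1 - 1 / f_low if f_low > 0 else -math.inf, 1 - 1 / f_high)
    return AgreementReport(n=n, k=k, icc_single=float(icc_s),
                           icc_average=float(icc_a), F=float(F),
                           df1=df1, df2=df2, icc_p=p,
                           icc_single_ci=tuple(map(float, ci_s)),
                           icc_average_ci=tuple(map(float, ci_a)))


def spearman_brown(icc_single: float, k: int) -> float:
    """Step-up from a single-measures to a k-measures average ICC."""
    if not (-1.0 < icc_single <= 1.0):
        raise ValueError(f"icc_single must be in (-1, 1], got {icc_single}")
    if k < 1:
        raise ValueError("k must be >= 1")
    denom = 1.0 + (k - 1) * icc_single
    if denom <= 0:
        raise ValueError("Spearman–Brown denominator <= 0")
    return k * icc_single / denom


def icc_average_from_f(F: float) -> float:
    """Average-measures consistency ICC implied by its F statistic: 1 − 1/F."""
    if F <= 0:
        raise ValueError("F must be positive")
    return 1.0 - 1.0 / F


def roc_auc(scores, labels) -> tuple[float, float]:
    """AUC as the tie-aware rank-sum statistic U/(n1·n0), with a two-sided p
    from the normal approximation of the rank-sum test against AUC = 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                             method="asymptotic")
    auc = float(res.statistic) / (pos.size * neg.size)
    return auc, float(res.pvalue)


def sensitivity_specificity(pred, truth) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if not ((truth == 1).any() and (truth == 0).any()):
        raise ValueError("both truth classes must be present")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp)
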