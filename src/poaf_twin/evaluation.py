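"""Discrimination and calibration metrics for POAF risk scores.

AUC is the Mann-Whitney concordance probability with ties counted 1/2,
with a class-stratified percentile-bootstrap confidence interval.
Threshold metrics use Youden's J (ties broken toward higher
specificity) and Wilson score intervals.  Calibration is assessed by the
Hosmer-Lemeshow decile-of-risk chi-square, the calibration slope from a
logistic regression of outcomes on the logit of the predictions (IRLS
implemented in-module), and the Brier score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import chi2, norm, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "roc_auc",
    "bootstrap_ci",
    "youden_threshold",
    "confusion_metrics",
    "hosmer_lemeshow",
    "calibration_slope",
    "brier_score",
    "metrics_report",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given labels (e.g. a single class)."""


@dataclass
class MetricsReport:
    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    hosmer_lemeshow_chi2: float | None
    hl_p: float | None
    calibration_slope: float | None
    brier: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("labels contain a single class")
    return y


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    pos = s[y == 1]
    neg = s[y == 0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, pos.size, replace=True)
        bn = rng.choice(neg, neg.size, replace=True)
        aucs[b] = roc_auc(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(bp.size), np.zeros(bn.size)]),
        )
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the observed score values; ties in J are
    broken toward the larger threshold (higher specificity).
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    thresholds = np.unique(s)
    n_pos = y.sum()
    n_neg = y.size - n_pos
    best_j, best_t = -np.inf, thresholds[0]
    for t in thresholds:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return float(best_t)


def _wilson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    z = norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return float(center - half), float(center + half)


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Sensitivity/specificity/PPV/NPV at ``scores >= threshold``, with
    Wilson score CIs.  An empty predicted-positive set leaves PPV NaN
    (flagged in the ``"flags"`` entry)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    flags = []
    if tp + fp == 0:
        flags.append("no predicted positives; ppv undefined")
    if tn + fn == 0:
        flags.append("no predicted negatives; npv undefined")
    out = {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
        "sensitivity_ci": _wilson(tp, tp + fn),
        "specificity_ci": _wilson(tn, tn + fp),
        "ppv_ci": _wilson(tp, tp + fp),
        "npv_ci": _wilson(tn, tn + fn),
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "flags": flags,
    }
    return out


def hosmer_lemeshow(pred_probs, outcomes, n_groups: int = 10
                    ) -> tuple[float, float]:
    """Hosmer-Lemeshow decile-of-risk test.

    Groups are deciles of predicted probability; the statistic is
    sum (O - E)^2 / (E (1 - E/n_g)) with ``n_groups - 2`` degrees of
    freedom.  Groups whose expected event count is zero are merged into
    their neighbour (logged).
    """
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(outcomes).astype(float)
    if p.size < n_groups:
        raise ValueError("need at least n_groups observations")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    # merge groups with zero expected events (or non-events)
    merged: list[np.ndarray] = []
    for g in groups:
        e = p[g].sum()
        if merged and (e == 0 or e == g.size):
            logger.info("merging degenerate Hosmer-Lemeshow group")
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    stat = 0.0
    for g in merged:
        n_g = g.size
        o = y[g].sum()
        e = p[g].sum()
        denom = e * (1 - e / n_g)
        if denom <= 0:
            continue
        stat += (o - e) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return float(stat), float(chi2.sf(stat, df))


def calibration_slope(pred_probs, outcomes, max_iter: int = 100,
                      tol: float = 1e-10) -> float:
    """Slope of a logistic fit of outcomes on logit(predictions), by IRLS.

    A perfectly calibrated score has slope 1; slopes below 1 indicate
    overdispersed (overconfident) predictions.  Raises on separation
    (non-convergence).
    """
    p = np.asarray(pred_probs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("pred_probs must lie strictly inside (0, 1)")
    y = np.asarray(outcomes).astype(float)
    x = np.log(p / (1 - p))
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if np.max(w) < 1e-12:
            break
        # weighted least squares step
        wx = X * w[:, None]
        H = X.T @ wx
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("IRLS failed (separation?)") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return float(beta[1])
    raise RuntimeError("IRLS did not converge (possible separation)")


def brier_score(pred_probs, outcomes) -> float:
    """Mean squared difference between probability and binary outcome."""
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(outcomes).astype(float)
    if p.shape != y.shape:
        raise ValueError("inputs must have the same length")
    return float(np.mean((p - y) ** 2))


def metrics_report(scores, labels, is_probability: bool | None = None,
                   n_boot: int = 2000, seed: int = 0) -> MetricsReport:
    """Full discrimination + calibration panel for one score.

    Calibration statistics require probabilistic scores; for ordinal
    scores (integer points) they are reported as None.  By default a
    score is treated as probabilistic when all values lie in [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    if is_probability is None:
        is_probability = bool(np.all((s >= 0) & (s <= 1)))
    thr = youden_threshold(s, y)
    cm = confusion_metrics(s, y, thr)
    hl = cal = br = None
    hl_p = None
    if is_probability:
        try:
            hl, hl_p = hosmer_lemeshow(s, y)
        except ValueError:
            pass
        inside = np.all((s > 0) & (s < 1))
        if inside:
            try:
                cal = calibration_slope(s, y)
            except RuntimeError:
                cal = None
        br = brier_score(s, y)
    return MetricsReport(
        auc=roc_auc(s, y),
        auc_ci=bootstrap_ci(s, y, n_boot=n_boot, seed=seed),
        youden_threshold=thr,
        sensitivity=cm["sensitivity"], sensitivity_ci=cm["sensitivity_ci"],
        specificity=cm["specificity"], specificity_ci=cm["specificity_ci"],
        ppv=cm["ppv"], ppv_ci=cm["ppv_ci"],
        npv=cm["npv"], npv_ci=cm["npv_ci"],
        hosmer_lemeshow_chi2=hl, hl_p=hl_p,
        calibration_slope=cal, brier=br,
    )
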