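"""Diagnostic evaluation: logistic fits, ROC/AUC, bootstrap, calibration.

Each marker is evaluated univariately: a maximum-likelihood logistic fit
of diagnosis on the marker (odds ratio with Wald 95% CI and p-value), an
oriented ROC curve with its AUC in the Mann-Whitney form, stratified
bootstrap distributions and percentile CIs for the AUC, and the
Hosmer-Lemeshow chi-square calibration test on the fitted probabilities
(decile-of-risk grouping, df = groups - 2).

Markers where *low* values indicate disease (here %fPSA) carry a
``lower_is_positive`` orientation: scores are negated internally so
sensitivity/specificity and AUC are reported on the oriented scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .scores import logistic_irls

__all__ = [
    "ROCCurve",
    "AUCEstimate",
    "LogisticFitResult",
    "HLResult",
    "roc_curve",
    "auc",
    "bootstrap_auc",
    "univariate_logistic",
    "hosmer_lemeshow",
    "bootstrap_hl",
    "compare_aucs",
    "AUCComparison",
]

log = logging.getLogger(__name__)


def _validate(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    return scores, labels


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep: subject called positive when score >= threshold.

    ``thresholds`` runs from +inf down to -inf through every distinct
    score value, so the curve starts at (sens 0, spec 1) and ends at
    (sens 1, spec 0).  For lower-is-positive markers the sweep is done on
    the negated scores and ``thresholds`` is on that negated scale;
    ``orientation`` records the convention.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: str  # "higher" | "lower"
    n_pos: int
    n_neg: int

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_curve(scores, labels, lower_is_positive: bool = False) -> ROCCurve:
    """ROC over all distinct score thresholds plus +-inf sentinels."""
    scores, labels = _validate(scores, labels)
    s = -scores if lower_is_positive else scores
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = labels[order]
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    cut = np.flatnonzero(distinct)  # first index of each distinct value
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    # at threshold = s_sorted[i] (a distinct value), all entries with that
    # value are called positive: take cumulative counts at the *last*
    # index of the tie block
    last = np.r_[cut[1:] - 1, len(s_sorted) - 1]
    thresholds = np.r_[np.inf, s_sorted[cut], -np.inf]
    tp = np.r_[0, tp_cum[last], n_pos]
    fp = np.r_[0, fp_cum[last], n_neg]
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=tp / n_pos,
        specificity=(n_neg - fp) / n_neg,
        orientation="lower" if lower_is_positive else "higher",
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(scores, labels, lower_is_positive: bool = False) -> float:
    """AUC in the Mann-Whitney form (ties counted half).

    Equals the probability that a random case outscores a random control
    on the oriented scale, and the trapezoidal area under
    :func:`roc_curve`.
    """
    scores, labels = _validate(scores, labels)
    s = -scores if lower_is_positive else scores
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(s)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _auc_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for (B, n_pos) vs (B, n_neg) samples."""
    B, n_pos = pos.shape
    n_neg = neg.shape[1]
    both = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(both, axis=1)
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class AUCEstimate:
    point: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    B: int
    seed: int


def bootstrap_auc(
    scores,
    labels,
    lower_is_positive: bool = False,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> AUCEstimate:
    """Stratified (within-class) bootstrap distribution and percentile CI.

    Cases and controls are resampled separately so every replicate keeps
    both classes; deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores, labels = _validate(scores, labels)
    s = -scores if lower_is_positive else scores
    pos = s[labels == 1]
    neg = s[labels == 0]
    rng = np.random.default_rng(seed)
    pos_rep = rng.choice(pos, size=(B, len(pos)), replace=True)
    neg_rep = rng.choice(neg, size=(B, len(neg)), replace=True)
    reps = _auc_matrix(pos_rep, neg_rep)
    alpha = (1 - ci_level) / 2 * 100
    lo, hi = np.percentile(reps, [alpha, 100 - alpha])
    return AUCEstimate(
        point=auc(scores, labels, lower_is_positive),
        replicates=reps,
        ci_low=float(lo),
        ci_high=float(hi),
        B=B,
        seed=seed,
    )


@dataclass(frozen=True)
class AUCComparison:
    delta: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    significant: bool
    B: int
    seed: int


def compare_aucs(
    marker_a,
    marker_b,
    labels,
    lower_is_positive_a: bool = False,
    lower_is_positive_b: bool = False,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> AUCComparison:
    """Paired bootstrap of AUC(a) - AUC(b) on shared resample indices.

    The CI excluding 0 is flagged ``significant``.
    """
    a, labels = _validate(marker_a, labels)
    b, _ = _validate(marker_b, labels)
    sa = -a if lower_is_positive_a else a
    sb = -b if lower_is_positive_b else b
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    pos_take = rng.choice(pos_idx, size=(B, len(pos_idx)), replace=True)
    neg_take = rng.choice(neg_idx, size=(B, len(neg_idx)), replace=True)
    reps = _auc_matrix(sa[pos_take], sa[neg_take]) - _auc_matrix(
        sb[pos_take], sb[neg_take]
    )
    alpha = (1 - ci_level) / 2 * 100
    lo, hi = np.percentile(reps, [alpha, 100 - alpha])
    delta = auc(a, labels, lower_is_positive_a) - auc(b, labels, lower_is_positive_b)
    return AUCComparison(
        delta=float(delta),
        replicates=reps,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        B=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Univariate logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFitResult:
    intercept: float
    slope: float
    slope_se: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    p_value: float
    fitted: np.ndarray
    separation: bool

    def p_display(self) -> str:
        """Printed p-value, '<0.001' below 0.0005."""
        return "<0.001" if self.p_value < 5e-4 else f"{self.p_value:.3f}"


def univariate_logistic(marker, labels) -> LogisticFitResult:
    """ML logistic fit of diagnosis on a single marker (statsmodels).

    OR = exp(slope) per unit of marker, Wald 95% CI, two-sided Wald p.
    Complete separation yields a flagged result (refit with a light ridge
    so fitted probabilities stay usable) rather than an exception.
    """
    marker, labels = _validate(marker, labels)
    if np.ptp(marker) == 0:
        raise ValueError("marker is constant")
    X = sm.add_constant(marker)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(labels, X).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            fitted = np.asarray(res.predict(X))
            if (
                not np.all(np.isfinite(bse))
                or np.max(np.abs(params)) > 1e3
                or (np.max(np.abs(X @ params)) > 30 and _is_separating(marker, labels))
            ):
                separated = True
        except Exception:  # PerfectSeparationError and friends
            separated = True
    if separated:
        beta, cov, _, _ = logistic_irls(X, labels, ridge=1e-6)
        params = beta
        bse = np.sqrt(np.diag(cov))
        fitted = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -700, 700)))
    slope, se = float(params[1]), float(bse[1])
    z = slope / se if se > 0 else np.inf
    return LogisticFitResult(
        intercept=float(params[0]),
        slope=slope,
        slope_se=se,
        odds_ratio=float(np.exp(slope)),
        or_ci_low=float(np.exp(slope - 1.96 * se)),
        or_ci_high=float(np.exp(slope + 1.96 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        fitted=np.clip(fitted, 1e-12, 1 - 1e-12),
        separation=separated,
    )


def _is_separating(marker, labels) -> bool:
    """True when some threshold on the marker classifies perfectly."""
    lo_pos, hi_pos = marker[labels == 1].min(), marker[labels == 1].max()
    lo_neg, hi_neg = marker[labels == 0].min(), marker[labels == 0].max()
    return hi_neg <= lo_pos or hi_pos <= lo_neg


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HLResult:
    statistic: float
    g: int
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    group_sizes: np.ndarray
    merged: int  # groups merged because mean risk hit 0 or 1


def hosmer_lemeshow(probabilities, labels, g: int = 10) -> HLResult:
    """Decile-of-risk chi-square calibration test.

    Subjects are sorted by fitted probability and split into ``g``
    near-equal groups; tied probabilities stay together in the lower
    group.  The statistic is sum_g (O_g - E_g)^2 / (n_g pbar_g (1 -
    pbar_g)) with E_g = n_g pbar_g, referred to chi-square with g - 2 df.
    Groups whose mean risk is exactly 0 or 1 are merged into their
    neighbour (counted in ``merged``).
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be 1-D and aligned")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    n = len(p)
    if g < 3:
        raise ValueError("need g >= 3 for df = g - 2 >= 1")
    if n < g:
        raise ValueError("need at least g subjects")
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    # nominal group boundaries, then push each boundary past any tie block
    bounds = [round(i * n / g) for i in range(1, g)]
    adj = []
    for b in bounds:
        while 0 < b < n and ps[b] == ps[b - 1]:
            b += 1
        adj.append(b)
    edges = np.unique([0] + [b for b in adj if b < n] + [n])
    obs, exp, sizes, pbars = [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        pb = ps[lo:hi].mean()
        obs.append(ys[lo:hi].sum())
        exp.append(ps[lo:hi].sum())
        sizes.append(hi - lo)
        pbars.append(pb)
    obs, exp = np.array(obs, float), np.array(exp, float)
    sizes, pbars = np.array(sizes, float), np.array(pbars, float)
    # merge degenerate groups (mean risk 0 or 1) into the neighbour
    merged = 0
    while len(sizes) > 1 and np.any((pbars <= 0) | (pbars >= 1)):
        i = int(np.argmax((pbars <= 0) | (pbars >= 1)))
        j = i - 1 if i > 0 else i + 1
        lo_i, hi_i = min(i, j), max(i, j)
        obs[lo_i] += obs[hi_i]
        exp[lo_i] += exp[hi_i]
        pbars[lo_i] = exp[lo_i] / (sizes[lo_i] + sizes[hi_i])
        sizes[lo_i] += sizes[hi_i]
        obs = np.delete(obs, hi_i)
        exp = np.delete(exp, hi_i)
        sizes = np.delete(sizes, hi_i)
        pbars = np.delete(pbars, hi_i)
        merged += 1
    g_eff = len(sizes)
    if g_eff < 3:
        raise ValueError("fewer than 3 usable risk groups after merging")
    denom = sizes * pbars * (1 - pbars)
    statistic = float(np.sum((obs - exp) ** 2 / denom))
    df = g_eff - 2
    return HLResult(
        statistic=statistic,
        g=g_eff,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        observed=obs,
        expected=exp,
        group_sizes=sizes,
        merged=merged,
    )


def bootstrap_hl(
    marker,
    labels,
    B: int = 1000,
    seed: int = 0,
    g: int = 10,
) -> np.ndarray:
    """Hosmer-Lemeshow p-values over B stratified bootstrap refits.

    Each resample refits the univariate logistic model (fast IRLS; same
    ML solution as :func:`univariate_logistic`) and evaluates the HL test
    on its fitted probabilities.  Resamples that separate or end with
    fewer than 3 usable risk groups are excluded; the exclusion count is
    logged.
    """
    marker, labels = _validate(marker, labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    pvals = []
    n_failed = 0
    for _ in range(B):
        take = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        x, y = marker[take], labels[take]
        X = np.column_stack([np.ones(len(x)), x])
        beta, _, _, separated = logistic_irls(X, y)
        if separated:
            n_failed += 1
            continue
        fitted = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -700, 700)))
        fitted = np.clip(fitted, 1e-12, 1 - 1e-12)
        try:
            pvals.append(hosmer_lemeshow(fitted, y, g=g).p_value)
        except ValueError:
            n_failed += 1
    if n_failed:
        log.warning("bootstrap_hl: %d of %d resamples excluded", n_failed, B)
    return np.asarray(pvals)
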