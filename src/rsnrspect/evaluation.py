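"""Diagnostic-evaluation statistics for cohort studies.

Covers the whole evaluation battery for a labeled cohort scored by one or
more continuous markers: group summary statistics with two-sample t-tests,
empirical ROC analysis with a Youden-optimal cutoff, paired comparison of
two classifiers' sensitivity and specificity by exact McNemar tests,
univariate logistic regression, and median-split subgroup performance
tables.

Conventions used throughout:

* ``label`` is ``"TVD"`` (positive / diseased) or ``"control"`` (negative).
* A score may be *lower* in disease (e.g. the stress SNR or the RSNR) or
  higher (e.g. summed perfusion scores); ROC orientation is chosen
  automatically so the AUC is at least 0.5.
* Classification at a cutoff always uses a strict inequality on the
  positive side: ``score < cutoff`` for lower-positive scores and
  ``score > cutoff`` for higher-positive scores. Reported cutoffs are
  midpoints between adjacent distinct scores.
* Report percentages are rounded to the nearest integer; raw values are
  retained on the result objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMetrics",
    "RocResult",
    "ComparisonResult",
    "LogisticResult",
    "confusion_metrics",
    "roc_analysis",
    "two_sample_ttest",
    "mcnemar_compare",
    "univariate_logistic",
    "subgroup_performance",
    "summarize_cohort",
    "LOWER_POSITIVE_SCORES",
]

POSITIVE_LABEL = "TVD"
NEGATIVE_LABEL = "control"

# markers whose value is lower in disease; they are auto-oriented for ROC and
# negated for logistic regression so the odds ratio reads > 1
LOWER_POSITIVE_SCORES = ("snr_stress", "rsnr")


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind == "b":
        return arr
    return arr == POSITIVE_LABEL


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    def rounded(self) -> tuple[int, int, int]:
        """(sensitivity, specificity, accuracy) rounded to integer percent."""
        return (
            int(round(self.sensitivity)),
            int(round(self.specificity)),
            int(round(self.accuracy)),
        )


def confusion_metrics(predictions, labels) -> ConfusionMetrics:
    """Sensitivity, specificity and accuracy of binary predictions.

    ``predictions`` holds ``"positive"``/``"negative"`` (or booleans);
    ``labels`` holds ``"TVD"``/``"control"`` (or booleans). Both classes must
    be present in the labels.
    """
    pred = np.asarray(predictions)
    if pred.dtype.kind != "b":
        pred = pred == "positive"
    truth = _as_bool_labels(labels)
    if len(pred) != len(truth):
        raise ValueError("predictions and labels differ in length")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present to compute sensitivity and specificity")
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    return ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass
class RocResult:
    """Empirical ROC curve with the Youden-optimal operating point."""

    auc: float
    curve: np.ndarray  # rows of (1 - specificity, sensitivity), as fractions
    optimal_cutoff: float | None
    orientation: str  # "higher-positive" or "lower-positive"
    metrics_at_cutoff: ConfusionMetrics | None
    degenerate: bool = False  # all scores tied: no usable cutoff

    @property
    def sensitivity(self) -> float:
        return self.metrics_at_cutoff.sensitivity

    @property
    def specificity(self) -> float:
        return self.metrics_at_cutoff.specificity

    @property
    def accuracy(self) -> float:
        return self.metrics_at_cutoff.accuracy


def classify_at_cutoff(scores, cutoff: float, orientation: str) -> np.ndarray:
    """Boolean positive calls at a cutoff under the stated orientation."""
    s = np.asarray(scores, dtype=float)
    if orientation == "lower-positive":
        return s < cutoff
    if orientation == "higher-positive":
        return s > cutoff
    raise ValueError(f"unknown orientation {orientation!r}")


def roc_analysis(scores, labels, orientation: str = "auto") -> RocResult:
    """Empirical ROC over all distinct thresholds with trapezoidal AUC.

    Orientation is auto-chosen so the oriented AUC is >= 0.5 (ties favor
    higher-positive). The optimal cutoff maximizes Youden's J = sensitivity +
    specificity - 1; ties are broken toward higher specificity. The AUC
    equals the concordant-pair (Mann-Whitney) statistic with half credit for
    ties.
    """
    s = np.asarray(scores, dtype=float)
    truth = _as_bool_labels(labels)
    if len(s) != len(truth):
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present for ROC analysis")

    n_pos, n_neg = int(truth.sum()), int((~truth).sum())

    def _curve_and_auc(sc: np.ndarray) -> tuple[np.ndarray, float]:
        # higher-positive convention on sc: sweep thresholds high -> low
        order = np.argsort(-sc, kind="stable")
        sorted_scores = sc[order]
        sorted_truth = truth[order]
        distinct = np.r_[np.diff(sorted_scores) != 0, True]
        tp = np.cumsum(sorted_truth)[distinct]
        fp = np.cumsum(~sorted_truth)[distinct]
        tpr = np.r_[0.0, tp / n_pos]
        fpr = np.r_[0.0, fp / n_neg]
        return np.column_stack([fpr, tpr]), float(np.trapezoid(tpr, fpr))

    _, auc_hi = _curve_and_auc(s)
    if orientation == "auto":
        orientation = "higher-positive" if auc_hi >= 0.5 else "lower-positive"
    oriented = s if orientation == "higher-positive" else -s
    curve, auc = _curve_and_auc(oriented)

    if float(np.ptp(s)) == 0.0:
        return RocResult(
            auc=0.5, curve=curve, optimal_cutoff=None, orientation=orientation,
            metrics_at_cutoff=None, degenerate=True,
        )

    # candidate cutoffs: midpoints between adjacent distinct oriented scores,
    # plus one beyond each extreme
    uniq = np.unique(oriented)
    gaps = np.diff(uniq)
    pad = float(gaps.min()) if len(gaps) else 1.0
    cands = np.r_[uniq[0] - pad / 2, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + pad / 2]
    best = None
    for c in cands:
        pred = oriented > c
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        sens = tp / n_pos
        spec = 1.0 - fp / n_neg
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, c)
    cut_oriented = best[1]
    cutoff = cut_oriented if orientation == "higher-positive" else -cut_oriented
    cm = confusion_metrics(classify_at_cutoff(s, cutoff, orientation), truth)
    return RocResult(
        auc=auc, curve=curve, optimal_cutoff=float(cutoff), orientation=orientation,
        metrics_at_cutoff=cm,
    )


def two_sample_ttest(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test; pooled-variance by default, Welch optionally.

    Returns (t statistic, two-sided p). Zero pooled variance with equal
    means yields t = 0, p = 1; with unequal means the statistic is undefined
    and a ValueError is raised.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ComparisonResult:
    """Exact McNemar comparison of two classifiers' sensitivity/specificity."""

    sensitivity_p: float
    sensitivity_discordant: tuple[int, int]  # (b, c)
    specificity_p: float
    specificity_discordant: tuple[int, int]
    flags: tuple[str, ...] = ()


def exact_mcnemar_p(b: int, c: int) -> float:
    """Two-sided exact binomial McNemar p from the discordant counts.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    b + c = 0 (no discordant pairs) returns 1.
    """
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def mcnemar_compare(pred_1, pred_2, labels) -> ComparisonResult:
    """Compare two paired classifiers on the same subjects.

    Sensitivity is compared on the positive-label subjects only: b counts
    subjects classifier 1 gets right and classifier 2 wrong, c the reverse.
    Specificity is compared analogously on the negatives.
    """
    p1 = np.asarray(pred_1)
    p2 = np.asarray(pred_2)
    if p1.dtype.kind != "b":
        p1 = p1 == "positive"
    if p2.dtype.kind != "b":
        p2 = p2 == "positive"
    truth = _as_bool_labels(labels)
    if not (len(p1) == len(p2) == len(truth)):
        raise ValueError("paired predictions must cover the same subjects")
    flags = []
    out = {}
    for name, sel, correct_call in (("sensitivity", truth, True), ("specificity", ~truth, False)):
        c1 = p1[sel] == correct_call
        c2 = p2[sel] == correct_call
        b = int(np.sum(c1 & ~c2))
        c = int(np.sum(~c1 & c2))
        if b + c == 0:
            flags.append(f"{name}: no discordant pairs")
        out[name] = (exact_mcnemar_p(b, c), (b, c))
    return ComparisonResult(
        sensitivity_p=out["sensitivity"][0],
        sensitivity_discordant=out["sensitivity"][1],
        specificity_p=out["specificity"][0],
        specificity_discordant=out["specificity"][1],
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class LogisticResult:
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    negated: bool
    separated: bool = False  # perfect separation: no finite MLE


def univariate_logistic(score, labels, negate: bool = False) -> LogisticResult:
    """Univariate logistic regression of disease status on one score.

    Fits logit P(positive) = b0 + b1 * x with x = -score when ``negate`` is
    set (the convention for markers that are lower in disease, so the odds
    ratio reads above 1). Returns the odds ratio exp(b1) with its Wald 95%
    CI and p-value, or a ``separated`` result when the MLE does not exist.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(score, dtype=float)
    if negate:
        x = -x
    y = _as_bool_labels(labels).astype(float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present for logistic regression")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return LogisticResult(None, None, None, None, negated=negate, separated=True)
    b1 = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e4 * max(abs(b1), 1.0):
        return LogisticResult(None, None, None, None, negated=negate, separated=True)
    z = stats.norm.ppf(0.975)
    return LogisticResult(
        odds_ratio=float(np.exp(b1)),
        ci_low=float(np.exp(b1 - z * se)),
        ci_high=float(np.exp(b1 + z * se)),
        p_value=float(fit.pvalues[1]),
        negated=negate,
    )


def _score_orientation(name: str) -> str:
    return "lower-positive" if name in LOWER_POSITIVE_SCORES else "higher-positive"


def subgroup_performance(
    records: pd.DataFrame,
    variable: str,
    cutoffs: dict[str, float],
    scores: list[str] | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy per covariate subgroup at fixed cutoffs.

    Numeric variables (age, bmi) are split at the cohort median — values
    equal to the median go to the upper group; ``sex`` splits by category.
    ``cutoffs`` maps score name to the whole-cohort ROC cutoff. Subgroups
    missing a class get NaN metrics and a flag column.
    """
    if variable not in records.columns:
        raise ValueError(f"variable {variable!r} missing from records")
    scores = scores or [c for c in cutoffs if c in records.columns]
    if variable == "sex":
        groups = [(str(v), records[records[variable] == v]) for v in ("M", "F")]
    else:
        med = float(records[variable].median())
        groups = [
            (f"{variable}<{med:g}", records[records[variable] < med]),
            (f"{variable}>={med:g}", records[records[variable] >= med]),
        ]
    rows = []
    for gname, sub in groups:
        row: dict = {"subgroup": gname, "n": len(sub), "flag": ""}
        labels = sub["label"] if len(sub) else pd.Series([], dtype=object)
        degenerate = len(sub) == 0 or labels.nunique() < 2
        if degenerate:
            row["flag"] = "subgroup missing a class"
        for score in scores:
            if degenerate:
                row[score] = ""
                continue
            orient = _score_orientation(score)
            pred = classify_at_cutoff(sub[score].to_numpy(), cutoffs[score], orient)
            cm = confusion_metrics(pred, labels.to_numpy())
            row[score] = "%d/%d/%d" % cm.rounded()
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(
    records: pd.DataFrame,
    scores: list[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-score group statistics and ROC results for a labeled cohort.

    ``records`` needs a ``label`` column plus one column per score; score
    columns that are absent are skipped, so cohorts without summed perfusion
    scores simply yield the SNR-based rows. Returns one row per score with
    mean/SD for all subjects and per group, t-test p, AUC, optimal cutoff
    and sensitivity/specificity/accuracy at that cutoff.
    """
    candidates = scores or ["srs", "sss", "sds", "snr_rest", "snr_stress", "rsnr"]
    present = [s for s in candidates if s in records.columns]
    truth = _as_bool_labels(records["label"].to_numpy())
    if truth.sum() < 2 or (~truth).sum() < 2:
        raise ValueError("need at least 2 records per group")
    rows = []
    for score in present:
        vals = records[score].to_numpy(dtype=float)
        pos, neg = vals[truth], vals[~truth]
        try:
            _, p = two_sample_ttest(neg, pos, welch=welch)
        except ValueError:  # degenerate variance: flagged as undefined
            p = float("nan")
        roc = roc_analysis(vals, truth)
        rows.append(
            {
                "score": score,
                "mean_all": vals.mean(),
                "sd_all": vals.std(ddof=1),
                "mean_control": neg.mean(),
                "sd_control": neg.std(ddof=1),
                "mean_tvd": pos.mean(),
                "sd_tvd": pos.std(ddof=1),
                "t_p": p,
                "auc": roc.auc,
                "cutoff": roc.optimal_cutoff,
                "orientation": roc.orientation,
                "sensitivity": None if roc.degenerate else roc.sensitivity,
                "specificity": None if roc.degenerate else roc.specificity,
                "accuracy": None if roc.degenerate else roc.accuracy,
            }
        )
    return pd.DataFrame(rows)
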