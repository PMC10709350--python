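"""Performance assessment for onset-time classification and rater comparison.

Implements the full protocol used to compare model, human raters, and
DL-augmented raters:

* ROC/AUC (Mann-Whitney convention, ties 0.5);
* two operating points for continuous scores — the Youden-index threshold and
  a threshold calibrated on the *validation* set to a target sensitivity (the
  multicenter human-rating benchmark of 0.62) and then applied to the test
  set;
* sensitivity / specificity / balanced accuracy;
* the categorical-rating pipeline: indeterminable cases count as "> 4.5 h"
  (they would be excluded from thrombolysis), and augmentation replaces
  exactly the indeterminable calls with the model's calls;
* Cohen's kappa for interrater agreement;
* paired bootstrap (subsets of N patients with replacement) + Wilcoxon
  signed-rank significance testing, with the repetition count grown until the
  mean bootstrap metric is within 0.01 of the full-set metric.

Binary-call convention throughout: ``score >= threshold`` means class 1
(onset <= 4.5 h, i.e. mismatch present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _wilcoxon
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_auc_score, roc_curve

#: sensitivity of the multicenter human DWI-FLAIR mismatch benchmark
TARGET_SENSITIVITY = 0.62

RATING_VALUES = ("mismatch", "no_mismatch", "indeterminable")


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def _check_both_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{what} requires both classes present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (equals the Mann-Whitney probability)."""
    y = _check_binary(labels)
    _check_both_classes(y, "AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique scores, plus sentinels
    below the minimum and above the maximum — a finite, complete search
    space for threshold optimization."""
    u = np.unique(np.asarray(scores, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def _sens_spec_at(scores, labels, thresholds) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)[:, None]
    y = np.asarray(labels)[:, None]
    calls = s >= np.asarray(thresholds)[None, :]
    pos = (y == 1)
    sens = (calls & pos).sum(axis=0) / max(pos.sum(), 1)
    spec = (~calls & ~pos).sum(axis=0) / max((~pos).sum(), 1)
    return sens, spec


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the larger threshold (the more specific operating
    point).
    """
    y = _check_binary(labels)
    _check_both_classes(y, "Youden threshold")
    cand = _candidate_thresholds(scores)
    sens, spec = _sens_spec_at(scores, y, cand)
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(cand[best[-1]])


def calibrate_to_sensitivity(val_scores, val_labels,
                             target: float = TARGET_SENSITIVITY) -> float:
    """Largest threshold whose validation sensitivity is >= ``target``.

    Because sensitivity decreases and specificity increases with the
    threshold, this is also the most specific qualifying operating point.
    The returned threshold is then applied unchanged to test predictions.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target sensitivity must be in [0, 1], got {target}")
    y = _check_binary(val_labels)
    _check_both_classes(y, "sensitivity calibration")
    cand = np.sort(_candidate_thresholds(val_scores))
    sens, _ = _sens_spec_at(val_scores, y, cand)
    ok = np.flatnonzero(sens >= target)
    # sens >= target is always achievable at the lowest sentinel (all called 1)
    return float(cand[ok[-1]])


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/balanced accuracy at one operating point."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    n: int
    threshold: float | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sensitivity", "specificity", "balanced_accuracy", "n", "threshold", "auc")}


def confusion_metrics(calls, labels, threshold: float | None = None,
                      scores=None) -> MetricsReport:
    """Sensitivity, specificity and their mean (balanced accuracy).

    If a class is absent its rate is NaN (with a warning) rather than an
    arbitrary value.
    """
    y = _check_binary(labels)
    c = _check_binary(calls)
    tn, fp, fn, tp = confusion_matrix(y, c, labels=[0, 1]).ravel()
    if tp + fn == 0:
        warnings.warn("no positive cases: sensitivity undefined (NaN)")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative cases: specificity undefined (NaN)")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    auc = None
    if scores is not None and len(np.unique(y)) == 2:
        auc = roc_auc(scores, y)
    return MetricsReport(sensitivity=float(sens), specificity=float(spec),
                         balanced_accuracy=float((sens + spec) / 2.0),
                         n=int(y.size), threshold=threshold, auc=auc)


def threshold_scores(scores, threshold: float) -> np.ndarray:
    """Binary calls: 1 (onset <= 4.5 h) iff score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


# -- categorical ratings ----------------------------------------------------

def _check_ratings(ratings) -> np.ndarray:
    r = np.asarray(ratings, dtype=object).astype(str)
    bad = set(np.unique(r)) - set(RATING_VALUES)
    if bad:
        raise ValueError(f"unknown rating values {sorted(bad)}; expected {RATING_VALUES}")
    return r


def ratings_to_calls(ratings) -> np.ndarray:
    """Map categorical ratings to binary calls.

    ``mismatch`` -> 1 (<= 4.5 h), ``no_mismatch`` -> 0, and ``indeterminable``
    -> 0: indeterminable patients would be excluded from the thrombolysis
    group, i.e. treated as > 4.5 h.
    """
    r = _check_ratings(ratings)
    return (r == "mismatch").astype(int)


def augment_ratings(ratings, dl_calls) -> np.ndarray:
    """Second-opinion augmentation: where the human rated ``indeterminable``
    the model's binary call is used; every other rating stands."""
    r = _check_ratings(ratings)
    dl = _check_binary(dl_calls)
    if r.size != dl.size:
        raise ValueError("ratings and DL calls must align patient-wise")
    calls = ratings_to_calls(r)
    indet = r == "indeterminable"
    calls[indet] = dl[indet]
    return calls


def cohens_kappa(calls_a, calls_b) -> float:
    """Cohen's kappa between two binary raters (chance-corrected agreement).

    Degenerate edge cases: if both raters are constant and identical, expected
    agreement is 1 and kappa is defined as 1.0 (with a warning); if exactly
    one rater is constant, kappa is 0.
    """
    a = np.asarray(calls_a).astype(int)
    b = np.asarray(calls_b).astype(int)
    if a.size != b.size:
        raise ValueError("rater call vectors must align")
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        warnings.warn("both raters constant: expected agreement is 1; kappa := 1 "
                      "if they agree else -1")
        return 1.0 if a[0] == b[0] else -1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = cohen_kappa_score(a, b, labels=[0, 1])
    if np.isnan(k):
        return 0.0
    return float(k)


def cohens_kappa_ratings(ratings_a, ratings_b, three_category: bool = False) -> float:
    """Kappa between two categorical raters.

    Default maps indeterminable -> no-mismatch first (two-category agreement,
    the clinically operative comparison); ``three_category=True`` keeps
    indeterminable as its own class.
    """
    if three_category:
        a = _check_ratings(ratings_a)
        b = _check_ratings(ratings_b)
        return float(cohen_kappa_score(a, b, labels=list(RATING_VALUES)))
    return cohens_kappa(ratings_to_calls(ratings_a), ratings_to_calls(ratings_b))


# -- bootstrap + Wilcoxon ---------------------------------------------------

_METRICS = {
    "sensitivity": lambda r: r.sensitivity,
    "specificity": lambda r: r.specificity,
    "balanced_accuracy": lambda r: r.balanced_accuracy,
}


@dataclass(frozen=True)
class BootstrapResult:
    """Paired bootstrap comparison of two rating schemes."""

    p_value: float
    significant: bool
    m: int                      # repetitions actually used
    pairs: np.ndarray           # (m, 2) per-bootstrap metric values (a, b)
    full_a: float
    full_b: float
    metric: str
    n_subset: int


def bootstrap_wilcoxon(calls_a, calls_b, labels, metric: str = "balanced_accuracy",
                       n_subset: int = 200, m_init: int = 200, m_max: int = 20000,
                       tol: float = 0.01, alpha_level: float = 0.05,
                       seed: int = 0) -> BootstrapResult:
    """Test whether two rating schemes differ on a metric.

    Each repetition samples ``n_subset`` patients with replacement and
    evaluates both schemes on the *same* subsample (paired design).  The
    repetition count starts at ``m_init`` (>= 10) and doubles until the mean
    bootstrap metric of each scheme is within ``tol`` of its full-set value.
    Significance is a two-sided Wilcoxon signed-rank test on the paired
    metric values, zero differences dropped.
    """
    if m_init < 10:
        raise ValueError("need at least 10 bootstrap repetitions")
    a = _check_binary(calls_a)
    b = _check_binary(calls_b)
    y = _check_binary(labels)
    n = y.size
    if a.size != n or b.size != n:
        raise ValueError("calls and labels must align")
    if n_subset > n * 50:
        raise ValueError(f"subset size {n_subset} unreasonably large for n={n}")
    try:
        mfun = _METRICS[metric]
    except KeyError:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}") from None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_a = mfun(confusion_metrics(a, y))
        full_b = mfun(confusion_metrics(b, y))

    rng = np.random.default_rng(seed)
    pairs: list[tuple[float, float]] = []
    m = m_init
    while True:
        while len(pairs) < m:
            idx = rng.integers(0, n, size=n_subset)
            ys = y[idx]
            if len(np.unique(ys)) < 2:
                continue  # degenerate subsample: metric undefined
            pairs.append((mfun(confusion_metrics(a[idx], ys)),
                          mfun(confusion_metrics(b[idx], ys))))
        arr = np.asarray(pairs)
        if (abs(arr[:, 0].mean() - full_a) < tol
                and abs(arr[:, 1].mean() - full_b) < tol) or m >= m_max:
            break
        m *= 2

    d = arr[:, 0] - arr[:, 1]
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-value set to 1")
        p = 1.0
    else:
        p = float(_wilcoxon(arr[:, 0], arr[:, 1], zero_method="wilcox",
                            alternative="two-sided", method="auto").pvalue)
    return BootstrapResult(p_value=p, significant=bool(p < alpha_level), m=len(pairs),
                           pairs=arr, full_a=full_a, full_b=full_b,
                           metric=metric, n_subset=n_subset)


# -- report assembly --------------------------------------------------------

def rater_comparison_table(ratings: pd.DataFrame, dl_calls: np.ndarray,
                           labels: np.ndarray, patient_ids) -> pd.DataFrame:
    """Per-rater metrics with and without model augmentation, mirroring the
    rater-vs-model comparison layout (one row per rater and per rater+DL)."""
    ids = pd.Index(patient_ids, name="patient_id")
    y = _check_binary(labels)
    dl = _check_binary(dl_calls)
    rows = []
    for rater, sub in ratings.groupby("rater_id"):
        sub = sub.set_index("patient_id").reindex(ids)
        if sub["rating"].isna().any():
            raise ValueError(f"rater {rater} is missing patients")
        r = sub["rating"].to_numpy()
        plain = confusion_metrics(ratings_to_calls(r), y)
        aug = confusion_metrics(augment_ratings(r, dl), y)
        rows.append({"rater": rater, **plain.to_dict()})
        rows.append({"rater": f"{rater} + DL", **aug.to_dict()})
    return pd.DataFrame(rows).drop(columns=["threshold", "auc"])
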