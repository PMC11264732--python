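"""Cohort classification and longitudinal monitoring analytics.

Classification: unpenalized logistic regression on per-region CPM features,
stratified k-fold cross-validation, out-of-fold ROC/AUC and a Youden-J
operating point.  Monitoring: per-patient post-operative score deltas and a
paired per-region signed-rank contribution test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .discovery import bh_fdr, rank_sum_test
from .insilico import spearman

__all__ = [
    "FoldResult",
    "roc_auc",
    "roc_points",
    "youden_operating_point",
    "fit_logistic_cv",
    "group_compare",
    "longitudinal_deltas",
    "region_contribution",
    "covariate_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    fold: int
    test_index: np.ndarray
    scores: np.ndarray  # out-of-fold predicted probabilities
    labels: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    roc: pd.DataFrame = field(repr=False, default=None)


def _as_binary(labels) -> np.ndarray:
    """Map labels to {0, 1}; accepts 0/1, bools, or case/control strings."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu" or arr.dtype.kind == "f":
        out = arr.astype(int)
        if not set(np.unique(out)) <= {0, 1}:
            raise ValueError("numeric labels must be 0/1")
        return out
    mapping = {"case": 1, "control": 0, "cancer": 1, "healthy": 0}
    try:
        return np.array([mapping[str(v).lower()] for v in arr])
    except KeyError as exc:
        raise ValueError(f"unrecognized label {exc.args[0]!r}") from None


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney identity: P(case score > control score),
    ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) over all unique score cuts;
    classification rule is score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    rows = [(0.0, 0.0, np.inf)]
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tpr = float((pred & (y == 1)).sum() / n1)
        fpr = float((pred & (y == 0)).sum() / n0)
        rows.append((fpr, tpr, float(t)))
    return pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])


def youden_operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1 over all cuts
    (rule: positive when score >= threshold); ties broken toward higher
    specificity (the larger threshold).  Returns (threshold, sens, spec)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    best = (np.inf, 0.0, 1.0)  # threshold +inf: nothing positive, J = 0
    best_j = 0.0
    for t in np.unique(scores)[::-1]:  # descending: higher spec visited first
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / n1
        spec = ((~pred) & (y == 0)).sum() / n0
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j = j
            best = (float(t), float(sens), float(spec))
    return best


def fit_logistic_cv(
    features, labels, k: int = 3, seed: int = 0, max_iter: int = 2000
) -> list[FoldResult]:
    """Stratified k-fold CV with unpenalized logistic regression (MLE).

    Under complete separation the MLE diverges; iterations are capped and the
    fitted direction retained (AUC is invariant to monotone rescaling of the
    scores), with a logged warning.  Returns per-fold out-of-fold results.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(f"fold {fold} does not contain both classes")
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X[train], y[train])
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning(
                "fold %d: logistic MLE did not converge within %d iterations "
                "(likely separation); direction retained", fold, max_iter,
            )
        scores = model.predict_proba(X[test])[:, 1]
        auc = roc_auc(scores, y[test])
        threshold, sens, spec = youden_operating_point(scores, y[test])
        results.append(
            FoldResult(
                fold=fold,
                test_index=test,
                scores=scores,
                labels=y[test],
                auc=auc,
                threshold=threshold,
                sensitivity=sens,
                specificity=spec,
                roc=roc_points(scores, y[test]),
            )
        )
    return results


def group_compare(scores_a, scores_b) -> float:
    """Two-sided rank-sum p-value between two score groups."""
    return rank_sum_test(scores_a, scores_b)


def longitudinal_deltas(
    patient_series: pd.DataFrame, pre_label: str = "preop"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient post-operative score deltas versus the pre-operative value.

    ``patient_series`` columns: patient, timepoint, ctcandi.  Patients without
    a ``pre_label`` timepoint are skipped with a warning.  Returns
    (per-timepoint table with delta and strict ``decreased`` flag,
    per-timepoint summary with the decreased fraction).
    """
    required = {"patient", "timepoint", "ctcandi"}
    if not required <= set(patient_series.columns):
        raise ValueError(f"patient_series needs columns {sorted(required)}")
    rows = []
    for patient, sub in patient_series.groupby("patient", sort=True):
        pre = sub.loc[sub["timepoint"] == pre_label, "ctcandi"]
        if pre.empty:
            warnings.warn(f"patient {patient!r} has no {pre_label!r} sample; skipped")
            continue
        pre_value = float(pre.iloc[0])
        for _, rec in sub[sub["timepoint"] != pre_label].iterrows():
            post = float(rec["ctcandi"])
            rows.append(
                {
                    "patient": patient,
                    "timepoint": rec["timepoint"],
                    "ctcandi": post,
                    "pre_ctcandi": pre_value,
                    "delta": post - pre_value,
                    "decreased": post < pre_value,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["patient", "timepoint", "ctcandi", "pre_ctcandi", "delta", "decreased"],
    )
    if table.empty:
        summary = pd.DataFrame(columns=["timepoint", "n", "n_decreased", "decreased_fraction"])
    else:
        summary = (
            table.groupby("timepoint", sort=True)["decreased"]
            .agg(n="size", n_decreased="sum")
            .reset_index()
        )
        summary["decreased_fraction"] = summary["n_decreased"] / summary["n"]
    return table, summary


def region_contribution(
    pre: pd.DataFrame, post: pd.DataFrame
) -> pd.DataFrame:
    """Per-region paired signed-rank test of pre vs post counts across patients.

    ``pre`` and ``post`` are patients x regions matrices with matching index
    and columns.  Regions with fewer than 2 complete pairs are skipped; BH
    adjustment over the tested regions; output ranked by q then by median
    delta (largest decrease first).
    """
    if list(pre.columns) != list(post.columns):
        raise ValueError("pre and post must share region columns")
    post = post.reindex(pre.index)
    rows = []
    for region in pre.columns:
        a = pre[region].to_numpy(dtype=float)
        b = post[region].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if a.size < 2:
            continue
        diff = a - b
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, zero_method="wilcox", method="auto").pvalue)
        rows.append(
            {
                "region": region,
                "n_pairs": int(a.size),
                "median_delta": float(np.median(diff)),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows, columns=["region", "n_pairs", "median_delta", "p_value"])
    if out.empty:
        out["q_value"] = []
        return out
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out = out.sort_values(
        ["q_value", "median_delta"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return out


def covariate_correlation(ctcandi_scores, covariate) -> tuple[float, float]:
    """Spearman correlation between scores and a clinical covariate."""
    return spearman(ctcandi_scores, covariate)
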