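"""Group comparison of lesion features: rank-sum tests and ROC cutoffs.

Lesions carry an objective-response label (OR = complete or partial
response; non-OR = stable or progressive disease).  Each feature, at each
of the three timepoint sets (pre, post, delta), is compared between groups
with the two-sided Wilcoxon rank-sum (Mann-Whitney U) test, and an ROC
analysis with the Youden index picks the operating cutoff for predicting
non-OR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_COLUMNS

__all__ = [
    "wilcoxon_ranksum",
    "roc_youden",
    "ROCResult",
    "group_comparison",
    "OR_LABEL",
    "NON_OR_LABEL",
]

OR_LABEL = "OR"
NON_OR_LABEL = "non-OR"

# exact null enumeration is feasible and tie-free below this pooled size
_EXACT_MAX_N = 12


def wilcoxon_ranksum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum test via the Mann-Whitney U statistic.

    Ties get mid-ranks.  The null distribution is enumerated exactly for
    small tie-free samples (n_x + n_y <= 12); otherwise the normal
    approximation with tie correction and continuity correction is used.

    Returns ``{"u": U statistic of x, "p": two-sided p, "exact": bool}``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if x.size + y.size < 2:
        raise ValueError("need at least 2 observations in total")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size <= _EXACT_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return {"u": float(res.statistic), "p": float(res.pvalue), "exact": exact}


@dataclass(frozen=True)
class ROCResult:
    """Operating point maximizing the Youden index J = sens + spec - 1.

    ``direction`` is ``">="`` if scores at or above the cutoff predict the
    positive class (non-OR), ``"<="`` otherwise.  Sensitivity and
    specificity are fractions of the positive and negative class.
    """

    auc: float
    cutoff: float
    direction: str
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def roc_youden(scores, labels, positive: str = NON_OR_LABEL) -> ROCResult:
    """ROC analysis of one feature with the Youden-index cutoff.

    AUC comes from the Mann-Whitney identity (ties count half).  Candidate
    cutoffs are the midpoints between adjacent sorted unique scores plus
    -inf/+inf; both reading directions are scanned and ties in J are broken
    toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(equal)
    diff = scores[pos][:, None] - scores[~pos][None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (n_pos * n_neg))

    uniq = np.unique(scores)
    cuts = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best = None
    for direction in (">=", "<="):
        for c in cuts:
            pred = scores >= c if direction == ">=" else scores <= c
            sens = float(np.sum(pred & pos) / n_pos)
            spec = float(np.sum(~pred & ~pos) / n_neg)
            j = sens + spec - 1.0
            key = (j, sens)
            if best is None or key > best[0]:
                best = (key, ROCResult(auc, float(c), direction, sens, spec))
    return best[1]


def _feature_frame(cohort: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    cols = [f"{timepoint}_{c}" for c in FEATURE_COLUMNS]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks feature columns: {missing}")
    return cohort[cols]


def group_comparison(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-feature OR vs non-OR comparison table (24 rows).

    ``cohort`` must have a ``group`` column (OR / non-OR) and, for each of
    the timepoint sets pre, post and delta, the eight feature columns named
    ``{timepoint}_{feature}``.  Each row reports group means, the two-sided
    rank-sum p-value, a significance flag at ``alpha``, and the ROC/Youden
    operating point for predicting non-OR.  ``bh_correction`` applies a
    Benjamini-Hochberg adjustment across the 24 p-values (off by default,
    matching univariate reporting).
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort table lacks a 'group' column")
    groups = cohort["group"].to_numpy()
    is_or = groups == OR_LABEL
    if not is_or.any() or is_or.all():
        raise ValueError("need at least one lesion in each response group")

    rows = []
    for timepoint in ("pre", "post", "delta"):
        frame = _feature_frame(cohort, timepoint)
        for feat in FEATURE_COLUMNS:
            vals = frame[f"{timepoint}_{feat}"].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            x = vals[ok & ~is_or]  # non-OR first, mirroring the table layout
            y = vals[ok & is_or]
            test = wilcoxon_ranksum(x, y)
            roc = roc_youden(vals[ok], np.where(is_or, OR_LABEL, NON_OR_LABEL)[ok])
            rows.append({
                "timepoint": timepoint,
                "feature": feat,
                "non_or_mean": float(x.mean()),
                "or_mean": float(y.mean()),
                "u": test["u"],
                "p": test["p"],
                "exact": test["exact"],
                "auc": roc.auc,
                "cutoff": roc.cutoff,
                "direction": roc.direction,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "youden_j": roc.youden_j,
            })
    table = pd.DataFrame(rows)
    if bh_correction:
        p = table["p"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(adj)
        q[order] = np.minimum(adj, 1.0)
        table["p_adjusted"] = q
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table
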