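"""Evaluation statistics: ROC/AUC with confidence intervals, the DeLong test
for correlated ROC curves, Youden-optimal cutpoints, one-vs-rest 4-class
reports with optional subgroup stratification, cohort-homogeneity chi-square,
and attention-based feature importance.

AUC is computed from the rank statistic (probability a positive outscores a
negative, ties counted half), the exact quantity the pairwise U-statistic
defines; the DeLong variance machinery is built on the same mid-rank
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "RocResult", "roc_auc", "delong_test", "auc_ci", "optimal_cutpoint",
    "one_vs_rest_report", "chisq_homogeneity", "feature_importance",
    "wilcoxon_ranksum", "pearson_corr",
]


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _check_binary(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both classes must be present")
    return s, y


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(s: np.ndarray, y: np.ndarray):
    """Per-observation U-statistic components (positives' and negatives')."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    rall = _midrank(np.concatenate([pos, neg]))
    rpos, rneg = _midrank(pos), _midrank(neg)
    v10 = (rall[:m] - rpos) / n                 # one entry per positive
    v01 = 1.0 - (rall[m:] - rneg) / m           # one entry per negative
    auc = v10.mean()
    return auc, v10, v01


def roc_auc(scores, labels, ci: bool = True) -> RocResult:
    """ROC curve and AUC via the rank statistic.

    AUC = P(score_pos > score_neg) + 0.5 P(tie); the curve enumerates all
    unique score thresholds (prediction positive when score >= threshold),
    starts at (0, 0) and ends at (1, 1).
    """
    s, y = _check_binary(scores, labels)
    auc, v10, v01 = _delong_components(s, y)
    m, n = int(y.sum()), int((1 - y).sum())
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    distinct = np.where(np.diff(s[order]) != 0)[0]
    idx = np.r_[distinct, len(ys) - 1]
    tpr = np.r_[0.0, tps[idx] / m]
    fpr = np.r_[0.0, fps[idx] / n]
    thr = np.r_[np.inf, s[order][idx]]
    lo, hi = (np.nan, np.nan)
    if ci:
        lo, hi = auc_ci(s, y)
    return RocResult(float(auc), lo, hi, m, n, fpr, tpr, thr)


def auc_ci(scores, labels, method: str = "auto", n_boot: int = 2000,
           seed: int = 0, alpha: float = 0.05):
    """95% CI for the AUC: DeLong variance by default, seeded bootstrap when
    positives are scarce (<10) or requested.  Fewer than 2 positives (or
    negatives) yields an NA interval."""
    s, y = _check_binary(scores, labels)
    m, n = int(y.sum()), int((1 - y).sum())
    if m < 2 or n < 2:
        log.warning("too few cases in one class: NA confidence interval")
        return (np.nan, np.nan)
    if method == "auto":
        method = "bootstrap" if min(m, n) < 10 else "delong"
    auc, v10, v01 = _delong_components(s, y)
    if method == "delong":
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(max(var, 0.0))
        return (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    if method != "bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)
    pos_i, neg_i = np.where(y == 1)[0], np.where(y == 0)[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bi = np.r_[rng.choice(pos_i, m), rng.choice(neg_i, n)]
        a, _, _ = _delong_components(s[bi], y[bi])
        reps[b] = a
    return (float(np.quantile(reps, alpha / 2)),
            float(np.quantile(reps, 1 - alpha / 2)))


def delong_test(scores_a, scores_b, labels):
    """Two-sided DeLong test comparing the AUCs of two correlated ROC curves
    measured on the same samples.

    Returns ``(z, p, auc_a, auc_b)``.  Identical score vectors have zero
    variance of the difference: z = 0, p = 1 by convention.
    """
    sa, y = _check_binary(scores_a, labels)
    sb, _ = _check_binary(scores_b, labels)
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return 0.0, 1.0, float(auc_a), float(auc_b)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p), float(auc_a), float(auc_b)


def optimal_cutpoint(scores, labels):
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores
    (plus the extremes); prediction is positive when score >= threshold.
    Ties on J are broken toward higher sensitivity, then lower threshold.
    Returns ``(threshold, sensitivity, specificity, accuracy)``.
    """
    s, y = _check_binary(scores, labels)
    uniq = np.unique(s)
    cands = np.r_[uniq[0] - 1.0, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + 1.0]
    m, n = y.sum(), (1 - y).sum()
    best = None
    for thr in cands:
        pred = s >= thr
        sens = (pred & (y == 1)).sum() / m
        spec = (~pred & (y == 0)).sum() / n
        key = (sens + spec - 1, sens, -thr)
        if best is None or key > best[0]:
            acc = ((pred == (y == 1)).sum()) / len(y)
            best = (key, thr, sens, spec, acc)
    _, thr, sens, spec, acc = best
    auc, _, _ = _delong_components(s, y)
    if auc < 0.5:
        log.warning("scores anti-correlated with labels (AUC %.3f < 0.5)", auc)
    return float(thr), float(sens), float(spec), float(acc)


def one_vs_rest_report(probs, labels, class_names=None, subgroups=None,
                       seed: int = 0) -> pd.DataFrame:
    """Per-class one-vs-rest performance, optionally stratified by subgroup.

    For each class the label is binarized, the class probability is the
    score, and AUC (95% CI), accuracy, sensitivity and specificity at the
    Youden-optimal cutpoint are reported.  A class absent from a subgroup
    yields an NA row.
    """
    from .network import CLASS_NAMES

    P = np.asarray(probs, float)
    y = np.asarray(labels, int)
    if np.any(np.abs(P.sum(axis=1) - 1) > 1e-6):
        raise ValueError("probability rows must lie on the simplex")
    names = list(class_names or CLASS_NAMES)
    strata = [("all", np.ones(len(y), bool))]
    if subgroups is not None:
        sg = np.asarray(subgroups)
        strata += [(str(g), sg == g) for g in pd.unique(sg)]
    rows = []
    for gname, gmask in strata:
        for c, cname in enumerate(names):
            yy = (y[gmask] == c).astype(int)
            row = {"subgroup": gname, "class": cname,
                   "n_pos": int(yy.sum()), "n": int(gmask.sum())}
            if yy.sum() == 0 or yy.sum() == len(yy):
                row.update({k: np.nan for k in
                            ("auc", "ci_low", "ci_high", "accuracy",
                             "sensitivity", "specificity", "threshold")})
            else:
                sc = P[gmask, c]
                res = roc_auc(sc, yy)
                thr, sens, spec, acc = optimal_cutpoint(sc, yy)
                row.update({"auc": res.auc, "ci_low": res.ci_low,
                            "ci_high": res.ci_high, "accuracy": acc,
                            "sensitivity": sens, "specificity": spec,
                            "threshold": thr})
            rows.append(row)
    return pd.DataFrame(rows)


def chisq_homogeneity(table):
    """Pearson chi-square of homogeneity, no continuity correction.

    Returns ``(chi2, df, p)`` with df = (r-1)(c-1).  The uncorrected Pearson
    variant is pinned by validation against published characteristics-table
    P values.  Zero row/column margins raise, naming the offender.
    """
    t = np.asarray(table)
    if isinstance(table, pd.DataFrame):
        t = table.to_numpy()
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    rowsum, colsum = t.sum(axis=1), t.sum(axis=0)
    for kind, sums, labels_ in (("row", rowsum, getattr(table, "index", None)),
                                ("column", colsum, getattr(table, "columns", None))):
        if (sums == 0).any():
            j = int(np.where(sums == 0)[0][0])
            name = labels_[j] if labels_ is not None else j
            raise ValueError(f"zero-margin {kind}: {name!r}")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def feature_importance(net, bags=None, X=None, idx=None, top_k: int = 8,
                       trained: bool = True):
    """Attention-derived importances of a fitted network.

    Tabular: mean attentive feature-mask mass per variable over the given
    rows, normalized to sum 1, ranked.  Image: per-patient top-k instances by
    attention weight (with coordinates when available).  An untrained
    checkpoint is allowed but flagged.
    """
    if not trained:
        log.warning("feature importance requested from an untrained checkpoint")
    out = {}
    if X is not None:
        from .autodiff import Tensor

        rows = np.asarray(X, float)
        if idx is not None:
            rows = rows[np.asarray(idx, int)]
        _, masks = net.encoder(Tensor(rows))
        mass = np.mean([m.data for m in masks], axis=(0, 1))
        mass = mass / mass.sum()
        out["tabular"] = mass
    if bags is not None:
        per_patient = []
        use = idx if idx is not None else range(len(bags))
        for i in use:
            bag = bags[i]
            row = None if X is None else X[i]
            mode = "image" if X is None else "mmmi"
            _, state = net.predict_proba(bag.features, row, mode=mode)
            tops = {}
            for sc, w in state["attention"].items():
                k = min(top_k, len(w))
                best = np.argsort(-w)[:k]
                tops[sc] = {"instance": best.tolist(),
                            "weight": w[best].tolist(),
                            "coords": bag.coords.get(sc, np.zeros((len(w), 2)))[best].tolist()}
            per_patient.append({"patient_id": bag.patient_id, "top": tops})
        out["image"] = per_patient
    return out


# thin, tested statistical utilities --------------------------------------

def wilcoxon_ranksum(a, b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (stat, p)."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def pearson_corr(a, b):
    """Pearson correlation coefficient and two-sided p value."""
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
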