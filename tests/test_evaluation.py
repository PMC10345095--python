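"""ROC/AUC, DeLong, cutpoints, reports, chi-square and importance."""

import numpy as np
import pandas as pd
import pytest

from mmmi.evaluation import (auc_ci, chisq_homogeneity, delong_test,
                             feature_importance, one_vs_rest_report,
                             optimal_cutpoint, pearson_corr, roc_auc,
                             wilcoxon_ranksum)


def pair_counting_auc(scores, labels):
    """Exhaustive oracle: wins + half ties over all positive-negative pairs."""
    s = np.asarray(scores)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_perfect_separation_auc_one():
    r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert r.auc == 1.0


def test_six_point_tie_case_matches_pair_oracle():
    s = [0.1, 0.4, 0.4, 0.6, 0.7, 0.2]
    y = [0, 0, 1, 1, 1, 0]
    r = roc_auc(s, y, ci=False)
    assert abs(r.auc - pair_counting_auc(s, y)) < 1e-12


def test_auc_equals_pair_oracle_on_random_sets(rng):
    for _ in range(20):
        n = int(rng.integers(10, 200))
        s = np.round(rng.normal(size=n), 1)      # force ties
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        r = roc_auc(s, y, ci=False)
        assert abs(r.auc - pair_counting_auc(s, y)) < 1e-12


def test_null_auc_within_3sd(rng):
    n = 10**4
    s = rng.normal(size=n)
    y = rng.integers(0, 2, n)
    m, nn = y.sum(), n - y.sum()
    sd = np.sqrt((m + nn + 1) / (12 * m * nn))
    assert abs(roc_auc(s, y, ci=False).auc - 0.5) <= 3 * sd


def test_roc_curve_valid(rng):
    s = rng.normal(size=100)
    y = rng.integers(0, 2, 100)
    r = roc_auc(s, y, ci=False)
    assert r.fpr[0] == 0 and r.tpr[0] == 0
    assert r.fpr[-1] == 1 and r.tpr[-1] == 1
    assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()


def test_single_class_input_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# -- DeLong -------------------------------------------------------------------

def test_delong_identical_scores_degenerate():
    s = np.linspace(0, 1, 30)
    y = (s > 0.6).astype(int)
    z, p, a, b = delong_test(s, s, y)
    assert z == 0.0 and p == 1.0 and a == b


def test_delong_antisymmetric(rng):
    n = 80
    y = rng.integers(0, 2, n)
    y[:5] = 1
    y[5:10] = 0
    sa = rng.normal(size=n) + y
    sb = rng.normal(size=n) + 0.3 * y
    z1, p1, *_ = delong_test(sa, sb, y)
    z2, p2, *_ = delong_test(sb, sa, y)
    assert abs(z1 + z2) < 1e-12 and abs(p1 - p2) < 1e-12
    assert 0 <= p1 <= 1


def test_delong_invariant_under_monotone_transform(rng):
    n = 100
    y = rng.integers(0, 2, n)
    y[0], y[1] = 0, 1
    sa = rng.normal(size=n) + y
    sb = rng.normal(size=n) + 0.5 * y
    z1, p1, *_ = delong_test(sa, sb, y)
    z2, p2, *_ = delong_test(np.exp(sa), 3 * sb - 7, y)
    assert abs(z1 - z2) < 1e-10 and abs(p1 - p2) < 1e-10


# -- confidence intervals -----------------------------------------------------

def test_ci_contains_auc_and_clips(rng):
    s = np.r_[rng.normal(2, 0.2, 200), rng.normal(0, 0.2, 200)]
    y = np.r_[np.ones(200, int), np.zeros(200, int)]
    r = roc_auc(s, y)
    assert r.ci_high == 1.0 and r.ci_low <= r.auc <= r.ci_high


def test_delong_and_bootstrap_cis_overlap(rng):
    s = rng.normal(size=120)
    y = (s + rng.normal(0, 1.2, 120) > 0).astype(int)
    lo1, hi1 = auc_ci(s, y, method="delong")
    lo2, hi2 = auc_ci(s, y, method="bootstrap", seed=1)
    assert max(lo1, lo2) < min(hi1, hi2)


def test_single_positive_gives_na_interval():
    y = np.r_[1, np.zeros(30, int)]
    s = np.arange(31, dtype=float)
    lo, hi = auc_ci(s, y)
    assert np.isnan(lo) and np.isnan(hi)


# -- cutpoints ----------------------------------------------------------------

def brute_force_best_J(scores, labels):
    s, y = np.asarray(scores), np.asarray(labels)
    best = -np.inf
    for thr in np.unique(np.r_[s - 1e-9, s + 1e-9]):
        pred = s >= thr
        sens = (pred & (y == 1)).sum() / y.sum()
        spec = (~pred & (y == 0)).sum() / (1 - y).sum()
        best = max(best, sens + spec - 1)
    return best


def test_cutpoint_perfect_separation_midpoint():
    thr, sens, spec, acc = optimal_cutpoint([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert sens == spec == acc == 1.0
    assert 0.2 < thr < 0.8


def test_cutpoint_matches_brute_force_scan(rng):
    for _ in range(20):
        s = np.round(rng.normal(size=50), 1)
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            continue
        thr, sens, spec, _ = optimal_cutpoint(s, y)
        assert abs((sens + spec - 1) - brute_force_best_J(s, y)) < 1e-12


def test_cutpoint_anticorrelated_flagged(caplog):
    s = np.arange(40, dtype=float)
    y = (s < 15).astype(int)
    with caplog.at_level("WARNING", logger="mmmi.evaluation"):
        optimal_cutpoint(s, y)
    assert any("anti-correlated" in r.message for r in caplog.records)


# -- reports ------------------------------------------------------------------

def test_report_perfect_onehot_all_auc_one(rng):
    y = rng.integers(0, 4, 40)
    probs = np.eye(4)[y] * 0.97 + 0.0075
    rep = one_vs_rest_report(probs, y)
    assert np.allclose(rep.auc, 1.0)


def test_report_uniform_predictions_auc_half(rng):
    y = rng.integers(0, 4, 40)
    rep = one_vs_rest_report(np.full((40, 4), 0.25), y)
    assert np.allclose(rep.auc, 0.5)


def test_report_row_count_and_absent_class_na(rng):
    y = np.array([0, 0, 1, 1, 2, 2, 3, 3] * 5)
    probs = np.full((40, 4), 0.25)
    sub = np.array((["A"] * 20) + (["B"] * 20))
    y[20:] = y[20:] % 3  # class 3 absent from subgroup B
    rep = one_vs_rest_report(probs, y, subgroups=sub)
    assert len(rep) == 4 * (1 + 2)
    row = rep[(rep.subgroup == "B") & (rep["class"] == "macro")].iloc[0]
    assert np.isnan(row.auc) and row.n_pos == 0


def test_report_rejects_off_simplex():
    with pytest.raises(ValueError):
        one_vs_rest_report(np.ones((3, 4)), [0, 1, 2])


# -- chi-square ---------------------------------------------------------------

def test_chisq_published_vascular_invasion_p():
    chi2, df, p = chisq_homogeneity([[609, 127], [592, 151]])
    assert df == 1 and round(p, 3) == 0.131


def test_chisq_identical_rows_p_one():
    chi2, df, p = chisq_homogeneity([[10, 20, 30], [10, 20, 30]])
    assert chi2 == 0.0 and p == 1.0


def test_chisq_zero_margin_names_offender():
    df = pd.DataFrame([[5, 0], [7, 0]], columns=["present", "absent"])
    with pytest.raises(ValueError, match="absent"):
        chisq_homogeneity(df)
    with pytest.raises(ValueError):
        chisq_homogeneity([[1, 2]])


# -- importance ---------------------------------------------------------------

def test_importance_sums_to_one_and_flags_untrained(small_cohort, small_config, caplog):
    from mmmi.network import MMMINet
    from mmmi.tabular import encode_categoricals, standardize

    net = MMMINet(small_config, seed=0)
    t = encode_categoricals(small_cohort.records)
    X, _ = standardize(t.matrix)
    with caplog.at_level("WARNING", logger="mmmi.evaluation"):
        imp = feature_importance(net, X=X, trained=False)
    assert abs(imp["tabular"].sum() - 1) < 1e-9
    assert any("untrained" in r.message for r in caplog.records)


def test_importance_no_spurious_dominance_on_noise(rng, small_config):
    from mmmi.network import MMMINet

    net = MMMINet(small_config, seed=1)
    X = rng.normal(size=(200, small_config.n_variables))
    imp = feature_importance(net, X=X)["tabular"]
    assert imp.max() < 2 * imp.mean()


def test_image_importance_topk(small_cohort, small_config):
    from mmmi.network import MMMINet
    from mmmi.tabular import encode_categoricals, standardize

    net = MMMINet(small_config, seed=0)
    t = encode_categoricals(small_cohort.records)
    X, _ = standardize(t.matrix)
    out = feature_importance(net, bags=small_cohort.bags[:3], X=X,
                             idx=[0, 1, 2], top_k=2)
    assert len(out["image"]) == 3
    for item in out["image"]:
        for sc, top in item["top"].items():
            assert len(top["instance"]) <= 2
            assert all(w >= 0 for w in top["weight"])


# -- thin utilities -----------------------------------------------------------

def test_wilcoxon_and_pearson(rng):
    a, b = rng.normal(0, 1, 50), rng.normal(1.2, 1, 50)
    _, p = wilcoxon_ranksum(a, b)
    assert p < 0.01
    x = rng.normal(size=60)
    r, _ = pearson_corr(x, 2 * x + rng.normal(0, 0.1, 60))
    assert r > 0.95
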