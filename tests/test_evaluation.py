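"""Fold assignment, nested CV contract, bootstrap statistics, cohort tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from veicans.evaluation import (
    ContingencyTable2x2,
    EvalConfig,
    assign_folds,
    auc_by_level,
    chi2_yates,
    mann_whitney,
    nested_cv,
    pearson_bootstrap,
    rank_auc,
    spearman_matrix,
)
from veicans.features import FeatureVector
from veicans.ltr import GradedRecord, TrainConfig


def _rec(subject, day, grade, *feats):
    return GradedRecord(subject, day, FeatureVector(frozenset(feats)),
                        float(grade))


# -- fold assignment -------------------------------------------------------

def test_equal_subject_counts_when_divisible():
    recs = [_rec(f"S{i}", 1, i % 5) for i in range(10)]
    fa = assign_folds(recs, k=5, seed=0)
    sizes = [list(fa.by_subject.values()).count(f) for f in range(5)]
    assert sizes == [2] * 5


def test_subject_days_stay_together():
    recs = [_rec("A", d, d % 4) for d in range(14)] + \
        [_rec(f"S{i}", 1, i % 5) for i in range(12)]
    fa = assign_folds(recs, k=5, seed=3)
    folds = fa.record_folds(recs)
    assert len({f for f, r in zip(folds, recs) if r.subject_id == "A"}) == 1


def test_too_few_subjects_rejected():
    with pytest.raises(ValueError, match="subjects < 5"):
        assign_folds([_rec("A", 1, 0), _rec("B", 1, 1)], k=5)


def test_stratification_beats_random_groupings(records):
    """Greedy grade stratification should land in the best decile of random
    subject-level groupings by fold grade-mean spread."""
    fa = assign_folds(records, k=5, seed=0)
    folds = fa.record_folds(records)
    grades = np.array([r.grade for r in records])

    def spread(fold_ids):
        means = [grades[fold_ids == f].mean() for f in range(5)]
        return max(means) - min(means)

    ours = spread(folds)
    subjects = sorted({r.subject_id for r in records})
    rng = np.random.default_rng(123)
    rand_spreads = []
    for _ in range(1000):
        perm = rng.permutation(len(subjects))
        assign = {s: perm[i] % 5 for i, s in enumerate(subjects)}
        rand_spreads.append(
            spread(np.array([assign[r.subject_id] for r in records])))
    assert ours <= np.percentile(rand_spreads, 10)


# -- nested CV -------------------------------------------------------------

def test_oracle_injection_gives_perfect_metrics(records):
    rep = nested_cv(records, EvalConfig(n_boot=50),
                    model_fn=lambda tr: (lambda r: r.grade))
    assert rep.pearson_r == pytest.approx(1.0)
    for a, lo, hi in rep.auc.values():
        assert a == pytest.approx(1.0)


def test_random_scores_give_null_correlation(records):
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        rep = nested_cv(records, EvalConfig(n_boot=10, seed=seed),
                        model_fn=lambda tr: (lambda r: rng.random()))
        hits += abs(rep.pearson_r) < 0.2
    assert hits >= 9


def test_every_record_scored_exactly_once(records):
    rep = nested_cv(records, EvalConfig(n_boot=10),
                    model_fn=lambda tr: (lambda r: r.grade))
    keys = set(zip(rep.predictions.subject_id, rep.predictions.day))
    assert len(rep.predictions) == len(records)
    assert keys == {(r.subject_id, r.day) for r in records}


def test_no_subject_leakage_across_many_seeds(records):
    for seed in range(50):
        fa = assign_folds(records, k=5, seed=seed)
        by_fold = {}
        for r in records:
            by_fold.setdefault(fa[r.subject_id], set()).add(r.subject_id)
        for f1, f2 in itertools.combinations(by_fold, 2):
            assert not by_fold[f1] & by_fold[f2]


# -- pearson bootstrap -----------------------------------------------------

def test_affine_relation_has_degenerate_ci():
    x = np.arange(20.0)
    r, lo, hi = pearson_bootstrap(x, 2 * x + 1, n_boot=100, seed=0)
    assert r == pytest.approx(1.0)
    assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)
    r, _, _ = pearson_bootstrap(x, -x, n_boot=50, seed=0)
    assert r == pytest.approx(-1.0)


def test_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        pearson_bootstrap(np.ones(10), np.arange(10.0))


def test_bootstrap_ci_monotone_in_confidence_level():
    rng = np.random.default_rng(1)
    x = rng.normal(size=60)
    y = 0.6 * x + rng.normal(size=60)
    boots = []
    brng = np.random.default_rng(9)
    for _ in range(500):
        idx = brng.integers(0, 60, 60)
        boots.append(sps.pearsonr(x[idx], y[idx])[0])
    lo95, hi95 = np.percentile(boots, [2.5, 97.5])
    lo99, hi99 = np.percentile(boots, [0.5, 99.5])
    assert lo99 <= lo95 and hi99 >= hi95


def test_bootstrap_ci_coverage_near_nominal():
    """Percentile bootstrap CI covers the true correlation at close to the
    nominal 95% rate (bivariate normal, rho = 0.6)."""
    rho, n, cover = 0.6, 50, 0
    reps = 200
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        _, lo, hi = pearson_bootstrap(x, y, n_boot=1000, seed=rep)
        cover += lo <= rho <= hi
    assert cover / reps >= 0.90


# -- AUC -------------------------------------------------------------------

def test_auc_extremes():
    scores = np.r_[np.zeros(10), np.ones(10)]
    grades = np.r_[np.zeros(10), np.full(10, 3.0)]
    a, lo, hi = auc_by_level(scores, grades, 2, n_boot=50, seed=0)
    assert a == 1.0
    rng = np.random.default_rng(0)
    a2, _, _ = auc_by_level(rng.random(2000),
                            np.r_[np.zeros(1000), np.full(1000, 3.0)],
                            2, n_boot=10, seed=0)
    assert abs(a2 - 0.5) < 0.05


def test_auc_equals_bruteforce_pair_count():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n_pos, n_neg = rng.integers(2, 12, size=2)
        pos = rng.integers(0, 6, n_pos).astype(float)
        neg = rng.integers(0, 6, n_neg).astype(float)
        brute = np.mean([(p > q) + 0.5 * (p == q)
                         for p in pos for q in neg])
        assert rank_auc(pos, neg) == pytest.approx(brute)


def test_auc_agrees_with_sklearn_roc():
    """Independent cross-check: the rank statistic equals the trapezoidal
    ROC area as computed by scikit-learn."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(17)
    for _ in range(20):
        scores = rng.integers(0, 8, 60).astype(float)
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            continue
        ours = rank_auc(scores[labels == 1], scores[labels == 0])
        assert ours == pytest.approx(roc_auc_score(labels, scores))


def test_auc_antisymmetric_under_score_negation():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=100)          # continuous: tie-free
    grades = np.r_[np.zeros(50), np.full(50, 2.0)]
    a, _, _ = auc_by_level(scores, grades, 2, n_boot=10, seed=0)
    b, _, _ = auc_by_level(-scores, grades, 2, n_boot=10, seed=0)
    assert a == pytest.approx(1 - b)


def test_auc_empty_class_rejected():
    with pytest.raises(ValueError, match="empty class"):
        auc_by_level(np.arange(4.0), np.array([1, 1, 2, 3.0]), 2)


# -- contingency statistics ------------------------------------------------

def test_chi2_reproduces_published_gpds_pvalue():
    stat, p = chi2_yates(ContingencyTable2x2(2, 156, 14, 159))
    assert round(p, 4) == 0.0054


def test_chi2_uncorrected_symmetric_table_is_null():
    stat, p = chi2_yates(ContingencyTable2x2(10, 50, 10, 50),
                         correction=False)
    assert stat == 0 and p == 1


def test_chi2_matches_textbook_closed_form():
    """Independent 2x2 shorthand N(|ad-bc| - N/2)^2 / (row and column
    products), equivalent to the unfloored cellwise correction."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        n1, n2 = rng.integers(5, 200, size=2)
        a = rng.integers(0, n1 + 1)
        c = rng.integers(0, n2 + 1)
        if a + c == 0 or a + c == n1 + n2:
            continue
        stat, p = chi2_yates(ContingencyTable2x2(a, n1, c, n2))
        b, d = n1 - a, n2 - c
        n = n1 + n2
        expect = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            n1 * n2 * (a + c) * (b + d))
        assert stat == pytest.approx(expect, abs=1e-10)
        assert p == pytest.approx(sps.chi2.sf(expect, 1), abs=1e-10)


def test_chi2_agrees_with_scipy_when_floor_inactive():
    t = ContingencyTable2x2(2, 156, 14, 159)
    stat, p = chi2_yates(t)
    res = sps.chi2_contingency([[2, 154], [14, 145]], correction=True)
    assert stat == pytest.approx(res.statistic)
    assert p == pytest.approx(res.pvalue)


def test_chi2_invariances():
    t = ContingencyTable2x2(7, 80, 19, 95)
    base = chi2_yates(t)[0]
    swapped_groups = chi2_yates(ContingencyTable2x2(19, 95, 7, 80))[0]
    swapped_rows = chi2_yates(ContingencyTable2x2(80 - 7, 80, 95 - 19, 95))[0]
    assert base == pytest.approx(swapped_groups)
    assert base == pytest.approx(swapped_rows)


def test_chi2_degenerate_margin_rejected():
    with pytest.raises(ValueError, match="zero expected"):
        chi2_yates(ContingencyTable2x2(0, 50, 0, 60))


def test_mann_whitney_basics():
    x = np.arange(20.0)
    assert mann_whitney(x, x)[1] == pytest.approx(1.0, abs=0.02)
    assert mann_whitney(x, x + 100)[1] < 1e-6


def test_mann_whitney_u_equals_bruteforce():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.integers(0, 10, rng.integers(3, 10)).astype(float)
        y = rng.integers(0, 10, rng.integers(3, 10)).astype(float)
        u, _ = mann_whitney(x, y)
        brute = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
        assert u == pytest.approx(brute)


# -- spearman matrix -------------------------------------------------------

def test_spearman_duplicated_feature_perfectly_correlated(vocab):
    recs = [_rec(f"S{i}", 1, i % 3, *(("gpds", "grda") if i % 2 else ()))
            for i in range(20)]
    m = spearman_matrix(recs, vocab)
    assert m.loc["gpds", "grda"] == pytest.approx(1.0)


def test_spearman_exclusive_features_anticorrelated(vocab):
    recs = [_rec(f"S{i}", 1, 0, "gpds" if i % 2 else "grda")
            for i in range(20)]
    m = spearman_matrix(recs, vocab)
    assert m.loc["gpds", "grda"] == pytest.approx(-1.0)


def test_spearman_matches_phi_for_binary_features(vocab):
    rng = np.random.default_rng(8)
    recs = []
    for i in range(40):
        feats = [f for f in ("gpds", "grda", "pdr") if rng.random() < 0.4]
        recs.append(_rec(f"S{i}", 1, 0, *feats))
    m = spearman_matrix(recs, vocab)
    x = np.array([1.0 if "gpds" in r.features.present else 0 for r in recs])
    y = np.array([1.0 if "pdr" in r.features.present else 0 for r in recs])
    phi = np.corrcoef(x, y)[0, 1]     # Pearson on binaries == rank corr
    assert m.loc["gpds", "pdr"] == pytest.approx(phi)


def test_spearman_constant_feature_flagged_not_zeroed(vocab, records):
    m = spearman_matrix(records, vocab)
    assert set(m.columns) == set(vocab.model_ids())
    prevalence = {f: sum(f in r.features.present for r in records)
                  for f in vocab.model_ids()}
    for f, count in prevalence.items():
        if count == 0:
            assert m[f].isna().all()
    sub = m.loc[m.notna().any(axis=1), m.notna().any(axis=0)]
    assert np.allclose(sub, sub.T, equal_nan=True)
    assert sub.le(1.0 + 1e-12).all().all()
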