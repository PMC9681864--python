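"""Evaluation protocol: grouped stratified nested CV and cohort statistics.

Out-of-sample performance of a trained scoring table is estimated with
five-fold nested cross-validation.  Folds are assigned at the subject level
(all days of a patient share one fold, preventing leakage of within-patient
correlation) while a greedy bin-packing heuristic keeps the ICANS grade
distribution approximately equal across folds.  The inner loop re-runs the
same grouped CV on the four training folds to pick the ElasticNet penalty;
the outer loop pools the five held-out predictions, so every patient-day is
scored exactly once by a model that never saw its subject.

Summary statistics mirror the study protocol: Pearson correlation between
predicted score and clinical grade with a 1000-replicate percentile
bootstrap CI; discrimination AUC for no-neurotoxicity (grade 0) versus
grade >= x, computed as the Mann-Whitney rank statistic with bootstrap CIs;
Yates-corrected chi-square and Mann-Whitney U tests for cohort contingency
rows; and the Spearman correlation matrix between input features.

The chi-square continuity correction here subtracts 0.5 from |O - E| without
flooring the corrected deviation at zero.  Degenerate 2x2 tables (|O-E| <
0.5) therefore keep a small positive statistic rather than collapsing to
zero; this is the convention the packaged cohort fixture was computed under.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ltr
from .features import FeatureVocabulary, ScoringTable, default_vocabulary, score
from .ltr import GradedRecord, TrainConfig

__all__ = [
    "FoldAssignment", "EvalConfig", "EvalReport", "ContingencyTable2x2",
    "assign_folds", "nested_cv", "pearson_bootstrap", "auc_by_level",
    "rank_auc", "chi2_yates", "mann_whitney", "spearman_matrix",
]


# -- fold assignment -------------------------------------------------------

@dataclass
class FoldAssignment:
    """Subject-level fold ids (0..k-1); all days of a subject share a fold."""

    by_subject: dict[str, int]
    k: int

    def record_folds(self, records: Sequence[GradedRecord]) -> np.ndarray:
        return np.array([self.by_subject[r.subject_id] for r in records])

    def values(self):
        return self.by_subject.values()

    def __getitem__(self, subject_id: str) -> int:
        return self.by_subject[subject_id]


def assign_folds(records: Sequence[GradedRecord], k: int = 5,
                 seed: int = 0) -> FoldAssignment:
    """Grouped, grade-stratified fold assignment.

    Greedy bin-packing on subject grade profiles: subjects are taken largest
    first (record count; ties shuffled by ``seed``) and each is placed in the
    fold — among those below the subject-capacity ceiling — whose grade
    distribution deviates least from the cohort's after the addition.
    """
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects < {k} folds")
    grade_values = sorted({r.grade for r in records})
    gidx = {g: i for i, g in enumerate(grade_values)}
    profiles = {s: np.zeros(len(grade_values)) for s in subjects}
    for r in records:
        profiles[r.subject_id][gidx[r.grade]] += 1
    total = sum(profiles.values())
    p_global = total / total.sum()

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(subjects))
    order.sort(key=lambda s: -profiles[s].sum())

    cap = math.ceil(len(subjects) / k)
    fold_counts = [np.zeros(len(grade_values)) for _ in range(k)]
    fold_sizes = [0] * k
    by_subject: dict[str, int] = {}
    for s in order:
        prof = profiles[s]
        best, best_cost = None, None
        for f in range(k):
            if fold_sizes[f] >= cap:
                continue
            after = fold_counts[f] + prof
            expected = after.sum() * p_global
            cost = (float(((after - expected) ** 2).sum()),
                    fold_counts[f].sum(), f)
            if best_cost is None or cost < best_cost:
                best, best_cost = f, cost
        by_subject[s] = best
        fold_counts[best] += prof
        fold_sizes[best] += 1
    return FoldAssignment(by_subject=by_subject, k=k)


# -- nested cross-validation -----------------------------------------------

@dataclass
class EvalConfig:
    k_outer: int = 5
    n_boot: int = 1000
    seed: int = 0
    auc_levels: tuple[int, ...] = (1, 2, 3, 4)
    bootstrap_unit: str = "record"      # record | subject
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class EvalReport:
    """Pooled out-of-sample scores and the study's summary statistics."""

    predictions: pd.DataFrame           # subject_id, day, grade, score, fold
    pearson_r: float
    pearson_ci: tuple[float, float]
    auc: dict[int, tuple[float, float, float]]   # level -> (auc, lo, hi)
    spearman: pd.DataFrame
    fold_assignment: FoldAssignment
    per_fold: list[dict]

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_ci": list(self.pearson_ci),
            "auc": {str(k): list(v) for k, v in self.auc.items()},
            "n_records": int(len(self.predictions)),
            "per_fold": self.per_fold,
        }


def nested_cv(records: Sequence[GradedRecord],
              config: EvalConfig | None = None,
              vocab: FeatureVocabulary | None = None,
              model_fn: Callable[[Sequence[GradedRecord]],
                                 Callable[[GradedRecord], float]] | None = None
              ) -> EvalReport:
    """Nested grouped stratified CV with pooled out-of-sample predictions.

    ``model_fn`` overrides the learning-to-rank trainer with an arbitrary
    model factory (fit on the training records, returning a per-record
    scorer); used for oracle-injection and null checks.
    """
    config = config or EvalConfig()
    vocab = vocab or default_vocabulary()
    records = list(records)
    folds = assign_folds(records, k=config.k_outer, seed=config.seed)
    rec_folds = folds.record_folds(records)

    rows = []
    per_fold = []
    for f in range(config.k_outer):
        train_recs = [r for r, rf in zip(records, rec_folds) if rf != f]
        test_recs = [r for r, rf in zip(records, rec_folds) if rf == f]
        assert not ({r.subject_id for r in train_recs}
                    & {r.subject_id for r in test_recs}), \
            "subject leaked across train/test folds"
        if model_fn is not None:
            scorer = model_fn(train_recs)
            info = {"fold": f, "model": "injected"}
        else:
            inner_cfg = TrainConfig(**{**config.train.__dict__,
                                       "seed": config.train.seed + f})
            table, fit = ltr.train(train_recs, inner_cfg, vocab)
            scorer = _table_scorer(table, vocab)
            info = {"fold": f,
                    "lambda": fit.hyperparameters["lambda"],
                    "pairwise_accuracy_integer":
                        fit.diagnostics["pairwise_accuracy_integer"]}
        for r in test_recs:
            rows.append({"subject_id": r.subject_id, "day": r.day,
                         "grade": r.grade, "score": float(scorer(r)),
                         "fold": f})
        per_fold.append(info)

    preds = pd.DataFrame(rows)
    assert len(preds) == len(records)

    clusters = preds["subject_id"].to_numpy() \
        if config.bootstrap_unit == "subject" else None
    r, lo, hi = pearson_bootstrap(preds["score"].to_numpy(),
                                  preds["grade"].to_numpy(),
                                  n_boot=config.n_boot, seed=config.seed,
                                  clusters=clusters)
    auc = {}
    for level in config.auc_levels:
        try:
            a, alo, ahi = auc_by_level(preds["score"].to_numpy(),
                                       preds["grade"].to_numpy(), level,
                                       n_boot=config.n_boot,
                                       seed=config.seed)
            auc[level] = (a, alo, ahi)
        except ValueError:
            continue   # a class is empty at this level for this cohort
    spearman = spearman_matrix(records, vocab)
    return EvalReport(predictions=preds, pearson_r=r, pearson_ci=(lo, hi),
                      auc=auc, spearman=spearman, fold_assignment=folds,
                      per_fold=per_fold)


def _table_scorer(table: ScoringTable, vocab: FeatureVocabulary):
    def scorer(r: GradedRecord) -> float:
        return float(score(r.features, table, vocab).value)
    return scorer


# -- correlation and discrimination ----------------------------------------

def pearson_bootstrap(x, y, n_boot: int = 1000, seed: int = 0,
                      clusters=None) -> tuple[float, float, float]:
    """Pearson r with a percentile bootstrap 95% CI.

    Resampling unit is the observation, or the cluster when ``clusters``
    labels are given (days within a patient are correlated).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    boots = []
    if clusters is None:
        for _ in range(n_boot):
            idx = rng.integers(0, len(x), len(x))
            if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
                continue
            boots.append(stats.pearsonr(x[idx], y[idx])[0])
    else:
        clusters = np.asarray(clusters)
        uniq = np.unique(clusters)
        members = {c: np.flatnonzero(clusters == c) for c in uniq}
        for _ in range(n_boot):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([members[c] for c in chosen])
            if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
                continue
            boots.append(stats.pearsonr(x[idx], y[idx])[0])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return r, float(lo), float(hi)


def rank_auc(pos, neg) -> float:
    """AUC as the Mann-Whitney rank statistic U/(n1*n0); ties count half."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def auc_by_level(scores, grades, level: float, n_boot: int = 1000,
                 seed: int = 0) -> tuple[float, float, float]:
    """Discrimination of no-neurotoxicity (grade 0) vs grade >= level.

    Records with 0 < grade < level are excluded from the comparison.  CI is
    a class-stratified percentile bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    grades = np.asarray(grades, dtype=float)
    pos = scores[grades >= level]
    neg = scores[grades == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"empty class for level {level}")
    a = rank_auc(pos, neg)
    rng = np.random.default_rng(seed)
    boots = [rank_auc(pos[rng.integers(0, len(pos), len(pos))],
                      neg[rng.integers(0, len(neg), len(neg))])
             for _ in range(n_boot)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return a, float(lo), float(hi)


# -- cohort statistics ------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Feature-present counts a (of n1) and c (of n2) in two groups."""

    a: int
    n1: int
    c: int
    n2: int

    def __post_init__(self):
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n2):
            raise ValueError("counts exceed group sizes")


def chi2_yates(t: ContingencyTable2x2, correction: bool = True
               ) -> tuple[float, float]:
    """Continuity-corrected chi-square on a 2x2 table, df=1, two-sided.

    The corrected deviation |O - E| - 0.5 is used as-is (not floored at
    zero); see the module docstring.
    """
    if t.n1 <= 0 or t.n2 <= 0:
        raise ValueError("empty group")
    obs = np.array([[t.a, t.n1 - t.a], [t.c, t.n2 - t.c]], dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if np.any(expected == 0):
        raise ValueError("zero expected count: chi-square undefined")
    d = np.abs(obs - expected)
    if correction:
        d = d - 0.5
    stat = float((d ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(records: Sequence[GradedRecord],
                    vocab: FeatureVocabulary | None = None,
                    feature_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Spearman correlation between all model input features.

    Constant features have undefined correlation; their entries are NaN
    (flagged, not silently zeroed), diagonal included.
    """
    vocab = vocab or default_vocabulary()
    if feature_ids is None:
        feature_ids = vocab.model_ids()
    if len(records) < 2:
        raise ValueError("need >= 2 records")
    X = ltr.feature_matrix(records, feature_ids)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    constant = np.ptp(X, axis=0) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    diag = np.where(constant, np.nan, 1.0)
    np.fill_diagonal(rho, diag)
    return pd.DataFrame(rho, index=list(feature_ids),
                        columns=list(feature_ids))
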