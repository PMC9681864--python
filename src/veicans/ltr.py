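"""Pairwise learning-to-rank derivation of integer EEG severity tables.

Every ordered pair of patient-days with strictly different ICANS grades
becomes one training example: the model should score the higher-grade day
above the lower-grade day.  With feature-difference vector dx = x_hi - x_lo
and coefficients w, the fit minimises the logistic ranking loss

    L(w) = (1/N) sum_pairs log(1 + exp(-w . dx)) + lam * (a*|w|_1 + (1-a)/2*|w|_2^2)

with no intercept (a difference model), subject to linear domain-knowledge
constraints: abnormal features score >= 0, normal features <= 0, and within
each slowing band a lower-frequency (more severe) bin scores at least as much
as a higher-frequency bin.  Under the sign constraints |w_i| = s_i * w_i with
known sign s_i, so the ElasticNet L1 term is linear and the whole problem is
smooth and convex over a polyhedron; it is solved with SLSQP.

Real-valued coefficients are then integerised (scale to a target point range,
round, repair feasibility, then greedy +/-1 local search maximising pairwise
ranking accuracy, ties broken toward smaller point values) so the table can
be applied at the bedside as a point system.

Severe-pattern days are excluded from pair construction: their score is the
maximal-score override a priori, and keeping them would distort the
coefficients of co-occurring features.  Rare features (fewer than
``min_count`` occurrences) are dropped before training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .features import (
    GRADE_COLUMN,
    SEIZURE_ID,
    FeatureVector,
    FeatureVocabulary,
    ScoringTable,
    default_vocabulary,
)


class RankingConstraintError(RuntimeError):
    """Infeasible constraint set or failed constrained optimisation."""

__all__ = [
    "GradedRecord", "RankedPair", "RankingFit", "TrainConfig",
    "records_from_frame", "filter_features", "make_pairs",
    "pair_diff_matrix", "pairwise_accuracy", "constraints_from_vocab",
    "fit_ranker", "integerize", "train",
]


# -- data containers -------------------------------------------------------

@dataclass(frozen=True)
class GradedRecord:
    """One patient-day: feature vector plus the clinical ICANS grade."""

    subject_id: str
    day: int
    features: FeatureVector
    grade: float

    def is_severe(self, severe_ids: Iterable[str]) -> bool:
        return any(f in self.features.present for f in severe_ids)


@dataclass(frozen=True)
class RankedPair:
    """Indices into the record list; ``hi`` has the strictly higher grade."""

    hi: int
    lo: int


@dataclass
class ConstraintSpec:
    """Linear constraints on the coefficient vector of retained features."""

    signs: np.ndarray                       # +1 abnormal, -1 normal
    ordinal: list[tuple[int, int]]          # (i, j) meaning w_i >= w_j
    enforce_sign: bool = True


@dataclass
class TrainConfig:
    """End-to-end training configuration."""

    lambda_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    alpha: float = 0.5                # ElasticNet mixing (1 = pure L1)
    min_count: int = 5                # minimum feature occurrences
    search_radius: int = 2            # integerisation local-search box
    target_max_points: int = 10       # point value of the largest coefficient
    inner_folds: int = 5              # grouped CV folds for lambda selection
    seed: int = 0
    weight_pairs_by_subject: bool = False  # down-weight prolific subjects


@dataclass
class RankingFit:
    """Trained coefficients with constraint metadata and diagnostics."""

    retained: list[str]
    excluded: dict[str, str]                  # feature id -> reason
    real_coefficients: dict[str, float]
    integer_coefficients: dict[str, int]
    hyperparameters: dict
    diagnostics: dict = field(default_factory=dict)


# -- record plumbing -------------------------------------------------------

def records_from_frame(df, vocab: FeatureVocabulary | None = None
                       ) -> list[GradedRecord]:
    """Build graded records from a validated patient-day feature table."""
    vocab = vocab or default_vocabulary()
    if GRADE_COLUMN not in df.columns:
        raise ValueError("feature table has no 'icans' column")
    feat_cols = [c for c in df.columns if c in vocab]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        fv = FeatureVector.from_mapping(
            {c: int(d[c]) for c in feat_cols}, vocab)
        records.append(GradedRecord(str(d["subject_id"]), int(d["day"]),
                                    fv, float(d[GRADE_COLUMN])))
    return records


def feature_matrix(records: Sequence[GradedRecord],
                   feature_ids: Sequence[str]) -> np.ndarray:
    X = np.zeros((len(records), len(feature_ids)))
    for i, r in enumerate(records):
        for j, fid in enumerate(feature_ids):
            if fid in r.features.present:
                X[i, j] = 1.0
    return X


# -- stage 1: feature filtering --------------------------------------------

def filter_features(records: Sequence[GradedRecord], min_count: int = 5,
                    vocab: FeatureVocabulary | None = None
                    ) -> tuple[list[str], dict[str, str]]:
    """Split the vocabulary into trainable and excluded features.

    A feature is retained iff it occurs at least ``min_count`` times across
    the records, is not a severe pattern (scored a priori at the maximum) and
    is not the seizure indicator (tautologically tied to the clinical grade).
    """
    if not records:
        raise ValueError("no records")
    vocab = vocab or default_vocabulary()
    counts = {fid: 0 for fid in vocab.ids}
    for r in records:
        for fid in r.features.present:
            counts[fid] += 1
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for f in vocab:
        if f.severe:
            excluded[f.id] = "severe a-priori"
        elif f.id == SEIZURE_ID:
            excluded[f.id] = "seizure indicator (direct grade correlate)"
        elif counts[f.id] < min_count:
            excluded[f.id] = (f"prevalence {counts[f.id]} < {min_count}")
        else:
            retained.append(f.id)
    return retained, excluded


# -- stage 2: pair expansion -----------------------------------------------

def make_pairs(records: Sequence[GradedRecord]) -> list[RankedPair]:
    """All unordered record pairs with unequal grades, oriented higher-first.

    The pair count obeys C(n,2) - sum_g C(n_g,2) where n_g counts records at
    grade g; exact ties carry no ranking information and are dropped.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to form pairs")
    grades = np.array([r.grade for r in records])
    a, b = np.triu_indices(len(records), k=1)
    gt = grades[a] > grades[b]
    lt = grades[a] < grades[b]
    pairs = [RankedPair(int(h), int(l)) for h, l in
             zip(np.concatenate([a[gt], b[lt]]),
                 np.concatenate([b[gt], a[lt]]))]
    if not pairs:
        warnings.warn("all grades equal: no informative pairs", stacklevel=2)
    return pairs


def pair_diff_matrix(X: np.ndarray, pairs: Sequence[RankedPair]) -> np.ndarray:
    """Feature-difference matrix (higher minus lower), one row per pair."""
    hi = np.fromiter((p.hi for p in pairs), dtype=int, count=len(pairs))
    lo = np.fromiter((p.lo for p in pairs), dtype=int, count=len(pairs))
    return X[hi] - X[lo]


def pairwise_accuracy(dX: np.ndarray, w: np.ndarray) -> float:
    """Fraction of pairs ranked correctly; zero margins count one half."""
    if len(dX) == 0:
        return float("nan")
    m = dX @ w
    return float(np.mean((m > 0) + 0.5 * (m == 0)))


# -- stage 3: constrained ElasticNet logistic ranking fit -------------------

def constraints_from_vocab(feature_ids: Sequence[str],
                           vocab: FeatureVocabulary | None = None
                           ) -> ConstraintSpec:
    """Sign and ordinal constraints for the given retained features."""
    vocab = vocab or default_vocabulary()
    idx = {fid: j for j, fid in enumerate(feature_ids)}
    signs = np.array([1.0 if vocab[f].polarity == "abnormal" else -1.0
                      for f in feature_ids])
    ordinal: list[tuple[int, int]] = []
    for members in vocab.ordinal_groups().values():
        present = [m for m in members if m in idx]
        for lo_f, hi_f in zip(present, present[1:]):
            ordinal.append((idx[lo_f], idx[hi_f]))
    return ConstraintSpec(signs=signs, ordinal=ordinal)


def _ranking_objective(dX: np.ndarray, lam: float, alpha: float,
                       signs: np.ndarray | None,
                       sample_weight: np.ndarray | None):
    n = len(dX)
    if sample_weight is None:
        wts = np.full(n, 1.0 / n)
    else:
        wts = np.asarray(sample_weight, dtype=float)
        wts = wts / wts.sum()

    def fun(w):
        m = dX @ w
        loss = float(wts @ np.logaddexp(0.0, -m))
        pen = lam * (1 - alpha) / 2.0 * float(w @ w)
        if alpha > 0:
            pen += lam * alpha * float(signs @ w)  # == lam*a*|w|_1 in-cone
        return loss + pen

    def grad(w):
        m = dX @ w
        sig = 1.0 / (1.0 + np.exp(np.clip(m, -700, 700)))   # sigmoid(-m)
        g = -(dX.T @ (wts * sig)) + lam * (1 - alpha) * w
        if alpha > 0:
            g = g + lam * alpha * signs
        return g

    return fun, grad


def fit_ranker(dX: np.ndarray, constraints: ConstraintSpec,
               lam: float = 1e-2, alpha: float = 0.5,
               sample_weight: np.ndarray | None = None,
               tol: float = 1e-10) -> np.ndarray:
    """Minimise the penalised logistic ranking loss under the linear
    constraint polyhedron.  Deterministic: cold start at zero.
    """
    if len(dX) == 0:
        raise ValueError("no pairs to fit")
    p = dX.shape[1]
    if alpha > 0 and not constraints.enforce_sign:
        raise RankingConstraintError(
            "the L1 term requires sign constraints (it is linearised as "
            "signs @ w); use alpha=0 for an unconstrained fit")
    fun, grad = _ranking_objective(dX, lam, alpha,
                                   constraints.signs, sample_weight)
    cons = []
    if constraints.enforce_sign:
        S = np.diag(constraints.signs)
        cons.append({"type": "ineq", "fun": lambda w: S @ w,
                     "jac": lambda w: S})
    if constraints.ordinal:
        A = np.zeros((len(constraints.ordinal), p))
        for k, (i, j) in enumerate(constraints.ordinal):
            A[k, i] = 1.0
            A[k, j] = -1.0
        cons.append({"type": "ineq", "fun": lambda w: A @ w,
                     "jac": lambda w: A})
    res = minimize(fun, np.zeros(p), jac=grad, method="SLSQP",
                   constraints=cons,
                   options={"maxiter": 500, "ftol": tol})
    if not res.success:
        raise RankingConstraintError(
            f"ranking fit did not converge: {res.message} "
            f"(nit={res.nit}, fun={res.fun:.6g})")
    w = res.x
    # snap constraint-boundary noise to exact feasibility
    if constraints.enforce_sign:
        w = np.where(constraints.signs * w < 0, 0.0, w)
    for i, j in constraints.ordinal:
        if w[i] < w[j]:
            w[i] = w[j] = 0.5 * (w[i] + w[j])
    return w


# -- stage 4: integerisation -----------------------------------------------

def _repair_feasibility(c: np.ndarray, constraints: ConstraintSpec
                        ) -> np.ndarray:
    c = c.astype(int).copy()
    if constraints.enforce_sign:
        c[(constraints.signs > 0) & (c < 0)] = 0
        c[(constraints.signs < 0) & (c > 0)] = 0
    # ordinal chains run low->high frequency; enforce monotone non-increase
    for i, j in constraints.ordinal:
        if c[i] < c[j]:
            c[j] = c[i]
    return c


def _is_feasible(c: np.ndarray, constraints: ConstraintSpec) -> bool:
    if constraints.enforce_sign and np.any(constraints.signs * c < 0):
        return False
    return all(c[i] >= c[j] for i, j in constraints.ordinal)


def integerize(w: np.ndarray, dX: np.ndarray, constraints: ConstraintSpec,
               search_radius: int = 2, target_max_points: int = 10
               ) -> np.ndarray:
    """Turn real coefficients into bedside point values.

    Already-integer feasible input is a fixed point.  Otherwise the vector is
    scaled so its largest magnitude maps to ``target_max_points``, rounded,
    repaired to feasibility, and improved by greedy +/-1 coordinate moves
    within ``search_radius`` of the rounded point, maximising pairwise
    ranking accuracy with ties broken toward smaller absolute point values.
    """
    w = np.asarray(w, dtype=float)
    if np.allclose(w, np.round(w)) and _is_feasible(
            np.round(w).astype(int), constraints):
        return np.round(w).astype(int)
    peak = np.max(np.abs(w))
    scaled = w * (target_max_points / peak) if peak > 0 else w
    base = np.round(scaled).astype(int)
    c = _repair_feasibility(base, constraints)

    def key(v):
        return (pairwise_accuracy(dX, v.astype(float)),
                -int(np.abs(v).sum()))

    best = c
    best_key = key(best)
    improved = True
    while improved:
        improved = False
        for j in range(len(best)):
            for step in (-1, 1):
                cand = best.copy()
                cand[j] += step
                if abs(cand[j] - base[j]) > search_radius:
                    continue
                if not _is_feasible(cand, constraints):
                    continue
                k = key(cand)
                if k > best_key:
                    best, best_key = cand, k
                    improved = True
    return best


# -- stage 5: end-to-end training ------------------------------------------

def _select_lambda(records, X, retained, constraints, config: TrainConfig
                   ) -> tuple[float, dict]:
    """Grouped, grade-stratified inner CV over the penalty grid, scored by
    held-out pairwise ranking accuracy; ties prefer stronger regularisation."""
    from .evaluation import assign_folds   # local import: avoids a cycle

    folds = assign_folds(records, k=config.inner_folds, seed=config.seed)
    grid_scores: dict[float, list[float]] = {l: [] for l in config.lambda_grid}
    for fold in sorted(set(folds.values())):
        tr_idx = [i for i, r in enumerate(records)
                  if folds[r.subject_id] != fold]
        va_idx = [i for i, r in enumerate(records)
                  if folds[r.subject_id] == fold]
        if len(tr_idx) < 2 or len(va_idx) < 2:
            continue
        tr_pairs = make_pairs([records[i] for i in tr_idx])
        va_pairs = make_pairs([records[i] for i in va_idx])
        if not tr_pairs or not va_pairs:
            continue
        dX_tr = pair_diff_matrix(X[tr_idx], tr_pairs)
        dX_va = pair_diff_matrix(X[va_idx], va_pairs)
        for lam in config.lambda_grid:
            w = fit_ranker(dX_tr, constraints, lam=lam, alpha=config.alpha)
            grid_scores[lam].append(pairwise_accuracy(dX_va, w))
    means = {l: (float(np.mean(v)) if v else float("-inf"))
             for l, v in grid_scores.items()}
    best = max(config.lambda_grid, key=lambda l: (means[l], l))
    return best, {f"{l:g}": means[l] for l in config.lambda_grid}


def train(records: Sequence[GradedRecord],
          config: TrainConfig | None = None,
          vocab: FeatureVocabulary | None = None
          ) -> tuple[ScoringTable, RankingFit]:
    """Derive an integer scoring table from graded patient-days.

    Pipeline: min-prevalence feature filter -> pair expansion over non-severe
    days -> constrained ElasticNet logistic ranking fit (penalty chosen by
    grouped inner CV when the grid has more than one value) -> integerisation
    -> table assembly with the severe set and auto maximal score attached.
    """
    config = config or TrainConfig()
    vocab = vocab or default_vocabulary()
    retained, excluded = filter_features(records, config.min_count, vocab)
    severe_ids = set(vocab.severe_ids())
    trainable = [r for r in records if not r.is_severe(severe_ids)]
    if len(trainable) < 2:
        raise ValueError("no informative pairs: fewer than 2 non-severe days")
    pairs = make_pairs(trainable)
    if not pairs:
        raise ValueError("no informative pairs: all grades equal")
    X = feature_matrix(trainable, retained)
    constraints = constraints_from_vocab(retained, vocab)

    if len(config.lambda_grid) > 1:
        lam, lambda_path = _select_lambda(trainable, X, retained,
                                          constraints, config)
    else:
        lam, lambda_path = config.lambda_grid[0], {}

    weights = None
    if config.weight_pairs_by_subject:
        n_days = {r.subject_id: 0 for r in trainable}
        for r in trainable:
            n_days[r.subject_id] += 1
        weights = np.array([
            1.0 / (n_days[trainable[p.hi].subject_id]
                   * n_days[trainable[p.lo].subject_id])
            for p in pairs])

    dX = pair_diff_matrix(X, pairs)
    w = fit_ranker(dX, constraints, lam=lam, alpha=config.alpha,
                   sample_weight=weights)
    c = integerize(w, dX, constraints,
                   search_radius=config.search_radius,
                   target_max_points=config.target_max_points)

    table = ScoringTable(
        coefficients={fid: int(ci) for fid, ci in zip(retained, c)
                      if ci != 0},
        severe=severe_ids,
        max_score=None,
        provenance=(f"trained on {len(records)} patient-days "
                    f"({len(pairs)} pairs), lambda={lam:g}, "
                    f"alpha={config.alpha:g}"),
        vocabulary_version=vocab.version,
    )
    fit = RankingFit(
        retained=list(retained),
        excluded=excluded,
        real_coefficients={fid: float(wi) for fid, wi in zip(retained, w)},
        integer_coefficients={fid: int(ci) for fid, ci in zip(retained, c)},
        hyperparameters={
            "lambda": lam, "alpha": config.alpha,
            "min_count": config.min_count,
            "search_radius": config.search_radius,
            "target_max_points": config.target_max_points,
            "seed": config.seed,
            "lambda_path": lambda_path,
        },
        diagnostics={
            "n_records": len(records),
            "n_trainable": len(trainable),
            "n_pairs": len(pairs),
            "pairwise_accuracy_real": pairwise_accuracy(dX, w),
            "pairwise_accuracy_integer": pairwise_accuracy(
                dX, c.astype(float)),
        },
    )
    return table, fit
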