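"""Generalized multifactor dimensionality reduction (GMDR) for binary traits.

GMDR screens combinations of categorical factors (SNP genotypes, binary
exposures) for joint association with a binary outcome while adjusting for
covariates.  The construction:

1.  Fit a covariate-only ("null") logistic model and take the score
    residual ``s_i = y_i - p_hat_i`` for each subject.  With an intercept
    the residuals sum to zero, so positive residuals mark subjects more
    affected than their covariates predict.
2.  For a candidate factor combination, partition subjects into the cells
    of the factor cross-classification.  A cell is labelled *high risk*
    when the mean training residual is positive (ties go to low risk),
    *low risk* when non-positive, *unclassifiable* when no training
    subject falls in it.
3.  Score the labelling on held-out subjects with a residual-weighted
    balanced accuracy: of the total absolute residual mass among
    classifiable test subjects, the fraction that is "correct" (positive
    residuals in high cells plus non-positive residuals in low cells).
4.  K-fold cross-validation (stratified by case status) yields a mean
    testing accuracy per combination, a cross-validation consistency
    (how many folds pick the same combination as training winner), an
    exact sign test on the fold accuracies against 0.5, and optionally a
    permutation test that re-runs the whole construction under shuffled
    case status.

The exhaustive search enumerates all factor subsets of each size and
reports the best per size, mirroring the one- to five-factor screens of
classical GMDR software.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import LogisticFit, fit_logistic
from .cohort import DEFAULT_COVARIATES, CohortTable
from .errors import ConfigurationError, ParameterError, UndefinedStatisticError
from .descriptives import TestResult

logger = logging.getLogger(__name__)


# -- score residuals --------------------------------------------------------


@dataclass
class ScoreVector:
    """Per-subject score residuals from the covariate-only null model.

    ``scores`` is aligned with the cohort row index; subjects dropped for
    missing covariates have NaN scores and are excluded downstream.
    """

    scores: pd.Series
    null_model: LogisticFit


def compute_score_residuals(
    table: CohortTable, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> ScoreVector:
    """Score residual ``y - p_hat`` from a covariate-only logistic model.

    With an empty covariate list the null model is intercept-only and every
    case scores ``1 - n_cases/n`` while every control scores ``-n_cases/n``.
    """
    y = table.status.astype(float)
    design = table.data[list(covariates)].astype(float) if covariates else (
        pd.DataFrame(index=table.data.index)
    )
    fit = fit_logistic(y, design)
    X = design.copy()
    X.insert(0, "const", 1.0)
    keep = X.notna().all(axis=1)
    eta = X.loc[keep].to_numpy() @ fit.params.to_numpy()
    p_hat = 1.0 / (1.0 + np.exp(-eta))
    scores = pd.Series(np.nan, index=table.data.index, name="score")
    scores[keep] = y[keep].to_numpy() - p_hat
    return ScoreVector(scores=scores, null_model=fit)


# -- factor coding ----------------------------------------------------------


def factor_matrix(
    table: CohortTable,
    snp_factors: Sequence[str] = (),
    env_factors: Sequence[str] = (),
) -> pd.DataFrame:
    """Integer-coded factor matrix for the GMDR search.

    SNPs enter as 3-level codominant factors (risk-allele count 0/1/2),
    binary clinical factors as 2-level; missing values stay NaN and the
    affected subjects are dropped per combination.
    """
    cols = {}
    for snp in snp_factors:
        cols[snp] = table.encode_genotype(snp, "additive")
    for env in env_factors:
        if env not in table.data.columns:
            raise ConfigurationError(f"factor {env!r} not in cohort")
        vals = table.data[env].astype(float)
        levels = set(vals.dropna().unique())
        if not levels <= {0.0, 1.0}:
            raise ConfigurationError(
                f"environmental factor {env!r} must be binary 0/1; "
                f"saw levels {sorted(levels)}"
            )
        cols[env] = vals
    return pd.DataFrame(cols, index=table.data.index)


def _codes(factors: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(n_subjects x n_factors int codes with -1 missing, levels per factor)."""
    arr = factors.to_numpy(dtype=float)
    codes = np.where(np.isnan(arr), -1, arr).astype(np.int64)
    n_levels = np.where(codes.max(axis=0) >= 0, codes.max(axis=0) + 1, 1)
    return codes, n_levels.astype(np.int64)


# -- cross-validation folds -------------------------------------------------


def assign_cv_folds(
    status: Sequence[int], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each subject a fold index in 0..k-1, stratified by status.

    Within each stratum fold sizes differ by at most one.  Deterministic
    for a given generator state.
    """
    status = np.asarray(status)
    if k < 2:
        raise ParameterError("k must be at least 2")
    folds = np.empty(len(status), dtype=np.int64)
    for level in np.unique(status):
        idx = np.flatnonzero(status == level)
        if len(idx) < k:
            raise ParameterError(
                f"stratum status={level} has {len(idx)} subjects < k={k}"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


# -- cell labelling and accuracy -------------------------------------------


@dataclass
class CellPartition:
    """High/low-risk labelling of the factor cross-classification.

    ``high`` and ``trained`` are flat arrays over the mixed-radix cell
    index; cells with no training member are unclassifiable.
    """

    factors: tuple[str, ...]
    n_levels: np.ndarray
    high: np.ndarray  # bool per cell
    trained: np.ndarray  # bool per cell
    cell_sum: np.ndarray
    cell_count: np.ndarray

    def cells(self) -> dict[tuple[int, ...], str]:
        """Human-readable mapping from level tuples to labels."""
        out = {}
        for flat in range(len(self.high)):
            levels = np.unravel_index(flat, tuple(self.n_levels))
            if not self.trained[flat]:
                label = "unclassifiable"
            else:
                label = "high" if self.high[flat] else "low"
            out[tuple(int(v) for v in levels)] = label
        return out


def _flat_index(codes: np.ndarray, n_levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-radix cell index per subject; invalid (missing) rows flagged."""
    valid = (codes >= 0).all(axis=1)
    idx = np.zeros(len(codes), dtype=np.int64)
    stride = 1
    for j in range(codes.shape[1]):
        idx += np.where(valid, codes[:, j], 0) * stride
        stride *= int(n_levels[j])
    return idx, valid


def label_cells(
    codes: np.ndarray,
    n_levels: np.ndarray,
    scores: np.ndarray,
    train_mask: np.ndarray,
    threshold: float = 0.0,
    factors: tuple[str, ...] = (),
) -> CellPartition:
    """Label each factor-combination cell high/low risk from training scores.

    A cell is high risk iff its mean training score exceeds ``threshold``
    (exact ties are low risk); cells without training members are
    unclassifiable.
    """
    if not train_mask.any():
        raise ParameterError("empty training set")
    idx, valid = _flat_index(codes, n_levels)
    use = train_mask & valid & ~np.isnan(scores)
    n_cells = int(np.prod(n_levels))
    cell_sum = np.bincount(idx[use], weights=scores[use], minlength=n_cells)
    cell_count = np.bincount(idx[use], minlength=n_cells)
    trained = cell_count > 0
    with np.errstate(invalid="ignore"):
        mean = np.where(trained, cell_sum / np.maximum(cell_count, 1), 0.0)
    high = trained & (mean > threshold)
    return CellPartition(
        factors=factors,
        n_levels=n_levels,
        high=high,
        trained=trained,
        cell_sum=cell_sum,
        cell_count=cell_count,
    )


def score_weighted_accuracy(
    codes: np.ndarray,
    partition: CellPartition,
    scores: np.ndarray,
    eval_mask: np.ndarray,
) -> float:
    """Residual-mass-weighted balanced accuracy of a labelled partition.

    Over evaluation subjects in classifiable cells: correct mass is
    ``sum |s_i|`` for positive scores in high cells plus ``sum |s_i|`` for
    non-positive scores in low cells; accuracy = correct mass / total mass.
    Subjects in unclassifiable cells (or with missing factors/scores) are
    excluded from numerator and denominator.
    """
    idx, valid = _flat_index(codes, partition.n_levels)
    use = eval_mask & valid & ~np.isnan(scores)
    use &= partition.trained[idx]
    if not use.any():
        raise UndefinedStatisticError("no classifiable subjects in evaluation set")
    s = scores[use]
    hi = partition.high[idx[use]]
    mass = np.abs(s)
    correct = mass[(s > 0) & hi].sum() + mass[(s <= 0) & ~hi].sum()
    total = mass.sum()
    if total == 0:
        raise UndefinedStatisticError("all evaluation scores are zero")
    return float(min(1.0, max(0.0, correct / total)))


# -- per-combination evaluation --------------------------------------------


@dataclass
class GmdrFoldResult:
    fold_index: int
    training_accuracy: float
    testing_accuracy: float


@dataclass
class GmdrModelResult:
    """Cross-validated evaluation of one factor combination."""

    factors: tuple[str, ...]
    fold_results: list[GmdrFoldResult]
    mean_testing_accuracy: float
    p_sign: float
    cvc: int | None = None
    k_folds: int = 10
    p_perm: float | None = None
    n_used: int = 0

    @property
    def cvc_label(self) -> str:
        return f"{self.cvc}/{self.k_folds}" if self.cvc is not None else "NA"


def sign_test(fold_accuracies: Sequence[float], null_value: float = 0.5) -> TestResult:
    """Exact one-sided sign test on cross-validation fold accuracies.

    Counts folds with accuracy strictly above ``null_value`` (ties count
    against the alternative) and returns the upper tail of
    Binomial(K, 1/2) at that count.
    """
    acc = np.asarray(fold_accuracies, dtype=float)
    if len(acc) < 1:
        raise ParameterError("need at least one fold accuracy")
    k_plus = int((acc > null_value).sum())
    p = float(stats.binom.sf(k_plus - 1, len(acc), 0.5))
    return TestResult(float(k_plus), float(len(acc)), p, "exact sign test")


def evaluate_combination(
    factors: pd.DataFrame,
    combination: Sequence[str],
    scores: ScoreVector | pd.Series,
    folds: np.ndarray,
    threshold: float = 0.0,
) -> GmdrModelResult:
    """K-fold cross-validated GMDR evaluation of one factor combination."""
    names = tuple(combination)
    if not names:
        raise ParameterError("need at least one factor")
    score_arr = (
        scores.scores if isinstance(scores, ScoreVector) else scores
    ).to_numpy(dtype=float)
    codes, n_levels = _codes(factors[list(names)])
    k = int(folds.max()) + 1
    fold_results = []
    for j in range(k):
        train = folds != j
        part = label_cells(codes, n_levels, score_arr, train, threshold, names)
        train_acc = score_weighted_accuracy(codes, part, score_arr, train)
        test_acc = score_weighted_accuracy(codes, part, score_arr, ~train)
        fold_results.append(GmdrFoldResult(j, train_acc, test_acc))
    accs = [f.testing_accuracy for f in fold_results]
    valid = ((codes >= 0).all(axis=1) & ~np.isnan(score_arr)).sum()
    return GmdrModelResult(
        factors=names,
        fold_results=fold_results,
        mean_testing_accuracy=float(np.mean(accs)),
        p_sign=sign_test(accs).p_value,
        k_folds=k,
        n_used=int(valid),
    )


# -- exhaustive search ------------------------------------------------------


@dataclass
class GmdrSearchResult:
    """Best model per size plus the full evaluation grid."""

    best_per_size: dict[int, GmdrModelResult]
    all_models: dict[int, list[GmdrModelResult]] = field(default_factory=dict)

    @property
    def best_model(self) -> GmdrModelResult:
        return max(
            self.best_per_size.values(), key=lambda m: m.mean_testing_accuracy
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for size in sorted(self.best_per_size):
            m = self.best_per_size[size]
            rows.append(
                {
                    "n_factors": size,
                    "model": ", ".join(m.factors),
                    "testing_accuracy": m.mean_testing_accuracy,
                    "cvc": m.cvc_label,
                    "p_sign": m.p_sign,
                    "p_perm": m.p_perm if m.p_perm is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def search_models(
    factors: pd.DataFrame,
    scores: ScoreVector | pd.Series,
    folds: np.ndarray,
    k_min: int = 1,
    k_max: int = 5,
    threshold: float = 0.0,
) -> GmdrSearchResult:
    """Exhaustive GMDR search over factor subsets of sizes k_min..k_max.

    Per size, every subset is cross-validated; the subset with the highest
    mean testing accuracy wins (ties broken by lexicographic factor order,
    logged).  Its cross-validation consistency (CVC) is the number of
    folds in which it also attains the best *training* accuracy among
    same-size subsets.
    """
    candidates = sorted(factors.columns)
    if not candidates:
        raise ConfigurationError("candidate factor list is empty")
    if k_max > len(candidates):
        raise ParameterError(
            f"k_max={k_max} exceeds the {len(candidates)} candidate factors"
        )
    best_per_size: dict[int, GmdrModelResult] = {}
    all_models: dict[int, list[GmdrModelResult]] = {}
    for size in range(k_min, k_max + 1):
        evaluated = [
            evaluate_combination(factors, combo, scores, folds, threshold)
            for combo in itertools.combinations(candidates, size)
        ]
        all_models[size] = evaluated
        best_acc = max(m.mean_testing_accuracy for m in evaluated)
        winners = [m for m in evaluated if m.mean_testing_accuracy == best_acc]
        if len(winners) > 1:
            logger.info(
                "size %d: %d models tied at accuracy %.4f; keeping %s",
                size, len(winners), best_acc, winners[0].factors,
            )
        winner = winners[0]  # combinations() yields lexicographic order
        k = winner.k_folds
        train_matrix = np.array(
            [[f.training_accuracy for f in m.fold_results] for m in evaluated]
        )
        winner_row = evaluated.index(winner)
        winner.cvc = int(
            (train_matrix[winner_row] >= train_matrix.max(axis=0) - 1e-12).sum()
        )
        best_per_size[size] = winner
    return GmdrSearchResult(best_per_size=best_per_size, all_models=all_models)


# -- permutation test -------------------------------------------------------


def permutation_test(
    table: CohortTable,
    combination: Sequence[str],
    snp_factors: Sequence[str],
    env_factors: Sequence[str],
    covariates: Sequence[str],
    k: int,
    n_permutations: int,
    rng: np.random.Generator,
    threshold: float = 0.0,
    observed_accuracy: float | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for one combination's mean testing accuracy.

    Each replicate shuffles case/control status over subjects, refits the
    covariate-only null model on the permuted outcome (preserving
    covariate structure under the null), reassigns stratified folds and
    re-evaluates the combination.  ``p = (1 + #{perm >= observed}) /
    (B + 1)``.

    Returns the p-value and the permuted accuracy distribution.
    """
    if n_permutations < 1:
        raise ParameterError("need at least one permutation")
    factors = factor_matrix(
        table,
        [f for f in snp_factors if f in combination],
        [f for f in env_factors if f in combination],
    )
    if observed_accuracy is None:
        scores = compute_score_residuals(table, covariates)
        folds = assign_cv_folds(table.status.to_numpy(), k, rng)
        observed_accuracy = evaluate_combination(
            factors, combination, scores, folds, threshold
        ).mean_testing_accuracy
    df = table.data
    perm_acc = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted = df.copy()
        permuted["status"] = rng.permutation(df["status"].to_numpy())
        perm_table = CohortTable(permuted, list(table.snps.values()))
        scores_b = compute_score_residuals(perm_table, covariates)
        folds_b = assign_cv_folds(perm_table.status.to_numpy(), k, rng)
        perm_acc[b] = evaluate_combination(
            factors, combination, scores_b, folds_b, threshold
        ).mean_testing_accuracy
    p = (1.0 + (perm_acc >= observed_accuracy).sum()) / (n_permutations + 1.0)
    return float(p), perm_acc
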