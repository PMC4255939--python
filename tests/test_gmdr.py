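"""GMDR: score residuals, folds, cell labelling, accuracy, search, tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gxescreen.cohort import CohortTable, DEFAULT_COVARIATES
from gxescreen.errors import ParameterError, UndefinedStatisticError
from gxescreen.gmdr import (
    _codes,
    assign_cv_folds,
    compute_score_residuals,
    evaluate_combination,
    factor_matrix,
    label_cells,
    permutation_test,
    score_weighted_accuracy,
    search_models,
    sign_test,
)
from gxescreen.simulate import generate_cohort, study_config

from conftest import RS10757274


class TestScoreResiduals:
    def test_intercept_only_closed_form(self, study_cohort):
        sv = compute_score_residuals(study_cohort, covariates=[])
        frac = study_cohort.n_cases / len(study_cohort)
        cases = sv.scores[study_cohort.status == 1]
        controls = sv.scores[study_cohort.status == 0]
        assert np.allclose(cases, 1 - frac, atol=1e-6)
        assert np.allclose(controls, -frac, atol=1e-6)

    def test_scores_sum_to_zero_with_covariates(self, study_cohort):
        sv = compute_score_residuals(study_cohort, DEFAULT_COVARIATES)
        assert abs(sv.scores.sum()) < 1e-6

    def test_adjustment_shrinks_planted_covariate_separation(self):
        config = study_config(11)
        config.disease_model.terms["age"] = 0.08  # strong age effect
        table = generate_cohort(config)
        status = table.status
        raw = compute_score_residuals(table, covariates=[]).scores
        adj = compute_score_residuals(table, covariates=["age"]).scores

        def gap(scores):
            return scores[status == 1].mean() - scores[status == 0].mean()

        assert gap(adj) < gap(raw)


class TestFolds:
    def test_stratified_sizes_and_determinism(self, study_cohort):
        status = study_cohort.status.to_numpy()
        folds = assign_cv_folds(status, 10, np.random.default_rng(5))
        again = assign_cv_folds(status, 10, np.random.default_rng(5))
        assert (folds == again).all()
        for level in (0, 1):
            sizes = np.bincount(folds[status == level], minlength=10)
            assert sizes.max() - sizes.min() <= 1

    def test_k_exceeding_stratum_rejected(self):
        status = np.r_[np.ones(5), np.zeros(100)]
        with pytest.raises(ParameterError):
            assign_cv_folds(status, 10, np.random.default_rng(0))


def _factors_from_arrays(**cols):
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})


class TestCellLabelling:
    def test_sign_rule_on_binary_factor(self):
        factors = _factors_from_arrays(f=[0, 0, 1, 1])
        codes, n_levels = _codes(factors)
        scores = np.array([0.3, 0.1, -0.2, 0.0])  # means (+0.2, -0.1)
        part = label_cells(codes, n_levels, scores, np.ones(4, bool))
        assert part.cells() == {(0,): "high", (1,): "low"}

    def test_tie_labels_low(self):
        factors = _factors_from_arrays(f=[0, 0, 1, 1])
        codes, n_levels = _codes(factors)
        part = label_cells(codes, n_levels, np.zeros(4), np.ones(4, bool))
        assert set(part.cells().values()) == {"low"}

    def test_two_snp_partition_covers_training_set(self):
        rng = np.random.default_rng(0)
        factors = _factors_from_arrays(
            a=rng.integers(0, 3, 60), b=rng.integers(0, 3, 60)
        )
        codes, n_levels = _codes(factors)
        part = label_cells(
            codes, n_levels, rng.normal(size=60), np.ones(60, bool)
        )
        assert len(part.cells()) == 9
        assert part.cell_count.sum() == 60

    def test_empty_training_set_rejected(self):
        factors = _factors_from_arrays(f=[0, 1])
        codes, n_levels = _codes(factors)
        with pytest.raises(ParameterError):
            label_cells(codes, n_levels, np.zeros(2), np.zeros(2, bool))


def _brute_force_accuracy(levels, labels, scores):
    """Independent re-computation of the weighted accuracy formula."""
    p = n = d = 0.0
    for level, s in zip(levels, scores):
        if labels.get(level) is None:
            continue
        d += abs(s)
        if s > 0 and labels[level] == "high":
            p += abs(s)
        elif s <= 0 and labels[level] == "low":
            n += abs(s)
    return (p + n) / d


class TestAccuracy:
    def test_perfect_separation_scores_one(self):
        factors = _factors_from_arrays(f=[0, 0, 1, 1, 0, 1])
        codes, n_levels = _codes(factors)
        scores = np.array([0.5, 0.2, -0.3, -0.1, 0.4, -0.2])
        mask = np.ones(6, bool)
        part = label_cells(codes, n_levels, scores, mask)
        assert score_weighted_accuracy(codes, part, scores, mask) == 1.0

    def test_six_subject_enumeration_matches_brute_force(self):
        levels = [0, 0, 1, 1, 2, 2]
        train_scores = np.array([0.2, 0.1, -0.4, 0.1, 0.0, 0.0])
        test_scores = np.array([0.15, -0.05, -0.2, 0.3, 0.1, -0.6])
        factors = _factors_from_arrays(f=levels + levels)
        codes, n_levels = _codes(factors)
        scores = np.r_[train_scores, test_scores]
        train = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        part = label_cells(codes, n_levels, scores, train)
        got = score_weighted_accuracy(codes, part, scores, ~train)
        labels = {0: "high", 1: "low", 2: "low"}  # means (+0.15, -0.15, 0)
        expected = _brute_force_accuracy(levels, labels, test_scores)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_labels_independent_of_scores_give_half(self):
        rng = np.random.default_rng(1)
        n = 200_000
        factors = _factors_from_arrays(f=rng.integers(0, 2, n))
        codes, n_levels = _codes(factors)
        scores = rng.normal(size=n)  # symmetric, independent of the factor
        train = rng.random(n) < 0.5
        part = label_cells(codes, n_levels, scores, train)
        acc = score_weighted_accuracy(codes, part, scores, ~train)
        assert acc == pytest.approx(0.5, abs=0.01)

    def test_no_classifiable_subjects_rejected(self):
        factors = _factors_from_arrays(f=[0, 1])
        codes, n_levels = _codes(factors)
        part = label_cells(
            codes, n_levels, np.array([0.5, -0.5]), np.array([True, False])
        )
        with pytest.raises(UndefinedStatisticError):
            # the held-out subject falls in an untrained cell
            score_weighted_accuracy(
                codes, part, np.array([0.5, -0.5]), np.array([False, True])
            )


class TestSignTest:
    @pytest.mark.parametrize(
        "k_above, expected",
        [(10, 0.0010), (9, 0.0107), (8, 0.0547)],
    )
    def test_published_binomial_tails(self, k_above, expected):
        accs = [0.6] * k_above + [0.4] * (10 - k_above)
        assert sign_test(accs).p_value == pytest.approx(expected, abs=5e-5)

    def test_exhaustive_binomial_tail_oracle(self):
        for k in range(1, 21):
            for k_plus in range(k + 1):
                accs = [0.7] * k_plus + [0.3] * (k - k_plus)
                expected = sum(math.comb(k, j) for j in range(k_plus, k + 1)) / 2**k
                assert sign_test(accs).p_value == pytest.approx(expected, abs=1e-12)

    def test_ties_count_against_alternative(self):
        assert sign_test([0.5] * 10).p_value == pytest.approx(1.0)


class TestEvaluateAndSearch:
    def test_constant_factor_gives_majority_mass_accuracy(self, study_cohort):
        sv = compute_score_residuals(study_cohort, covariates=[])
        factors = pd.DataFrame(
            {"const_factor": np.zeros(len(study_cohort))},
            index=study_cohort.data.index,
        )
        folds = assign_cv_folds(
            study_cohort.status.to_numpy(), 10, np.random.default_rng(0)
        )
        result = evaluate_combination(factors, ["const_factor"], sv, folds)
        # single cell labelled low (cases are the majority, scores sum to 0
        # per fold only approximately); accuracy = mass fraction of the
        # labelled side, which is near one half here
        assert 0.4 <= result.mean_testing_accuracy <= 0.6

    def test_search_enumerates_all_subset_sizes(self, study_cohort):
        sv = compute_score_residuals(study_cohort, DEFAULT_COVARIATES)
        factors = factor_matrix(
            study_cohort,
            ["rs10757274", "rs6903956"],
            ["t2dm", "hypertension", "hyperlipidemia"],
        )
        folds = assign_cv_folds(
            study_cohort.status.to_numpy(), 10, np.random.default_rng(1)
        )
        search = search_models(factors, sv, folds, 1, 5)
        assert sorted(search.best_per_size) == [1, 2, 3, 4, 5]
        assert [len(search.all_models[k]) for k in range(1, 6)] == [5, 10, 10, 5, 1]
        for model in search.best_per_size.values():
            assert 0 <= model.cvc <= 10
            for fold in model.fold_results:
                assert fold.training_accuracy >= 0.5  # labelling optimises train
        frame = search.to_frame()
        assert list(frame["n_factors"]) == [1, 2, 3, 4, 5]

    def test_search_winner_matches_independent_enumeration(self):
        table = generate_cohort(study_config(21, n_cases=60, n_controls=40))
        sv = compute_score_residuals(table, covariates=["age", "sex"])
        factors = factor_matrix(
            table, ["rs10757274", "rs6903956"], ["t2dm", "hypertension"]
        )
        folds = assign_cv_folds(table.status.to_numpy(), 5, np.random.default_rng(2))
        search = search_models(factors, sv, folds, 1, 3)
        for size in (1, 2, 3):
            accs = {}
            for combo in itertools.combinations(sorted(factors.columns), size):
                accs[combo] = evaluate_combination(
                    factors, combo, sv, folds
                ).mean_testing_accuracy
            best = max(sorted(accs), key=lambda c: accs[c])
            assert search.best_per_size[size].factors == best

    def test_search_is_deterministic_under_fixed_seed(self, study_cohort):
        sv = compute_score_residuals(study_cohort, DEFAULT_COVARIATES)
        factors = factor_matrix(study_cohort, ["rs10757274"], ["t2dm"])

        def run():
            folds = assign_cv_folds(
                study_cohort.status.to_numpy(), 10, np.random.default_rng(9)
            )
            return search_models(factors, sv, folds, 1, 2)

        a, b = run(), run()
        for size in a.best_per_size:
            assert a.best_per_size[size].factors == b.best_per_size[size].factors
            assert (
                a.best_per_size[size].mean_testing_accuracy
                == b.best_per_size[size].mean_testing_accuracy
            )

    def test_monotone_in_planted_interaction_strength(self):
        """Median pair accuracy rises with the planted joint effect."""
        medians = []
        for extra in (0.0, 1.0, 2.0):
            accs = []
            for seed in range(12):
                config = study_config(800 + seed)
                config.disease_model.terms["rs10757274:t2dm"] += extra
                table = generate_cohort(config)
                sv = compute_score_residuals(table, DEFAULT_COVARIATES)
                factors = factor_matrix(table, ["rs10757274"], ["t2dm"])
                folds = assign_cv_folds(
                    table.status.to_numpy(), 10, np.random.default_rng(seed)
                )
                accs.append(
                    evaluate_combination(
                        factors, ["rs10757274", "t2dm"], sv, folds
                    ).mean_testing_accuracy
                )
            medians.append(float(np.median(accs)))
        assert medians[0] < medians[1] < medians[2]


class TestPermutation:
    def test_planted_interaction_yields_small_p(self):
        table = generate_cohort(study_config(31))
        p, dist = permutation_test(
            table,
            ["rs10757274", "t2dm"],
            ["rs10757274", "rs6903956"],
            ["t2dm"],
            DEFAULT_COVARIATES,
            k=10,
            n_permutations=49,
            rng=np.random.default_rng(0),
        )
        assert len(dist) == 49
        assert 1 / 50 <= p <= 1.0
        assert p <= 0.05

    def test_p_value_lower_bound_is_one_over_b_plus_one(self):
        table = generate_cohort(study_config(32))
        p, _ = permutation_test(
            table,
            ["t2dm"],
            [],
            ["t2dm"],
            [],
            k=5,
            n_permutations=9,
            rng=np.random.default_rng(3),
        )
        assert p >= 1 / 10
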