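import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from roilogit import (
    CohortSpec,
    FittedLogit,
    evaluate,
    fit_logistic,
    generate_feature_table,
    kfold_cv,
    logistic_probability,
    recursive_feature_elimination,
    sidak_adjust,
    split_search,
    stratified_split,
)
from roilogit.classifier_core import _grad, _sigmoid
from roilogit.exceptions import (
    DegenerateOutcomeError,
    FoldError,
    LeakageError,
    ValidationError,
)

from conftest import make_table


def make_model(intercept, coefficients, classes=("control", "case")):
    return FittedLogit(
        classes=list(classes),
        intercept=intercept,
        coefficients=coefficients,
        p_values={},
        p_values_sidak={},
        feature_names=list(coefficients),
        covariates=[],
        training={"training_ids": []},
    )


class TestLogisticProbability:
    def test_all_zero_gives_half(self):
        m = make_model(0.0, {"a": 0.0, "b": 0.0})
        assert logistic_probability(m, {"a": 5.0, "b": -2.0}) == pytest.approx(0.5)

    def test_printed_intercept_at_zero_features(self):
        m = make_model(0.36, {"a": 1.0})
        expected = 1.0 / (1.0 + np.exp(-0.36))
        assert logistic_probability(m, {"a": 0.0}) == pytest.approx(expected, abs=1e-12)

    def test_large_intercept_limit(self):
        m = make_model(500.0, {})
        assert logistic_probability(m, {}) == pytest.approx(1.0)

    def test_missing_feature_named(self):
        m = make_model(0.0, {"region_x": 1.0})
        with pytest.raises(ValidationError, match="region_x"):
            logistic_probability(m, {})

    def test_monotone_in_positive_coefficient(self):
        m = make_model(-1.0, {"a": 0.7, "b": -0.2})
        probs = [logistic_probability(m, {"a": x, "b": 3.0}) for x in (0.0, 1.0, 2.0, 5.0)]
        assert all(q > p for p, q in zip(probs, probs[1:]))


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # x=0: 10 subjects (9 control, 1 case); x=1: 10 subjects (1 control, 9 case)
        counts = np.array([[0]] * 10 + [[1]] * 10)
        groups = ["control"] * 9 + ["case"] + ["control"] + ["case"] * 9
        table = make_table(counts, groups)
        model = fit_logistic(table, features=["Region_001"], covariates=())
        p1 = logistic_probability(model, {"Region_001": 1.0})
        assert p1 == pytest.approx(0.9, abs=1e-3)
        # log-odds difference is log(9) - log(1/9) = 2 log 9
        assert model.coefficients["Region_001"] == pytest.approx(2 * np.log(9), abs=1e-3)

    def test_degenerate_outcome(self):
        table = make_table([[1], [2], [3]], ["case", "case", "case"])
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(table, features=["Region_001"], covariates=())

    def test_gradient_at_optimum(self, small_table):
        model = fit_logistic(small_table, features=small_table.region_names)
        from roilogit.classifier_core import _build_xy

        X, y_raw, _ = _build_xy(small_table, "group", small_table.region_names, model.covariates)
        y = (y_raw == model.positive_class).astype(float)
        beta = np.r_[model.intercept, [model.coefficients[n] for n in (*model.feature_names, *model.covariates)]]
        assert np.max(np.abs(_grad(X, y, beta))) <= 1e-6

    def test_covariates_always_present(self, small_table):
        model = fit_logistic(small_table, features=["Region_001"])
        for cov in ("age", "sex", "bmi"):
            assert cov in model.coefficients

    def test_separation_flagged_but_usable(self):
        counts = np.array([[0]] * 8 + [[50]] * 8)
        groups = ["control"] * 8 + ["case"] * 8
        table = make_table(counts, groups)
        model = fit_logistic(table, features=["Region_001"], covariates=())
        assert model.training["separation_flagged"]
        assert np.isfinite(model.coefficients["Region_001"])
        assert (model.predict(table) == np.array(groups)).all()

    def test_sgd_mode_agrees_with_newton(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 30, size=(40, 2))
        logits = 0.15 * counts[:, 0] - 0.1 * counts[:, 1] - 0.5
        groups = np.where(rng.random(40) < _sigmoid(logits), "case", "control")
        table = make_table(counts, groups)
        newton = fit_logistic(table, features=table.region_names, covariates=())
        sgd = fit_logistic(table, features=table.region_names, covariates=(), method="sgd", seed=1)
        assert sgd.training["method"] == "sgd"
        for name in table.region_names:
            assert sgd.coefficients[name] == pytest.approx(newton.coefficients[name], abs=1e-4)

    def test_pvalues_in_unit_interval(self, small_table):
        model = fit_logistic(small_table, features=["Region_001", "Region_002"])
        for p in model.p_values.values():
            assert 0.0 <= p <= 1.0
        for name, p in model.p_values.items():
            assert model.p_values_sidak[name] >= p - 1e-15

    def test_json_round_trip(self, small_table, tmp_path):
        model = fit_logistic(small_table, features=["Region_001"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedLogit.from_json(path)
        assert back.intercept == pytest.approx(model.intercept)
        assert back.coefficients == model.coefficients

    def test_brute_force_oracle_small_instances(self):
        # independent route: coarse start + derivative-free polish of the
        # negative log-likelihood written from scratch here
        rng = np.random.default_rng(11)
        for trial in range(4):
            n, k = 24, rng.integers(1, 4)
            x = rng.normal(0, 1.0, size=(n, k))
            true_beta = rng.normal(0, 0.8, size=k + 1)
            eta = true_beta[0] + x @ true_beta[1:]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            if y.min() == y.max():
                continue
            counts = np.round(np.abs(x) * 10).astype(int)
            # fit on the raw continuous design through the package path:
            # use the counts table but replace values with scaled ints is lossy,
            # so instead check the package solver on the integer design
            table = make_table(counts, np.where(y == 1, "case", "control"))
            model = fit_logistic(table, features=table.region_names, covariates=())
            X = np.column_stack([np.ones(n), counts.astype(float)])

            def negll(beta):
                eta = X @ beta
                return float(np.logaddexp(0.0, eta).sum() - y @ eta)

            starts = [np.zeros(k + 1)]
            grid = np.linspace(-1, 1, 3)
            starts += [np.r_[g, np.zeros(k)] for g in grid]
            best = None
            for s in starts:
                res = optimize.minimize(
                    negll, s, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 50_000, "maxfev": 50_000},
                )
                if best is None or res.fun < best.fun:
                    best = res
            fitted = np.r_[model.intercept, [model.coefficients[f] for f in table.region_names]]
            np.testing.assert_allclose(fitted, best.x, atol=1e-3)


class TestSidak:
    def test_identity_at_m_one(self):
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_zero_stays_zero(self):
        assert sidak_adjust(0.0, 17) == 0.0

    def test_closed_form_m29(self):
        assert sidak_adjust(0.01, 29) == pytest.approx(1 - 0.99**29, abs=1e-12)
        assert sidak_adjust(0.01, 29) == pytest.approx(0.25283, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sidak_adjust(1.5, 3)
        with pytest.raises(ValidationError):
            sidak_adjust(0.5, 0)

    @settings(max_examples=80, deadline=None)
    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 200))
    def test_bounds_property(self, p, m):
        adj = sidak_adjust(p, m)
        assert adj >= p - 1e-12                      # never smaller than raw
        assert adj <= min(1.0, m * p) + 1e-9         # Bonferroni dominance


class TestStratifiedSplit:
    def test_table1_class_sizes_at_70_30(self):
        labels = np.array(["case"] * 80 + ["control"] * 31)
        tr, te = stratified_split(labels, 0.7, seed=0)
        assert len(tr) == 78
        assert (labels[tr] == "case").sum() == 56
        assert (labels[tr] == "control").sum() == 22
        assert len(te) == 33

    def test_infeasible_tiny_split(self):
        labels = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValidationError):
            stratified_split(labels, 0.9, seed=0)

    def test_deterministic_given_seed(self):
        labels = np.array(["case"] * 30 + ["control"] * 20)
        a = stratified_split(labels, 0.7, seed=3)
        b = stratified_split(labels, 0.7, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_partition_is_exact(self):
        labels = np.array(["x"] * 13 + ["y"] * 9)
        tr, te = stratified_split(labels, 0.6, seed=1)
        assert sorted(np.r_[tr, te].tolist()) == list(range(22))


class TestSplitSearch:
    def test_infeasible_ratios_skipped_with_warning(self, balanced_table):
        sub = balanced_table.subset(balanced_table.subject_ids[:4] + balanced_table.subject_ids[-4:])
        with pytest.warns(UserWarning, match="skipped"):
            result = split_search(sub, ratios=(0.5, 0.9), n_repeats=3, seed=0)
        assert 0.9 not in result.accuracies

    def test_chosen_ratio_is_feasible_argmax(self, small_table):
        result = split_search(small_table, features=["Region_001"], ratios=(0.6, 0.7), n_repeats=4, seed=1)
        assert result.chosen_ratio in (0.6, 0.7)
        best = result.results.loc[result.results["mean_accuracy"].idxmax()]
        assert result.results[result.results["ratio"] == result.chosen_ratio]["mean_accuracy"].iloc[0] == pytest.approx(best["mean_accuracy"])


class TestKFoldCV:
    def test_perfectly_separable_gives_one(self):
        counts = np.r_[np.zeros((10, 1)), np.full((10, 1), 60)].astype(int)
        groups = ["control"] * 10 + ["case"] * 10
        table = make_table(counts, groups)
        assert kfold_cv(table, features=["Region_001"], k=5, seed=0, covariates=()) == 1.0

    def test_loo_matches_explicit_loop(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 20, (12, 2))
        groups = ["case"] * 6 + ["control"] * 6
        table = make_table(counts, groups)
        loo = kfold_cv(table, features=table.region_names, k=12, seed=0, covariates=())
        ids = np.array(table.subject_ids)
        hits = []
        for i in range(12):
            train = table.subset(np.delete(ids, i))
            test = table.subset(ids[i : i + 1])
            model = fit_logistic(train, features=table.region_names, covariates=())
            hits.append(float(model.predict(test)[0] == groups[i]))
        assert loo == pytest.approx(np.mean(hits))

    def test_n_less_than_k(self):
        table = make_table([[1], [2], [3], [4]], ["case", "case", "control", "control"])
        with pytest.raises(FoldError):
            kfold_cv(table, features=["Region_001"], k=10)


class TestRFE:
    def test_single_candidate_selected(self, small_table):
        result = recursive_feature_elimination(small_table, candidates=["Region_003"], seed=0)
        assert result.selected == ["Region_003"]

    def test_no_candidates_rejected(self, small_table):
        with pytest.raises(ValidationError):
            recursive_feature_elimination(small_table, candidates=[], seed=0)

    def test_informative_regions_survive(self):
        spec = CohortSpec(
            n_per_group=[60, 60], n_regions=8, baseline_mean=20, dispersion=5,
            effect_regions={1: [15.0, 0.0], 2: [0.0, 15.0]}, seed=21,
        )
        table = generate_feature_table(spec)
        result = recursive_feature_elimination(table, seed=21)
        assert {"Region_001", "Region_002"} <= set(result.selected)

    def test_all_noise_concentrates_at_minimum(self):
        sizes = []
        for seed in range(8):
            spec = CohortSpec(n_per_group=[25, 25], n_regions=8, baseline_mean=20, dispersion=5, seed=seed)
            table = generate_feature_table(spec)
            sizes.append(len(recursive_feature_elimination(table, seed=seed).selected))
        assert np.median(sizes) <= 3

    def test_deterministic(self, small_table):
        a = recursive_feature_elimination(small_table, seed=5)
        b = recursive_feature_elimination(small_table, seed=5)
        assert a.selected == b.selected
        assert a.elimination_order == b.elimination_order


class TestEvaluate:
    def test_defining_ratios(self):
        # construct a model and data realizing TP=5 FN=5 TN=9 FP=1
        counts = np.r_[np.full((5, 1), 10), np.zeros((5, 1)), np.zeros((9, 1)), np.full((1, 1), 10)].astype(int)
        groups = ["case"] * 10 + ["control"] * 10
        table = make_table(counts, groups)
        model = make_model(-5.0, {"Region_001": 1.0})
        model.training["outcome"] = "group"
        report = evaluate(model, table)
        assert (report.tp, report.fn, report.tn, report.fp) == (5, 5, 9, 1)
        assert report.sensitivity == pytest.approx(0.5)
        assert report.specificity == pytest.approx(0.9)
        assert report.accuracy == pytest.approx(0.7)
        assert report.ppv == pytest.approx(5 / 6)
        assert report.npv == pytest.approx(9 / 14)

    def test_all_correct(self):
        counts = np.r_[np.full((4, 1), 10), np.zeros((4, 1))].astype(int)
        table = make_table(counts, ["case"] * 4 + ["control"] * 4)
        model = make_model(-5.0, {"Region_001": 1.0})
        model.training["outcome"] = "group"
        report = evaluate(model, table)
        assert (report.accuracy, report.sensitivity, report.specificity, report.ppv, report.npv) == (1, 1, 1, 1, 1)

    def test_tie_at_half_predicts_negative(self):
        table = make_table([[0], [0]], ["case", "control"])
        model = make_model(0.0, {"Region_001": 0.0})  # p = exactly 0.5
        model.training["outcome"] = "group"
        report = evaluate(model, table)
        assert report.tp == 0 and report.fp == 0
        assert report.tn == 1 and report.fn == 1

    def test_leakage_rejected(self, small_table):
        model = fit_logistic(small_table, features=["Region_001"])
        with pytest.raises(LeakageError):
            evaluate(model, small_table)

    def test_random_model_near_chance(self):
        rng = np.random.default_rng(13)
        n = 1000
        counts = rng.integers(0, 40, (n, 1))
        groups = np.where(rng.random(n) < 0.5, "case", "control")
        table = make_table(counts, groups)
        model = make_model(0.0, {"Region_001": 0.05})  # predictions unrelated to labels
        model.training["outcome"] = "group"
        acc = evaluate(model, table).accuracy
        se = 0.5 / np.sqrt(n)
        assert abs(acc - 0.5) < 4 * se


class TestThreeClassPath:
    def _subgroup_table(self, seed=0):
        spec = CohortSpec(
            n_per_group=[60, 10],
            n_regions=5,
            baseline_mean=20,
            dispersion=5,
            subgroup_sizes=[20, 30, 10],
            subgroup_effect_regions={1: [15.0, 0.0, 0.0], 2: [0.0, 15.0, 0.0]},
            seed=seed,
        )
        table = generate_feature_table(spec)
        cases = table.metadata["group"] == "case"
        return table.subset(table.metadata.index[cases])

    def test_per_class_sets_share_support(self):
        table = self._subgroup_table()
        model = fit_logistic(table, outcome="subgroup", features=["Region_001", "Region_002"])
        assert model.multiclass
        assert model.classes == ["POTS", "START", "STOPP"]
        supports = [tuple(sorted(model.coefficients[c])) for c in model.classes]
        assert len(set(supports)) == 1

    def test_predictions_land_in_classes(self):
        table = self._subgroup_table()
        train = table.subset(table.subject_ids[:45])
        test = table.subset(table.subject_ids[45:])
        model = fit_logistic(train, outcome="subgroup", features=["Region_001", "Region_002"])
        model.training["outcome"] = "subgroup"
        assert set(model.predict(test)) <= {"START", "STOPP", "POTS"}
        report = evaluate(model, test)
        assert set(report.per_class) == {"START", "STOPP", "POTS"}
        assert 0.0 <= report.accuracy <= 1.0
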