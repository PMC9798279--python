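import numpy as np
import pandas as pd
import pytest

from hipposbm.stats import (
    DesignError,
    InsufficientDataError,
    SeparationError,
    auc_mann_whitney,
    bonferroni_alpha,
    compare_demographics,
    fit_logistic,
    mancova_loadings,
    roc_and_classify,
    roc_points,
)


def make_table(n_mdd=30, n_hs=30, seed=0):
    rng = np.random.default_rng(seed)
    groups = ["MDD"] * n_mdd + ["HS"] * n_hs
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n_mdd + n_hs)],
            "group": groups,
            "age": rng.normal(45, 10, n_mdd + n_hs),
            "sex": rng.choice(["F", "M"], n_mdd + n_hs),
            "education_years": rng.normal(14, 3, n_mdd + n_hs),
        }
    )


class TestDemographics:
    def test_identical_groups_t_zero_p_one(self):
        table = make_table(10, 10)
        table.loc[table.group == "HS", ["age", "education_years"]] = (
            table.loc[table.group == "MDD", ["age", "education_years"]].to_numpy()
        )
        rep = compare_demographics(table).set_index("variable")
        assert rep.loc["age", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert rep.loc["age", "p"] == pytest.approx(1.0)

    def test_chi2_hand_computation(self):
        # 2x2 table (30,20 / 20,30): chi2 = sum (O-E)^2/E = 4.0
        table = pd.DataFrame(
            {
                "subject_id": [str(i) for i in range(100)],
                "group": ["MDD"] * 50 + ["HS"] * 50,
                "sex": ["F"] * 30 + ["M"] * 20 + ["F"] * 20 + ["M"] * 30,
                "age": np.arange(100, dtype=float),
                "education_years": np.arange(100, dtype=float),
            }
        )
        rep = compare_demographics(table).set_index("variable")
        assert rep.loc["sex", "statistic"] == pytest.approx(4.0)

    def test_confounded_synthetic_ages_detected(self):
        # planted Table-1-like means/SDs give a significant age difference
        from hipposbm.synthetic import SyntheticConfig, make_subjects_and_loadings

        hits = 0
        for seed in range(20):
            table, _ = make_subjects_and_loadings(SyntheticConfig(seed=300 + seed))
            rep = compare_demographics(table).set_index("variable")
            hits += rep.loc["age", "p"] < 0.01
        assert hits >= 19

    def test_tiny_group_rejected(self):
        table = make_table(1, 10)
        with pytest.raises(InsufficientDataError):
            compare_demographics(table)


class TestMancova:
    def test_covariate_absorbs_loading(self):
        # loading an exact linear function of age only: group F ~ 0, p ~ 1
        table = make_table(25, 25, seed=1)
        A = (2.0 * table["age"].to_numpy() - 3.0)[:, None]
        res = mancova_loadings(A, table)
        assert res.per_component.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.per_component.loc[0, "p"] == pytest.approx(1.0, abs=1e-9)

    def test_partial_eta_sq_bounds_and_monotonicity(self):
        table = make_table(40, 40, seed=2)
        mdd = (table.group == "MDD").to_numpy()
        rng = np.random.default_rng(3)
        base = rng.standard_normal(80)
        etas = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            a = base + effect * mdd
            res = mancova_loadings(a[:, None], table)
            eta = res.per_component.loc[0, "partial_eta_sq"]
            assert 0.0 <= eta <= 1.0
            etas.append(eta)
        assert etas == sorted(etas)

    def test_planted_component_has_max_f(self):
        from hipposbm.synthetic import SyntheticConfig, make_subjects_and_loadings

        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                group_effect=(0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0), seed=400 + seed
            )
            table, A = make_subjects_and_loadings(cfg)
            res = mancova_loadings(A, table)
            hits += int(res.per_component["F"].idxmax()) == 0
        # ncp ~= 0.5/0.16 = 3.1 puts the planted component on top in ~3/4 of
        # draws, far above the 1/7 chance level
        assert hits >= 6

    def test_rank_deficient_design_named(self):
        table = make_table(20, 20, seed=4)
        table["education_years"] = table["age"] * 2.0
        with pytest.raises(DesignError, match="education_years|age"):
            mancova_loadings(np.random.default_rng(0).normal(size=(40, 2)), table)

    def test_wilks_lambda_matches_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA

        table = make_table(30, 30, seed=5)
        rng = np.random.default_rng(6)
        A = rng.standard_normal((60, 3))
        A[:, 0] += 0.8 * (table.group == "MDD").to_numpy()
        res = mancova_loadings(A, table)
        exog = np.column_stack(
            [
                np.ones(60),
                (table.group == "MDD").to_numpy(float),
                table.age,
                (table.sex == "F").to_numpy(float),
                table.education_years,
            ]
        )
        mv = MANOVA(A, exog)
        out = mv.mv_test([("group", np.eye(5)[[1]])])
        stat = out.results["group"]["stat"]
        assert res.wilks["lambda"] == pytest.approx(
            float(stat.loc["Wilks' lambda", "Value"]), rel=1e-8
        )
        assert res.wilks["p"] == pytest.approx(
            float(stat.loc["Wilks' lambda", "Pr > F"]), rel=1e-6, abs=1e-12
        )


class TestBonferroni:
    def test_seven_components_displays_0007(self):
        alpha = bonferroni_alpha(7, 0.05)
        assert alpha == pytest.approx(0.05 / 7)
        assert f"{alpha:.3f}" == "0.007"

    @pytest.mark.parametrize("n,fam,expected", [(1, 0.05, 0.05), (10, 0.05, 0.005)])
    def test_exact_division(self, n, fam, expected):
        assert bonferroni_alpha(n, fam) == pytest.approx(expected)

    @pytest.mark.parametrize("n,fam", [(0, 0.05), (5, 0.0), (5, 1.0)])
    def test_invalid_inputs(self, n, fam):
        with pytest.raises(ValueError):
            bonferroni_alpha(n, fam)


class TestLogistic:
    def test_null_model_closed_form(self):
        table = make_table(40, 10, seed=7)
        A = np.zeros((50, 2))
        model = fit_logistic(A, table)
        coef = model.coefficients.set_index("predictor")
        assert coef.loc["component_0", "odds_ratio"] == pytest.approx(1.0)
        assert coef.loc["component_1", "odds_ratio"] == pytest.approx(1.0)
        assert coef.loc["intercept", "coef"] == pytest.approx(np.log(40 / 10), abs=1e-6)

    def test_single_binary_predictor_cross_product_ratio(self):
        # counts (40,10 / 20,30): OR = 40*30/(10*20) = 6
        y = ["MDD"] * 50 + ["HS"] * 50
        x = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        table = pd.DataFrame(
            {
                "subject_id": [str(i) for i in range(100)],
                "group": y,
                "age": 0.0,
                "sex": "F",
                "education_years": 0.0,
            }
        )
        model = fit_logistic(x[:, None], table)
        coef = model.coefficients.set_index("predictor")
        assert coef.loc["component_0", "odds_ratio"] == pytest.approx(6.0, rel=1e-4)
        assert coef.loc["component_0", "ci_low"] < 6.0 < coef.loc["component_0", "ci_high"]

    def test_perfect_separation_raises(self):
        table = make_table(20, 20, seed=8)
        x = np.r_[np.ones(20), -np.ones(20)][:, None]
        with pytest.raises(SeparationError):
            fit_logistic(x, table)


class TestRoc:
    def test_worked_example_auc(self):
        # positives (0.9, 0.8), negatives (0.8, 0.1): the tied pair counts
        # 1/2, so 3.5 of 4 pairs -> 0.875
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.8, 0.8, 0.1])
        assert auc_mann_whitney(y, p) == pytest.approx(0.875)

    def test_matches_brute_force_all_pairs_oracle(self, rng):
        for n in (10, 57, 200):
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            pairs = [
                1.0 if sp > sn else 0.5 if sp == sn else 0.0
                for sp in scores[y]
                for sn in scores[~y]
            ]
            assert auc_mann_whitney(y, scores) == pytest.approx(np.mean(pairs))

    def test_rank_auc_equals_trapezoidal_roc_area(self, rng):
        y = rng.random(150) < 0.5
        scores = rng.normal(size=150) + y
        fpr, tpr = roc_points(y, scores)
        assert auc_mann_whitney(y, scores) == pytest.approx(np.trapezoid(tpr, fpr))

    def test_permutation_null_centered_at_half(self, rng):
        scores = rng.normal(size=400)
        aucs = []
        for _ in range(1000):
            y = np.zeros(400, dtype=bool)
            y[rng.choice(400, 200, replace=False)] = True
            aucs.append(auc_mann_whitney(y, scores))
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_perfect_separation_metrics(self):
        table = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "group": ["MDD"] * 3 + ["HS"] * 3,
                "age": 0.0,
                "sex": "F",
                "education_years": 0.0,
            }
        )
        from hipposbm.stats import LogisticModel

        model = LogisticModel(
            coefficients=pd.DataFrame(),
            fitted_probabilities=np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1]),
            y=np.array([1, 1, 1, 0, 0, 0]),
        )
        out = roc_and_classify(model, cutoff=0.5)
        assert out["auc"] == 1.0
        assert out["accuracy_pct"] == 100.0
        assert out["sensitivity_pct"] == 100.0 and out["specificity_pct"] == 100.0

    def test_ties_at_cutoff_classified_positive(self):
        from hipposbm.stats import LogisticModel

        model = LogisticModel(
            coefficients=pd.DataFrame(),
            fitted_probabilities=np.array([0.5, 0.5, 0.4, 0.6]),
            y=np.array([1, 0, 0, 1]),
        )
        out = roc_and_classify(model, cutoff=0.5)
        assert out["confusion"]["tp"] == 2 and out["confusion"]["fp"] == 1
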