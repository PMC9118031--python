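"""Penalized multinomial rhythm models, cross-validation and stacking."""

import numpy as np
import pandas as pd
import pytest

from bearrhythms import rhythm_model as rm
from bearrhythms.synthetic import simulate_rhythm_cohort

CLASSES = ("diel", "ultradian", "infradian", "arrhythmic")


def balanced_frame(n_per_class=20):
    return pd.DataFrame({"rhythm_class": np.repeat(CLASSES, n_per_class)})


class TestSplineBasis:
    def test_penalty_symmetric_positive_semidefinite(self, rng):
        x = rng.uniform(0, 10, 100)
        _, S, _ = rm.spline_basis(x, 10)
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_infinite_smoothing_recovers_straight_line(self, rng):
        x = np.sort(rng.uniform(0, 1, 200))
        y = np.sin(3 * x) + rng.normal(0, 0.1, 200)
        B, S, _ = rm.spline_basis(x, 8)
        X = np.column_stack([np.ones(200), B])
        P = np.zeros((9, 9))
        P[1:, 1:] = 1e9 * S
        fit = X @ np.linalg.solve(X.T @ X + P, X.T @ y)
        A = np.column_stack([np.ones(200), x])
        resid = fit - A @ np.linalg.lstsq(A, fit, rcond=None)[0]
        r2_affine = 1 - (resid @ resid) / np.sum((fit - fit.mean()) ** 2)
        assert r2_affine > 0.999

    def test_reproduces_cubic_polynomial_exactly(self, rng):
        x = np.sort(rng.uniform(-1, 2, 150))
        y = 1.0 - 2 * x + 0.5 * x**2 + 0.25 * x**3
        B, _, _ = rm.spline_basis(x, 12)
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        assert np.max(np.abs(B @ coef - y)) < 1e-6

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rm.spline_basis(np.full(30, 2.0), 8)


class TestFit:
    def test_intercept_only_reproduces_frequencies_exactly(self):
        df = pd.DataFrame(
            {"rhythm_class": ["diel"] * 60 + ["ultradian"] * 30 + ["infradian"] * 10}
        )
        m = rm.fit_multinomial(rm.ModelSpec("null"), df)
        p = m.predict_probs(df.iloc[:1]).iloc[0]
        assert p["diel"] == pytest.approx(0.6, abs=1e-9)
        assert p["ultradian"] == pytest.approx(0.3, abs=1e-9)
        assert p["infradian"] == pytest.approx(0.1, abs=1e-9)

    def test_row_duplication_leaves_estimates_unchanged(self):
        coef = np.array([[0.5, -0.3, -0.8], [0.3, -0.2, 0.1]])
        data, _ = simulate_rhythm_cohort(300, coef, {"x": (-2, 2)}, seed=3)
        spec = rm.ModelSpec("s", (rm.Term("x", "smooth"),))
        m1 = rm.fit_multinomial(spec, data, lam=1.0)
        m2 = rm.fit_multinomial(spec, pd.concat([data, data], ignore_index=True), lam=1.0)
        assert np.allclose(m1.coef, m2.coef, atol=1e-6)

    def test_slope_recovery_within_three_se(self):
        coef = np.array([[2.5, -2.0, -3.0], [-0.25, 0.05, 0.1]])
        data, _ = simulate_rhythm_cohort(2000, coef, {"day_length": (6.0, 19.0)}, seed=4)
        spec = rm.ModelSpec("lin", (rm.Term("day_length", "linear"),))
        m = rm.fit_multinomial(spec, data)
        se = m.se()
        truth_col = {"ultradian": 0, "infradian": 1, "arrhythmic": 2}
        for j, cls in enumerate(m.nonref_classes):
            z = (m.coef[1, j] - coef[1, truth_col[cls]]) / se[1, j]
            assert abs(z) < 3.0

    def test_matches_statsmodels_unpenalized(self):
        sm = pytest.importorskip("statsmodels.api")
        coef = np.array([[0.4, -0.5, -1.0], [0.6, -0.3, 0.2]])
        data, _ = simulate_rhythm_cohort(800, coef, {"x": (-1.5, 1.5)}, seed=5)
        spec = rm.ModelSpec("lin", (rm.Term("x", "linear"),))
        ours = rm.fit_multinomial(spec, data)
        X = sm.add_constant(data[["x"]].to_numpy())
        codes = pd.Categorical(data["rhythm_class"]).codes
        ref = sm.MNLogit(codes, X).fit(disp=0, method="newton", maxiter=200)
        p_ref = ref.predict(X)  # columns in categorical code order
        cats = list(pd.Categorical(data["rhythm_class"]).categories)
        p_ours = ours.predict_probs(data)[cats].to_numpy()
        assert np.max(np.abs(p_ours - p_ref)) < 1e-5

    def test_single_class_rejected(self):
        df = pd.DataFrame({"rhythm_class": ["diel"] * 20})
        with pytest.raises(ValueError, match="2 observed classes"):
            rm.fit_multinomial(rm.ModelSpec("null"), df)

    def test_separation_is_reported(self):
        df = pd.DataFrame(
            {"rhythm_class": ["diel"] * 30 + ["ultradian"] * 30, "x": [0.0] * 30 + [1.0] * 30}
        )
        with pytest.warns(UserWarning, match="separation|diverging"):
            m = rm.fit_multinomial(rm.ModelSpec("lin", (rm.Term("x", "linear"),)), df)
        assert m.separation


class TestPredict:
    def test_probabilities_sum_to_one(self):
        coef = np.array([[0.3, -0.2, 0.4], [0.2, 0.1, -0.3]])
        data, _ = simulate_rhythm_cohort(500, coef, {"x": (-2, 2)}, seed=6)
        m = rm.fit_multinomial(rm.ModelSpec("lin", (rm.Term("x", "linear"),)), data)
        probs = m.predict_probs(data)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs.to_numpy() > 0).all()

    def test_balanced_intercept_only_is_uniform(self):
        m = rm.fit_multinomial(rm.ModelSpec("null"), balanced_frame())
        p = m.predict_probs(balanced_frame().iloc[:1]).iloc[0]
        assert np.allclose(p.to_numpy(), 0.25, atol=1e-9)

    def test_positive_slope_makes_class_probability_increase(self):
        data, _ = simulate_rhythm_cohort(
            400, np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]), {"x": (-2, 2)}, seed=7
        )
        m = rm.fit_multinomial(rm.ModelSpec("lin", (rm.Term("x", "linear"),)), data)
        grid = pd.DataFrame({"x": np.linspace(-2, 2, 50)})
        # identify the class whose fitted slope is strictly largest
        slopes = dict(zip(m.nonref_classes, m.coef[1]))
        top = max(slopes, key=slopes.get)
        p = m.predict_probs(grid)[top].to_numpy()
        assert np.all(np.diff(p) > 0)

    def test_unseen_category_level_named_in_error(self):
        df = pd.DataFrame(
            {"rhythm_class": ["diel", "ultradian"] * 20, "g": ["a", "b"] * 20}
        )
        m = rm.fit_multinomial(rm.ModelSpec("cat", (rm.Term("g", "categorical"),)), df)
        with pytest.raises(ValueError, match="'c'"):
            m.predict_probs(pd.DataFrame({"g": ["c"]}))


class TestCrossValidation:
    def test_uniform_predictor_elpd_closed_form(self):
        df = balanced_frame(20)  # 80 observations, 4 classes
        r = rm.cv_elpd(rm.ModelSpec("null"), df, n_folds=4, grouping=None, seed=0)
        assert r.elpd == pytest.approx(80 * np.log(0.25), abs=1e-6)
        assert r.se == pytest.approx(0.0, abs=1e-6)

    def test_grouped_folds_keep_bears_together(self):
        coef = np.array([[0.2, -0.2, 0.1], [0.3, 0.0, -0.1]])
        data, _ = simulate_rhythm_cohort(200, coef, {"x": (-1, 1)}, seed=8)
        data["bear_id"] = [f"bear{i % 7}" for i in range(len(data))]
        fold = rm._make_folds(data, 3, "bear_id", "rhythm_class", seed=0)
        for b in data["bear_id"].unique():
            assert len(np.unique(fold[(data["bear_id"] == b).to_numpy()])) == 1

    def test_informative_model_beats_null(self):
        coef = np.array([[2.5, -2.0, -3.0], [-0.25, 0.0, 0.0]])
        data, _ = simulate_rhythm_cohort(1500, coef, {"day_length": (6, 19)}, seed=9)
        spec = rm.ModelSpec("lin", (rm.Term("day_length", "linear"),))
        r_lin = rm.cv_elpd(spec, data, grouping=None, seed=0)
        r_null = rm.cv_elpd(rm.ModelSpec("null"), data, grouping=None, seed=0)
        assert r_lin.elpd - r_null.elpd > 4.0

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            rm.cv_elpd(rm.ModelSpec("null"), balanced_frame(), n_folds=1)


class TestStacking:
    def test_single_model_gets_full_weight(self):
        r = rm.stacking_weights(np.full((50, 1), 0.4))
        assert r.weights.tolist() == [1.0]

    def test_identical_models_share_weight(self, rng):
        p = rng.uniform(0.1, 0.9, 60)
        r = rm.stacking_weights(np.column_stack([p, p]))
        assert np.allclose(r.weights, [0.5, 0.5])

    def test_weights_on_simplex(self, rng):
        P = rng.uniform(0.05, 0.95, (100, 4))
        r = rm.stacking_weights(P)
        assert (r.weights >= -1e-12).all()
        assert r.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dominant_model_takes_most_weight(self, rng):
        truth = rng.uniform(0.5, 0.95, 200)
        noise = rng.uniform(0.05, 0.3, 200)
        r = rm.stacking_weights(np.column_stack([truth, noise]))
        assert r.weights[0] > 0.9


class TestCandidateSets:
    def test_hibernation_set_has_fifteen_models(self):
        specs = rm.candidate_models("hibernation")
        assert len(specs) == 15
        assert specs[0].name == "null"
        assert any("snow_depth" in s.name for s in specs)

    def test_active_set_has_thirteen_models(self):
        specs = rm.candidate_models("active")
        assert len(specs) == 13
        assert any(t.by == "day_length_direction" for s in specs for t in s.terms)

    def test_all_specs_constructible_on_cohort_frame(self, rng):
        n = 120
        frame = pd.DataFrame(
            {
                "rhythm_class": rng.choice(["diel", "infradian"], n),
                "body_mass": rng.uniform(20, 200, n),
                "age_class": rng.choice(["adult", "subadult"], n),
                "sex": rng.choice(["F", "M"], n),
                "status": rng.choice(["solitary", "pregnant", "with cubs"], n),
                "snow_depth": rng.uniform(0, 0.6, n),
                "day_length": rng.uniform(6, 19, n),
                "day_length_direction": rng.choice(["increasing", "decreasing"], n),
                "ambient_temp": rng.uniform(-15, 19, n),
                "open_area": rng.uniform(1, 100, n),
                "den_type": rng.choice(["anthill", "nest", "rock", "soil", "uprooted tree"], n),
                "bear_id": rng.choice([f"bear{i}" for i in range(8)], n),
                "season": rng.choice([2015, 2016], n),
            }
        )
        for state in ("hibernation", "active"):
            for spec in rm.candidate_models(state):
                design = rm.Design(spec, frame)
                X = design.matrix(frame, training=True)
                assert X.shape == (n, design.n_columns)
                assert np.isfinite(X).all()
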