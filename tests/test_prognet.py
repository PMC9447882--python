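"""Calibration, evaluation-metric and cross-validation tests."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ohca_interact import (
    ModelEnsemble,
    calibrate_class_weights,
    cv_folds,
    evaluate,
    run_cv,
    stratified_split,
    train_model,
)
from ohca_interact.metrics import MetricsError, auroc_rank, delong_ci, metrics_report
from ohca_interact.mlp import ClassWeights, NetConfig


class TestMetrics:
    def test_perfect_predictor(self):
        y = np.array([0, 1, 0, 1], dtype=bool)
        rep = metrics_report(y.astype(float), y)
        assert rep.sensitivity_pos == 1.0
        assert rep.sensitivity_neg == 1.0
        assert rep.auroc == 1.0

    def test_constant_predictor_degenerate_ranking(self):
        y = np.array([0, 0, 1, 1], dtype=bool)
        rep = metrics_report(np.full(4, 0.3), y)
        assert rep.sensitivity_pos == 0.0
        assert rep.sensitivity_neg == 1.0
        assert rep.auroc == 0.5

    def test_auroc_against_all_pairs_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1], dtype=bool)
        # brute force over all (pos, neg) pairs
        pairs = [(s_p, s_n) for s_p in scores[y] for s_n in scores[~y]]
        oracle = np.mean([1.0 if sp > sn else 0.5 if sp == sn else 0.0 for sp, sn in pairs])
        assert oracle == 0.75
        assert auroc_rank(scores, y) == pytest.approx(0.75)

    def test_auroc_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        scores[::7] = scores[3]  # inject ties
        y = rng.random(200) < 0.3
        assert auroc_rank(scores, y) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_delong_ci_brackets_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(1)

        def ci_width(n):
            y = np.arange(n) < n // 4
            scores = rng.normal(size=n) + 1.5 * y
            auc, (lo, hi) = delong_ci(scores, y)
            assert lo <= auc <= hi
            return hi - lo

        assert ci_width(2000) < ci_width(200)

    def test_single_class_labels_rejected(self):
        with pytest.raises(MetricsError, match="single class"):
            metrics_report(np.array([0.2, 0.4]), np.array([True, True]))


class TestCalibration:
    @staticmethod
    def step_stub_factory(val_y, breakpoint):
        """Sensitivity is a step function of w_pos with a known breakpoint."""

        def trainer(w_pos):
            # above the breakpoint every positive scores 1, else everything 0
            if w_pos >= breakpoint:
                return val_y.astype(float)
            return np.zeros_like(val_y, dtype=float)

        return trainer

    def test_already_qualifying_at_unit_weight_returns_one(self):
        val_y = np.array([1, 1, 0, 0], dtype=bool)
        res = calibrate_class_weights(
            None, None, None, val_y,
            trainer=self.step_stub_factory(val_y, breakpoint=0.5),
        )
        assert res.weights.w_pos == 1.0
        assert res.converged

    def test_bisection_converges_to_step_breakpoint(self):
        val_y = np.repeat([True, False], [10, 90])
        breakpoint = 10.0
        res = calibrate_class_weights(
            None, None, None, val_y,
            trainer=self.step_stub_factory(val_y, breakpoint),
            weight_rtol=0.01,
        )
        assert res.converged
        # smallest qualifying weight within the bisection tolerance
        assert breakpoint <= res.weights.w_pos <= breakpoint * 1.01
        # trace records every evaluation as (w_pos, sens_pos, sens_neg)
        assert all(len(t) == 3 for t in res.trace)
        ws = [t[0] for t in res.trace]
        assert any(w < breakpoint for w in ws) and any(w >= breakpoint for w in ws)

    def test_unreachable_target_flags_failure_with_best_weight(self):
        val_y = np.repeat([True, False], [10, 90])

        def trainer(w_pos):
            # sensitivity grows with the weight but saturates at 40%
            scores = np.zeros_like(val_y, dtype=float)
            scores[: int(w_pos // 16)] = 1.0
            return scores

        res = calibrate_class_weights(None, None, None, val_y, trainer=trainer)
        assert not res.converged
        assert res.weights.w_pos == 64.0  # best achiever on the grid

    def test_single_class_validation_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            calibrate_class_weights(
                None, None, None, np.array([True, True]), trainer=lambda w: np.ones(2)
            )


def imbalanced_toy(n=900, seed=0):
    """Linearly-driven imbalanced outcome, ~10% positive."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    eta = -2.6 + 1.8 * X[:, 0] + 0.9 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestRunCv:
    def make(self, calibrate=False, epochs=15):
        X, y = imbalanced_toy()
        plan = stratified_split(y.astype(bool), k=5, seed=2)
        folds = cv_folds(plan)
        cfg = NetConfig(input_width=3, hidden_widths=(8, 6, 4), epochs=epochs, seed=2)
        ens, reports, cals = run_cv(
            X, y, folds, cfg, calibrate=calibrate,
            class_weights=None if calibrate else ClassWeights(w_pos=9.0),
        )
        return X, y, plan, ens, reports, cals

    def test_four_models_with_distinct_validation_groups(self):
        X, y, plan, ens, reports, cals = self.make()
        assert len(ens.models) == 4
        assert len(reports) == 4
        # decent signal: the toy problem is learnable in every fold
        assert all(r.auroc > 0.75 for r in reports)

    def test_ensemble_prediction_is_member_mean(self):
        X, y, plan, ens, *_ = self.make()
        p = ens.predict(X[:20])
        members = ens.member_predictions(X[:20])
        assert members.shape == (4, 20)
        np.testing.assert_allclose(p, members.mean(axis=0), atol=1e-14)

    def test_run_is_seed_deterministic(self):
        _, _, _, ens1, *_ = self.make()
        _, _, _, ens2, *_ = self.make()
        X, _ = imbalanced_toy()
        np.testing.assert_array_equal(ens1.predict(X[:10]), ens2.predict(X[:10]))

    def test_calibrated_folds_reach_target_band(self):
        # per-fold weight calibration drives minority sensitivity toward 80%
        X, y, plan, ens, reports, cals = self.make(calibrate=True)
        assert all(c is not None for c in cals)
        reached = [r.sensitivity_pos for r, c in zip(reports, cals) if c.converged]
        assert len(reached) >= 2
        assert all(s >= 0.7 for s in reached)

    def test_evaluate_on_ensemble(self):
        X, y, plan, ens, *_ = self.make()
        test = plan.test_indices
        rep = evaluate(ens, X[test], y[test])
        assert 0.0 <= rep.sensitivity_pos <= 1.0
        assert rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1]


class TestParameterRecovery:
    def test_prediction_tracks_generative_probability(self, included_cohort):
        """Rank correlation between model score and the true risk is positive."""
        from scipy.stats import spearmanr

        from ohca_interact import (
            EffectModel,
            RecordPredictor,
            default_schema,
            fit_encode,
            true_outcome_probability,
        )

        df = included_cohort
        y = df["outcome_cpc12"].to_numpy(dtype=float)
        schema = default_schema()
        enc = fit_encode(df, schema)
        model = train_model(
            enc.values, y,
            NetConfig(input_width=schema.width, epochs=12, seed=3),
            ClassWeights(w_pos=25.0),
        )
        pred = RecordPredictor(model, schema, enc.standardization)
        rho = spearmanr(pred.mean_probability(df),
                        true_outcome_probability(df, EffectModel())).statistic
        assert rho > 0.5
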