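"""Weighted regularized logistic fitting, thresholds, CV and evaluation."""

import numpy as np
import pandas as pd
import pytest

from trackrel.config import LrHyper, WeightScheme
from trackrel.model import (
    ConfusionReport,
    average_fold_thresholds,
    evaluate,
    fit_weighted_lr,
    loo_cv,
    loss_value,
    mcnemar_exact,
    model_scores,
    predict_proba,
    select_threshold,
    sensitivity_at_specificity,
    sigmoid,
    sweep_weights_and_hyper,
)


def _toy(n=200, p=3, seed=0, beta=None, beta0=-0.2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    beta = np.asarray(beta if beta is not None else rng.normal(size=p))
    prob = sigmoid(beta0 + x @ beta)
    y = (rng.uniform(size=n) < prob).astype(float)
    return x, y, beta, beta0


class TestFitWeightedLr:
    def test_huge_penalty_shrinks_coefficients(self):
        x, y, _, _ = _toy()
        fit = fit_weighted_lr(x, y, hyper=LrHyper(lam=1e6, penalty="l2"))
        assert np.all(np.abs(fit.betas) < 1e-3)

    def test_weight_two_equals_duplicated_row(self):
        x, y, _, _ = _toy(60, seed=3)
        w = np.ones(len(y))
        w[7] = 2.0
        a = fit_weighted_lr(x, y, w, LrHyper(lam=0.05, penalty="l2", tol=1e-12))
        x2 = np.vstack([x, x[7:8]])
        y2 = np.append(y, y[7])
        b = fit_weighted_lr(x2, y2, None, LrHyper(lam=0.05, penalty="l2", tol=1e-12))
        # identical loss up to the weight normalization: same optimum
        np.testing.assert_allclose(
            np.r_[a.beta0, a.betas], np.r_[b.beta0, b.betas], atol=1e-8
        )

    def test_separable_data_positive_slope(self):
        x = np.linspace(-2, 2, 50).reshape(-1, 1)
        y = (x.ravel() > 0).astype(float)
        fit = fit_weighted_lr(x, y, hyper=LrHyper(lam=0.1, penalty="l2"))
        assert fit.betas[0] > 0

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError):
            fit_weighted_lr(x, np.ones(20))

    def test_nonpositive_weights_rejected(self):
        x, y, _, _ = _toy(30)
        w = np.ones(30)
        w[0] = 0.0
        with pytest.raises(ValueError):
            fit_weighted_lr(x, y, w)

    @pytest.mark.parametrize("penalty,l1_ratio", [("l2", 0.5), ("l1", 0.5),
                                                  ("elastic_net", 0.3)])
    def test_matches_generic_minimizer_oracle(self, penalty, l1_ratio):
        """FISTA optimum matches an independent Nelder-Mead minimization
        of the same written-down loss."""
        from scipy.optimize import minimize

        x, y, _, _ = _toy(100, p=2, seed=5)
        hyper = LrHyper(lam=0.1, penalty=penalty, l1_ratio=l1_ratio, tol=1e-12)
        fit = fit_weighted_lr(x, y, hyper=hyper)
        res = minimize(
            lambda th: loss_value(th, x, y, np.ones(len(y)), hyper),
            np.zeros(3),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000},
        )
        np.testing.assert_allclose(np.r_[fit.beta0, fit.betas], res.x, atol=1e-4)

    def test_matches_sklearn_l2_cross_check(self):
        """Independent cross-check against sklearn's logistic regression
        (C mapped onto the weighted-mean-loss parameterization)."""
        from sklearn.linear_model import LogisticRegression

        x, y, _, _ = _toy(300, p=4, seed=9)
        lam = 0.05
        fit = fit_weighted_lr(x, y, hyper=LrHyper(lam=lam, penalty="l2",
                                                  tol=1e-12))
        # sklearn minimizes sum CE + (1/C)*0.5*||b||^2; ours is mean CE
        # + lam*||b||^2, so C = 1 / (2 * lam * n)
        sk = LogisticRegression(C=1.0 / (2 * lam * len(y)), tol=1e-12,
                                max_iter=10000)
        sk.fit(x, y)
        np.testing.assert_allclose(fit.betas, sk.coef_.ravel(), atol=1e-3)
        assert fit.beta0 == pytest.approx(float(sk.intercept_[0]), abs=1e-3)

    def test_sgd_solver_approaches_fista_optimum(self):
        x, y, _, _ = _toy(400, p=3, seed=11)
        det = fit_weighted_lr(x, y, hyper=LrHyper(lam=0.05, penalty="l2"))
        sto = fit_weighted_lr(
            x, y, hyper=LrHyper(lam=0.05, penalty="l2", solver="sgd",
                                max_iter=20000, seed=4)
        )
        np.testing.assert_allclose(sto.betas, det.betas, atol=0.05)

    def test_sgd_deterministic_given_seed(self):
        x, y, _, _ = _toy(100, seed=2)
        h = LrHyper(solver="sgd", max_iter=2000, seed=9)
        a = fit_weighted_lr(x, y, hyper=h)
        b = fit_weighted_lr(x, y, hyper=h)
        np.testing.assert_array_equal(a.betas, b.betas)

    def test_parameter_recovery_on_simulated_model(self):
        """Data simulated from the domain-adapted model with known
        coefficients: each is recovered within +-0.1 at weak penalty."""
        rng = np.random.default_rng(42)
        n = 5000
        beta0 = -0.3
        beta = np.array([0.7, 2.6, -0.23, 0.02, 2.9, -0.09, -1.19, -0.27, -0.33])
        rows = []
        for di in (0.0, 1.0):
            xs = rng.normal(size=(n, 4))
            x = np.column_stack([xs, np.full(n, di), xs * di])
            rows.append(x)
        x = np.vstack(rows)
        y = (rng.uniform(size=2 * n) < sigmoid(beta0 + x @ beta)).astype(float)
        fit = fit_weighted_lr(x, y, hyper=LrHyper(lam=1e-4, penalty="l2"))
        assert abs(fit.beta0 - beta0) < 0.1
        np.testing.assert_allclose(fit.betas, beta, atol=0.1)


class TestThresholds:
    def _bruteforce(self, scores, labels, target):
        neg = scores[~labels.astype(bool)]
        cands = np.unique(scores)
        cands = np.concatenate(
            [[cands[0] / 2], (cands[:-1] + cands[1:]) / 2, [(cands[-1] + 1) / 2]]
        )
        ok = [t for t in cands if np.mean(neg < t) >= target]
        return min(ok) if ok else None

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(10, 60)
            scores = rng.uniform(size=n)
            labels = rng.uniform(size=n) < 0.6
            if labels.all():
                labels[0] = False
            target = rng.choice([0.5, 0.8, 0.9, 0.95])
            expected = self._bruteforce(scores, labels, target)
            got = select_threshold(scores, labels, target)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_perfect_separation_keeps_full_sensitivity(self):
        scores = np.array([0.1, 0.2, 0.8, 0.95])
        labels = np.array([0, 0, 1, 1], bool)
        t = select_threshold(scores, labels, 0.95)
        assert np.mean(scores[labels] >= t) == 1.0

    def test_zero_target_accepts_everything(self):
        scores = np.array([0.2, 0.5, 0.9])
        labels = np.array([0, 1, 1], bool)
        t = select_threshold(scores, labels, 0.0)
        assert np.all(scores >= t)

    def test_no_negatives_is_error(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.5, 0.9]), np.array([1, 1], bool))

    def test_fold_average(self):
        assert average_fold_thresholds([0.5, 0.6, 0.7]) == pytest.approx(0.6)
        assert average_fold_thresholds([0.42]) == 0.42
        assert average_fold_thresholds([0.7, 0.5, 0.6]) == pytest.approx(0.6)


class TestEvaluate:
    def test_printed_formulas_on_counts(self):
        rep = ConfusionReport(tp=1958, fp=54, tn=1040, fn=722, threshold=0.5,
                              sensitivity=1958 / 2680, specificity=1 - 54 / 1094)
        assert rep.sensitivity * 100 == pytest.approx(73.1, abs=0.1)
        assert rep.specificity * 100 == pytest.approx(95.1, abs=0.1)

    def test_perfect_scores(self):
        scores = np.array([0.1, 0.2, 0.9, 0.95])
        labels = np.array([0, 0, 1, 1], bool)
        rep = evaluate(scores, labels, 0.5)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0 and rep.auc == 1.0

    def test_no_positives_reports_absent_sensitivity(self):
        rep = evaluate(np.array([0.2, 0.3]), np.array([0, 0], bool), 0.5)
        assert rep.sensitivity is None and rep.specificity == 1.0

    def test_random_scores_have_half_auc(self):
        """Label-independent scores: mean AUC 0.5 +- 0.02 over 50 seeds."""
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            scores = rng.uniform(size=10_000)
            labels = rng.uniform(size=10_000) < 0.5
            aucs.append(evaluate(scores, labels, 0.5).auc)
        assert float(np.mean(aucs)) == pytest.approx(0.5, abs=0.02)

    def test_specificity_monotone_sensitivity_antitone_in_threshold(self, rng):
        scores = rng.uniform(size=500)
        labels = rng.uniform(size=500) < 0.5
        grid = np.linspace(0.05, 0.95, 19)
        reps = [evaluate(scores, labels, t) for t in grid]
        spec = [r.specificity for r in reps]
        sens = [r.sensitivity for r in reps]
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_threshold_calibration_on_simulated_scores(self):
        """Specificity realized at the averaged 95%-target cutoff stays
        within 3 points of 95% on held-out draws (20 seeds)."""
        realized = []
        for seed in range(20):
            rng = np.random.default_rng(seed)

            def draw(n):
                x = rng.normal(size=(n, 2))
                p = sigmoid(-0.5 + x @ np.array([2.0, 1.0]))
                y = rng.uniform(size=n) < p
                return sigmoid(-0.5 + x @ np.array([2.0, 1.0])), y

            folds = [select_threshold(*draw(2000), 0.95) for _ in range(5)]
            cutoff = average_fold_thresholds(folds)
            scores, y = draw(6000)
            neg = scores[~y]
            assert len(neg) >= 2000
            realized.append(float(np.mean(neg < cutoff)))
        assert abs(float(np.mean(realized)) - 0.95) <= 0.03

    def test_interaction_zeroing_reduces_to_phantom_model(self, rng):
        """Zeroing DI and interaction columns makes patient predictions
        equal the phantom-coefficient model (algebraic identity)."""
        from trackrel.model import LrFit

        fit = LrFit(beta0=0.3, betas=rng.normal(size=9), converged=True,
                    grad_norm=0.0, n_iter=0)
        xs = rng.normal(size=(20, 4))
        patient = np.column_stack([xs, np.ones(20), xs])
        zeroed = patient.copy()
        zeroed[:, 4:] = 0.0
        phantom_model = predict_proba(
            LrFit(fit.beta0, fit.betas.copy(), True, 0.0, 0),
            np.column_stack([xs, np.zeros(20), np.zeros_like(xs)]),
        )
        np.testing.assert_allclose(predict_proba(fit, zeroed), phantom_model)


def _cv_table(n_datasets=5, n=40, modality="SE"):
    frames = []
    for k in range(n_datasets):
        rng = np.random.default_rng(100 + k)
        domain = "phantom" if k == 0 else "patient"
        score = rng.uniform(0.3, 1.0, n)
        label = (score + rng.normal(0, 0.15, n) > 0.6).astype(int)
        if label.min() == label.max():
            label[0] = 1 - label[0]
        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": f"{'f' if domain == 'phantom' else 'p'}{k}",
                    "modality": modality,
                    "domain": domain,
                    "frame_index": np.arange(n),
                    "match_score": score,
                    "psr": rng.gamma(4, 1, n) + 3 * label,
                    "vx": rng.normal(0, 1, n),
                    "vy": rng.normal(0, 2, n),
                    "label": label,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


QUALITY = {f"p{k}": b for k, b in zip(range(1, 5), ["good", "moderate", "poor",
                                                    "good"])}


class TestLooCv:
    def test_one_fold_per_patient_dataset(self):
        table = _cv_table()
        mf = loo_cv(table, QUALITY)
        assert [f.held_out for f in mf.folds] == ["p1", "p2", "p3", "p4"]

    def test_deterministic(self):
        table = _cv_table()
        a = loo_cv(table, QUALITY)
        b = loo_cv(table, QUALITY)
        np.testing.assert_array_equal(a.betas, b.betas)
        assert a.thresholds == b.thresholds

    def test_validation_outlier_does_not_leak_into_training_scalers(self):
        table = _cv_table()
        spiked = table.copy()
        sel = spiked["dataset_id"] == "p1"
        spiked.loc[sel, "psr"] = 1e6
        a = loo_cv(table, QUALITY)
        b = loo_cv(spiked, QUALITY)
        fold_a = next(f for f in a.folds if f.held_out == "p1")
        fold_b = next(f for f in b.folds if f.held_out == "p1")
        assert fold_a.scaler_state.params == fold_b.scaler_state.params

    def test_interval_summaries_cover_final_coefficients(self):
        mf = loo_cv(_cv_table(), QUALITY)
        assert set(mf.coef_interval) == {f"beta{k}" for k in range(10)}
        for lo, hi in mf.coef_interval.values():
            assert lo <= hi

    def test_too_few_datasets_rejected(self):
        table = _cv_table(2)
        with pytest.raises(ValueError):
            loo_cv(table, {"p1": "good"})

    def test_model_fit_serializes_to_json(self):
        import json

        mf = loo_cv(_cv_table(), QUALITY)
        blob = json.loads(mf.to_json())
        assert len(blob["betas"]) == 9
        assert set(blob["thresholds"]) <= {"phantom", "patient"}


class TestSweepAndPairing:
    def test_single_point_grid_returns_it(self):
        table = _cv_table()
        scheme, hyper, sweep = sweep_weights_and_hyper(
            table, QUALITY, moderate_grid=[0.6], poor_grid=[0.2],
            hyper_grid=[LrHyper()],
        )
        assert scheme.moderate == 0.6 and scheme.poor == 0.2
        assert len(sweep) == 1

    def test_mcnemar_exact_matches_binomial(self):
        a = np.array([True] * 8 + [False] * 2)
        b = np.array([True] * 2 + [False] * 8)
        from scipy.stats import binomtest

        # discordant pairs: 6 where only a correct, 0 where only b
        expected = binomtest(0, 6, 0.5).pvalue
        assert mcnemar_exact(a, b) == pytest.approx(expected)

    def test_mcnemar_no_discordance_is_one(self):
        a = np.array([True, False, True])
        assert mcnemar_exact(a, a) == 1.0

    def test_sensitivity_at_specificity_consistency(self, rng):
        scores = rng.uniform(size=300)
        labels = rng.uniform(size=300) < 0.5
        s = sensitivity_at_specificity(scores, labels, 0.9)
        t = select_threshold(scores, labels, 0.9)
        assert s == pytest.approx(float(np.mean(scores[labels] >= t)))
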