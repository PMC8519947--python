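import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from passig.model import (PassSignature, TrainSettings,
                          class_weights, enlr_objective, fit_enlr,
                          fit_enlr_fixed, lambda_max, pass_score, sample_odds,
                          train_signature, train_time_signatures,
                          youden_cutoff)


def random_instance(rng, n=None, k=None):
    n = n or int(rng.integers(20, 60))
    k = k or int(rng.integers(2, 8))
    X = rng.normal(size=(n, k))
    X = (X - X.mean(0)) / X.std(0)
    y = (rng.random(n) < 0.4).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        y[:4] = [1, 1, 0, 0]
    return X, y, class_weights(y)


class TestEnlrSolver:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            X, y, w = random_instance(rng)
            alpha = float(rng.uniform(0.2, 1.0))
            lmax = lambda_max(X, y, w, alpha)
            _, beta = fit_enlr_fixed(X, y, w, alpha, lmax * (1 + 1e-6))
            assert np.all(beta == 0.0)

    def test_nonzero_just_below_lambda_max(self):
        rng = np.random.default_rng(1)
        X, y, w = random_instance(rng, n=80, k=5)
        lmax = lambda_max(X, y, w, 0.5)
        _, beta = fit_enlr_fixed(X, y, w, 0.5, lmax * 0.5)
        assert np.any(beta != 0.0)

    def test_objective_matches_generic_convex_optimizer(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X, y, w = random_instance(rng)
            alpha = float(rng.uniform(0.2, 0.9))
            lam = lambda_max(X, y, w, alpha) * float(rng.uniform(0.01, 0.5))
            b0, b = fit_enlr_fixed(X, y, w, alpha, lam)
            mine = enlr_objective(b0, b, X, y, w, alpha, lam)

            def obj(theta):
                return enlr_objective(theta[0], theta[1:], X, y, w, alpha, lam)

            ref = optimize.minimize(obj, np.zeros(X.shape[1] + 1),
                                    method="Nelder-Mead",
                                    options={"maxiter": 20000,
                                             "xatol": 1e-10, "fatol": 1e-14})
            assert mine <= ref.fun + 1e-6

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X, y, w = random_instance(rng, n=60)
            alpha = 0.5
            lam = lambda_max(X, y, w, alpha) * 0.1
            b0, b = fit_enlr_fixed(X, y, w, alpha, lam)
            n = len(y)
            p = 1.0 / (1.0 + np.exp(-(b0 + X @ b)))
            grad = (w * (p - y)) @ X / n
            for j in range(X.shape[1]):
                if b[j] == 0:
                    assert abs(grad[j]) <= lam * alpha + 1e-6
                else:
                    resid = grad[j] + lam * (1 - alpha) * b[j] + \
                        lam * alpha * np.sign(b[j])
                    assert abs(resid) <= 1e-6

    def test_class_weights_inverse_frequency(self):
        w = class_weights(np.array([1, 1, 0, 0, 0, 0]))
        assert np.allclose(w[:2], 6 / 4) and np.allclose(w[2:], 6 / 8)
        assert w.mean() == pytest.approx(1.0)


def score_frame(rng, n_feat, n_samp):
    X = pd.DataFrame(rng.normal(size=(n_feat, n_samp)),
                     index=[f"P{i}" for i in range(n_feat)],
                     columns=[f"s{j}" for j in range(n_samp)])
    return X


class TestFitEnlr:
    def _labeled(self, rng, n=60, k=6, informative=True):
        X = score_frame(rng, k, n)
        if informative:
            y_num = (X.iloc[0] + 0.5 * X.iloc[1] +
                     rng.normal(0, 0.5, n) > 0)
        else:
            y_num = rng.random(n) < 0.4
        y = pd.Series(np.where(y_num, "R", "NR"), index=X.columns)
        if (y == "R").sum() < 3 or (y == "NR").sum() < 3:
            y.iloc[:6] = ["R", "R", "R", "NR", "NR", "NR"]
        return X, y

    def test_one_se_rule_largest_qualifying_lambda(self):
        rng = np.random.default_rng(4)
        X, y = self._labeled(rng)
        m = fit_enlr(X, y, seed=1)
        thr = m.cv_mean.min() + m.cv_se[np.argmin(m.cv_mean)]
        qualifying = np.flatnonzero(m.cv_mean <= thr)
        assert m.lambda_index == qualifying.min()
        assert m.lambda_chosen == m.lambda_path[m.lambda_index]

    def test_duplicating_every_sample_keeps_coefficients(self):
        rng = np.random.default_rng(5)
        X, y = self._labeled(rng, n=40)
        m1 = fit_enlr(X, y, seed=2)
        X2 = pd.concat([X, X.add_suffix("_dup")], axis=1)
        y2 = pd.concat([y, y.add_suffix("_dup")])
        b0_1, b_1 = fit_enlr_fixed(
            ((X.to_numpy().T - m1.feature_means) / m1.feature_sds),
            (y == "R").to_numpy(float),
            class_weights((y == "R").to_numpy(float)), 0.5, m1.lambda_chosen)
        b0_2, b_2 = fit_enlr_fixed(
            ((X2.to_numpy().T - m1.feature_means) / m1.feature_sds),
            (y2 == "R").to_numpy(float),
            class_weights((y2 == "R").to_numpy(float)), 0.5, m1.lambda_chosen)
        assert b0_2 == pytest.approx(b0_1, abs=1e-6)
        np.testing.assert_allclose(b_2, b_1, atol=1e-6)

    def test_coefficient_path_is_continuous(self):
        rng = np.random.default_rng(6)
        X, y = self._labeled(rng)
        Xs = (X.to_numpy().T - X.to_numpy().T.mean(0)) / X.to_numpy().T.std(0)
        yb = (y == "R").to_numpy(float)
        w = class_weights(yb)
        lmax = lambda_max(Xs, yb, w, 0.5)
        path = lmax * np.logspace(0, -2, 30)
        prev = np.zeros(X.shape[0])
        b0 = 0.0
        max_jump = 0.0
        for lam in path:
            b0, b = fit_enlr_fixed(Xs, yb, w, 0.5, lam, beta0=b0, beta=prev)
            max_jump = max(max_jump, float(np.max(np.abs(b - prev), initial=0)))
            prev = b.copy()
        assert max_jump < 1.0  # smoke bound: no wild discontinuity

    def test_single_class_rejected(self):
        rng = np.random.default_rng(7)
        X = score_frame(rng, 3, 10)
        y = pd.Series("R", index=X.columns)
        with pytest.raises(ValueError):
            fit_enlr(X, y)


def signature(effects, intercept=0.0, cutoff=0.5):
    return PassSignature(
        pathways=list(effects), leading_edges={p: {"g"} for p in effects},
        effect_sizes=effects, intercept=intercept, cutoff=cutoff,
        timepoint="ON", alpha_mix=0.5, lambda_chosen=0.1, ssgsea_alpha=0.25,
        ssgsea_normalize=True, seed=0)


class TestPassScore:
    def test_equal_weights_give_arithmetic_mean(self):
        sig = signature({"A": 1.0, "B": 1.0})
        X = pd.DataFrame({"s": [0.2, 0.6]}, index=["A", "B"])
        assert pass_score(sig, X)["s"] == pytest.approx(0.4)

    def test_single_feature_average(self):
        sig = signature({"A": 2.0})
        X = pd.DataFrame({"s": [0.3]}, index=["A"])
        assert pass_score(sig, X)["s"] == pytest.approx(0.3)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        eff = {"A": 0.5, "B": -1.2, "C": 2.0}
        X = pd.DataFrame(rng.normal(size=(3, 8)), index=list("ABC"))
        s1 = pass_score(signature(eff), X)
        s2 = pass_score(signature({k: 7.3 * v for k, v in eff.items()}), X)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_missing_pathway_rejected(self):
        sig = signature({"A": 1.0, "B": 1.0})
        X = pd.DataFrame({"s": [0.2]}, index=["A"])
        with pytest.raises(KeyError):
            pass_score(sig, X)


class TestSampleOdds:
    def test_unit_odds_at_zero_eta(self):
        sig = signature({"A": 1.0}, intercept=0.0)
        X = pd.DataFrame({"s": [0.0]}, index=["A"])
        assert sample_odds(sig, X)["s"] == pytest.approx(1.0)

    def test_log_three_eta(self):
        sig = signature({"A": 1.0}, intercept=np.log(3.0))
        X = pd.DataFrame({"s": [0.0]}, index=["A"])
        assert sample_odds(sig, X)["s"] == pytest.approx(3.0)

    def test_odds_monotone_in_score_but_not_scale_invariant(self):
        rng = np.random.default_rng(1)
        eff = {"A": 1.0, "B": 0.5}
        sig = signature(eff)
        X = pd.DataFrame(rng.normal(size=(2, 30)), index=["A", "B"])
        s = pass_score(sig, X)
        o = sample_odds(sig, X)
        order = np.argsort(s.to_numpy())
        assert (np.diff(o.to_numpy()[order]) > 0).all()
        sig2 = signature({k: 2 * v for k, v in eff.items()})
        assert not np.allclose(sample_odds(sig2, X), o)


def youden_brute_force(scores, labels):
    s = np.asarray(scores, float)
    pos = np.asarray(labels) == "R"
    best = (-np.inf, None)
    for c in np.concatenate([[s.min() - 1], np.unique(s),
                             (np.unique(s)[:-1] + np.unique(s)[1:]) / 2,
                             [s.max() + 1]]):
        pred = s > c
        j = (pred & pos).sum() / pos.sum() + ((~pred) & ~pos).sum() / (~pos).sum() - 1
        if j > best[0] + 1e-12:
            best = (j, c)
    return best


class TestYoudenCutoff:
    def test_perfect_separation_midpoint(self):
        c = youden_cutoff([0.9, 0.8, 0.1, 0.2], ["R", "R", "NR", "NR"])
        assert c == pytest.approx(0.5)

    def test_all_equal_scores_j_zero(self):
        c = youden_cutoff([0.5] * 6, ["R"] * 3 + ["NR"] * 3)
        pred = np.array([0.5] * 6) > c
        assert pred.all() or (~pred).all()  # J = 0 either way

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.normal(size=20)
            lab = np.where(rng.random(20) < 0.5, "R", "NR")
            if (lab == "R").all() or (lab == "NR").all():
                lab[:2] = ["R", "NR"]
            c = youden_cutoff(s, lab)
            j_best, _ = youden_brute_force(s, lab)
            pos = lab == "R"
            pred = s > c
            j = (pred & pos).sum() / pos.sum() + \
                ((~pred) & ~pos).sum() / (~pos).sum() - 1
            assert j == pytest.approx(j_best, abs=1e-12)


class TestTrainingPipelines:
    def test_driver_pathways_selected(self, default_cohort):
        counts, samples, truth, gs, lengths = default_cohort
        cfg = TrainSettings(n_perm=500, seed=3)
        sig, model, report = train_signature(counts, samples, gs, lengths,
                                             "ON", cfg)
        assert len(set(sig.pathways) & set(truth.driver_pathways)) >= 2
        assert report.candidates[:len(sig.pathways)]  # NES-ordered candidates

    def test_same_seed_identical_signature_json(self, default_cohort, tmp_path):
        counts, samples, truth, gs, lengths = default_cohort
        cfg = TrainSettings(n_perm=500, seed=4)
        for i in (1, 2):
            sig, _, _ = train_signature(counts, samples, gs, lengths, "ON", cfg)
            sig.to_json(tmp_path / f"sig{i}.json")
        assert (tmp_path / "sig1.json").read_bytes() == \
            (tmp_path / "sig2.json").read_bytes()

    def test_time_signatures_share_candidates(self, default_cohort):
        counts, samples, truth, gs, lengths = default_cohort
        cfg = TrainSettings(n_perm=500, seed=5)
        pre, on = train_time_signatures(counts, samples, gs, lengths, cfg)
        # both models draw from one candidate list; selected subsets and
        # leading edges must agree wherever they overlap
        shared = set(pre.pathways) & set(on.pathways)
        for p in shared:
            assert pre.leading_edges[p] == on.leading_edges[p]
        assert pre.timepoint == "PRE" and on.timepoint == "ON"

    def test_no_responders_at_timepoint_is_error(self, default_cohort):
        counts, samples, truth, gs, lengths = default_cohort
        mask = ~((samples.table["response"] == "R") &
                 (samples.table["timepoint"] == "ON")).to_numpy()
        broken = samples.subset(mask)
        with pytest.raises(ValueError):
            train_time_signatures(counts.subset_samples(broken.sample_ids),
                                  broken, gs, lengths,
                                  TrainSettings(n_perm=200, seed=1))

    def test_signature_round_trip(self, tmp_path):
        sig = signature({"A": 1.5, "B": -0.3}, intercept=0.7, cutoff=0.42)
        p = tmp_path / "sig.json"
        sig.to_json(p)
        back = PassSignature.from_json(p)
        assert back == sig
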