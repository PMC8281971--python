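"""Core estimator: labels, closed-form updates, objective, fit loop,
prediction, and consistency diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcper
from pcper.core import (
    FAKE_CONSISTENT,
    INCONSISTENT,
    INTRINSIC,
    GramPair,
    Hyperparams,
    categorize_consistency,
    decision_gradient,
    init_labeled_membership,
    solve_decision,
    update_membership,
)
from pcper.errors import InvalidInputError, InvalidParameterError

from oracles import (
    loop_decision_values,
    loop_full_objective,
    numeric_decision_minimizer,
    numeric_membership_minimizer,
)


def random_instance(rng, n=20, M=3, d=2, n_lab=None):
    """A small random semi-supervised problem with Gram pair and memberships."""
    n_lab = n_lab or 2 * M
    X = rng.standard_normal((n, d))
    codes = np.full(n, -1)
    lab = rng.choice(n, size=n_lab, replace=False)
    codes[lab] = np.concatenate([np.arange(M), rng.integers(0, M, n_lab - M)])
    labels = pcper.LabelSet(codes, M)
    g = pcper.build_knn_graph(X, k=4, gamma=0.7)
    K = pcper.gram(X, X, pcper.KernelConfig("rbf", 0.5))
    gp = GramPair.from_graph(K, g)
    V = rng.uniform(size=(M, labels.n_unlabeled))
    return X, labels, gp, V


class TestLabelSet:
    def test_labeled_block_is_identity_for_one_label_per_class(self):
        labels = pcper.LabelSet(np.array([0, 1, -1]), 2)
        V, fixed = init_labeled_membership(labels)
        np.testing.assert_array_equal(fixed, np.eye(2))
        np.testing.assert_array_equal(V, np.zeros((2, 1)))

    def test_three_class_onehot_row(self):
        labels = pcper.LabelSet(np.array([0, 1, 2, -1]), 3)
        Y = labels.onehot_labeled()
        np.testing.assert_array_equal(Y[:, 2], [0, 0, 1])

    def test_class_without_label_rejected(self):
        with pytest.raises(InvalidInputError):
            pcper.LabelSet(np.array([0, 0, -1]), 2)

    def test_out_of_range_code_rejected(self):
        with pytest.raises(InvalidInputError):
            pcper.LabelSet(np.array([0, 1, 2]), 2)


class TestSolveDecision:
    def test_identity_gram_ridge_closed_form(self):
        # fully labeled 2-point problem, K = I, lambda = 1: each output
        # coordinate minimizes (a - 1)^2 + a^2 -> a = 1/2
        labels = pcper.LabelSet(np.array([0, 1]), 2)
        gp = GramPair(np.eye(2), np.eye(2))
        alpha = solve_decision(gp, labels, np.zeros((2, 0)), lam=1.0, lam_s=0.0)
        np.testing.assert_allclose(alpha, 0.5 * np.eye(2), atol=1e-12)

    def test_zero_memberships_match_labeled_only_numeric_minimizer(self, rng):
        X, labels, gp, _ = random_instance(rng, n=12, M=2)
        V0 = np.zeros((2, labels.n_unlabeled))
        alpha = solve_decision(gp, labels, V0, lam=0.3, lam_s=0.0)
        a_num, f_num = numeric_decision_minimizer(
            gp.K, gp.K_bar, labels.codes, 2, V0, 0.3, 0.0,
            x0=alpha.ravel() + 0.05)
        f_cf = loop_full_objective(alpha, gp.K, gp.K_bar, labels.codes, 2,
                                   V0, 0.3, 0.0, C=1.0)
        assert f_cf <= f_num + 1e-6 * (1 + abs(f_num))

    def test_gradient_vanishes_at_solution(self, rng):
        X, labels, gp, V = random_instance(rng)
        alpha = solve_decision(gp, labels, V, lam=0.4, lam_s=0.2)
        g = decision_gradient(alpha, gp, labels, V, 0.4, 0.2)
        assert np.linalg.norm(g) <= 1e-6 * (1 + np.linalg.norm(alpha))

    def test_beats_random_perturbations(self, rng):
        X, labels, gp, V = random_instance(rng)
        lam, lam_s = 0.4, 0.2
        alpha = solve_decision(gp, labels, V, lam, lam_s)
        base = pcper.objective(alpha, V, gp, labels, lam, lam_s, 1.0)
        for _ in range(200):
            delta = 0.1 * rng.standard_normal(alpha.shape)
            pert = pcper.objective(alpha + delta, V, gp, labels, lam, lam_s, 1.0)
            assert base <= pert + 1e-10

    def test_invalid_parameters_rejected(self, rng):
        X, labels, gp, V = random_instance(rng)
        with pytest.raises(InvalidParameterError):
            solve_decision(gp, labels, V, lam=0.0, lam_s=0.1)
        with pytest.raises(InvalidInputError):
            solve_decision(gp, labels, V + 2.0, lam=0.1, lam_s=0.1)


class TestUpdateMembership:
    def test_zero_distances_give_full_membership(self):
        f = np.array([[1.0], [0.0]])  # f(x) = c_0 exactly
        w = update_membership(f, f, C=1.0, lambda_s=1.0)
        assert w[0, 0] == pytest.approx(1.0)

    def test_unit_distances_give_exp_minus_one(self):
        # ||f(x) - c_m||^2 = 1 and ||f(x_hat) - c_m||^2 = 1, lam_s=1, C=1
        f = np.array([[0.0], [0.0]])  # distance to each code is 1
        w = update_membership(f, f, C=1.0, lambda_s=1.0)
        np.testing.assert_allclose(w, np.exp(-1.0) * np.ones((2, 1)))

    def test_far_instances_get_vanishing_membership(self):
        f = np.array([[50.0], [-50.0]])
        w = update_membership(f, f, C=1.0, lambda_s=0.5)
        assert w.max() < 1e-300 or w.max() == 0.0

    @pytest.mark.parametrize("d1,d2,lam_s,C", [
        (0.3, 0.7, 0.1, 1.0), (2.0, 0.0, 1.5, 0.5), (0.0, 3.0, 0.7, 2.0)])
    def test_matches_numeric_minimizer(self, d1, d2, lam_s, C):
        # build f-values realizing the requested squared distances to c_0
        # in a 2-class layout: f = (1 - sqrt(d/2), sqrt(d/2)) has
        # ||f - c_0||^2 = d
        def fvec(d):
            s = np.sqrt(d / 2.0)
            return np.array([[1.0 - s], [s]])

        w = update_membership(fvec(d1), fvec(d2), C=C, lambda_s=lam_s)[0, 0]
        w_num = numeric_membership_minimizer(d1, d2, lam_s, C)
        assert w == pytest.approx(w_num, abs=1e-6)

    def test_nonpositive_C_rejected(self):
        with pytest.raises(InvalidParameterError):
            update_membership(np.zeros((2, 1)), np.zeros((2, 1)), 0.0, 0.1)


class TestObjective:
    def test_zero_alpha_zero_membership(self, rng):
        X, labels, gp, _ = random_instance(rng, n=15, M=3)
        V0 = np.zeros((3, labels.n_unlabeled))
        lam_s = 0.4
        F = pcper.objective(np.zeros((3, 15)), V0, gp, labels, 0.1, lam_s, 2.0)
        assert F == pytest.approx(labels.n_labeled * (1 + lam_s))

    def test_full_membership_at_zero_distance_contributes_minus_C(self):
        # perfect decision values, one unlabeled point with w = 1 in its
        # class: the entropy term contributes exactly -C
        labels = pcper.LabelSet(np.array([0, 1, -1]), 2)
        gp = GramPair(np.eye(3), np.eye(3))
        alpha = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])  # f(x_j) = codes
        V = np.array([[1.0], [0.0]])
        lam, C = 0.01, 2.0
        F = pcper.objective(alpha, V, gp, labels, lam, 0.0, C)
        assert F == pytest.approx(lam * 3.0 - C, rel=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        X, labels, gp, V = random_instance(rng, n=10, M=3)
        alpha = rng.standard_normal((3, 10))
        got = pcper.objective(alpha, V, gp, labels, 0.2, 0.3, 1.5)
        want = loop_full_objective(alpha, gp.K, gp.K_bar, labels.codes, 3,
                                   V, 0.2, 0.3, 1.5)
        assert got == pytest.approx(want, rel=1e-10)


class TestFit:
    def test_two_separated_classes_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 0.3, 12), rng.normal(10, 0.3, 12)])[:, None]
        codes = np.full(24, -1)
        codes[0], codes[12] = 0, 1
        labels = pcper.LabelSet(codes, 2)
        model = pcper.fit(X, labels, Hyperparams(k=3))
        truth = np.repeat([0, 1], 12)
        assert np.array_equal(pcper.predict(model), truth)

    def test_objective_trace_non_increasing(self):
        for seed in range(5):
            spec = pcper.SyntheticSpec(M=2, n_per_class=15, d=2, seed=seed,
                                       n_labeled_per_class=2, n_labeled_total=None)
            X, labels, *_ = pcper.make_problem(spec)
            m = pcper.fit(X, labels)
            tr = np.array(m.objective_trace)
            assert np.all(np.diff(tr) <= 1e-10 * np.abs(tr[:-1]))

    def test_max_iter_zero_is_labeled_only_initialization(self, blob_problem):
        X, labels, *_ = blob_problem
        m = pcper.fit(X, labels, Hyperparams(max_iter=0))
        assert m.objective_trace == [] and not m.converged
        V0 = np.zeros((labels.M, labels.n_unlabeled))
        expected = solve_decision(m.gram_pair, labels, V0,
                                  m.hyper.lambda_, m.hyper.lambda_s)
        np.testing.assert_allclose(m.alpha, expected, atol=1e-12)

    def test_all_identical_points_rejected(self):
        labels = pcper.LabelSet(np.array([0, 1, -1, -1]), 2)
        with pytest.raises(InvalidInputError):
            pcper.fit(np.ones((4, 2)), labels)

    def test_fully_labeled_rejected(self):
        labels = pcper.LabelSet(np.array([0, 1, 0, 1]), 2)
        with pytest.raises(InvalidInputError):
            pcper.fit(np.arange(8.0).reshape(4, 2), labels)


class TestPrediction:
    def test_training_decision_values_equal_alpha_K(self, blob_model):
        model, X, labels, _ = blob_model
        np.testing.assert_allclose(
            pcper.decision_values(model), (model.alpha @ model.Ktrain).T)
        # and out-of-sample evaluation at the training points agrees
        np.testing.assert_allclose(
            pcper.decision_values(model, X), (model.alpha @ model.Ktrain).T,
            atol=1e-10)

    def test_zero_alpha_gives_zero_scores_and_lowest_code_ties(self, blob_model):
        model, X, labels, _ = blob_model
        import dataclasses
        zero = dataclasses.replace(model, alpha=np.zeros_like(model.alpha))
        assert np.all(pcper.decision_values(zero) == 0)
        assert np.all(pcper.predict(zero) == 0)  # exact ties -> class 0

    def test_decision_values_match_scalar_loop(self, rng, blob_model):
        model, X, *_ = blob_model
        Xnew = X[:5] + 0.05 * rng.standard_normal((5, 2))
        Kx = pcper.gram(model.Xtrain, Xnew, model.kernel)
        want = loop_decision_values(model.alpha, Kx).T
        np.testing.assert_allclose(pcper.decision_values(model, Xnew), want,
                                   atol=1e-10)

    def test_membership_path_mirrors_update_formula(self, blob_model):
        model, X, labels, _ = blob_model
        W = pcper.membership_values(model)
        fX = model.alpha @ model.Ktrain
        fL = model.alpha @ model.K_bar
        want = update_membership(fX, fL, model.hyper.C, model.hyper.lambda_s).T
        np.testing.assert_allclose(W, want, atol=1e-12)
        assert np.all(W > 0) and np.all(W <= 1.0)

    def test_lambda_s_zero_makes_both_predictors_identical(self, blob_problem):
        X, labels, truth, _ = blob_problem
        model = pcper.fit(X, labels, Hyperparams(lambda_s=0.0))
        pd_ = pcper.predict(model, by="decision")
        pm = pcper.predict(model, by="membership")
        np.testing.assert_array_equal(pd_, pm)

    def test_unknown_score_rejected(self, blob_model):
        model, *_ = blob_model
        with pytest.raises(InvalidParameterError):
            pcper.predict(model, by="argmax")


class TestConsistency:
    def test_equal_decision_values_are_intrinsic(self):
        f = np.array([[0.8, 0.1], [0.2, 0.9]])
        cats = categorize_consistency(f, f, lambda_s=0.5)
        assert list(cats) == [INTRINSIC, INTRINSIC]

    def test_fake_consistent_margin_inequality(self):
        # argmax differs but 0.5 - 0.4 = 0.1 < (1 - 0)/0.1 = 10
        fX = np.array([[1.0], [0.0]])
        fL = np.array([[0.4], [0.5]])
        cats = categorize_consistency(fX, fL, lambda_s=0.1)
        assert cats[0] == FAKE_CONSISTENT

    def test_inconsistent_when_margin_fails(self):
        # 1 - 0 = 1 >= (0.6 - 0.4)/10 = 0.02
        fX = np.array([[0.6], [0.4]])
        fL = np.array([[0.0], [1.0]])
        cats = categorize_consistency(fX, fL, lambda_s=10.0)
        assert cats[0] == INCONSISTENT

    def test_lambda_s_zero_rate_is_exactly_one(self, blob_problem):
        X, labels, *_ = blob_problem
        model = pcper.fit(X, labels, Hyperparams(lambda_s=0.0))
        rep = pcper.classify_consistency(model)
        assert rep.prediction_consistency_rate == 1.0
        assert rep.ground_truth_consistency_rate == 1.0

    def test_categories_partition_instances(self, blob_model):
        model, X, labels, _ = blob_model
        rep = pcper.classify_consistency(model)
        assert sum(rep.counts.values()) == labels.n
        # agreement between the two predictors covers intrinsic and fake
        agree = pcper.predict(model, by="decision") == pcper.predict(
            model, by="membership")
        cats = rep.categories
        assert np.all(agree[(cats == INTRINSIC) | (cats == FAKE_CONSISTENT)])


class TestPrecomputedKernel:
    def test_linear_gram_matches_explicit_linear_kernel(self, blob_problem):
        # under a linear kernel the feature space IS the input space, so
        # the precomputed route (graph from kernel-space distances) must
        # reproduce the explicit-feature route exactly
        X, labels, truth, _ = blob_problem
        m_feat = pcper.fit(X, labels, kernel=pcper.KernelConfig("linear"))
        m_pre = pcper.fit(X @ X.T, labels, kernel=pcper.KernelConfig("precomputed"))
        assert m_pre.hyper == m_feat.hyper  # same auto gamma and C
        np.testing.assert_array_equal(m_pre.graph.neighbors, m_feat.graph.neighbors)
        # alpha itself is non-unique when K is rank-deficient (linear kernel,
        # d << n); the decision values f = alpha K are the determined quantity
        np.testing.assert_allclose(pcper.decision_values(m_pre),
                                   pcper.decision_values(m_feat), atol=1e-6)
        np.testing.assert_array_equal(pcper.predict(m_pre), pcper.predict(m_feat))
        # transductive membership path is available for precomputed models
        W = pcper.membership_values(m_pre)
        assert W.shape == (labels.n, labels.M)

    def test_out_of_sample_needs_cross_gram(self, blob_problem):
        X, labels, *_ = blob_problem
        m = pcper.fit(X @ X.T, labels, kernel=pcper.KernelConfig("precomputed"))
        Kx = X[:4] @ X.T  # (n_new, n_train) cross-Gram
        np.testing.assert_allclose(pcper.decision_values(m, Kx),
                                   pcper.decision_values(m)[:4], atol=1e-10)
        with pytest.raises(InvalidInputError):
            pcper.membership_values(m, Kx)  # LWM path is transductive-only


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    vals=st.lists(st.floats(-3, 3), min_size=6, max_size=6),
    lam_s=st.floats(0.0, 2.0),
    C=st.floats(0.05, 5.0),
)
def test_membership_values_always_in_unit_interval(vals, lam_s, C):
    f = np.asarray(vals).reshape(3, 2)
    w = update_membership(f, -f, C=C, lambda_s=lam_s)
    assert np.all(w >= 0.0) and np.all(w <= 1.0)
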