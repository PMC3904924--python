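"""Criterion functions and their exact minimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlsep import (
    CplSpec,
    FeatureSubspace,
    LinearClassifier,
    is_linearly_separable,
    minimize_cpl,
    phi,
    psi,
)
from ._oracle import oracle_min_psi, oracle_separable, random_instance
from .conftest import make_dataset


def clf1d(w, theta):
    return LinearClassifier(np.array([w]), theta, FeatureSubspace((0,)))


class TestCriterionValues:
    @pytest.mark.parametrize(
        "w,theta,expected",
        [
            (1.0, 1.0, 0.0),   # both margins met exactly
            (1.0, 0.0, 0.5),   # hinge terms 0 and 1, class-balanced alpha
            (0.0, 0.0, 1.0),   # every hinge term equals delta
        ],
    )
    def test_phi_hand_values(self, toy_1d, w, theta, expected):
        assert phi(clf1d(w, theta), toy_1d) == pytest.approx(expected)

    def test_phi_zero_at_w0_is_delta_weighted(self, xor_2d):
        # w = 0: every hinge is delta, so Phi = delta * sum(alpha) = 1
        clf = LinearClassifier(np.zeros(2), 0.0, FeatureSubspace((0, 1)))
        assert phi(clf, xor_2d) == pytest.approx(1.0)

    def test_psi_reduces_to_phi_at_lam0(self, toy_1d):
        clf = clf1d(1.3, 0.2)
        assert psi(clf, toy_1d, CplSpec(lam=0.0)) == pytest.approx(phi(clf, toy_1d))

    def test_psi_adds_cost_term(self, toy_1d):
        assert psi(clf1d(1.0, 1.0), toy_1d, CplSpec(lam=0.3)) == pytest.approx(0.3)

    def test_psi_with_zero_weights_ignores_lam(self, toy_1d):
        clf = clf1d(0.0, 0.4)
        for lam in (0.0, 1.0, 100.0):
            assert psi(clf, toy_1d, CplSpec(lam=lam)) == pytest.approx(
                phi(clf, toy_1d))

    def test_theta_never_penalized(self, toy_1d):
        a = psi(clf1d(1.0, 5.0), toy_1d, CplSpec(lam=2.0))
        b = psi(clf1d(1.0, -5.0), toy_1d, CplSpec(lam=2.0))
        # same |w| cost, different theta: cost parts equal
        assert a - phi(clf1d(1.0, 5.0), toy_1d) == pytest.approx(
            b - phi(clf1d(1.0, -5.0), toy_1d))


class TestMinimization:
    def test_separable_toy_reaches_zero(self, toy_1d):
        sol = minimize_cpl(toy_1d)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert phi(sol.classifier, toy_1d) == pytest.approx(0.0, abs=1e-9)

    def test_xor_positive_and_matches_oracle(self, xor_2d):
        sol = minimize_cpl(xor_2d)
        assert sol.objective > 0.1
        alpha = CplSpec().resolve_alpha(xor_2d.y)
        ref = oracle_min_psi(xor_2d.X, xor_2d.y, alpha, np.ones(2), 0.0)
        assert sol.objective == pytest.approx(ref, abs=1e-6)

    def test_huge_lambda_kills_all_weights(self, xor_2d, toy_1d):
        for ds in (xor_2d, toy_1d):
            sol = minimize_cpl(ds, CplSpec(lam=1e3))
            assert np.all(sol.classifier.weights == 0.0)
            assert sol.objective == pytest.approx(1.0, abs=1e-6)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            X, y = random_instance(rng)
            ds = make_dataset(X, y)
            alpha = CplSpec().resolve_alpha(y)
            for lam in (0.0, 0.01, 0.1, 1.0):
                sol = minimize_cpl(ds, CplSpec(lam=lam))
                ref = oracle_min_psi(X, y, alpha, np.ones(X.shape[1]), lam)
                assert sol.objective == pytest.approx(ref, abs=1e-6)

    def test_objective_nondecreasing_in_lambda(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, m_max=25, n_max=5)
        ds = make_dataset(X, y)
        objs = [minimize_cpl(ds, CplSpec(lam=lam)).objective
                for lam in (0.0, 0.01, 0.1, 1.0, 10.0)]
        assert all(b >= a - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_phi_part_nondecreasing_under_feature_removal(self):
        rng = np.random.default_rng(6)
        X, y = random_instance(rng, m_max=25, n_max=6)
        ds = make_dataset(X, y)
        n = X.shape[1]
        prev = -1.0
        for k in range(n, 0, -1):
            sol = minimize_cpl(ds, CplSpec(lam=0.0), FeatureSubspace(tuple(range(k))))
            assert sol.objective >= prev - 1e-9
            prev = sol.objective

    def test_subspace_restriction(self, wide_margin_cohort):
        sol = minimize_cpl(wide_margin_cohort, subspace=FeatureSubspace((0,)))
        assert sol.classifier.subspace.dimension == 1
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_missing_values_rejected(self, toy_1d):
        ds = toy_1d
        ds.X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            minimize_cpl(ds)


class TestSeparability:
    def test_basic_cases(self, toy_1d, xor_2d):
        assert is_linearly_separable(toy_1d)
        assert not is_linearly_separable(xor_2d)

    def test_general_position_always_separable(self):
        # <= d+1 points in general position are separable for any labels
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 9))
        for trial in range(5):
            y = rng.choice([-1, 1], 10)
            if not ((y == 1).any() and (y == -1).any()):
                continue
            ds = make_dataset(X, y)
            assert is_linearly_separable(ds)
            assert oracle_separable(X, y)

    def test_agrees_with_lp_feasibility(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            X, y = random_instance(rng, m_max=30, n_max=6)
            ds = make_dataset(X, y)
            assert is_linearly_separable(ds) == oracle_separable(X, y)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(17)
        X, y = random_instance(rng, m_max=20, n_max=4)
        base = is_linearly_separable(make_dataset(X, y))
        assert is_linearly_separable(make_dataset(X * scale, y)) == base

    def test_superspace_inheritance(self, wide_margin_cohort):
        ds = wide_margin_cohort
        assert is_linearly_separable(ds, FeatureSubspace((0,)))
        assert is_linearly_separable(ds, FeatureSubspace((0, 3, 7)))
        assert is_linearly_separable(ds)  # full space


class TestCplSpec:
    def test_default_alpha_class_balanced(self):
        y = np.array([1, 1, 1, -1, -1])
        a = CplSpec().resolve_alpha(y)
        assert a[y == 1].sum() == pytest.approx(0.5)
        assert a[y == -1].sum() == pytest.approx(0.5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CplSpec(lam=-1.0)
        with pytest.raises(ValueError):
            CplSpec(delta=0.0)
        with pytest.raises(ValueError):
            CplSpec(gamma=np.array([1.0, 0.0]))
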