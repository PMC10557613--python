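"""Permutation GLM, BH correction, and BIC Bayes factors."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemimorph import (
    PermutationGLMTester,
    bayes_factor_bic,
    bh_adjust,
    fit_glm,
    permutation_test,
)
from hemimorph.inference import _perm_betas


def _instance(rng, n=40, effect=0.0):
    group = rng.permutation(np.repeat([0.0, 1.0], n // 2))
    cov = np.column_stack([rng.uniform(8, 24, n), rng.integers(0, 2, n)])
    y = 2.5 + effect * group - 0.01 * cov[:, 0] + 0.05 * cov[:, 1] + rng.normal(0, 0.2, n)
    return y, group, cov


# ------------------------------------------------------------------------ GLM


def test_constant_y_gives_zero_slopes(rng):
    y = np.full(20, 3.0)
    X = np.column_stack([np.ones(20), rng.integers(0, 2, 20), rng.uniform(0, 1, 20)])
    beta = fit_glm(y, X, names=["intercept", "group", "age"])
    assert beta["group"] == pytest.approx(0.0, abs=1e-12)
    assert beta["intercept"] == pytest.approx(3.0)


def test_exact_linear_in_age_recovered(rng):
    n = 30
    age = rng.uniform(8, 24, n)
    group = rng.integers(0, 2, n).astype(float)
    y = 1.0 + 0.5 * age
    X = np.column_stack([np.ones(n), group, age])
    beta = fit_glm(y, X, names=["intercept", "group", "age"])
    assert beta["age"] == pytest.approx(0.5)
    assert beta["group"] == pytest.approx(0.0, abs=1e-10)


def test_matches_normal_equations_oracle(rng):
    n = 12
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    y = rng.normal(size=n)
    beta = fit_glm(y, X).to_numpy()
    oracle = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(beta, oracle, atol=1e-10)


def test_rank_deficient_design_rejected(rng):
    n = 15
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(np.linalg.LinAlgError):
        fit_glm(rng.normal(size=n), X)


def test_fwl_shortcut_equals_full_ols(rng):
    """The vectorized permutation beta equals the plain GLM group coefficient."""
    y, group, cov = _instance(rng, effect=0.3)
    n = len(y)
    X = np.column_stack([np.ones(n), group, cov])
    full = fit_glm(y, X, names=["b0", "group", "age", "gender"])["group"]
    fwl = _perm_betas(y, group, cov, np.arange(n)[None, :])[0]
    assert fwl == pytest.approx(full, abs=1e-10)


# ---------------------------------------------------------------- permutation


def test_constant_y_degenerate_p_zero(rng):
    y = np.full(16, 2.0)
    group = np.repeat([0.0, 1.0], 8)
    res = permutation_test(y, group, n_perm=200, random_state=0)
    assert res.beta_obs == 0.0
    assert res.p_raw == 0.0  # strict '>' never exceeds |0|
    smoothed = permutation_test(y, group, n_perm=200, random_state=0, tie_rule="smoothed")
    assert smoothed.p_raw == pytest.approx(1.0 / 201.0)


def test_exhaustive_enumeration_oracle_small_n(rng):
    """1,000 shuffles agree with the exhaustive 70-relabeling p at n=8."""
    n = 8
    y, group, cov = _instance(rng, n=n, effect=0.4)
    res = permutation_test(y, group, cov, n_perm=1000, random_state=3)
    # oracle: all C(8,4)=70 assignments of four 1-labels, brute-force OLS
    betas = []
    for ones in combinations(range(n), 4):
        g = np.zeros(n)
        g[list(ones)] = 1.0
        X = np.column_stack([np.ones(n), g, cov])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            betas.append(0.0)  # relabeling collinear with covariates
        else:
            betas.append(np.linalg.lstsq(X, y, rcond=None)[0][1])
    tol = 1e-9 * max(1.0, abs(res.beta_obs))
    p_exact = np.mean(np.abs(betas) > abs(res.beta_obs) + tol)
    mc_sd = np.sqrt(p_exact * (1 - p_exact) / 1000)
    assert abs(res.p_raw - p_exact) <= 3 * mc_sd + 1e-12


def test_p_invariant_to_group_relabeling(rng):
    y, group, cov = _instance(rng, effect=0.3)
    a = permutation_test(y, group, cov, n_perm=500, random_state=7)
    b = permutation_test(y, 1.0 - group, cov, n_perm=500, random_state=7)
    assert a.p_raw == b.p_raw
    assert a.beta_obs == pytest.approx(-b.beta_obs)


def test_p_and_bf_invariant_to_constant_shift(rng):
    y, group, cov = _instance(rng, effect=0.3)
    n = len(y)
    X0 = np.column_stack([np.ones(n), cov])
    X1 = np.column_stack([X0, group])
    a = permutation_test(y, group, cov, n_perm=300, random_state=5)
    b = permutation_test(y + 100.0, group, cov, n_perm=300, random_state=5)
    assert a.p_raw == b.p_raw
    assert bayes_factor_bic(y, X1, X0) == pytest.approx(
        bayes_factor_bic(y + 100.0, X1, X0), rel=1e-9
    )


def test_single_group_rejected():
    with pytest.raises(ValueError, match="group"):
        permutation_test(np.arange(6.0), np.ones(6), n_perm=10)


def test_power_monotone_in_effect_size():
    """Median p over replicates shrinks as the injected effect grows."""
    med_ps = []
    for effect in (0.0, 0.15, 0.4):
        ps = []
        for seed in range(30):
            r = np.random.default_rng(1000 + seed)
            y, group, cov = _instance(r, n=60, effect=effect)
            ps.append(
                permutation_test(y, group, cov, n_perm=300, random_state=seed).p_raw
            )
        med_ps.append(np.median(ps))
    assert med_ps[0] > med_ps[1] > med_ps[2]


# ------------------------------------------------------------------------- BH


def test_bh_hand_computed_step_up():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_monotone_and_bounded(ps):
    q = bh_adjust(ps)
    assert np.all((q >= 0) & (q <= 1))
    order = np.argsort(ps)
    assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)  # p_i <= p_j => q_i <= q_j


# ------------------------------------------------------------------------- BF


def test_bf_sqrt_n_when_group_explains_nothing():
    n = 36
    rng = np.random.default_rng(2)
    cov = rng.normal(size=(n, 2))
    X0 = np.column_stack([np.ones(n), cov])
    # group column orthogonal to y's residuals: y independent of a group col
    # that is itself in X0's column space -> identical RSS
    group = X0 @ np.array([0.5, 1.0, -2.0])  # lies in span(X0)
    X1 = np.column_stack([X0, group])
    y = rng.normal(size=n)
    # identical RSS => BF01 = sqrt(n) exactly under the BIC approximation
    # (rank-deficient X1 is fine for lstsq: min-norm solution, same fit)
    assert bayes_factor_bic(y, X1, X0) == pytest.approx(np.sqrt(n), rel=1e-9)


def test_bf_supports_alternative_under_strong_effect():
    rng = np.random.default_rng(3)
    n = 80
    group = np.repeat([0.0, 1.0], n // 2)
    y = 1.0 + 2.0 * 0.2 * group + rng.normal(0, 0.2, n)  # beta = 2 noise SDs
    X0 = np.ones((n, 1))
    X1 = np.column_stack([X0, group])
    assert bayes_factor_bic(y, X1, X0) < 1.0


def test_bf_matches_direct_bic_arithmetic(rng):
    y, group, cov = _instance(rng, effect=0.25)
    n = len(y)
    X0 = np.column_stack([np.ones(n), cov])
    X1 = np.column_stack([X0, group])

    def ll(X):
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - X @ b) ** 2)
        return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)

    bic1 = X1.shape[1] * np.log(n) - 2 * ll(X1)
    bic0 = X0.shape[1] * np.log(n) - 2 * ll(X0)
    assert bayes_factor_bic(y, X1, X0) == pytest.approx(np.exp((bic1 - bic0) / 2))


def test_non_nested_designs_rejected(rng):
    n = 20
    X0 = np.column_stack([np.ones(n), rng.normal(size=n)])
    X1 = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    with pytest.raises(ValueError, match="nested"):
        bayes_factor_bic(rng.normal(size=n), X1, X0)


# -------------------------------------------------------------------- tester


def test_tester_results_frame_and_substream_independence(rng):
    n = 50
    group = np.repeat([0.0, 1.0], 25)
    cov = np.column_stack([rng.uniform(8, 24, n), rng.integers(0, 2, n)])
    X = rng.normal(size=(n, 3)) + 0.5 * group[:, None] * np.array([1.0, 0.0, 0.0])
    t_all = PermutationGLMTester(n_perm=200, random_state=9).fit(
        X, group, covariates=cov, feature_names=["a", "b", "c"]
    )
    # per-feature substreams: dropping a column leaves the others' p unchanged
    t_sub = PermutationGLMTester(n_perm=200, random_state=9).fit(
        X[:, :2], group, covariates=cov, feature_names=["a", "b"]
    )
    assert t_all.p_values_[0] == t_sub.p_values_[0]
    assert t_all.p_values_[1] == t_sub.p_values_[1]
    assert list(t_all.results_.columns) == [
        "region", "beta_obs", "p_raw", "q_bh", "bf01", "n_perm",
    ]
    assert np.allclose(t_all.q_values_, bh_adjust(t_all.p_values_))
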