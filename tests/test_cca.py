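"""Canonical correlation solver, contributions and Pillai-Bartlett tests."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tdslink import (
    canonical_series,
    coefficient_table,
    contribution_proportions,
    fit_cca,
    permutation_pillai_pvalue,
    pillai_dimension_tests,
    select_num_variables,
)
from tdslink.cca import DimensionTestTable, model_to_dict


def grid_search_rho1(x, y, n_angles=2000):
    """Independent brute-force maximizer of corr(Xa, Yb) over dense grids of
    unit coefficient directions (p = q = 2 only)."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    theta = np.linspace(0, np.pi, n_angles, endpoint=False)
    a = np.stack([np.cos(theta), np.sin(theta)])
    b = np.stack([np.cos(theta), np.sin(theta)])
    u = x @ a  # N x n_angles
    v = y @ b
    u = u / np.linalg.norm(u, axis=0, keepdims=True)
    v = v / np.linalg.norm(v, axis=0, keepdims=True)
    return float(np.abs(u.T @ v).max())


def _random_pair(seed, n=50, p=2, q=2, couple=0.5):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 1))
    x = rng.normal(size=(n, p)) + couple * z
    y = rng.normal(size=(n, q)) + couple * z
    return x - x.mean(0), y - y.mean(0)


class TestFitCCA:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 4))
        model = fit_cca(x, x.copy())
        np.testing.assert_allclose(model.correlations, 1.0, atol=1e-8)

    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 2 * x
        model = fit_cca(x, y)
        assert model.correlations[0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_grid_search_oracle(self, seed):
        x, y = _random_pair(seed)
        model = fit_cca(x, y)
        assert model.correlations[0] == pytest.approx(
            grid_search_rho1(x, y), abs=1e-3
        )

    def test_training_invariants(self):
        """corr(u_j, v_j) equals rho_j and variates of one set are mutually
        uncorrelated."""
        x, y = _random_pair(7, n=80, p=5, q=3)
        model = fit_cca(x, y)
        u = x @ model.coeff_x.T
        v = y @ model.coeff_y.T
        for j in range(model.r):
            c = np.corrcoef(u[:, j], v[:, j])[0, 1]
            assert c == pytest.approx(model.correlations[j], abs=1e-8)
        for mat in (u, v):
            corr = np.corrcoef(mat.T)
            off = corr - np.diag(np.diag(corr))
            assert np.abs(off).max() < 1e-8
        assert np.all(np.diff(model.correlations) <= 1e-12)
        # unit-variance variate scaling
        np.testing.assert_allclose(u.var(axis=0, ddof=1), 1.0, atol=1e-8)

    @given(
        scales=st.lists(
            st.floats(min_value=0.1, max_value=9.0), min_size=5, max_size=5
        ),
        offsets=st.lists(
            st.floats(min_value=-5, max_value=5), min_size=5, max_size=5
        ),
    )
    def test_affine_invariance(self, scales, offsets):
        x, y = _random_pair(11, n=60, p=3, q=2)
        base = fit_cca(x, y).correlations
        sx = np.array(scales[:3])
        sy = np.array(scales[3:])
        rescaled = fit_cca(
            x * sx + np.array(offsets[:3]), y * sy + np.array(offsets[3:])
        ).correlations
        np.testing.assert_allclose(rescaled, base, atol=1e-8)

    def test_sign_convention(self):
        x, y = _random_pair(5, n=70, p=4, q=3)
        model = fit_cca(x, y)
        for j in range(model.r):
            i = np.argmax(np.abs(model.coeff_x[j]))
            assert model.coeff_x[j, i] > 0

    def test_rank_deficiency_gets_ridge_and_warning(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 2))
        x = np.column_stack([x, x[:, 0]])  # duplicated column
        y = rng.normal(size=(30, 2))
        with pytest.warns(UserWarning, match="rank deficient"):
            model = fit_cca(x, y)
        assert model.ridge_x > 0

    def test_small_sample_warning(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="overfit"):
            fit_cca(rng.normal(size=(8, 4)), rng.normal(size=(8, 4)))


class TestCanonicalSeries:
    def test_zero_input_gives_zero_series(self):
        x, y = _random_pair(3)
        model = fit_cca(x, y)
        series = canonical_series(
            model, np.zeros((10, 2)), np.zeros((10, 2))
        )
        np.testing.assert_array_equal(series.u, 0.0)
        np.testing.assert_array_equal(series.v, 0.0)

    def test_training_stack_reproduces_correlations(self):
        x, y = _random_pair(4, n=60)
        model = fit_cca(x, y)
        series = canonical_series(model, x, y)
        for j in range(model.r):
            c = np.corrcoef(series.u[:, j], series.v[:, j])[0, 1]
            assert c == pytest.approx(model.correlations[j], abs=1e-8)

    def test_homogeneity(self):
        x, y = _random_pair(5)
        model = fit_cca(x, y)
        s1 = canonical_series(model, x, y)
        s2 = canonical_series(model, 2 * x, 2 * y)
        np.testing.assert_allclose(s2.u, 2 * s1.u)

    def test_attribute_order_checked(self):
        x, y = _random_pair(5)
        model = fit_cca(x, y)
        with pytest.raises(ValueError, match="attribute order"):
            canonical_series(model, x, y, attributes_x=("b", "a"))


class TestContributions:
    def test_bruteforce_recomputation(self):
        x, y = _random_pair(9, n=90, p=5, q=3)
        model = fit_cca(x, y)
        table = contribution_proportions(model, x, y)
        u = x @ model.coeff_x.T
        for j in range(model.r):
            direct = np.mean(
                [np.corrcoef(x[:, k], u[:, j])[0, 1] ** 2 for k in range(5)]
            )
            assert table.contributions_x[j] == pytest.approx(direct, abs=1e-10)

    def test_full_rank_smaller_set_sums_to_one(self):
        x, y = _random_pair(10, n=120, p=6, q=4)
        model = fit_cca(x, y)
        table = contribution_proportions(model, x, y)
        assert table.contributions_y.sum() == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_set_contributes_equally(self):
        """If Y's columns are exactly uncorrelated and standardized, every
        canonical variate extracts 1/q of Y's variance."""
        rng = np.random.default_rng(2)
        n, q = 80, 4
        a = rng.normal(size=(n, q))
        a -= a.mean(axis=0)
        qmat, _ = np.linalg.qr(a)
        y = qmat * np.sqrt(n - 1)
        x = rng.normal(size=(n, 5))
        model = fit_cca(x - x.mean(0), y)
        table = contribution_proportions(model, x, y)
        np.testing.assert_allclose(table.contributions_y, 1 / q, atol=1e-8)

    def test_zero_variance_column_rejected(self):
        x, y = _random_pair(1)
        model = fit_cca(x, y)
        bad = y.copy()
        bad[:, 0] = 0.0
        with pytest.raises(ValueError, match="zero-variance"):
            contribution_proportions(model, x, bad)


class TestPillai:
    def test_trace_is_tail_sum_of_squares(self):
        x, y = _random_pair(6, n=100, p=4, q=3)
        model = fit_cca(x, y)
        table = pillai_dimension_tests(model)
        rho2 = model.correlations**2
        for j in range(model.r):
            assert table.pillai_trace[j] == pytest.approx(
                rho2[j:].sum(), abs=1e-10
            )
        assert np.all(np.diff(table.pillai_trace) <= 1e-12)
        assert np.all((table.p_value >= 0) & (table.p_value <= 1))

    def test_null_correlations_give_p_one(self):
        x, y = _random_pair(6, n=100, p=4, q=3)
        model = fit_cca(x, y)
        model.correlations = np.zeros(3)
        table = pillai_dimension_tests(model)
        np.testing.assert_array_equal(table.pillai_trace, 0.0)
        np.testing.assert_array_equal(table.p_value, 1.0)

    def test_known_trace_values(self):
        x, y = _random_pair(6, n=100, p=2, q=2)
        model = fit_cca(x, y)
        model.correlations = np.array([0.8, 0.5])
        table = pillai_dimension_tests(model)
        np.testing.assert_allclose(table.pillai_trace, [0.89, 0.25])

    def test_needs_enough_samples(self):
        x, y = _random_pair(6, n=100, p=4, q=3)
        model = fit_cca(x, y)
        with pytest.raises(ValueError, match="N > p \\+ q"):
            pillai_dimension_tests(model, n_samples=7)

    def test_agrees_with_permutation_oracle(self):
        """The asymptotic first-dimension p-value matches a row-shuffling
        permutation oracle on an iid instance within Monte-Carlo error."""
        x, y = _random_pair(17, n=60, p=3, q=2, couple=0.25)
        model = fit_cca(x, y)
        p_asym = pillai_dimension_tests(model).p_value[0]
        p_perm = permutation_pillai_pvalue(x, y, n_permutations=1000, seed=0)
        assert 0.01 < p_asym < 0.99  # informative, non-degenerate instance
        assert p_asym == pytest.approx(p_perm, abs=0.05)


class TestSelectNumVariables:
    def _table(self, pvals):
        k = len(pvals)
        return DimensionTestTable(
            pillai_trace=np.zeros(k), f_value=np.zeros(k),
            df1=np.zeros(k), df2=np.zeros(k),
            p_value=np.array(pvals), alpha=0.05,
            n_selected=0,
        )

    def test_sequential_cutoff(self):
        assert select_num_variables(self._table([0.001, 0.01, 0.2, 0.3])) == 2

    def test_saturation(self):
        assert select_num_variables(self._table([0.01, 0.01, 0.01])) == 3

    def test_stops_at_first_failure_without_resuming(self):
        assert select_num_variables(self._table([0.001, 0.2, 0.01])) == 1


def test_coefficient_table_scaling():
    x, y = _random_pair(8, n=70, p=4, q=3)
    model = fit_cca(x, y)
    raw = coefficient_table(model, "x")
    assert list(raw.index) == list(model.attributes_x)
    scaled = coefficient_table(model, "x", scale="sum-abs-100")
    np.testing.assert_allclose(scaled.abs().sum(axis=0), 100.0)
    # scaling preserves within-dimension patterns
    ratio = raw.iloc[:, 0] / scaled.iloc[:, 0]
    np.testing.assert_allclose(ratio, ratio.iloc[0])


def test_model_serialization_roundtrip(tmp_path):
    import json

    from tdslink.cca import write_model

    x, y = _random_pair(8, n=70, p=4, q=3)
    model = fit_cca(x, y)
    tests = pillai_dimension_tests(model)
    contrib = contribution_proportions(model, x, y)
    path = tmp_path / "model.json"
    write_model(path, model, tests, contrib)
    data = json.loads(path.read_text())
    np.testing.assert_allclose(data["correlations"], model.correlations)
    assert data["pillai_tests"]["n_selected"] == tests.n_selected
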