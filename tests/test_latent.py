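import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from screenmine.latent import (
    assign_items,
    bivariate_normal_cdf,
    cronbach_alpha,
    oblimin_rotate,
    principal_axis_factor,
    tetrachoric_matrix,
    tetrachoric_pair,
    tucker_congruence,
)
from screenmine.synthetic import GeneratorConfig, generate
from screenmine.transactions import TransactionMatrix


class TestBivariateNormalCdf:
    @pytest.mark.parametrize("h,k,rho", [
        (0.0, 0.0, 0.5), (0.0, 1.0, -0.7), (2.0, -1.0, 0.9),
        (1.0, 1.0, 0.999), (-0.3, 0.4, 0.0), (1.5, -2.0, -0.95),
    ])
    def test_against_scipy_mvn(self, h, k, rho):
        ref = stats.multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
        assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)

    def test_degenerate_correlations(self):
        assert bivariate_normal_cdf(0.5, 1.5, 1.0) == pytest.approx(
            stats.norm.cdf(0.5))
        assert bivariate_normal_cdf(0.5, -0.5, -1.0) == pytest.approx(0.0, abs=1e-12)


class TestTetrachoricPair:
    def test_independence_table(self):
        # margins 0.5 x 0.8, cells exactly proportional to independence
        table = np.array([[40, 10], [40, 10]])
        assert tetrachoric_pair(table).rho == pytest.approx(0.0, abs=0.01)

    def test_simulation_recovery(self):
        config = GeneratorConfig(
            n=100_000, items=("a", "b"), prevalences=np.array([0.8, 0.6]),
            loadings=np.array([[np.sqrt(0.5)], [np.sqrt(0.5)]]),
            factor_correlations=np.eye(1), seed=17,
        )
        T = generate(config)
        a = T.column("a").astype(bool)
        b = T.column("b").astype(bool)
        table = np.array([[(a & b).sum(), (a & ~b).sum()],
                          [(~a & b).sum(), (~a & ~b).sum()]])
        assert tetrachoric_pair(table).rho == pytest.approx(0.5, abs=0.05)

    def test_perfect_concordance_hits_upper_clamp(self):
        res = tetrachoric_pair(np.array([[50, 0], [0, 50]]))
        assert res.rho >= 0.99
        assert res.continuity_corrected

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            tetrachoric_pair(np.array([[0, 0], [0, 0]]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.integers(1, 20))
    def test_monotone_in_odds_ratio(self, shift):
        """At fixed margins, a higher odds ratio gives a higher estimate."""
        base = np.array([[30, 30], [30, 30]])
        moved = np.array([[30 + shift, 30 - shift], [30 - shift, 30 + shift]])
        assert tetrachoric_pair(moved).rho > tetrachoric_pair(base).rho


class TestTetrachoricMatrix:
    def test_duplicated_column_clamped(self):
        rng = np.random.default_rng(5)
        x = (rng.random(500) < 0.5).astype(np.uint8)
        T = TransactionMatrix.from_arrays(np.column_stack([x, x]), ("a", "b"))
        tet = tetrachoric_matrix(T)
        assert tet.pair("a", "b") == pytest.approx(0.999)

    def test_constant_column_error_names_item(self):
        T = TransactionMatrix.from_arrays([[1, 1], [0, 1]], ("ok", "frozen"))
        with pytest.raises(ValueError, match="frozen"):
            tetrachoric_matrix(T)

    def test_independent_columns_near_zero(self):
        config = GeneratorConfig(
            n=100_000, items=("a", "b", "c"),
            prevalences=np.array([0.3, 0.5, 0.7]),
            loadings=np.zeros((3, 1)), factor_correlations=np.eye(1), seed=23,
        )
        tet = tetrachoric_matrix(generate(config))
        off = tet.values[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.03)


class TestPrincipalAxis:
    def test_noiseless_orthogonal_recovery(self):
        lam = np.array([[0.8, 0.0], [0.7, 0.0], [0.6, 0.1],
                        [0.0, 0.75], [0.0, 0.65], [0.1, 0.6]])
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        sol = principal_axis_factor(r, 2)
        assert sol.converged
        rep = sol.unrotated @ sol.unrotated.T
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(rep[off], r[off], atol=1e-4)

    def test_identity_matrix_has_no_common_variance(self):
        sol = principal_axis_factor(np.eye(5), 4)
        assert np.all(np.abs(sol.unrotated) < 0.05)
        assert np.all(sol.communalities < 0.05)

    def test_heywood_case_clamped_and_flagged(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.3], [0.9, 0.3, 1.0]])
        sol = principal_axis_factor(r, 1)
        assert sol.heywood
        assert np.all(sol.communalities <= 0.999)

    def test_nonconvergence_is_flagged_not_silent(self):
        rng = np.random.default_rng(2)
        lam = rng.uniform(0.3, 0.8, size=(8, 2))
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        sol = principal_axis_factor(r, 2, max_iter=2)
        assert not sol.converged
        assert sol.iterations == 2


class TestObliminRotation:
    @staticmethod
    def _paf(r, k):
        return principal_axis_factor(r, k)

    def test_reproduced_matrix_invariant(self):
        lam = np.array([[0.8, 0.05], [0.7, 0.1], [0.1, 0.75],
                        [0.0, 0.65], [0.6, 0.2]])
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        sol = self._paf(r, 2)
        rot = oblimin_rotate(sol)
        assert np.allclose(rot.reproduced(), sol.reproduced(), atol=1e-8)

    def test_block_structure_is_fixed_point(self):
        # 3 indicators per factor so the loadings are identified
        lam = np.array([[0.8, 0.0], [0.7, 0.0], [0.6, 0.0],
                        [0.0, 0.75], [0.0, 0.65], [0.0, 0.7]])
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        rot = oblimin_rotate(self._paf(r, 2))
        # up to column permutation/sign, rotated loadings match the block pattern
        recovered = np.abs(rot.rotated)
        target = np.abs(lam)
        perms = [recovered, recovered[:, ::-1]]
        assert any(np.allclose(p, target, atol=0.02) for p in perms)

    def test_single_factor_rotation_is_identity(self):
        lam = np.array([[0.8], [0.7], [0.6]])
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        sol = self._paf(r, 1)
        assert oblimin_rotate(sol) is sol


class TestAssignment:
    def test_single_factor_assigns_everything(self):
        lam = np.array([[0.8], [0.7], [0.6]])
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        sol = oblimin_rotate(principal_axis_factor(r, 1))
        assignment = assign_items(sol)
        assert all(a.factor == 0 for a in assignment.values())

    def test_zero_row_unassignable_and_tie_flagged(self):
        from screenmine.latent import FactorSolution

        sol = FactorSolution(
            items=("a", "b"),
            unrotated=np.array([[0.0, 0.0], [0.5, 0.5]]),
            rotated=np.array([[0.0, 0.0], [0.5, 0.5]]),
            factor_correlations=np.eye(2),
            communalities=np.array([0.0, 0.5]),
            uniquenesses=np.array([1.0, 0.5]),
            iterations=1, converged=True, heywood=False, residual_norm=0.0,
        )
        assignment = assign_items(sol)
        assert assignment["a"].factor is None
        assert assignment["b"].factor == 0 and assignment["b"].tied


class TestCronbachAlpha:
    def test_duplicated_items_give_one(self):
        x = np.array([1, 0, 1, 1, 0, 0, 1], dtype=np.uint8)
        T = TransactionMatrix.from_arrays(np.column_stack([x, x]), ("a", "b"))
        assert cronbach_alpha(T, ("a", "b")).alpha == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(31)
        values = (rng.random((200_000, 2)) < 0.5).astype(np.uint8)
        T = TransactionMatrix.from_arrays(values, ("a", "b"))
        assert cronbach_alpha(T, ("a", "b")).alpha == pytest.approx(0.0, abs=0.02)

    def test_worked_hand_example(self):
        values = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8)
        T = TransactionMatrix.from_arrays(values, ("a", "b"))
        rep = cronbach_alpha(T, ("a", "b"))
        assert rep.item_variances.sum() == pytest.approx(0.5)
        assert rep.total_variance == pytest.approx(0.5)
        assert rep.alpha == pytest.approx(0.0)

    def test_invariant_under_item_reordering(self, study_cohort):
        _, T = study_cohort
        items = ("smoking", "alcohol", "diet", "exercise")
        assert cronbach_alpha(T, items).alpha == pytest.approx(
            cronbach_alpha(T, items[::-1]).alpha
        )

    def test_errors(self):
        T = TransactionMatrix.from_arrays([[1, 1], [1, 1]], ("a", "b"))
        with pytest.raises(ValueError, match="at least 2"):
            cronbach_alpha(T, ("a",))
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(T, ("a", "b"))


def test_tucker_congruence_bounds():
    x = np.array([0.8, 0.7, 0.1])
    assert tucker_congruence(x, x) == pytest.approx(1.0)
    assert tucker_congruence(x, -x) == pytest.approx(-1.0)
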