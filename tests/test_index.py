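"""Index-construction tests: correlations, adequacy tests, factor analysis,
parameter selection and the composite-index formula."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kcqi.index import (
    QualityFactorAnalysis,
    add_kcqi_column,
    bartlett_sphericity,
    compute_kcqi,
    kmo,
    pearson_matrix,
    select_parameters,
    varimax,
    zscore_normalize,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def kmo_from_data_oracle(X):
    """KMO via regression-residual partial correlations (anti-image), a
    computational route independent of the inverse-matrix formula."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    Q = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            A = np.hstack([np.ones((n, 1)), X[:, others]])
            ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
            rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
            Q[i, j] = Q[j, i] = np.corrcoef(ri, rj)[0, 1]
    off = ~np.eye(p, dtype=bool)
    return np.sum(R[off] ** 2) / (np.sum(R[off] ** 2) + np.sum(Q[off] ** 2))


def varimax_jacobi_oracle(L, sweeps=200, tol=1e-14):
    """Classic pairwise-rotation varimax, independent of the SVD algorithm."""
    L = np.asarray(L, dtype=float).copy()
    p, k = L.shape
    for _ in range(sweeps):
        changed = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                num = 2 * (p * u @ v - u.sum() * v.sum())
                den = p * (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) > tol:
                    c, s = np.cos(phi), np.sin(phi)
                    L[:, i], L[:, j] = c * x + s * y, -s * x + c * y
                    changed = True
        if not changed:
            break
    return L


def varimax_criterion(L):
    L2 = L**2
    return float(np.sum(L2.var(axis=0)))


# ---------------------------------------------------------------------------
# Pearson / z-score
# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "pos": 2 * x + 3, "neg": -x})
        R = pearson_matrix(df)
        assert R.loc["x", "pos"] == pytest.approx(1.0)
        assert R.loc["x", "neg"] == pytest.approx(-1.0)

    def test_synthetic_ssc_a_correlation(self, big_table):
        r = pearson_matrix(big_table).loc["ssc", "a"]
        assert r == pytest.approx(0.52, abs=0.05)

    def test_symmetric_unit_diagonal(self, default_table):
        R = pearson_matrix(default_table).to_numpy()
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1 + 1e-12)


class TestZScore:
    def test_moments_and_idempotence(self, default_table):
        Z = zscore_normalize(default_table)
        np.testing.assert_allclose(Z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(ddof=0), 1.0, atol=1e-12)
        Z2 = zscore_normalize(Z)
        np.testing.assert_allclose(Z2.to_numpy(), Z.to_numpy(), atol=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_normalize(pd.DataFrame({"u": [1.0, 1.0, 1.0],
                                           "v": [1.0, 2.0, 3.0]}))


# ---------------------------------------------------------------------------
# KMO / Bartlett
# ---------------------------------------------------------------------------

class TestKMO:
    def test_two_variable_matrix_is_half(self):
        """For p = 2 the partial correlation equals the raw correlation, so
        KMO = 0.5 regardless of r."""
        for r in (0.2, -0.7, 0.95):
            R = np.array([[1.0, r], [r, 1.0]])
            assert kmo(R) == pytest.approx(0.5, abs=1e-12)

    def test_default_synthetic_table_clears_gate(self, default_table):
        R = pearson_matrix(default_table).to_numpy()
        assert kmo(R) > 0.5

    def test_one_factor_limit(self):
        """Single-common-factor data: KMO increases toward 1 as the
        variable-specific noise vanishes."""
        rng = np.random.default_rng(0)
        n, p = 4000, 6
        f = rng.normal(size=n)
        vals = []
        for noise in (0.8, 0.3, 0.05):
            X = f[:, None] + noise * rng.normal(size=(n, p))
            vals.append(kmo(np.corrcoef(X, rowvar=False)))
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 0.95

    def test_matches_regression_oracle(self):
        """Inverse-matrix KMO equals the regression-residual oracle on
        random datasets, to 1e-6."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            A = rng.normal(size=(5, 3))
            X = rng.normal(size=(400, 3)) @ A.T + 0.7 * rng.normal(size=(400, 5))
            R = np.corrcoef(X, rowvar=False)
            assert kmo(R) == pytest.approx(kmo_from_data_oracle(X), abs=1e-6)


class TestBartlett:
    def test_identity_matrix(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 10
        assert p == pytest.approx(1.0)

    def test_formula_against_direct_recomputation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 4))
        X[:, 1] += X[:, 0]
        R = np.corrcoef(X, rowvar=False)
        chi2, df, p = bartlett_sphericity(R, n=80)
        expected = -(80 - 1 - (2 * 4 + 5) / 6) * math.log(np.linalg.det(R))
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert df == 6

    def test_singular_limit_is_infinite(self):
        R = np.ones((3, 3))
        chi2, _, p = bartlett_sphericity(R, n=50)
        assert chi2 == np.inf and p == 0.0

    def test_default_synthetic_table_rejects_sphericity(self, default_table):
        R = pearson_matrix(default_table).to_numpy()
        _, _, p = bartlett_sphericity(R, n=len(default_table))
        assert p < 1e-10


# ---------------------------------------------------------------------------
# Factor analysis + rotation
# ---------------------------------------------------------------------------

class TestVarimax:
    def test_communalities_preserved(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(8, 3))
        Lr = varimax(L)
        np.testing.assert_allclose((Lr**2).sum(axis=1), (L**2).sum(axis=1),
                                   atol=1e-8)

    def test_matches_jacobi_oracle(self):
        """SVD varimax reaches the same criterion value (and the same
        loadings up to column order/sign) as pairwise Jacobi rotations."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            L = rng.normal(size=(10, 3))
            a = varimax(L)
            b = varimax_jacobi_oracle(L)
            assert varimax_criterion(a) == pytest.approx(
                varimax_criterion(b), abs=1e-6
            )
            # canonical form: columns sorted by squared sums, signs fixed
            def canon(M):
                M = M.copy()
                for j in range(M.shape[1]):
                    i = np.argmax(np.abs(M[:, j]))
                    if M[i, j] < 0:
                        M[:, j] *= -1
                order = np.argsort(-np.sum(M**2, axis=0), kind="stable")
                return M[:, order]
            np.testing.assert_allclose(canon(a), canon(b), atol=1e-5)


class TestFactorAnalysis:
    def test_two_block_structure_recovered(self):
        """Two uncorrelated blocks of perfectly correlated variables yield
        two factors with a clean 1/0 loading pattern."""
        rng = np.random.default_rng(5)
        f1, f2 = rng.normal(size=(2, 500))
        X = np.column_stack([f1, f1, f1, f2, f2])
        X = X + 1e-6 * rng.normal(size=X.shape)  # break exact singularity
        fa = QualityFactorAnalysis(variance_threshold=95.0).fit(
            pd.DataFrame(X, columns=list("vwxyz"))
        )
        assert fa.retained_k_ == 2
        L = np.abs(fa.loadings_.to_numpy())
        big, small = np.sort(L, axis=1)[:, ::-1].T
        # block pattern up to finite-sample cross-correlation of the factors
        np.testing.assert_allclose(big, 1.0, atol=0.01)
        np.testing.assert_allclose(small, 0.0, atol=0.1)

    def test_synthetic_cumulative_variance(self, default_table):
        fa = QualityFactorAnalysis().fit(default_table)
        assert fa.cumulative_variance_[2] > 90.0  # three factors > 90%
        assert fa.retained_k_ <= 3
        assert np.all(np.diff(fa.cumulative_variance_) >= -1e-9)

    def test_rotation_preserves_communalities(self, default_table):
        fa = QualityFactorAnalysis().fit(default_table)
        L = fa.loadings_.to_numpy()
        w = fa.eigenvalues_[: fa.retained_k_]
        V_unrotated = np.linalg.eigh(fa.correlation_.to_numpy())
        # communalities from the unrotated PCA loadings
        evals, evecs = V_unrotated
        evals, evecs = evals[::-1], evecs[:, ::-1]
        L0 = evecs[:, : fa.retained_k_] * np.sqrt(evals[: fa.retained_k_])
        np.testing.assert_allclose((L**2).sum(axis=1), (L0**2).sum(axis=1),
                                   atol=1e-8)

class TestSelectParameters:
    # rotated loading matrix reported for the real-fruit study
    STUDY_LOADINGS = np.array([
        [-0.807, 0.302, -0.437],   # SSC
        [0.833, -0.408, 0.155],    # firmness
        [0.869, 0.277, 0.027],     # L*
        [-0.698, 0.494, 0.504],    # a*
        [0.434, 0.822, -0.048],    # b*
        [0.922, 0.331, -0.120],    # chroma
    ])
    NAMES = ["ssc", "firmness", "L", "a", "b", "chroma"]

    def test_study_matrix_selects_five_parameters(self):
        """The published loading pattern selects SSC, firmness, L*, b* and
        chroma; a* is excluded as cross-loaded and factor 3 is dropped."""
        sel = select_parameters(self.STUDY_LOADINGS, names=self.NAMES,
                                retained=[0, 1])
        assert sel.selected == ["ssc", "firmness", "L", "b", "chroma"]
        assert sel.cross_loaded == ["a"]
        assert sel.kept_factors == [0, 1]
        assert sel.dominant_factor["b"] == 1  # b* loads on factor 2

    def test_all_below_threshold_empty_with_warning(self):
        L = np.full((4, 2), 0.3)
        with pytest.warns(UserWarning, match="empty"):
            sel = select_parameters(L)
        assert sel.selected == []

    def test_single_dominant_loading(self):
        L = np.array([[0.9], [0.1], [0.1]])
        sel = select_parameters(L, names=["u", "v", "w"])
        assert sel.selected == ["u"]


# ---------------------------------------------------------------------------
# KCQI formula
# ---------------------------------------------------------------------------

class TestKCQI:
    def test_log_unity(self):
        rec = dict(firmness=1.0, L=1.0, b=1.0, chroma=1.0, ssc=1000.0)
        assert compute_kcqi(rec) == pytest.approx(0.0, abs=1e-14)

    def test_doubling_firmness_adds_log_two(self):
        rec = dict(firmness=13.5, L=55.0, b=30.0, chroma=31.32, ssc=12.0)
        base = compute_kcqi(rec)
        rec2 = dict(rec, firmness=27.0)
        assert compute_kcqi(rec2) - base == pytest.approx(math.log(2),
                                                          abs=1e-12)

    def test_high_precision_oracle(self):
        """Exact-rational evaluation of ln(1000*F*L*b*C/SSC) for the day-0
        reference fruit (~17.88)."""
        ratio = (Fraction(1000) * Fraction("13.5") * Fraction(55)
                 * Fraction(30) * Fraction("31.32") / Fraction(12))
        expected = math.log(ratio.numerator) - math.log(ratio.denominator)
        rec = dict(firmness=13.5, L=55.0, b=30.0, chroma=31.32, ssc=12.0)
        assert compute_kcqi(rec) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(17.88, abs=0.005)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        delta=st.floats(min_value=0.01, max_value=2.0),
        field=st.sampled_from(["firmness", "L", "b", "chroma", "ssc"]),
    )
    def test_monotonicity(self, delta, field):
        """KCQI strictly increases in F, L*, b*, C and decreases in SSC."""
        rec = dict(firmness=10.0, L=50.0, b=25.0, chroma=27.0, ssc=14.0)
        bumped = dict(rec)
        bumped[field] += delta
        diff = compute_kcqi(bumped) - compute_kcqi(rec)
        assert diff < 0 if field == "ssc" else diff > 0

    def test_nonpositive_input_names_field(self):
        rec = dict(firmness=10.0, L=50.0, b=-1.0, chroma=27.0, ssc=14.0)
        with pytest.raises(ValueError, match="b"):
            compute_kcqi(rec)

    def test_mean_kcqi_declines_over_shelf_life(self, default_table_kcqi):
        means = default_table_kcqi.groupby("day")["kcqi"].mean()
        assert means[0] > means[3] > means[6] > means[9]

    def test_column_matches_rowwise_formula(self, default_table_kcqi):
        row = default_table_kcqi.iloc[17]
        assert row["kcqi"] == pytest.approx(compute_kcqi(row), abs=1e-12)
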