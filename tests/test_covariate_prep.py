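"""Covariate preparation: rescaling, screening, imputation, PCA, VIF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spaterich.covariate_prep import (
    CovariateSpec,
    DesignMatrix,
    climate_pca,
    correlation_screen,
    encode_grazing,
    mean_impute,
    prepare_design,
    rescale_covariate,
    vif,
)

# (name, divisor, original endpoints, rescaled endpoints at 2 decimals)
RESCALE_CASES = [
    ("altitude_national", 100.0, (0.0, 975.0), (0.00, 9.75)),
    ("precip_national", 250.0, (554.33, 3305.80), (2.22, 13.22)),
    ("sheep_change", 10.0, (-11.19, 88.47), (-1.12, 8.85)),
    ("precip_gradient", 250.0, (604.9, 1773.3), (2.42, 7.09)),
    ("topsoil_al", 200.0, (11.60, 1318.75), (0.06, 6.59)),
    ("topsoil_ph", 0.5, (3.69, 5.37), (7.38, 10.74)),
    ("altitude_gradient", 100.0, (15.0, 500.0), (0.15, 5.00)),
    ("slope", 10.0, (0.0, 60.0), (0.00, 6.00)),
    ("soil_moisture_deficit", 10.0, (1.66, 48.94), (0.17, 4.89)),
]


@pytest.mark.parametrize("name,divisor,orig,expected", RESCALE_CASES)
def test_rescale_reproduces_reported_range_endpoints(name, divisor, orig, expected):
    spec = CovariateSpec(name=name, divisor=divisor)
    out = rescale_covariate(np.asarray(orig), spec, decimals=2)
    assert out == pytest.approx(expected, abs=1e-12)


def test_rescale_identity_and_errors():
    spec = CovariateSpec(name="v", divisor=1.0)
    v = np.array([1.5, -2.0, 0.0])
    assert np.array_equal(rescale_covariate(v, spec, decimals=6), v)
    with pytest.raises(ValueError, match="row 1"):
        rescale_covariate(np.array([1.0, np.nan]), CovariateSpec(name="v", divisor=2.0))
    with pytest.raises(ValueError):
        CovariateSpec(name="v", divisor=0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    scale=st.floats(min_value=0.1, max_value=100.0),
    divisor=st.floats(min_value=0.01, max_value=1000.0),
)
def test_rescale_is_linear_before_rounding(scale, divisor):
    v = np.array([1.0, 2.5, -3.0, 10.0])
    spec = CovariateSpec(name="v", divisor=divisor)
    a = rescale_covariate(scale * v, spec, decimals=12)
    b = scale * (v / divisor)
    assert np.allclose(a, b, rtol=1e-9, atol=1e-9)


class TestCorrelationScreen:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        pairs = correlation_screen(df, threshold=0.7)
        got = {frozenset(p): round(r, 6) for p, r in pairs}
        assert got[frozenset(("a", "b"))] == 1.0
        assert got[frozenset(("a", "c"))] == -1.0
        assert got[frozenset(("b", "c"))] == -1.0

    def test_independent_columns_yield_no_pairs(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
        assert correlation_screen(df, threshold=0.5) == []
        # oracle: direct Pearson never exceeds ~4 / sqrt(n) here
        assert np.abs(np.corrcoef(df.to_numpy().T)[np.triu_indices(4, 1)]).max() < 0.5

    def test_zero_variance_column_reported_and_excluded(self):
        X = DesignMatrix(columns=["a", "b", "c"],
                         values=np.column_stack([np.arange(9.0),
                                                 np.arange(9.0) * 2,
                                                 np.ones(9)]))
        pairs = correlation_screen(X, threshold=0.5)
        assert [set(p) for p, _ in pairs] == [{"a", "b"}]
        assert any("zero-variance" in line for line in X.provenance)

    def test_sorted_by_descending_magnitude(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.2, 200),
                           "c": x + rng.normal(0, 1.0, 200)})
        pairs = correlation_screen(df, threshold=0.1)
        rs = [abs(r) for _, r in pairs]
        assert rs == sorted(rs, reverse=True)


class TestMeanImpute:
    def test_basic_and_identity(self):
        assert np.array_equal(mean_impute(np.array([2.0, 4.0, np.nan])), [2, 4, 3])
        v = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(mean_impute(v), v)

    def test_constant_column_with_missing_block(self):
        # 15 of 320 entries missing, the rest equal: imputation fills the constant
        v = np.full(320, 7.25)
        v[:15] = np.nan
        out = mean_impute(v)
        assert np.all(out == 7.25)

    def test_all_missing_errors_with_name(self):
        with pytest.raises(ValueError, match="pet"):
            mean_impute(np.array([np.nan, np.nan]), name="pet")


class TestClimatePca:
    def test_duplicated_correlated_pair_gives_single_component(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        Z = np.column_stack([x, 2 * x + 5, -x, 0.5 * x])
        scores, loadings, frac = climate_pca(Z)
        assert frac[0] == pytest.approx(1.0, abs=1e-10)
        assert frac[1] == pytest.approx(0.0, abs=1e-10)

    def test_scores_uncorrelated_and_sign_convention(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(200, 4)) @ rng.normal(size=(4, 4))
        scores, loadings, _ = climate_pca(Z)
        r = np.corrcoef(scores.T)[0, 1]
        assert abs(r) < 1e-10
        assert loadings[0, 0] >= 0 and loadings[1, 0] >= 0

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(150, 4)) @ rng.normal(size=(4, 4)) + rng.normal(size=4)
        scores, _, frac = climate_pca(Z)
        Zs = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(np.corrcoef(Zs.T))
        order = np.argsort(evals)[::-1]
        ref = Zs @ evecs[:, order[:2]]
        for k in range(2):
            agree = np.allclose(scores[:, k], ref[:, k], atol=1e-8) or np.allclose(
                scores[:, k], -ref[:, k], atol=1e-8
            )
            assert agree
        assert frac[:2] == pytest.approx(evals[order[:2]] / 4.0, rel=1e-6)

    def test_row_order_invariance_up_to_nothing(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(50, 4))
        perm = rng.permutation(50)
        s1, _, _ = climate_pca(Z)
        s2, _, _ = climate_pca(Z[perm])
        assert np.allclose(s1[perm], s2, atol=1e-8)

    def test_constant_column_rejected(self):
        Z = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2,
                             np.arange(10.0) ** 3])
        with pytest.raises(ValueError, match="constant"):
            climate_pca(Z, ["a", "b", "c", "d"])


class TestVif:
    def test_orthogonal_columns_give_one(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({
            "s1": np.sin(2 * np.pi * t / n), "c1": np.cos(2 * np.pi * t / n),
            "s2": np.sin(4 * np.pi * t / n),
        })
        assert np.allclose(vif(df).to_numpy(), 1.0, atol=1e-10)

    def test_two_predictor_closed_form(self):
        # |r| = 0.83 exactly -> VIF = 1 / (1 - 0.83^2) for both columns
        rng = np.random.default_rng(7)
        n = 320
        x = rng.normal(size=n)
        xc = x - x.mean()
        e = rng.normal(size=n)
        ec = e - e.mean()
        ec -= xc * (xc @ ec) / (xc @ xc)  # orthogonalize in the centred space
        r = 0.83
        y = r * xc / xc.std() + np.sqrt(1 - r**2) * ec / ec.std()
        df = pd.DataFrame({"a": x, "b": y})
        expect = 1.0 / (1.0 - 0.83**2)
        assert vif(df).to_numpy() == pytest.approx([expect, expect], rel=1e-6)

    def test_duplicate_column_flagged_infinite(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        v = vif(df)
        assert np.isinf(v["a"]) and np.isinf(v["b"]) and np.isfinite(v["c"])

    def test_matches_brute_force_r2_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n, m = rng.integers(20, 50), rng.integers(2, 6)
            V = rng.normal(size=(n, m)) @ rng.normal(size=(m, m))
            df = pd.DataFrame(V, columns=[f"v{j}" for j in range(m)])
            got = vif(df)
            import statsmodels.api as sm

            for j in range(m):
                ols = sm.OLS(V[:, j], sm.add_constant(np.delete(V, j, axis=1))).fit()
                assert got.iloc[j] == pytest.approx(1.0 / (1.0 - ols.rsquared), rel=1e-6)

    def test_grouped_mode_runs_and_stays_finite(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        g = np.repeat(np.arange(12), 5)
        v = vif(df, group=g)
        assert np.all(v >= 1.0) and np.all(np.isfinite(v))


def test_prepare_design_end_to_end():
    rng = np.random.default_rng(11)
    n = 120
    table = pd.DataFrame({
        "alt": rng.uniform(0, 900, n),
        "pet": np.where(rng.random(n) < 0.1, np.nan, rng.normal(600, 40, n)),
        "t1": rng.normal(12, 2, n),
        "t2": rng.normal(6, 1, n),
        "t3": rng.normal(9, 1.5, n),
        "graz": rng.choice(["low", "medium", "high"], n),
    })
    table["pet"] = table["pet"] + 10 * table["t1"]  # correlate the climate block
    specs = [CovariateSpec(name="alt", divisor=100.0, role="terrain")]
    X = prepare_design(table, specs, climate_block=["pet", "t1", "t2", "t3"],
                       grazing_column="graz")
    assert X.columns == ["alt", "Climate PC1", "Climate PC2",
                         "grazing_medium", "grazing_high"]
    assert X.n_rows == n and np.all(np.isfinite(X.values))
    assert any("imputed" in line for line in X.provenance)
    assert any("PCA" in line for line in X.provenance)
    assert any("VIF" in line for line in X.provenance)
    assert X.values[:, 0] == pytest.approx(table["alt"].to_numpy() / 100.0)


def test_encode_grazing_reference_level():
    out = encode_grazing(pd.Series(["low", "medium", "high", "low"]))
    assert out["grazing_medium"].tolist() == [0, 1, 0, 0]
    assert out["grazing_high"].tolist() == [0, 0, 1, 0]
    with pytest.raises(ValueError, match="unknown"):
        encode_grazing(pd.Series(["none"]))
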