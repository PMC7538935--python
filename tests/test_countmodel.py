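import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxiseq import ValidationError, bh_adjust, estimate_dispersion, nb_wald_contrast, size_factors
from oxiseq.countmodel import moderate_dispersion
from oxiseq.errors import ConfigurationError


def frame(values, cols):
    arr = np.asarray(values, float)
    return pd.DataFrame(arr, index=[f"T{i}" for i in range(arr.shape[0])], columns=cols)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = frame([[10, 10], [3, 3], [7, 7]], ["a", "b"])
        res = size_factors(df)
        assert res.method == "median_of_ratios"
        np.testing.assert_allclose(res.size_factors.to_numpy(), [1.0, 1.0])

    def test_doubled_column_gives_factors_proportional_1_2(self):
        # hand computation: ratios to the geometric row mean are 1/sqrt(2)
        # and sqrt(2) for every row, so the factors are proportional to (1, 2)
        df = frame([[10, 20], [50, 100], [3, 6]], ["a", "b"])
        res = size_factors(df)
        f = res.size_factors
        assert f["b"] / f["a"] == pytest.approx(2.0)
        np.testing.assert_allclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_all_zero_matrix_errors(self):
        df = frame(np.zeros((3, 2)), ["a", "b"])
        with pytest.raises(ValidationError, match="no usable rows"):
            size_factors(df)

    def test_no_common_positive_row_falls_back_to_total_count(self):
        df = frame([[10, 0], [0, 10]], ["a", "b"])
        with pytest.warns(UserWarning, match="total-count"):
            res = size_factors(df)
        assert res.method == "total_count"
        np.testing.assert_allclose(res.size_factors.to_numpy(), [1.0, 1.0])

    def test_scale_equivariance_of_factor_ratios(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(10, 500, size=(40, 4))
        cols = list("abcd")
        f0 = size_factors(frame(base, cols)).size_factors
        for k in (0.5, 3.0, 10.0):
            scaled = base.copy()
            scaled[:, 2] *= k
            f1 = size_factors(frame(scaled, cols)).size_factors
            # factors are defined up to a common scale; ratios must scale by k
            np.testing.assert_allclose(
                (f1["c"] / f1["a"]), k * (f0["c"] / f0["a"]), rtol=1e-9
            )
            np.testing.assert_allclose(f1["b"] / f1["a"], f0["b"] / f0["a"], rtol=1e-9)


class TestDispersion:
    def test_constant_counts_get_floor(self):
        df = frame([[10, 10, 10, 10]], list("abcd"))
        sf = pd.Series(1.0, index=list("abcd"))
        alpha = estimate_dispersion(df, ["a", "b"], ["c", "d"], sf, floor=1e-4)
        assert alpha.iloc[0] == 1e-4

    def test_hand_method_of_moments_value(self):
        # groups (5,15) and (5,15): within-group variances 50 (ddof=1) pooled,
        # mean 10 -> alpha = (50 - 10) / 100 = 0.4
        df = frame([[5, 15, 5, 15]], list("abcd"))
        sf = pd.Series(1.0, index=list("abcd"))
        alpha = estimate_dispersion(df, ["a", "b"], ["c", "d"], sf, floor=1e-4)
        assert alpha.iloc[0] == pytest.approx(0.4)

    def test_all_zero_row_gets_floor(self):
        df = frame([[0, 0, 0, 0]], list("abcd"))
        sf = pd.Series(1.0, index=list("abcd"))
        alpha = estimate_dispersion(df, ["a", "b"], ["c", "d"], sf, floor=1e-4)
        assert alpha.iloc[0] == 1e-4

    def test_moderation_never_below_per_row_estimate(self):
        rng = np.random.default_rng(0)
        df = frame(rng.poisson(100, size=(200, 4)), list("abcd"))
        sf = pd.Series(1.0, index=list("abcd"))
        gene = estimate_dispersion(df, ["a", "b"], ["c", "d"], sf)
        mod = moderate_dispersion(df, ["a", "b"], ["c", "d"], sf)
        assert (mod.to_numpy() >= gene.to_numpy() - 1e-15).all()


class TestBH:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_step_up_example(self):
        # sorted p_i * n/i = (.04, .04, .04, .04); cumulative min keeps 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_nan_passthrough(self):
        out = bh_adjust([0.5, np.nan, 0.5])
        assert out[0] == 0.5 and out[2] == 0.5 and np.isnan(out[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_properties_hold_for_any_vector(self, p):
        out = bh_adjust(p)
        p = np.asarray(p)
        assert (out >= p - 1e-12).all()
        assert (out <= 1 + 1e-12).all()
        # permutation invariance
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), out[perm])
        if (p == 1).all():
            assert (out == 1).all()


class TestWaldContrast:
    def test_identical_groups_give_zero_log2fc_and_p_one(self):
        df = frame([[10, 20, 10, 20], [5, 5, 5, 5]], list("abcd"))
        res = nb_wald_contrast(df, ["a", "b"], ["c", "d"])
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_zero_group_gives_finite_positive_log2fc_and_small_p(self):
        rows = np.random.default_rng(0).poisson(100, size=(30, 4)).astype(float)
        rows[0] = [0, 0, 2000, 2100]
        df = frame(rows, list("abcd"))
        res = nb_wald_contrast(df, ["a", "b"], ["c", "d"])
        assert np.isfinite(res["log2fc"].iloc[0])
        assert res["log2fc"].iloc[0] > 5
        assert res["p"].iloc[0] < 1e-6

    def test_all_zero_row_has_absent_p(self):
        rows = np.ones((5, 4)) * 50
        rows[2] = 0
        df = frame(rows, list("abcd"))
        res = nb_wald_contrast(df, ["a", "b"], ["c", "d"])
        assert np.isnan(res["p"].iloc[2]) and np.isnan(res["p_adj"].iloc[2])
        assert res["p"].drop("T2").notna().all()

    def test_empty_group_is_configuration_error(self):
        df = frame([[1, 2]], ["a", "b"])
        with pytest.raises(ConfigurationError):
            nb_wald_contrast(df, [], ["a", "b"])

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(5)
        df = frame(rng.poisson(80, size=(100, 4)), list("abcd"))
        res = nb_wald_contrast(df, ["a", "b"], ["c", "d"])
        ok = res["p"].notna()
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p"] - 1e-12).all()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_group_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        df = frame(rng.poisson(rng.uniform(5, 300), size=(20, 4)), list("abcd"))
        fwd = nb_wald_contrast(df, ["a", "b"], ["c", "d"])
        rev = nb_wald_contrast(df, ["c", "d"], ["a", "b"])
        np.testing.assert_allclose(rev["log2fc"], -fwd["log2fc"], atol=1e-9)
        ok = fwd["p"].notna()
        np.testing.assert_allclose(rev.loc[ok, "p"], fwd.loc[ok, "p"], atol=1e-9)
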