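"""Weighted aggregation and variable-reduction pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psimap.surveyprep import (
    ClusterAggregate, IndicatorSpec, aggregate_clusters, drop_zero_variance,
    factor_select, kmo, prune_correlated, weighted_median, weighted_proportion,
)


def make_agg(df: pd.DataFrame) -> ClusterAggregate:
    meta = pd.DataFrame({"cluster_id": [f"C{i}" for i in range(len(df))],
                         "x": 0.0, "y": 0.0})
    return ClusterAggregate(pd.concat([meta, df.reset_index(drop=True)], axis=1))


class TestWeightedStats:
    @pytest.mark.parametrize("vals,w,expected", [
        ([1, 0, 1], [1, 1, 2], 0.75),
        ([1, 1, 1], [5, 1, 9], 1.0),
        ([0, 0], [2, 3], 0.0),
    ])
    def test_weighted_proportion(self, vals, w, expected):
        assert weighted_proportion(vals, w) == pytest.approx(expected)

    @pytest.mark.parametrize("vals,w,expected", [
        ([1, 2, 3], [1, 1, 4], 3.0),  # cumulative weight reaches half at 3
        ([1, 2, 3], [1, 1, 1], 2.0),
        ([5], [2], 5.0),
    ])
    def test_weighted_median_lower_convention(self, vals, w, expected):
        assert weighted_median(vals, w) == expected

    def test_weighted_median_against_brute_force(self, rng):
        for _ in range(50):
            v = rng.integers(0, 10, size=rng.integers(1, 12))
            w = rng.uniform(0.1, 3.0, size=len(v))
            # brute force: scan sorted values for 50% cumulative weight
            order = np.argsort(v, kind="stable")
            cum = 0.0
            for idx in order:
                cum += w[idx]
                if cum >= 0.5 * w.sum():
                    expected = float(v[idx])
                    break
            assert weighted_median(v, w) == expected

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_equal_weights_match_unweighted(self, bits):
        w = np.full(len(bits), 2.5)
        assert weighted_proportion(bits, w) == pytest.approx(np.mean(bits))
        assert weighted_median(bits, w) == np.sort(bits)[
            int(np.searchsorted(np.arange(1, len(bits) + 1), 0.5 * len(bits)))]

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_proportion([1, 0], [1.0, 0.0])
        with pytest.raises(ValueError):
            weighted_median([1, 2], [-1.0, 1.0])


class TestAggregation:
    def test_cluster_aggregate_values(self, small_survey):
        survey, _ = small_survey
        agg = aggregate_clusters(survey, {
            "owns_car": IndicatorSpec("households", "proportion", "HSLS"),
            "sickness": IndicatorSpec("roster", "proportion", "HSHS"),
        })
        assert agg.table["owns_car"].between(0, 1).all()
        assert not agg.table["cluster_id"].isna().any()
        # spot-check one cluster against a direct weighted computation
        cid = agg.table["cluster_id"].iloc[0]
        grp = survey.households[survey.households["cluster_id"] == cid]
        direct = np.sum(grp["owns_car"] * grp["household_final_weight"]) \
            / np.sum(grp["household_final_weight"])
        assert agg.table.set_index("cluster_id").loc[cid, "owns_car"] == pytest.approx(direct)
        # provenance records table and weight per column
        assert agg.provenance["sickness"]["weight"] == "trimmed_person_nonresponse_weight"
        assert (agg.counts["sickness"] > 0).all()

    def test_missing_indicator_rejected(self, small_survey):
        survey, _ = small_survey
        with pytest.raises(KeyError):
            aggregate_clusters(survey, {"nope": IndicatorSpec("households", "proportion")})


class TestReduction:
    def test_drop_zero_variance(self):
        df = pd.DataFrame({
            "const": np.ones(30), "const2": np.full(30, 7.0),
            "a": np.r_[np.zeros(15), np.ones(15)],
            "b": np.arange(30.0), "c": np.r_[np.ones(29), 0.0],
        })
        out = drop_zero_variance(make_agg(df))
        assert sorted(out.indicator_columns) == ["a", "b", "c"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            drop_zero_variance(make_agg(pd.DataFrame({"k": np.ones(10)})))

    def test_duplicate_column_pruned(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        out = prune_correlated(make_agg(df))
        assert len(out.indicator_columns) == 2 and "c" in out.indicator_columns

    def test_below_threshold_kept(self, rng):
        z = rng.normal(size=2000)
        a = z + 1.03 * rng.normal(size=2000)  # r about 0.69
        df = pd.DataFrame({"a": a, "b": z})
        r = df.corr().iloc[0, 1]
        assert 0.6 < r < 0.7
        out = prune_correlated(make_agg(df))
        assert len(out.indicator_columns) == 2

    def test_greedy_rule_hand_case(self):
        # r(A,B) and r(A,C) above threshold, r(B,C) low: A has the larger mean
        # |r| to the rest, so A is removed and B, C stay
        rng = np.random.default_rng(5)
        n = 4000
        target = np.array([[1.0, 0.8, 0.75], [0.8, 1.0, 0.25], [0.75, 0.25, 1.0]])
        base = rng.normal(size=(n, 3)) @ np.linalg.cholesky(target).T
        df = pd.DataFrame(base, columns=["A", "B", "C"])
        corr = df.corr()
        assert corr.loc["A", "B"] >= 0.7 and corr.loc["A", "C"] >= 0.7
        assert corr.loc["B", "C"] < 0.7
        out = prune_correlated(make_agg(df))
        assert sorted(out.indicator_columns) == ["B", "C"]

    def test_negative_pairs_survive(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": -x + 0.01 * rng.normal(size=200)})
        out = prune_correlated(make_agg(df))
        assert len(out.indicator_columns) == 2

    def test_no_remaining_pair_above_threshold(self, rng):
        # brute-force all-pairs check on the output
        z = rng.normal(size=(300, 3))
        df = pd.DataFrame({
            "v1": z[:, 0], "v2": z[:, 0] + 0.3 * z[:, 1],
            "v3": z[:, 1], "v4": z[:, 2], "v5": 0.9 * z[:, 2] + 0.2 * z[:, 0],
        })
        out = prune_correlated(make_agg(df), threshold=0.7)
        corr = out.values().corr().to_numpy()
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert (off < 0.7).all()


class TestKmo:
    def test_orthogonal_degenerate_returns_half(self):
        # exactly uncorrelated variables (principal-component scores) hit the
        # 0/0 case, which returns 0.5 by convention
        z = np.random.default_rng(0).normal(size=(40, 3))
        z = z - z.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(z.T))
        scores = z @ vecs
        out = kmo(make_agg(pd.DataFrame(scores, columns=["a", "b", "c"])))
        assert out == pytest.approx(0.5)

    def test_against_independent_formula(self, rng):
        # oracle: partial correlations from explicit per-pair OLS residuals
        z = rng.normal(size=(500, 4))
        df = pd.DataFrame({
            "a": z[:, 0], "b": 0.6 * z[:, 0] + 0.8 * z[:, 1],
            "c": z[:, 2], "d": 0.5 * z[:, 2] + 0.5 * z[:, 3] + 0.2 * z[:, 0],
        })
        corr = df.corr().to_numpy()
        p = corr.shape[0]
        r2 = q2 = 0.0
        X = (df - df.mean()) / df.std()
        cols = list(df.columns)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                others = [c for k, c in enumerate(cols) if k not in (i, j)]
                A = X[others].to_numpy()
                proj = A @ np.linalg.lstsq(A, X[cols[i]].to_numpy(), rcond=None)[0]
                ri = X[cols[i]].to_numpy() - proj
                proj = A @ np.linalg.lstsq(A, X[cols[j]].to_numpy(), rcond=None)[0]
                rj = X[cols[j]].to_numpy() - proj
                q2 += np.corrcoef(ri, rj)[0, 1] ** 2
                r2 += corr[i, j] ** 2
        expected = r2 / (r2 + q2)
        assert kmo(make_agg(df)) == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_column_order(self, rng):
        z = rng.normal(size=(200, 4))
        df = pd.DataFrame(z, columns=list("abcd"))
        df["b"] = df["a"] * 0.5 + df["b"]
        assert kmo(make_agg(df)) == pytest.approx(
            kmo(make_agg(df[list("dcba")])), abs=1e-12)

    def test_singular_matrix_names_columns(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "dup": x})
        with pytest.raises(ValueError, match="dup"):
            kmo(make_agg(df))


class TestFactorSelect:
    @staticmethod
    def block_data(seed, n=300):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        cols = {f"u{i}": z1 + 0.3 * rng.normal(size=n) for i in range(3)}
        cols |= {f"v{i}": z2 + 0.3 * rng.normal(size=n) for i in range(3)}
        return pd.DataFrame(cols)

    def test_two_blocks_give_two_factors_with_one_rep_each(self):
        hits = 0
        for seed in range(20):
            sol = factor_select(make_agg(self.block_data(seed)))
            ok = (sol.n_factors == 2
                  and {r[0] for r in sol.representatives} == {"u", "v"})
            hits += ok
        assert hits >= 18

    def test_single_factor_data(self, rng):
        z = rng.normal(size=400)
        df = pd.DataFrame({f"w{i}": z + 0.4 * rng.normal(size=400) for i in range(4)})
        sol = factor_select(make_agg(df))
        assert sol.n_factors == 1
        assert sol.representatives[0] in df.columns

    def test_varimax_preserves_communalities(self):
        sol = factor_select(make_agg(self.block_data(1)), n_factors=2)
        # rotation is orthogonal: row sums of squared loadings = communalities
        np.testing.assert_allclose(
            (sol.loadings ** 2).sum(axis=1), sol.communalities, atol=1e-8)

    def test_loadings_bounded(self):
        sol = factor_select(make_agg(self.block_data(3)))
        assert (sol.loadings.abs() <= 1.0 + 1e-6).all().all()

    def test_representatives_subset_of_columns(self):
        df = self.block_data(5)
        sol = factor_select(make_agg(df))
        assert set(sol.representatives) <= set(df.columns)

    def test_low_kmo_warns_but_proceeds(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(60, 3)))
        df = pd.DataFrame(q, columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="KMO"):
            sol = factor_select(make_agg(df))
        assert sol.n_factors >= 1
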