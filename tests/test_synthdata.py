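"""Synthetic country generator: geometry, covariates, fields, survey, SHDI."""

import numpy as np
import pytest
import shapely
from scipy.special import kv

from psimap.synthdata import (
    AdminHierarchy, TruthFieldSpec, generate_admin_hierarchy,
    generate_covariates, generate_shdi, generate_truth_and_survey,
    matern_correlation, morans_i, realize_truth, sample_matern_field,
)
from psimap.grids import RasterGrid


class TestAdminHierarchy:
    def test_counts_and_nesting(self):
        h = generate_admin_hierarchy(2, 2, (100_000.0, 100_000.0), seed=1)
        assert len(h.provinces) == 2 and len(h.districts) == 4
        prov = {p.unit_id: p.geometry for p in h.provinces}
        for d in h.districts:
            # district lies within its parent (tolerance for clipping slivers)
            inter = d.geometry.intersection(prov[d.parent_id]).area
            assert inter / d.geometry.area > 1 - 1e-9

    def test_partition_covers_extent(self):
        h = generate_admin_hierarchy(3, 5, (120_000.0, 80_000.0), seed=7)
        assert len(h.districts) == 15
        union = shapely.unary_union([d.geometry for d in h.districts])
        extent_area = 120_000.0 * 80_000.0
        assert abs(union.area - extent_area) < 1e-6 * extent_area
        # pairwise overlaps are degenerate (shared boundaries only)
        areas = sum(d.geometry.area for d in h.districts)
        assert abs(areas - extent_area) < 1e-6 * extent_area

    def test_deterministic(self, tmp_path):
        a = generate_admin_hierarchy(2, 3, (50_000.0, 50_000.0), seed=3)
        b = generate_admin_hierarchy(2, 3, (50_000.0, 50_000.0), seed=3)
        fa, fb = tmp_path / "a.geojson", tmp_path / "b.geojson"
        a.to_geojson(fa)
        b.to_geojson(fb)
        assert fa.read_bytes() == fb.read_bytes()

    def test_geojson_round_trip(self, small_hierarchy, tmp_path):
        path = tmp_path / "h.geojson"
        small_hierarchy.to_geojson(path)
        back = AdminHierarchy.from_geojson(path)
        assert back.district_ids() == small_hierarchy.district_ids()
        assert back.extent == small_hierarchy.extent

    @pytest.mark.parametrize("args", [(1, 2), (2, 1)])
    def test_too_few_units_rejected(self, args):
        with pytest.raises(ValueError):
            generate_admin_hierarchy(*args, (10_000.0, 10_000.0), seed=0)

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(ValueError):
            generate_admin_hierarchy(2, 2, (0.0, 10_000.0), seed=0)


class TestCovariates:
    def test_grid_shape(self, small_hierarchy):
        stack = generate_covariates(small_hierarchy, cell_m=400.0, seed=5)
        assert stack.grid.nrows == 100 and stack.grid.ncols == 100

    def test_eleven_layers_with_physical_ranges(self, small_stack):
        assert len(small_stack.names) == 11
        ly = small_stack.layers
        for name in ("EVI", "NDVI"):
            assert ly[name].min() >= -1.0 and ly[name].max() <= 1.0
        for name in ("SLOPE", "POPPP", "DMROADS", "DMROADSINT", "DMWATER", "NLIGHTS"):
            assert ly[name].min() >= 0.0, name

    def test_distance_zero_on_feature(self, small_stack):
        # some cell lies on a generated road, where distance must vanish
        assert small_stack.layers["DMROADS"].min() == 0.0

    def test_spatial_autocorrelation(self, small_stack):
        assert morans_i(small_stack.layers["NDVI"]) > 0.5

    def test_cell_must_divide_extent(self, small_hierarchy):
        with pytest.raises(ValueError):
            generate_covariates(small_hierarchy, cell_m=7_001.0, seed=0)

    def test_deterministic(self, small_hierarchy):
        a = generate_covariates(small_hierarchy, cell_m=2000.0, seed=9)
        b = generate_covariates(small_hierarchy, cell_m=2000.0, seed=9)
        for name in a.names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_standardized_layers(self, small_stack):
        std = small_stack.standardized()
        for name in std.names:
            assert abs(np.nanmean(std.layers[name])) < 1e-8
            assert abs(np.nanstd(std.layers[name]) - 1.0) < 1e-8


class TestMaternField:
    def test_correlation_at_zero_and_range(self):
        assert matern_correlation(0.0, 1000.0) == 1.0
        # nu = 1 under the sqrt(8 nu)/kappa convention: corr(rho) = s K_1(s), s = sqrt(8)
        s = np.sqrt(8.0)
        expected = s * kv(1, s)
        assert abs(matern_correlation(1000.0, 1000.0) - expected) < 1e-12

    def test_realized_field_moments(self):
        grid = RasterGrid(0, 0, 1000.0, 60, 60)
        sds, means = [], []
        for seed in range(8):
            f = sample_matern_field(grid, 12_000.0, 0.7, np.random.default_rng(seed))
            sds.append(f.std())
            means.append(f.mean())
        assert abs(np.mean(sds) - 0.7) < 0.1
        assert abs(np.mean(means)) < 0.15

    def test_zero_sd_gives_flat_field(self):
        grid = RasterGrid(0, 0, 1000.0, 10, 10)
        f = sample_matern_field(grid, 10_000.0, 0.0, np.random.default_rng(0))
        assert np.all(f == 0)

    def test_unknown_covariate_rejected(self, small_stack):
        spec = TruthFieldSpec("c", "HSHS", 0.0, {"NOPE": 1.0}, 10_000.0, 0.1)
        with pytest.raises(KeyError):
            realize_truth(spec, small_stack.standardized().layers,
                          small_stack.grid, np.random.default_rng(0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TruthFieldSpec("c", "SIDEWAYS", 0.0, {}, 10_000.0, 0.1)
        with pytest.raises(ValueError):
            TruthFieldSpec("c", "HSHS", 0.0, {}, -5.0, 0.1)


class TestSurvey:
    def test_structure_and_weights(self, small_survey):
        survey, _ = small_survey
        assert set(survey.households.columns) >= {
            "cluster_id", "household_id", "household_final_weight", "owns_car"}
        assert set(survey.roster.columns) >= {
            "cluster_id", "household_id", "person_id",
            "trimmed_person_nonresponse_weight", "sickness"}
        for table, wcol in [(survey.households, "household_final_weight"),
                            (survey.roster, "trimmed_person_nonresponse_weight"),
                            (survey.individuals, "individual_final_weight")]:
            assert (table[wcol] > 0).all()
            assert table["cluster_id"].isin(survey.clusters["cluster_id"]).all()

    def test_masked_centroid_inside_district(self, small_survey, small_hierarchy):
        survey, _ = small_survey
        geom = {d.unit_id: d.geometry for d in small_hierarchy.districts}
        for _, row in survey.clusters.iterrows():
            assert geom[row["district_id"]].covers(
                shapely.points(row["x"], row["y"]))
            jitter = np.hypot(row["x"] - row["true_x"], row["y"] - row["true_y"])
            assert jitter <= 1000.0 + 1e-9

    def test_deterministic(self, small_hierarchy, small_stack):
        spec = [TruthFieldSpec("c", "HSHS", -1.0, {}, 15_000.0, 0.3)]
        a, _ = generate_truth_and_survey(small_hierarchy, small_stack, spec,
                                         n_clusters=30, households_per_cluster=5, seed=3)
        b, _ = generate_truth_and_survey(small_hierarchy, small_stack, spec,
                                         n_clusters=30, households_per_cluster=5, seed=3)
        for name in ("households", "roster", "individuals", "clusters"):
            assert getattr(a, name).equals(getattr(b, name))

    def test_null_model_matches_intercept(self, small_hierarchy, small_stack):
        # betas = 0, sigma -> 0: every cluster's expected proportion is
        # inv-logit(beta0)
        beta0 = -1.0
        spec = [TruthFieldSpec("c", "HSHS", beta0, {}, 15_000.0, 0.0, table="roster")]
        survey, truths = generate_truth_and_survey(
            small_hierarchy, small_stack, spec, n_clusters=40,
            households_per_cluster=30, seed=5)
        expected = 1.0 / (1.0 + np.exp(-beta0))
        np.testing.assert_allclose(truths[0].p_raster, expected, atol=1e-12)
        observed = survey.roster["c"].mean()
        assert abs(observed - expected) < 0.02

    def test_covariate_signal_recoverable(self):
        # beta_ACCESS = 1, others 0: cluster ACCESS correlates with logit(p-hat)
        h = generate_admin_hierarchy(2, 2, (80_000.0, 80_000.0), seed=21)
        stack = generate_covariates(h, cell_m=1000.0, seed=22)
        spec = [TruthFieldSpec("c", "HSHS", 0.0, {"ACCESS": 1.0}, 15_000.0, 0.0,
                               table="roster")]
        survey, _ = generate_truth_and_survey(h, stack, spec, n_clusters=200,
                                              households_per_cluster=10,
                                              mask_jitter_m=0.0, seed=23)
        grp = survey.roster.groupby("cluster_id")["c"].mean().clip(0.01, 0.99)
        cl = survey.clusters.set_index("cluster_id").loc[grp.index]
        std = stack.standardized()
        access = std.sample("ACCESS", cl["x"].to_numpy(), cl["y"].to_numpy())
        r = np.corrcoef(access, np.log(grp / (1 - grp)))[0, 1]
        assert r > 0.5


class TestShdi:
    def test_noise_free_reverses_ranking(self, small_hierarchy, small_stack, small_survey):
        _, truths = small_survey
        shdi = generate_shdi(small_hierarchy, truths, small_stack.grid,
                             noise_sd=0.0, seed=1)
        from psimap.synthdata import district_truth_summary
        truth = district_truth_summary(truths, small_hierarchy, small_stack.grid)
        prov = truth.groupby("province_id")["true_susceptibility"].median()
        joined = shdi.table.set_index("province_id").join(prov)
        order_h = joined["health_index"].rank()
        order_t = joined["true_susceptibility"].rank()
        assert (order_h == len(joined) + 1 - order_t).all()

    def test_indices_in_unit_interval(self, small_hierarchy, small_stack, small_survey):
        _, truths = small_survey
        for seed in range(5):
            shdi = generate_shdi(small_hierarchy, truths, small_stack.grid,
                                 noise_sd=0.5, seed=seed)
            assert shdi.table["health_index"].between(0, 1).all()
            assert shdi.table["life_expectancy_index"].between(0, 1).all()

    def test_negative_correlation_with_truth(self):
        # noisy indices still rank provinces against susceptibility
        from psimap.synthdata import district_truth_summary
        from psimap.validation import spearman
        h = generate_admin_hierarchy(5, 2, (80_000.0, 80_000.0), seed=31)
        stack = generate_covariates(h, cell_m=2000.0, seed=32)
        spec = [TruthFieldSpec("c", "HSHS", -0.5, {"ACCESS": 0.8}, 20_000.0, 0.6)]
        truths = [realize_truth(spec[0], stack.standardized().layers, stack.grid,
                                np.random.default_rng(33))]
        truth = district_truth_summary(truths, h, stack.grid)
        prov = truth.groupby("province_id")["true_susceptibility"].median()
        rhos = []
        for seed in range(20):
            shdi = generate_shdi(h, truths, stack.grid, noise_sd=0.02, seed=seed)
            joined = shdi.table.set_index("province_id").join(prov)
            rhos.append(spearman(joined["health_index"],
                                 joined["true_susceptibility"]))
        assert np.median(rhos) < -0.8
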