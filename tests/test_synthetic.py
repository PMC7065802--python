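"""Ground-truth forest generator: determinism, limits, and recovery checks."""

import numpy as np
import pytest

from treecomp.census import read_census
from treecomp.grouping import cluster_traits
from treecomp.neighborhood import count_parameters
from treecomp.pipeline import assemble, fit_growth_model
from treecomp.bayes import residuals
from treecomp.synthetic import (
    SyntheticSpec,
    h0_spec,
    random_trait_table,
    recovery_report,
    simulate_forest,
)


class TestSimulateForest:
    def test_deterministic_growth_limit(self):
        """sigma -> 0, lambda = 0, beta_dbh = 0: growth is exactly beta0."""
        J = 3
        spec = SyntheticSpec(
            plot_extent=(0, 80, 0, 80), J=J, seed=5, sigma=1e-12,
            true_lambda=np.zeros((J, J)), true_beta_dbh=np.zeros(J),
            mortality=0.0,
        )
        c1, c2 = simulate_forest(spec)
        asm = assemble(c1, c2, spec.true_grouping())
        ds = asm.dataset
        for j, g in enumerate(spec.group_labels):
            rows = ds.frame["focal_group"] == g
            np.testing.assert_allclose(ds.y[rows.to_numpy()], spec.true_beta0[j],
                                       atol=1e-9)

    def test_expected_stem_count_is_poisson_mean(self):
        spec = SyntheticSpec(plot_extent=(0, 100, 0, 100), stem_density=500.0)
        counts = [
            len(simulate_forest(spec, np.random.default_rng(s))[0])
            for s in range(30)
        ]
        mean = np.mean(counts)
        # Poisson(500): mean within 5 sd of sqrt(500)/sqrt(30)
        assert abs(mean - 500.0) < 5 * np.sqrt(500.0 / 30)

    def test_fixed_seed_identical_forests(self):
        spec = SyntheticSpec(plot_extent=(0, 60, 0, 60), seed=9)
        c1a, c2a = simulate_forest(spec)
        c1b, c2b = simulate_forest(spec)
        assert c1a.data.equals(c1b.data)
        assert c2a.data.equals(c2b.data)

    def test_mortality_thins_second_census(self):
        spec = SyntheticSpec(plot_extent=(0, 150, 0, 150), mortality=0.3, seed=2)
        c1, c2 = simulate_forest(spec)
        frac_dead = (c2.data["status"] == "dead").mean()
        assert 0.25 < frac_dead < 0.35

    def test_round_trip_through_census_io(self, tmp_path):
        spec = SyntheticSpec(plot_extent=(0, 60, 0, 60), seed=11)
        c1, _ = simulate_forest(spec)
        path = tmp_path / "c1.csv"
        c1.data.to_csv(path, index=False)
        back = read_census(path, census_date=spec.date1, plot_extent=spec.plot_extent)
        assert len(back) == len(c1)
        np.testing.assert_allclose(back.data["dbh"], c1.data["dbh"])

    def test_clustered_mode_produces_aggregation(self):
        kwargs = dict(plot_extent=(0.0, 200.0, 0.0, 200.0), stem_density=400.0)
        rng = np.random.default_rng(4)
        c1u, _ = simulate_forest(SyntheticSpec(**kwargs, spatial_mode="uniform"), rng)
        rng = np.random.default_rng(4)
        c1c, _ = simulate_forest(
            SyntheticSpec(**kwargs, spatial_mode="clustered", cluster_sd=5.0), rng
        )
        from scipy.spatial import cKDTree

        def mean_nn(tab):
            xy = tab.data[["x", "y"]].to_numpy()
            d, _ = cKDTree(xy).query(xy, k=2)
            return d[:, 1].mean()

        assert mean_nn(c1c) < mean_nn(c1u)  # clustering shrinks NN distances


class TestH0Spec:
    def test_constant_rows_unchanged(self):
        lam = np.full((3, 3), -2e-5)
        spec = SyntheticSpec(J=3, true_lambda=lam)
        np.testing.assert_array_equal(h0_spec(spec).true_lambda, lam)

    def test_rows_flattened_to_mean(self):
        lam = np.array([[-1.0, 0.0, 1.0], [1.0, 1.0, 1.0], [0.0, 3.0, 0.0]]) * 1e-5
        spec = SyntheticSpec(J=3, true_lambda=lam)
        flat = h0_spec(spec).true_lambda
        np.testing.assert_allclose(flat, np.repeat(lam.mean(axis=1, keepdims=True), 3, axis=1))
        np.testing.assert_allclose(flat.mean(axis=1), lam.mean(axis=1))


class TestRecoveryReport:
    def test_row_count_is_parameter_count_minus_sigma(self):
        spec = SyntheticSpec(plot_extent=(0, 80, 0, 80), J=2, seed=21)
        rep = recovery_report(spec, n_replicates=2)
        assert len(rep) == count_parameters(2, 2) - 1
        assert set(rep.columns) >= {"parameter", "true", "bias", "rmse", "coverage"}

    def test_noiseless_large_n_bias_vanishes(self):
        spec = SyntheticSpec(
            plot_extent=(0, 150, 0, 150), J=2, sigma=1e-10, seed=23, mortality=0.0
        )
        rep = recovery_report(spec, n_replicates=2, V0=1e8)
        assert np.abs(rep["bias"]).max() < 1e-6

    def test_replicate_floor(self):
        with pytest.raises(ValueError):
            recovery_report(SyntheticSpec(), n_replicates=1)


class TestSpatialField:
    def test_smooth_field_induces_positive_residual_autocorrelation(self):
        """A smooth growth-rate field leaves spatially clumped residuals."""
        spec = SyntheticSpec(
            plot_extent=(0.0, 200.0, 0.0, 200.0), J=2, seed=17,
            spatial_mode="smooth_field", field_amplitude=0.15,
            field_length_scale=40.0, stem_density=400.0,
        )
        c1, c2 = simulate_forest(spec)
        asm = assemble(c1, c2, spec.true_grouping())
        fit = fit_growth_model(asm.dataset)
        tab = residuals(fit, asm.dataset)
        xy = tab[["x", "y_coord"]].to_numpy()
        r = tab["residual"].to_numpy()
        r = r - r.mean()
        from scipy.spatial import cKDTree

        # Moran's-I-style statistic over 15 m neighbor pairs (sign check)
        pairs = cKDTree(xy).query_pairs(15.0, output_type="ndarray")
        moran = np.mean(r[pairs[:, 0]] * r[pairs[:, 1]]) / r.var()
        assert moran > 0.05

    def test_uniform_mode_has_no_residual_autocorrelation(self):
        spec = SyntheticSpec(
            plot_extent=(0.0, 200.0, 0.0, 200.0), J=2, seed=18, stem_density=400.0
        )
        c1, c2 = simulate_forest(spec)
        asm = assemble(c1, c2, spec.true_grouping())
        fit = fit_growth_model(asm.dataset)
        tab = residuals(fit, asm.dataset)
        xy = tab[["x", "y_coord"]].to_numpy()
        r = tab["residual"].to_numpy()
        r = r - r.mean()
        from scipy.spatial import cKDTree

        pairs = cKDTree(xy).query_pairs(15.0, output_type="ndarray")
        moran = np.mean(r[pairs[:, 0]] * r[pairs[:, 1]]) / r.var()
        assert abs(moran) < 0.05


class TestTraitTable:
    def test_random_traits_cluster(self):
        species = [f"sp{i}" for i in range(10)]
        t = random_trait_table(species, np.random.default_rng(3))
        s = cluster_traits(t, k=4)
        assert s.J == 4
        assert set(s.mapping) == set(species)
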