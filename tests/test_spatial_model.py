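"""Spatial Poisson MCMC: design building, sampler correctness, summaries."""

import numpy as np
import pandas as pd
import pytest

from ctclmap import (
    MCMCConfig,
    ModelSpec,
    build_design,
    compute_dic,
    compute_gd,
    fit_mcmc,
    rr_table,
    summarize_sir,
)
from ctclmap.geography import grid_adjacency
from ctclmap.spatial_model import PosteriorSamples
from ctclmap.synthetic_registry import SyntheticConfig, SyntheticTruth, simulate_cases, simulate_registry
from ctclmap.validation import _fit_synthetic, aggregate_cells, conjugate_check


def tiny_counts():
    return pd.DataFrame(
        {
            "tract_id": ["t1", "t1", "t2", "t2"],
            "sex": ["male", "female", "male", "female"],
            "cases": [3, 1, 2, 2],
            "person_years": [1000.0, 1100.0, 900.0, 950.0],
        }
    )


class TestBuildDesign:
    def test_two_tracts_two_sexes(self):
        design = build_design(tiny_counts(), ModelSpec(factors=("sex",), spatial=False))
        assert design.X.shape == (4, 1)
        assert design.colnames == ("sex:female",)
        assert design.n_cells == 4 and design.n_tracts == 2

    def test_reference_rows_are_all_zero(self):
        design = build_design(tiny_counts(), ModelSpec(factors=("sex",), spatial=False))
        tab = tiny_counts().sort_values(["tract_id", "sex"]).reset_index(drop=True)
        male_rows = np.flatnonzero((tab["sex"] == "male").to_numpy())
        assert (design.X[male_rows] == 0).all()

    def test_zero_person_year_cells_dropped_and_counted(self):
        tab = tiny_counts()
        tab.loc[1, "person_years"] = 0.0
        tab.loc[1, "cases"] = 0
        design = build_design(tab, ModelSpec(factors=("sex",), spatial=False))
        assert design.n_dropped == 1 and design.n_cells == 3

    def test_zero_person_years_with_cases_rejected(self):
        tab = tiny_counts()
        tab.loc[1, "person_years"] = 0.0
        with pytest.raises(ValueError, match="no person-years"):
            build_design(tab, ModelSpec(factors=("sex",), spatial=False))

    def test_missing_reference_level_rejected(self):
        tab = tiny_counts()[tiny_counts()["sex"] == "female"]
        with pytest.raises(ValueError, match="reference"):
            build_design(tab, ModelSpec(factors=("sex",), spatial=False))

    def test_graph_tract_mismatch_rejected(self):
        graph = grid_adjacency(2, 2)  # node ids r0c0... do not match t1/t2
        with pytest.raises(ValueError, match="absent from adjacency graph"):
            build_design(tiny_counts(), ModelSpec(factors=("sex",)), graph=graph)

    def test_empty_level_warns_but_is_retained(self):
        tab = tiny_counts()
        tab["race"] = pd.Categorical(["NHW", "NHW", "NHB", "NHB"],
                                     categories=["NHW", "NHB", "API"])
        with pytest.warns(UserWarning, match="API.*empty"):
            design = build_design(tab, ModelSpec(factors=("race",), spatial=False))
        assert "race:API" in design.colnames and "race:NHB" in design.colnames


class TestSamplerCore:
    def test_conjugate_oracle(self):
        """Primary correctness gate: the intercept-only non-spatial chain must
        reproduce the closed-form Gamma(sum O, sum PY) posterior of the rate."""
        res = conjugate_check(seed=2)
        assert abs(res["mcmc_mean"] - res["analytic_mean"]) < 3 * res["mcmc_mcse"]
        assert res["mcmc_sd"] == pytest.approx(res["analytic_sd"], rel=0.25)

    def test_chain_reproducibility_same_seed(self):
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        runs = []
        for _ in range(2):
            _, _, s = _fit_synthetic(
                counts, tracts, graph, ("sex",),
                MCMCConfig(iterations=400, burn_in=100, thin=2, seed=77),
            )
            runs.append(s)
        np.testing.assert_array_equal(runs[0].beta, runs[1].beta)
        np.testing.assert_array_equal(runs[0].f, runs[1].f)
        np.testing.assert_array_equal(runs[0].deviance, runs[1].deviance)

    def test_cell_order_invariance(self):
        """Permuting input rows leaves the chain unchanged (canonical sort)."""
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        agg = aggregate_cells(counts, ("sex",))
        spec = ModelSpec(factors=("sex",))
        mcmc = MCMCConfig(iterations=300, burn_in=100, thin=2, seed=5)
        d1 = build_design(agg, spec, graph=graph)
        shuffled = agg.sample(frac=1.0, random_state=1).reset_index(drop=True)
        d2 = build_design(shuffled, spec, graph=graph)
        s1, s2 = fit_mcmc(d1, spec, mcmc), fit_mcmc(d2, spec, mcmc)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(s1.f, s2.f)

    def test_spatial_field_sums_to_zero_every_retained_draw(self):
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        _, _, s = _fit_synthetic(
            counts, tracts, graph, (),
            MCMCConfig(iterations=600, burn_in=100, thin=5, seed=3),
        )
        assert np.abs(s.f.sum(axis=1)).max() < 1e-8

    def test_degenerate_spatial_prior_shrinks_sirs_to_one(self):
        """Prior mass forced onto tau^2 ~ 0 -> all smoothed SIRs ~ 1."""
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        _, _, s = _fit_synthetic(
            counts, tracts, graph, (),
            MCMCConfig(iterations=1500, burn_in=500, thin=2, seed=3,
                       ig_a=1e7, ig_b=1e-4),
        )
        sir, (lo, hi) = summarize_sir(s)
        assert lo == pytest.approx(1.0, abs=0.02)
        assert hi == pytest.approx(1.0, abs=0.02)
        assert np.allclose(sir["sir"], 1.0, atol=0.02)

    def test_nonspatial_requires_no_graph_but_spatial_does(self):
        design = build_design(tiny_counts(), ModelSpec(factors=("sex",)))
        with pytest.raises(ValueError, match="graph"):
            fit_mcmc(design, ModelSpec(factors=("sex",), spatial=True),
                     MCMCConfig(iterations=20, burn_in=2, thin=1, seed=0))

    def test_bym_unstructured_effect_runs_and_centers(self):
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        agg = aggregate_cells(counts, ())
        spec = ModelSpec(factors=(), spatial=True, unstructured=True)
        design = build_design(agg, spec, graph=graph)
        s = fit_mcmc(design, spec, MCMCConfig(iterations=400, burn_in=100, thin=4, seed=1))
        assert s.u is not None and np.abs(s.u.sum(axis=1)).max() < 1e-8
        assert s.tau2_u is not None and (s.tau2_u > 0).all()


def degenerate_samples(colnames=("sex:female",), n_tracts=4, n_draws=10):
    spec = ModelSpec(factors=("sex",))
    return PosteriorSamples(
        colnames=colnames,
        intercept=np.full(n_draws, -8.0),
        beta=np.tile(np.array([[0.5]]), (n_draws, 1)),
        f=np.zeros((n_draws, n_tracts)),
        u=None,
        tau2_f=np.full(n_draws, 0.1),
        tau2_u=None,
        deviance=np.full(n_draws, 123.4),
        tract_ids=tuple(f"t{i}" for i in range(n_tracts)),
        spec=spec,
        mcmc=MCMCConfig(iterations=20, burn_in=10, thin=1, seed=0),
        acceptance={},
    )


class TestSummaries:
    def test_dic_degenerate_chain_has_zero_pd(self):
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        agg = aggregate_cells(counts, ("sex",))
        spec = ModelSpec(factors=("sex",), spatial=False)
        design = build_design(agg, spec)
        # freeze a degenerate chain at fixed parameter values
        s = degenerate_samples(n_tracts=design.n_tracts, n_draws=5)
        eta = design.offset - 8.0 + design.X @ np.array([0.5])
        from scipy.special import gammaln

        dev = -2 * (design.y @ np.log(np.exp(eta)) - np.exp(eta).sum()
                    - gammaln(design.y + 1).sum())
        s.deviance[:] = dev
        s.f = None
        dic, p_d, dbar = compute_dic(s, design)
        assert p_d == pytest.approx(0.0, abs=1e-6)
        assert dic == pytest.approx(dev, rel=1e-12)

    def test_rr_table_identities(self):
        s = degenerate_samples()
        tab = rr_table(s, s.spec).set_index("level")
        assert tab.loc["male", "referent"]
        assert tab.loc["female", "rr"] == pytest.approx(np.exp(0.5))
        rng = np.random.default_rng(0)
        draws = rng.normal(0.2, 0.1, size=(s.n_draws,))
        s.beta[:, 0] = draws
        tab = rr_table(s, s.spec).set_index("level")
        assert tab.loc["female", "rr"] == pytest.approx(np.exp(draws.mean()))
        assert tab.loc["female", "lower"] == pytest.approx(
            np.exp(np.percentile(draws, 2.5))
        )

    def test_sir_of_zero_field_is_one_unflagged(self):
        s = degenerate_samples()
        sir, (lo, hi) = summarize_sir(s)
        assert (sir["sir"] == 1.0).all()
        assert not sir["cluster"].any()
        assert lo == hi == 1.0

    def test_sir_requires_spatial_effect(self):
        s = degenerate_samples()
        s.f = None
        with pytest.raises(ValueError, match="spatial"):
            summarize_sir(s)

    def test_sir_point_summary_options(self):
        s = degenerate_samples()
        rng = np.random.default_rng(1)
        s.f = rng.normal(0, 0.3, size=s.f.shape)
        mean_exp, _ = summarize_sir(s, point="mean-exp")
        exp_mean, _ = summarize_sir(s, point="exp-mean")
        # Jensen: posterior mean of exp(f) >= exp(posterior mean of f)
        assert (mean_exp["sir"].to_numpy() >= exp_mean["sir"].to_numpy() - 1e-12).all()

    def test_gd_zero_field_gives_zero(self):
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        agg = aggregate_cells(counts, ("sex",))
        spec = ModelSpec(factors=("sex",))
        design = build_design(agg, spec, graph=graph)
        s = degenerate_samples(n_tracts=design.n_tracts)
        s.beta = np.tile(np.array([[0.5]]), (s.n_draws, 1))
        assert compute_gd(s, design) == pytest.approx(0.0)

    def test_gd_covariate_free_model_is_100(self):
        cfg = SyntheticConfig(grid_rows=4, grid_cols=4, seed=8)
        tracts, graph, counts, _ = simulate_registry(cfg)
        agg = aggregate_cells(counts, ())
        spec = ModelSpec(factors=())
        design = build_design(agg, spec, graph=graph)
        s = degenerate_samples(colnames=(), n_tracts=design.n_tracts)
        s.beta = np.empty((s.n_draws, 0))
        rng = np.random.default_rng(2)
        s.f = rng.normal(0, 0.5, size=(s.n_draws, design.n_tracts))
        assert compute_gd(s, design) == pytest.approx(100.0)


def test_hot_spot_tract_is_flagged():
    """An injected high-risk tract (RR 3, ample population) must be detected."""
    cfg = SyntheticConfig(grid_rows=5, grid_cols=5, tract_population=40_000,
                          true_effects={}, spatial_variance=0.0, seed=17)
    from ctclmap.synthetic_registry import make_geography, make_population, make_truth

    tracts, graph = make_geography(cfg)
    pop = make_population(cfg, tracts)
    n = graph.n_nodes
    field = np.full(n, -np.log(3.0) / (n - 1))
    hot = graph.index_of("r2c2")
    field[hot] = np.log(3.0)
    field -= field.mean()
    truth = SyntheticTruth(intercept=cfg.true_intercept, betas=make_truth(cfg, graph).betas,
                           spatial_field=field, tau2=0.0)
    counts = simulate_cases(pop, truth, cfg, tracts, graph)
    _, _, s = _fit_synthetic(
        counts, tracts, graph, (),
        MCMCConfig(iterations=3000, burn_in=1000, thin=2, seed=4),
    )
    sir, _ = summarize_sir(s)
    assert bool(sir.set_index("tract_id").loc["r2c2", "cluster"])
    assert sir.set_index("tract_id").loc["r2c2", "sir"] > 1.5
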