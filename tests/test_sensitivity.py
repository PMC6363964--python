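import numpy as np
import pandas as pd
import pytest

from rsfpm.cohort import apply_period_window, winsorise_age
from rsfpm.fpm import ModelConfig
from rsfpm.nonparam import pohar_perme
from rsfpm.sensitivity import (
    GridSpec, difference_table, load_published_differences, make_grid, run_grid,
    select_models, summarise_differences,
)
from rsfpm.simulate import SimulationParams, simulate_cohort, simulate_lifetable


class TestMakeGrid:
    def test_default_grid_has_sixty_models(self):
        assert len(make_grid(GridSpec())) == 60

    def test_singleton_sets_single_config(self):
        spec = GridSpec(df_baseline_set=(5,), df_age_set=(3,), df_tvc_set=(3,),
                        reference=(5, 3, 3))
        assert [c.as_tuple() for c in make_grid(spec)] == [(5, 3, 3)]

    def test_reduced_tvc_set_cardinality(self):
        spec = GridSpec(df_tvc_set=(2,), reference=(5, 3, 2))
        assert len(make_grid(spec)) == 15

    def test_cardinality_law(self):
        spec = GridSpec(df_baseline_set=(3, 5), df_age_set=(3, 4), df_tvc_set=(2, 3),
                        reference=(3, 3, 2))
        assert len(make_grid(spec)) == spec.size == 8

    def test_reference_must_be_in_grid(self):
        with pytest.raises(ValueError, match="not in grid"):
            GridSpec(df_baseline_set=(3, 4), reference=(5, 3, 3))

    def test_baseline_major_order(self):
        grid = [c.as_tuple() for c in make_grid(GridSpec())]
        assert grid[0] == (3, 3, 2)
        assert grid[-1] == (7, 5, 5)
        assert grid == sorted(grid)


def _fake_fit(cfg, loglik, n_obs=1000, converged=True):
    from rsfpm.fpm import FittedFPM

    p = 1 + cfg.df_baseline + cfg.df_age + cfg.df_tvc
    return FittedFPM(config=cfg, knots_time=None, knots_age=None, knots_tvc=None,
                     age_center=70.0, age_low=40.0, age_high=95.0,
                     theta=np.zeros(p), cov=None, loglik=loglik, n_params=p,
                     n_obs=n_obs, aic=-2 * loglik + 2 * p,
                     bic=-2 * loglik + p * np.log(n_obs), converged=converged)


class TestSelectModels:
    def test_single_converged_fit_chosen_by_both(self):
        fits = [_fake_fit(ModelConfig(3, 3, 2), -500.0),
                _fake_fit(ModelConfig(4, 3, 2), -400.0, converged=False)]
        aic, bic = select_models(fits)
        assert aic.as_tuple() == bic.as_tuple() == (3, 3, 2)

    def test_aic_tie_broken_by_fewer_parameters(self):
        small = _fake_fit(ModelConfig(3, 3, 2), -500.0)          # p = 9
        big = _fake_fit(ModelConfig(4, 3, 2), -501.0)            # p = 10
        big.aic = small.aic                                      # force the tie
        aic, _ = select_models([big, small])
        assert aic.as_tuple() == (3, 3, 2)

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(8)
        fits = [_fake_fit(cfg, float(-1000 + 10 * rng.random())) for cfg in make_grid(GridSpec())]
        aic_cfg, bic_cfg = select_models(fits)
        best_aic = min(fits, key=lambda f: (f.aic, f.n_params))
        best_bic = min(fits, key=lambda f: (f.bic, f.n_params))
        assert aic_cfg.as_tuple() == best_aic.config.as_tuple()
        assert bic_cfg.as_tuple() == best_bic.config.as_tuple()

    def test_no_converged_fits_rejected(self):
        with pytest.raises(ValueError, match="no converged"):
            select_models([_fake_fit(ModelConfig(3, 3, 2), -1.0, converged=False)])


class TestSummariseDifferences:
    def test_reproduces_published_female_summary_means(self):
        table = load_published_differences()
        for columns, want in (("standardised_aic", 0.091), ("standardised_bic", 0.110),
                              ("standardised_pp", 0.213), ("age_group_aic", 0.229),
                              ("age_specific_aic", 0.271), ("age_specific_bic", 0.140)):
            got = summarise_differences(table, columns, "mean", sex="female")
            assert got == pytest.approx(want, abs=0.005), columns

    def test_published_medians_close(self):
        # medians computed from the printed (rounded) cells only match loosely
        table = load_published_differences()
        assert summarise_differences(table, "standardised_aic", "median", sex="female") \
            == pytest.approx(0.083, abs=0.01)
        assert summarise_differences(table, "standardised_pp", "median", sex="female") \
            == pytest.approx(0.182, abs=0.01)

    def test_all_zero_table(self):
        table = pd.DataFrame({"sex": ["female"] * 3, "std_aic": [0.0, 0.0, 0.0]})
        assert summarise_differences(table, ["std_aic"], "mean") == 0.0
        assert summarise_differences(table, ["std_aic"], "median") == 0.0

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame({"sex": ["male"] * 10, "std_aic": rng.normal(0, 1, 10),
                              "std_bic": rng.normal(0, 1, 10)})
        got = summarise_differences(table, ["std_aic", "std_bic"], "mean")
        assert got == pytest.approx(np.mean(np.abs(table[["std_aic", "std_bic"]].to_numpy())))

    def test_empty_selection_errors(self):
        table = load_published_differences()
        with pytest.raises(ValueError):
            summarise_differences(table, ["nonexistent"], "mean")

    def test_fixture_checksum_guard(self):
        table = load_published_differences(verify_checksum=True)
        # two horizons for 9 female and 8 male cancer types
        assert len(table) == 34
        assert set(table["sex"]) == {"male", "female"}


@pytest.fixture(scope="module")
def small_grid_run():
    """A reduced df grid on a small cohort, for difference-table plumbing."""
    params = SimulationParams(n=3000, seed=19)
    lt = simulate_lifetable(params)
    coh, lo, hi = winsorise_age(simulate_cohort(params, lt))
    rows = apply_period_window(coh, (2011.0, 2014.0))
    spec = GridSpec(df_baseline_set=(3, 4), df_age_set=(3,), df_tvc_set=(2,),
                    reference=(3, 3, 2))
    fits = run_grid(rows, lt, spec, age_low=lo, age_high=hi)
    pp = pohar_perme(rows, lt)
    return {"spec": spec, "fits": fits, "rows": rows, "pp": pp, "lifetable": lt}


class TestRunGrid:
    def test_one_fit_per_config_deterministic(self, small_grid_run):
        fits = small_grid_run["fits"]
        assert len(fits) == 2
        refit = run_grid(small_grid_run["rows"], small_grid_run["lifetable"],
                         small_grid_run["spec"])
        assert [f.loglik for f in fits] == [f.loglik for f in refit]

    def test_tvc_linear_only_single_delta(self, small_grid_run):
        spec = GridSpec(df_baseline_set=(3,), df_age_set=(3,), df_tvc_set=(4,),
                        reference=(3, 3, 4), tvc_linear_only=True)
        fits = run_grid(small_grid_run["rows"], small_grid_run["lifetable"], spec)
        assert all(len(f.delta) == 1 for f in fits)


class TestDifferenceTable:
    def test_reference_vs_itself_is_zero(self, small_grid_run):
        ref_cfg = ModelConfig(3, 3, 2)
        table = difference_table(small_grid_run["fits"], (ref_cfg, ref_cfg),
                                 small_grid_run["pp"], small_grid_run["rows"],
                                 reference=(3, 3, 2))
        aic_bic_cols = [c for c in table.columns if c.endswith(("_aic", "_bic"))]
        np.testing.assert_allclose(table[aic_bic_cols].to_numpy(dtype=float), 0.0, atol=1e-12)

    def test_cells_are_percentage_points(self, small_grid_run):
        from rsfpm.predict import marginal_estimates

        fits = small_grid_run["fits"]
        sel = (ModelConfig(4, 3, 2), ModelConfig(4, 3, 2))
        table = difference_table(fits, sel, small_grid_run["pp"],
                                 small_grid_run["rows"], reference=(3, 3, 2))
        ref = next(f for f in fits if f.config.as_tuple() == (3, 3, 2))
        cmp_ = next(f for f in fits if f.config.as_tuple() == (4, 3, 2))
        r = marginal_estimates(ref, small_grid_run["rows"], [1.0, 5.0], "standardised")[0]
        c = marginal_estimates(cmp_, small_grid_run["rows"], [1.0, 5.0], "standardised")[0]
        want = 100.0 * (r.estimate - c.estimate)
        np.testing.assert_allclose(table["std_aic"].to_numpy(dtype=float), want, rtol=1e-10)

    def test_horizon_beyond_followup_errors(self, small_grid_run):
        sel = (ModelConfig(3, 3, 2), ModelConfig(3, 3, 2))
        with pytest.raises(ValueError, match="beyond observed follow-up"):
            difference_table(small_grid_run["fits"], sel, small_grid_run["pp"],
                             small_grid_run["rows"], horizons=(1.0, 50.0),
                             reference=(3, 3, 2))
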