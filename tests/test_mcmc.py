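import dataclasses

import numpy as np
import pandas as pd
import pytest

import spatqreg as sq
from conftest import make_categorical_dataset


def _intercept_only(n=500, seed=0, tau=0.5):
    rng = np.random.default_rng(seed)
    data, _ = make_categorical_dataset(rng, n, coefs=(0.0, 0.0), sd=1.0,
                                       intercept=0.0)
    spec = sq.ModelSpec(tau=tau, fixed_terms=[], smooth_terms=[],
                        spatial_term=None)
    return data, spec


class TestSampler:
    def test_intercept_only_median(self):
        # symmetric data, tau = 0.5: posterior mean tracks the sample median
        data, spec = _intercept_only(n=500, seed=1)
        fit = sq.fit_model(data, None, spec,
                           sq.MCMCSettings(seed=2, iters=3000, burnin=1000,
                                           thin=1))
        assert fit.fixed[:, 0].mean() == pytest.approx(
            np.median(data.y), abs=0.05)

    def test_chain_determinism(self, grid28):
        data, _ = sq.simulate_dataset(300, grid28, noise="ald", seed=5)
        spec = sq.default_spec(0.05)
        st = sq.MCMCSettings(seed=9, iters=400, burnin=100, thin=2)
        f1 = sq.fit_model(data, grid28, spec, st)
        f2 = sq.fit_model(data, grid28, spec, st)
        assert np.array_equal(f1.fixed, f2.fixed)
        assert np.array_equal(f1.spatial, f2.spatial)
        for k in f1.smooths:
            assert np.array_equal(f1.smooths[k], f2.smooths[k])

    def test_constrained_blocks_sum_to_zero(self, small_ald_fit):
        _, _, fit = small_ald_fit
        assert np.abs(fit.spatial.sum(axis=1)).max() < 1e-8
        for draws in fit.smooths.values():
            assert np.abs(draws.sum(axis=1)).max() < 1e-8

    def test_missing_graph_with_spatial_term_rejected(self):
        data, spec = _intercept_only()
        spec = dataclasses.replace(spec, spatial_term="d")
        with pytest.raises(ValueError, match="graph"):
            sq.fit_model(data, None, spec, sq.MCMCSettings(seed=1, iters=20,
                                                           burnin=10))

    def test_spatial_truth_recovery(self, grid28):
        # simulate-then-recover: correlation with the true district
        # effect at K = 28, n = 3000, ICAR precision 4
        data, truth = sq.simulate_dataset(3000, grid28, noise="ald",
                                          tau=0.05, seed=1, delta_spatial=4.0)
        fit = sq.fit_model(data, grid28, sq.default_spec(0.05),
                           sq.MCMCSettings(seed=2, iters=2500, burnin=1000,
                                           thin=2))
        corr = np.corrcoef(fit.spatial.mean(axis=0), truth.spatial)[0, 1]
        assert corr > 0.7


class TestSummaries:
    def _with_fixed_draws(self, fit, draws, names):
        return dataclasses.replace(fit, fixed=draws, fixed_names=names,
                                   smooths={}, smooth_grids={}, spatial=None,
                                   spatial_labels=None, deltas={},
                                   sigma=np.ones(len(draws)))

    def test_significance_flags_from_ci(self, small_ald_fit):
        # CI (0.0807, 0.1923) -> significant; (-0.0706, 0.0530) -> not
        _, _, fit = small_ald_fit
        S = 2000
        pos = np.linspace(0.0807, 0.1923, S)    # 2.5/97.5% inside (0.08, 0.20)
        mixed = np.linspace(-0.0706, 0.0530, S)
        zero = np.zeros(S)
        crafted = self._with_fixed_draws(
            fit, np.column_stack([pos, mixed, zero]), ["a", "b", "c"])
        tab = sq.posterior_summary(crafted).set_index("name")
        assert bool(tab.loc["a", "significant"]) and tab.loc["a", "mean"] > 0
        assert not tab.loc["b", "significant"]
        assert tab.loc["c", "mean"] == 0
        assert (tab.loc["c", "ci_lower"], tab.loc["c", "ci_upper"]) == (0, 0)
        assert not tab.loc["c", "significant"]

    def test_ci_brackets_mean(self, small_ald_fit):
        _, _, fit = small_ald_fit
        tab = sq.posterior_summary(fit)
        assert (tab.ci_lower <= tab["mean"] + 1e-12).all()
        assert (tab["mean"] <= tab.ci_upper + 1e-12).all()

    def test_spatial_table_categories_and_centering(self, small_ald_fit):
        _, _, fit = small_ald_fit
        tab = sq.spatial_effect_table(fit)
        assert set(tab.category) <= {"negative", "insignificant", "positive"}
        assert tab["mean"].sum() == pytest.approx(0.0, abs=1e-8)
        # a district whose draws are all positive must be flagged positive
        shifted = dataclasses.replace(fit, spatial=fit.spatial + 0.0)
        shifted.spatial = fit.spatial.copy()
        shifted.spatial[:, 0] = np.abs(shifted.spatial[:, 0]) + 0.5
        tab2 = sq.spatial_effect_table(shifted)
        assert tab2.loc[0, "category"] == "positive"

    def test_all_cis_cover_zero_means_all_insignificant(self, small_ald_fit):
        _, _, fit = small_ald_fit
        damped = dataclasses.replace(fit, spatial=fit.spatial * 1e-6)
        rng = np.random.default_rng(0)
        damped.spatial = rng.standard_normal(fit.spatial.shape) * 0.01
        damped.spatial -= damped.spatial.mean(axis=1, keepdims=True)
        tab = sq.spatial_effect_table(damped)
        assert (tab.category == "insignificant").all()


class TestDIC:
    def test_single_draw_has_zero_pd(self, small_ald_fit):
        _, _, fit = small_ald_fit
        one = dataclasses.replace(
            fit, fixed=fit.fixed[:1],
            smooths={k: v[:1] for k, v in fit.smooths.items()},
            spatial=fit.spatial[:1], deltas={k: v[:1] for k, v in fit.deltas.items()},
            sigma=fit.sigma[:1])
        res = sq.compute_dic(one)
        assert res.pd == pytest.approx(0.0, abs=1e-8)
        assert res.dic == pytest.approx(res.dbar, abs=1e-8)

    def test_thinning_invariance(self, grid28):
        data, _ = sq.simulate_dataset(800, grid28, noise="ald", seed=21)
        spec = sq.default_spec(0.05)
        fit = sq.fit_model(data, grid28, spec,
                           sq.MCMCSettings(seed=3, iters=2500, burnin=500,
                                           thin=1))
        thinned = dataclasses.replace(
            fit, fixed=fit.fixed[::5],
            smooths={k: v[::5] for k, v in fit.smooths.items()},
            spatial=fit.spatial[::5],
            deltas={k: v[::5] for k, v in fit.deltas.items()},
            sigma=fit.sigma[::5])
        d1, d5 = sq.compute_dic(fit), sq.compute_dic(thinned)
        assert d5.dic == pytest.approx(d1.dic, rel=0.01)

    def test_recompute_from_data_matches_cached(self, small_ald_fit):
        data, _, fit = small_ald_fit
        cached = sq.compute_dic(fit)
        fresh = sq.compute_dic(fit, data, fit.spec)
        assert fresh.dic == pytest.approx(cached.dic, rel=1e-10)

    def test_spatial_model_preferred_when_truth_is_spatial(self, grid28):
        # strong district effects (ICAR precision 1): the matching model
        # must beat the one omitting the spatial term, paired per dataset
        wins = 0
        for rep in range(5):
            data, _ = sq.simulate_dataset(1200, grid28, noise="ald", tau=0.05,
                                          seed=300 + rep, delta_spatial=1.0)
            st = sq.MCMCSettings(seed=400 + rep, iters=1500, burnin=500, thin=2)
            spec = sq.default_spec(0.05)
            with_sp = sq.fit_model(data, grid28, spec, st)
            spec_ns = dataclasses.replace(spec, spatial_term=None)
            without = sq.fit_model(data, None, spec_ns, st)
            wins += with_sp.dic.dic <= without.dic.dic
        assert wins >= 4
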