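import math

import numpy as np
import pytest

from sfs2d import (JointSFS, ParamSet, aic, akaike_weights, compare_models,
                   delta_aic, expected_jsfs, get_model, model_registry,
                   optimize_model, poisson_loglik, profile_theta, residuals)
from sfs2d.fit import OptimizationError

#: small settings for optimizer tests: coarse spectra, few engine replicates
FAST = dict(nreps=2_000, rounds=((2, 2.0, 20), (1, 1.5, 25)), n_scan=60)


def _sfs(counts, folded=True, mask=None):
    return JointSFS(np.asarray(counts, dtype=float), folded=folded, mask=mask)


class TestThetaProfiling:
    def test_ratio(self):
        obs = _sfs([[0, 60], [40, 0]])
        model = _sfs([[0, 15], [10, 0]])
        assert profile_theta(obs, model) == pytest.approx(4.0)

    def test_identity(self):
        obs = _sfs([[0, 3], [2, 0]])
        assert profile_theta(obs, obs) == pytest.approx(1.0)

    def test_theta_hat_is_local_optimum(self):
        rng = np.random.default_rng(2)
        model = _sfs(rng.random((5, 4)) + 0.1)
        obs = _sfs(rng.poisson(50 * model.counts).astype(float),
                   mask=model.mask.copy())
        th = profile_theta(obs, model)
        ll = poisson_loglik(obs, model, th)
        assert ll >= poisson_loglik(obs, model, th * 1.01)
        assert ll >= poisson_loglik(obs, model, th * 0.99)

    def test_zero_model_mass_rejected(self):
        obs = _sfs([[0, 1], [1, 0]])
        model = _sfs([[0, 0], [0, 0]])
        with pytest.raises(OptimizationError):
            profile_theta(obs, model)


class TestPoissonLoglik:
    def test_single_cell_hand_value(self):
        # obs=2 at mu=1: 2*ln1 - 1 - ln2 = -1.6931
        obs = _sfs([[0, 2], [0, 0]])
        model = _sfs([[0, 1], [0, 0]])
        # only the (0,1) cell is unmasked and non-zero on both sides
        ll = poisson_loglik(obs, model, 1.0)
        assert ll == pytest.approx(2 * math.log(1) - 1 - math.log(2), abs=1e-4)

    def test_loglik_at_mean_is_poisson_mass(self):
        obs = _sfs([[0, 4], [9, 0]])
        ll = poisson_loglik(obs, obs, 1.0)
        expected = sum(k * math.log(k) - k - math.lgamma(k + 1)
                       for k in (4, 9))
        assert ll == pytest.approx(expected)

    def test_doubling_theta_lowers_loglik(self):
        rng = np.random.default_rng(5)
        model = _sfs(rng.random((4, 4)) + 0.5)
        obs = _sfs(rng.poisson(30 * model.counts).astype(float),
                   mask=model.mask.copy())
        th = profile_theta(obs, model)
        assert poisson_loglik(obs, model, th) > poisson_loglik(obs, model, 2 * th)
        assert poisson_loglik(obs, model, th) > poisson_loglik(obs, model, th / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik(_sfs([[0, 1], [1, 0]]),
                           _sfs([[0, 1, 1], [1, 1, 0]]), 1.0)


class TestAIC:
    def test_published_margin(self):
        """AIC arithmetic on the two best published models: the k=5 model at
        logL -177.32 beats the k=8 model at -175.33 by exactly 2.02."""
        a1 = aic(-177.32, 5)
        a2 = aic(-175.33, 8)
        assert a1 == pytest.approx(364.64)
        assert a2 == pytest.approx(366.66)
        assert a2 - a1 == pytest.approx(2.02)

    def test_single_model(self):
        assert delta_aic([123.4]) == [0.0]
        assert akaike_weights([123.4]) == [1.0]

    def test_weight_formula(self):
        w = akaike_weights([0.0, 2.02])
        assert w[0] == pytest.approx(0.7330, abs=1e-4)
        assert w[1] == pytest.approx(0.2670, abs=1e-4)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        aics = list(rng.random(6) * 50)
        assert sum(akaike_weights(aics)) == pytest.approx(1.0, abs=1e-9)
        assert min(delta_aic(aics)) == 0.0

    def test_ranking_depends_on_loglik_only_through_k(self):
        # shifting every loglik by a constant leaves the ranking unchanged
        logliks = [-100.0, -98.5, -104.0]
        ks = [5, 8, 5]
        base = [aic(l, k) for l, k in zip(logliks, ks)]
        shifted = [aic(l + 7.5, k) for l, k in zip(logliks, ks)]
        assert np.argsort(base).tolist() == np.argsort(shifted).tolist()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            delta_aic([])


class TestOptimizeModel:
    @pytest.fixture(scope="class")
    def vic_obs(self):
        model = get_model("vic_no_mig")
        truth = ParamSet(nuA=1.0, nu1=1.5, nu2=3.0, T=0.5, s=0.3)
        exp = expected_jsfs(model, truth, 8, 6, nreps=40_000, seed=77).fold()
        rng = np.random.default_rng(123)
        obs = JointSFS(rng.poisson(400.0 * exp.counts).astype(float),
                       folded=True, mask=exp.mask.copy())
        return model, truth, obs

    def test_s_never_exceeds_bound(self, vic_obs):
        model, _, obs = vic_obs
        for seed in (1, 2, 3):
            fit = optimize_model(model, obs, seed=seed, **FAST)
            assert fit.params["s"] <= 0.5

    def test_reproducible_given_seed(self, vic_obs):
        model, _, obs = vic_obs
        a = optimize_model(model, obs, seed=42, **FAST)
        b = optimize_model(model, obs, seed=42, **FAST)
        assert a.loglik == b.loglik
        assert a.params.as_dict() == b.params.as_dict()

    def test_recovers_dominant_size_from_truth_start(self, vic_obs):
        """Local identifiability: starting near the generating values, the
        fitted daughter-population size lands within 30%."""
        model, truth, obs = vic_obs
        errs = []
        for seed in (1, 2, 3, 4, 5):
            fit = optimize_model(model, obs, nreps=4_000, seed=seed,
                                 rounds=((2, 2.0, 30), (1, 1.5, 40)),
                                 start=truth)
            errs.append(abs(fit.params["nu2"] - truth["nu2"]) / truth["nu2"])
        assert np.median(errs) <= 0.30

    def test_unfolded_observation_rejected(self):
        model = get_model("vic_no_mig")
        obs = JointSFS(np.ones((3, 3)), folded=False)
        with pytest.raises(ValueError, match="folded"):
            optimize_model(model, obs)

    def test_trajectory_schema_echo(self, vic_obs):
        from sfs2d.fit import DEFAULT_ROUNDS
        assert DEFAULT_ROUNDS == ((10, 3.0, 30), (20, 2.0, 40),
                                  (30, 2.0, 50), (40, 1.0, 60))
        model, _, obs = vic_obs
        fit = optimize_model(model, obs, seed=7, **FAST)
        rounds_seen = sorted({r for r, _, _ in fit.trajectory})
        assert rounds_seen == [0, 1, 2]  # scan round plus two NM rounds


class TestCompareModels:
    @pytest.fixture(scope="class")
    def obs(self):
        model = get_model("vic_no_mig")
        truth = ParamSet(nuA=1.0, nu1=1.5, nu2=3.0, T=0.5, s=0.3)
        exp = expected_jsfs(model, truth, 8, 6, nreps=40_000, seed=77).fold()
        rng = np.random.default_rng(5)
        return JointSFS(rng.poisson(400.0 * exp.counts).astype(float),
                        folded=True, mask=exp.mask.copy())

    def test_ranked_output_is_deterministic(self, obs):
        registry = [get_model("vic_no_mig"), get_model("founder_no_mig")]
        a = compare_models(obs, registry, seed=3, **FAST)
        b = compare_models(obs, registry, seed=3, **FAST)
        assert [f.model for f in a.results] == [f.model for f in b.results]
        assert a.weights == b.weights
        assert a.delta_aic[0] == 0.0
        assert sum(a.weights) == pytest.approx(1.0, abs=1e-9)

    def test_published_fixed_inputs_rank_vicariance_first(self):
        """Given the two published best fits of the second population pair
        as fixed (loglik, k) inputs, the no-migration vicariance model
        ranks first."""
        from sfs2d.fit import FitResult, ModelComparison, delta_aic, akaike_weights
        r_vic = FitResult("vic_no_mig", ParamSet(), -177.32, 5, 96.62)
        r_fnd = FitResult("founder_anc_asym_two_epoch", ParamSet(),
                          -175.33, 8, 458.67)
        fits = sorted([r_fnd, r_vic], key=lambda f: f.aic)
        assert fits[0].model == "vic_no_mig"
        ds = delta_aic([f.aic for f in fits])
        assert ds[1] == pytest.approx(2.02, abs=1e-9)

    def test_empty_registry_rejected(self, obs):
        with pytest.raises(ValueError):
            compare_models(obs, [])


class TestResiduals:
    def test_zero_at_perfect_fit(self):
        sfs = _sfs([[0, 4], [9, 0]])
        grid = residuals(sfs, sfs, 1.0)
        assert np.nansum(np.abs(grid)) == pytest.approx(0.0)

    def test_hand_value(self):
        obs = _sfs([[0, 4], [0, 0]])
        model = _sfs([[0, 1], [0, 0]])
        grid = residuals(obs, model, 1.0)
        assert grid[0, 1] == pytest.approx(3.0)

    def test_masked_corners_nan(self):
        obs = _sfs([[0, 4], [9, 0]])
        grid = residuals(obs, obs, 1.0)
        assert grid.shape == obs.shape
        assert math.isnan(grid[0, 0]) and math.isnan(grid[1, 1])
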