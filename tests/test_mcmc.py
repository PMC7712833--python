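"""Sampler machinery: joint density, conjugate updates, reproducibility."""

import math

import numpy as np
import pytest
from scipy import stats

from mbndiallel import (
    EffectsBlock,
    FarrowingRecord,
    GibbsSampler,
    McmcConfig,
    McmcState,
    ModelSpec,
    Pedigree,
    VarianceComponents,
    log_joint,
    prepare_data,
    run_chain,
)


def make_state(data, spec, **vc_kwargs):
    vc = VarianceComponents(
        G=vc_kwargs.get("G", np.diag([0.1, 0.4])),
        P=vc_kwargs.get("P", np.diag([0.4, 0.4])),
        sigma2_et=vc_kwargs.get("sigma2_et", 4.5),
        theta=vc_kwargs.get("theta", 1.0),
    )
    return McmcState(
        effects_t=EffectsBlock.zeros(data.levels),
        effects_l=EffectsBlock.zeros(data.levels),
        spec=spec,
        vc=vc,
    )


class TestLogJoint:
    def setup_method(self):
        self.ped = Pedigree.from_tuples([("s1", None, None)])
        self.recs = [
            FarrowingRecord("s1", "EE", 1, "y1", 10, 2),
            FarrowingRecord("s1", "EE", 1, "y1", 12, 1),
        ]
        self.spec = ModelSpec(model_id="I", t_bar=11.0)
        self.data = prepare_data(self.recs, self.ped, self.spec)

    def test_finite_and_theta_one_reduces_to_binomial(self):
        state = make_state(self.data, self.spec, theta=1.0)
        total, parts = log_joint(self.data, state, return_parts=True)
        assert np.isfinite(total)
        phi = 0.5  # zero effects -> logit phi = 0
        expected = sum(
            stats.binom.logpmf(r.sb, r.tnb, phi) for r in self.recs
        )
        assert parts["mbn"] == pytest.approx(expected, rel=1e-12)

    def test_likelihood_additivity_under_data_doubling(self):
        state = make_state(self.data, self.spec)
        _, parts = log_joint(self.data, state, return_parts=True)
        doubled = prepare_data(self.recs * 2, self.ped, self.spec)
        state2 = make_state(doubled, self.spec)
        _, parts2 = log_joint(doubled, state2, return_parts=True)
        assert parts2["mbn"] == pytest.approx(2 * parts["mbn"], rel=1e-12)
        assert parts2["gauss"] == pytest.approx(2 * parts["gauss"], rel=1e-12)

    def test_out_of_bounds_and_non_pd_give_minus_inf(self):
        state = make_state(self.data, self.spec)
        state.vc.theta = 99.0  # above default bound
        assert log_joint(self.data, state) == -np.inf
        state = make_state(self.data, self.spec)
        state.vc.G = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        assert log_joint(self.data, state) == -np.inf


class TestLocationT:
    def _chain(self, recs, init_vc, n_iter=4000, burn=500, update=("b_t",), seed=3):
        ped = Pedigree.from_tuples([("s1", None, None)])
        spec = ModelSpec(model_id="I", t_bar=9.0)
        cfg = McmcConfig(n_iter=n_iter, burn_in=burn, thin=1, seed=seed, update=update)
        data = prepare_data(recs, ped, spec)
        init = make_state(data, spec, **init_vc)
        sampler = GibbsSampler(data, spec, cfg, init=init)
        return sampler.run()

    def test_conditional_matches_least_squares_on_toy(self):
        """Flat-prior conjugate draw for one fixed effect = N(OLS mean, s2/n)."""
        recs = [FarrowingRecord("s1", "EE", 1, "y1", t, 0) for t in (7, 9, 12)]
        chain = self._chain(recs, {"sigma2_et": 4.5})
        draws = chain.draws["b_t_cross_EE"]
        assert draws.mean() == pytest.approx(np.mean([7, 9, 12]), abs=4 * math.sqrt(4.5 / 3 / len(draws) ** 0.5))
        assert draws.var() == pytest.approx(4.5 / 3, rel=0.15)

    def test_degenerate_residual_variance_concentrates_on_observation(self):
        recs = [FarrowingRecord("s1", "EE", 1, "y1", 8, 0)]
        chain = self._chain(recs, {"sigma2_et": 1e-5}, n_iter=500, burn=100)
        draws = chain.draws["b_t_cross_EE"]
        assert abs(draws.mean() - 8.0) < 0.05
        assert draws.std() < 0.02


class TestChainMechanics:
    def test_empty_chain_when_all_burn_in(self, two_record_toy):
        ped, recs = two_record_toy
        cfg = McmcConfig(n_iter=50, burn_in=50, thin=1, seed=0)
        chain = run_chain(recs, ped, ModelSpec(model_id="I"), cfg)
        assert len(chain) == 0
        assert chain.loglik.shape[1] == 0

    def test_same_seed_bitwise_identical(self, two_record_toy):
        ped, recs = two_record_toy
        cfg = McmcConfig(n_iter=300, burn_in=100, thin=2, seed=123)
        a = run_chain(recs, ped, ModelSpec(model_id="II"), cfg)
        b = run_chain(recs, ped, ModelSpec(model_id="II"), cfg)
        assert a.draws.equals(b.draws)
        assert np.array_equal(a.loglik, b.loglik)

    def test_chain_length_and_loglik_shape(self, short_chain, small_sim):
        cfg = short_chain.config
        expected = (cfg.n_iter - cfg.burn_in) // cfg.thin
        assert len(short_chain) == expected
        assert short_chain.loglik.shape == (len(small_sim.records), expected)

    def test_acceptance_rates_reasonable_after_adaptation(self, short_chain):
        for block, rate in short_chain.accept_rates.items():
            if rate == rate:  # skip NaN (unused blocks)
                assert 0.2 <= rate <= 0.7, (block, rate)

    def test_minimum_proposal_step_enforced(self, two_record_toy):
        ped, recs = two_record_toy
        cfg = McmcConfig(
            n_iter=400, burn_in=300, thin=1, seed=5, step_b_l=1e-9, min_step=1e-4
        )
        data = prepare_data(recs, ped, ModelSpec(model_id="I"))
        sampler = GibbsSampler(data, ModelSpec(model_id="I"), cfg)
        sampler.run()
        assert all(s >= cfg.min_step for s in sampler.steps.values())

    def test_save_load_round_trip(self, short_chain, tmp_path):
        short_chain.save(tmp_path / "chain")
        from mbndiallel import Chain

        draws = Chain.load_draws(tmp_path / "chain")
        assert np.allclose(draws.to_numpy(), short_chain.draws.to_numpy())
        L = Chain.load_loglik(tmp_path / "chain")
        assert np.allclose(L, short_chain.loglik)
        joint = Chain.load_loglik(tmp_path / "chain", "joint")
        assert np.allclose(joint, short_chain.loglik + short_chain.loglik_gauss)


class TestVarianceUpdates:
    def test_G_draws_symmetric_pd_along_chain(self, two_record_toy):
        ped, recs = two_record_toy
        spec = ModelSpec(model_id="II")
        data = prepare_data(recs, ped, spec)
        cfg = McmcConfig(n_iter=100, burn_in=0, thin=1, seed=2)
        sampler = GibbsSampler(data, spec, cfg)
        for _ in range(100):
            sampler.iterate()
            G = sampler.vc.G
            assert np.allclose(G, G.T)
            assert np.linalg.eigvalsh(G)[0] > 0

    def test_frozen_zero_u_pushes_G_to_lower_bound(self):
        """With u frozen at 0, |G|^(-q/2) piles posterior mass at the lower bound."""
        from conftest import random_pedigree

        ped = random_pedigree(np.random.default_rng(0), n=60)
        recs = [
            FarrowingRecord(ped.ids[-1], "EE", 1, "y1", 10, 2),
            FarrowingRecord(ped.ids[-2], "RR", 1, "y1", 12, 1),
        ]
        spec = ModelSpec(model_id="I")
        data = prepare_data(recs, ped, spec)
        cfg = McmcConfig(n_iter=100, burn_in=0, thin=1, seed=4, update=("G",))
        sampler = GibbsSampler(data, spec, cfg)
        draws = []
        for _ in range(200):
            sampler.iterate()
            draws.append(sampler.vc.G[0, 0])
        assert np.median(draws) < 100 * cfg.var_lo

    def test_theta_posterior_detects_overdispersion(self, short_chain, small_sim):
        """Data generated at theta < 1 pull the posterior below 1."""
        assert small_sim.truth.vc.theta < 1
        assert short_chain.draws["theta"].mean() < 1.0

    def test_log_joint_finite_at_chain_states(self, two_record_toy):
        ped, recs = two_record_toy
        spec = ModelSpec(model_id="II")
        data = prepare_data(recs, ped, spec)
        cfg = McmcConfig(n_iter=50, burn_in=0, thin=1, seed=8)
        sampler = GibbsSampler(data, spec, cfg)
        for _ in range(50):
            sampler.iterate()
        assert np.isfinite(log_joint(data, sampler.state, cfg))
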