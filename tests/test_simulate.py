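"""Synthetic diallel generator: design structure, calibration, generative laws."""

import numpy as np
import pytest

from mbndiallel import (
    CROSSES,
    MbnParams,
    SimConfig,
    VarianceComponents,
    mbn_success_prob,
    simulate,
    simulate_pedigree,
)
from mbndiallel.pedigree import MISSING, tabular_A
from mbndiallel.simulate import _gene_drop


def test_pedigree_cross_codes_and_counts():
    cfg = SimConfig(scale=0.05, seed=1)
    rng = np.random.default_rng(1)
    ped = simulate_pedigree(cfg, rng)
    counts = cfg.scaled_counts()
    seen = {c: 0 for c in CROSSES}
    for i, ind in enumerate(ped.ids):
        if ind[:2] in CROSSES and "_" in ind:
            cross = ind[:2]
            seen[cross] += 1
            # sire breed letter first, dam breed letter second
            assert ped.populations[ped.sires[i]] == cross[0]
            assert ped.populations[ped.dams[i]] == cross[1]
    assert seen == counts


def test_founder_only_pedigree_has_identity_A():
    cfg = SimConfig(scale=0.02, seed=0)
    rng = np.random.default_rng(0)
    ped = simulate_pedigree(cfg, rng)
    founders = [i for i in range(len(ped)) if ped.sires[i] == MISSING]
    A = tabular_A(ped)
    sub = A[np.ix_(founders, founders)]
    assert np.allclose(sub, np.eye(len(founders)))


def test_same_seed_identical_dataset():
    a = simulate(SimConfig(scale=0.03, seed=9))
    b = simulate(SimConfig(scale=0.03, seed=9))
    assert a.records == b.records
    assert a.pedigree.ids == b.pedigree.ids


def test_calibration_default_targets(small_sim):
    """Full-scale default hits the configured average litter size."""
    res = simulate(SimConfig(seed=2024))
    tnb = np.array([r.tnb for r in res.records])
    assert abs(tnb.mean() - 8.46) < 0.1
    # record count ~ sows x mean parity span
    assert 8_000 < len(res.records) < 12_000
    assert len({r.sow_id for r in res.records}) == 2110


def test_binomial_special_case_matches_distribution_module():
    """theta=1, no recursion, no random effects: SB | TNB is plain binomial."""
    tiny = 1e-8
    cfg = SimConfig(
        scale=0.4,
        seed=5,
        model_id="I",
        lambda1=0.0,
        records_per_sow=(6, 6),
        cross_dev_l={c: 0.0 for c in CROSSES},
        parity_effects_l=(0.0,) * 6,
        ys_sd_l=0.0,
        vc=VarianceComponents(
            G=np.diag([tiny, 0.4]), P=np.diag([tiny, 0.37]), sigma2_et=4.5, theta=1.0
        ),
    )
    res = simulate(cfg)
    tnb = np.array([r.tnb for r in res.records])
    sb = np.array([r.sb for r in res.records])
    n_events = tnb.sum()
    rate = sb.sum() / n_events
    # with theta=1 the per-event probability is phi itself, the calibrated target
    p = cfg.mean_success_prob
    se = np.sqrt(p * (1 - p) / n_events)
    assert abs(rate - p) < 4 * se
    # conditional variance check: Var(sb | tnb) ~ tnb p (1-p) pooled
    expected_var = (tnb * p * (1 - p)).mean()
    observed_var = np.var(sb - tnb * p)
    assert abs(observed_var - expected_var) < 6 * expected_var / np.sqrt(len(sb))


def test_gene_drop_covariance_matches_A_kron_G():
    """Across replicates, cov of simulated (u_l, u_t) converges to A (x) G."""
    rows = [("a", None, None), ("b", None, None), ("c", "a", "b"), ("d", "a", "b"), ("e", "c", "d")]
    from mbndiallel import Pedigree

    ped = Pedigree.from_tuples(rows)
    A = tabular_A(ped)
    G = np.array([[0.5, 0.2], [0.2, 1.0]])
    rng = np.random.default_rng(7)
    reps = np.array([_gene_drop(ped, G, rng) for _ in range(4000)])  # reps x ind x 2
    n = len(ped)
    # check Cov(u_x[i], u_y[j]) = A[i,j] * G[x,y] on a few entries
    for (i, j) in [(0, 0), (2, 3), (4, 4), (0, 4)]:
        for (x, y) in [(0, 0), (0, 1), (1, 1)]:
            sample = np.cov(reps[:, i, x], reps[:, j, y])[0, 1]
            expected = A[i, j] * G[x, y]
            if abs(expected) > 1e-12:
                assert abs(sample - expected) < 0.12 * abs(expected) + 0.02


def test_positive_recursion_raises_mortality_in_large_litters():
    cfg = SimConfig(scale=0.2, seed=13, lambda1=0.257)
    res = simulate(cfg)
    tnb = np.array([r.tnb for r in res.records])
    sb = np.array([r.sb for r in res.records])
    big, small = tnb >= 10, tnb <= 7
    rate_big = sb[big].sum() / tnb[big].sum()
    rate_small = sb[small].sum() / tnb[small].sum()
    assert rate_big > rate_small

    cfg0 = SimConfig(scale=0.2, seed=13, model_id="I", lambda1=0.0)
    res0 = simulate(cfg0)
    tnb0 = np.array([r.tnb for r in res0.records])
    sb0 = np.array([r.sb for r in res0.records])
    big0, small0 = tnb0 >= 10, tnb0 <= 7
    gap0 = sb0[big0].sum() / tnb0[big0].sum() - sb0[small0].sum() / tnb0[small0].sum()
    assert rate_big - rate_small > gap0


def test_truth_state_reproduces_generated_predictors(small_sim):
    """The packaged truth evaluates to a valid state with finite predictors."""
    from mbndiallel import logit_phi, linear_predictor_t

    truth = small_sim.truth
    for rec in small_sim.records[:20]:
        lp = logit_phi(truth.spec, truth.effects_l, rec)
        et = linear_predictor_t(truth.effects_t, rec)
        assert np.isfinite(lp) and np.isfinite(et)
        # mean litter size plus effects of at most a few piglets
        assert 2 < et < 15
        assert -9 < lp < 2
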