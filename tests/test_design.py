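"""Design matrices and the five logit-phi predictors."""

import numpy as np
import pytest

from mbndiallel import (
    EffectsBlock,
    FarrowingRecord,
    ModelSpec,
    Pedigree,
    build_designs,
    linear_predictor_t,
    logit_phi,
)


@pytest.fixture
def toy():
    ped = Pedigree.from_tuples([("s1", None, None), ("s2", None, None)])
    recs = [
        FarrowingRecord("s1", "EE", 1, "y1", 8, 0),
        FarrowingRecord("s1", "RT", 2, "y2", 10, 1),
        FarrowingRecord("s2", "RT", 1, "y1", 9, 2),
    ]
    return ped, recs


def test_design_shapes_and_incidence(toy):
    ped, recs = toy
    X, Z_u, Z_p, levels = build_designs(recs, ped)
    # 9 cross + (2-1) parity + (2-1) ys columns
    assert X.shape == (3, 11)
    # first record: first parity and first ys are absorbed -> single 1
    assert X[0].sum() == 1
    assert X[1].sum() == 3
    # same sow -> identical Z rows
    assert np.array_equal(Z_u[0].toarray(), Z_u[1].toarray())
    assert np.array_equal(Z_p[0].toarray(), Z_p[1].toarray())
    assert Z_u.shape == (3, 2) and Z_p.shape == (3, 2)


def test_design_full_column_rank_on_simulation(small_sim):
    X, _, _, levels = build_designs(small_sim.records, small_sim.pedigree)
    rank = np.linalg.matrix_rank(X.toarray())
    assert rank == X.shape[1] == levels.n_b


def test_missing_sow_rejected(toy):
    ped, recs = toy
    recs = recs + [FarrowingRecord("ghost", "EE", 1, "y1", 8, 0)]
    with pytest.raises(ValueError, match="ghost"):
        build_designs(recs, ped)


class TestLogitPhi:
    def setup_method(self):
        self.ped = Pedigree.from_tuples([("s1", None, None)])
        self.recs = [
            FarrowingRecord("s1", "RT", 1, "y1", 9, 1),
            FarrowingRecord("s1", "RT", 1, "y1", 12, 1),
        ]
        _, _, _, self.levels = build_designs(self.recs, self.ped)
        self.effects = EffectsBlock.zeros(self.levels)

    def test_recursion_slope_per_piglet(self):
        """One extra piglet moves the model-II logit by lambda1 (0.257 here)."""
        spec = ModelSpec(model_id="II", t_bar=8.0, lambda1=0.257)
        rec = FarrowingRecord("s1", "RT", 1, "y1", 9, 1)  # t = t_bar + 1
        assert logit_phi(spec, self.effects, rec) == pytest.approx(0.257)

    def test_model_I_ignores_litter_size(self):
        spec = ModelSpec(model_id="I")
        vals = {logit_phi(spec, self.effects, r) for r in self.recs}
        assert len(vals) == 1

    def test_model_V_only_own_cross_lambdas_contribute(self):
        lam1 = np.arange(9, dtype=float)
        lam2 = np.arange(9, dtype=float) / 10
        spec = ModelSpec(model_id="V", t_bar=8.0, lambda1_by_cross=lam1, lambda2_by_cross=lam2)
        rec = self.recs[0]  # cross RT, index 5, d = 1
        expected = lam1[5] * 1 + lam2[5] * 1
        assert logit_phi(spec, self.effects, rec) == pytest.approx(expected)
        # other lambdas inert
        lam1_alt = lam1.copy(); lam1_alt[0] = 99.0
        spec_alt = ModelSpec(model_id="V", t_bar=8.0, lambda1_by_cross=lam1_alt, lambda2_by_cross=lam2)
        assert logit_phi(spec_alt, self.effects, rec) == pytest.approx(expected)

    def test_model_IV_with_equal_lambdas_reduces_to_model_II(self):
        spec2 = ModelSpec(model_id="II", t_bar=8.0, lambda1=0.3)
        spec4 = ModelSpec(model_id="IV", t_bar=8.0, lambda1_by_cross=np.full(9, 0.3))
        for rec in self.recs:
            assert logit_phi(spec4, self.effects, rec) == pytest.approx(
                logit_phi(spec2, self.effects, rec)
            )

    @pytest.mark.parametrize("model_id", ["II", "III", "IV", "V"])
    def test_finite_difference_slope_recovers_lambda(self, model_id):
        t_bar = 8.0
        kwargs = dict(t_bar=t_bar)
        if model_id in ("II", "III"):
            kwargs["lambda1"] = 0.31
        if model_id == "III":
            kwargs["lambda2"] = -0.02
        if model_id in ("IV", "V"):
            kwargs["lambda1_by_cross"] = np.linspace(0.1, 0.9, 9)
        if model_id == "V":
            kwargs["lambda2_by_cross"] = np.linspace(-0.05, 0.03, 9)
        spec = ModelSpec(model_id=model_id, **kwargs)
        k = 5  # RT
        d0 = 3.0
        lam1 = kwargs.get("lambda1", kwargs.get("lambda1_by_cross", np.zeros(9)))
        lam1_k = lam1[k] if np.ndim(lam1) else lam1
        lam2 = kwargs.get("lambda2", kwargs.get("lambda2_by_cross", np.zeros(9)))
        lam2_k = lam2[k] if np.ndim(lam2) else lam2
        h = 1e-5
        f = lambda d: float(spec.recursion_term(np.array([d]), np.array([k]))[0])
        slope = (f(d0 + h) - f(d0 - h)) / (2 * h)
        assert slope == pytest.approx(lam1_k + 2 * lam2_k * d0, abs=1e-8)

    def test_linear_predictor_t(self):
        rec = self.recs[0]
        assert linear_predictor_t(self.effects, rec) == 0.0
        eff = EffectsBlock.zeros(self.levels)
        eff.b[5] = 2.5  # RT cross effect
        for r in self.recs:
            assert linear_predictor_t(eff, r) == pytest.approx(2.5)
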