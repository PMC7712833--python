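"""Gibbs sampler with Metropolis-Hastings steps for the recursive MBN model.

One iteration cycles through

1. ``update_location_t``  — exact conjugate single-site Gibbs scans for the
   systematic, additive genetic and permanent-environment effects of the
   Gaussian litter-size model;
2. ``update_location_l``  — adaptive single-site random-walk Metropolis for
   the corresponding effects of the logit-phi model and for the recursion
   coefficients lambda;
3. ``update_variances``   — inverse-Wishart draws for G and P (flat prior,
   df = q - 3 for the 2x2 case), scaled inverse-chi-square for sigma2_et
   (df = N - 2), truncated to the configured bounds by rejection;
4. ``update_theta``       — random-walk Metropolis on log theta with a flat
   prior on theta inside its bounds.

Proposal standard deviations (one per block) adapt toward an acceptance
rate of 0.44 during burn-in and are frozen afterwards, so the post-burn-in
kernel is a fixed, valid MH kernel.  All randomness flows from a single
numpy Generator; runs are bitwise reproducible from the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from . import _kernels as K
from .design import EffectsBlock, LevelMaps, ModelSpec, build_designs
from .io import CROSSES, FarrowingRecord
from .pedigree import Pedigree, RelationshipMatrix, build_relationship

__all__ = [
    "VarianceComponents",
    "McmcConfig",
    "McmcState",
    "Chain",
    "PreparedData",
    "prepare_data",
    "log_joint",
    "GibbsSampler",
    "run_chain",
]


@dataclass
class VarianceComponents:
    """(Co)variance structure: G and P are 2x2 over the (l, t) trait pair."""

    G: np.ndarray
    P: np.ndarray
    sigma2_et: float
    theta: float

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        for name, M in (("G", self.G), ("P", self.P)):
            if M.shape != (2, 2) or not np.allclose(M, M.T):
                raise ValueError(f"{name} must be a symmetric 2x2 matrix")
            if np.linalg.eigvalsh(M)[0] <= 0:
                raise ValueError(f"{name} must be positive definite")
        if self.sigma2_et <= 0 or self.theta <= 0:
            raise ValueError("sigma2_et and theta must be positive")

    @property
    def r_a(self) -> float:
        return float(self.G[0, 1] / math.sqrt(self.G[0, 0] * self.G[1, 1]))

    @property
    def r_p(self) -> float:
        return float(self.P[0, 1] / math.sqrt(self.P[0, 0] * self.P[1, 1]))

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(self.G.copy(), self.P.copy(), self.sigma2_et, self.theta)


_ALL_BLOCKS = ("b_t", "u_t", "p_t", "b_l", "u_l", "p_l", "lam", "theta", "sigma2_et", "G", "P")


@dataclass
class McmcConfig:
    """Chain controls, prior bounds and proposal tuning.

    The default chain (30,000 iterations, 5,000 burn-in, thin 10) is the
    desk-scale setting; production-length chains are a matter of raising
    ``n_iter``/``burn_in``.
    """

    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    # flat-prior bounds
    var_lo: float = 1e-6
    var_hi: float = 100.0
    theta_lo: float = 1e-3
    theta_hi: float = 5.0
    # proposal tuning
    step_b_l: float = 0.3
    step_u_l: float = 0.3
    step_p_l: float = 0.3
    step_lambda: float = 0.05
    step_theta: float = 0.05
    adapt_interval: int = 25
    target_accept: float = 0.44
    min_step: float = 1e-4
    max_tries: int = 10_000
    #: parameter blocks to sample; removing a name freezes that block.
    update: tuple[str, ...] = _ALL_BLOCKS

    def __post_init__(self) -> None:
        if self.burn_in > self.n_iter:
            raise ValueError("burn_in cannot exceed n_iter")
        unknown = set(self.update) - set(_ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown update blocks {sorted(unknown)}")


@dataclass
class McmcState:
    """A full parameter state of the model."""

    effects_t: EffectsBlock
    effects_l: EffectsBlock
    spec: ModelSpec
    vc: VarianceComponents
    iteration: int = 0


@dataclass
class Chain:
    """Thinned posterior draws plus the per-record log-likelihoods CPO needs."""

    draws: pd.DataFrame
    loglik: np.ndarray          # records x draws, MBN log p(y_i | t_i, state)
    loglik_gauss: np.ndarray    # records x draws, Gaussian log p(t_i | state)
    accept_rates: dict[str, float]
    spec: ModelSpec
    levels: LevelMaps
    config: McmcConfig

    def __len__(self) -> int:
        return len(self.draws)

    def cross_effect_draws(self, trait: str) -> pd.DataFrame:
        cols = [f"b_{trait}_cross_{c}" for c in CROSSES]
        return self.draws[cols]

    def loglik_matrix(self, likelihood: str = "sb") -> np.ndarray:
        if likelihood == "sb":
            return self.loglik
        if likelihood == "joint":
            return self.loglik + self.loglik_gauss
        raise ValueError("likelihood must be 'sb' or 'joint'")

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(outdir / "draws.csv", index=False)
        np.savetxt(outdir / "loglik_sb.csv", self.loglik, delimiter=",")
        np.savetxt(outdir / "loglik_gauss.csv", self.loglik_gauss, delimiter=",")
        meta = {
            "accept_rates": self.accept_rates,
            "model_id": self.spec.model_id,
            "t_bar": self.spec.t_bar,
            "n_iter": self.config.n_iter,
            "burn_in": self.config.burn_in,
            "thin": self.config.thin,
            "seed": self.config.seed,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load_draws(outdir: str | Path) -> pd.DataFrame:
        return pd.read_csv(Path(outdir) / "draws.csv")

    @staticmethod
    def load_loglik(outdir: str | Path, likelihood: str = "sb") -> np.ndarray:
        sb = np.loadtxt(Path(outdir) / "loglik_sb.csv", delimiter=",", ndmin=2)
        if likelihood == "sb":
            return sb
        return sb + np.loadtxt(Path(outdir) / "loglik_gauss.csv", delimiter=",", ndmin=2)


@dataclass
class PreparedData:
    """Flat-array view of records + pedigree consumed by the kernels."""

    records: list[FarrowingRecord]
    pedigree: Pedigree
    rel: RelationshipMatrix
    levels: LevelMaps
    sb: np.ndarray
    tnb: np.ndarray
    t_obs: np.ndarray
    d: np.ndarray
    d2: np.ndarray
    cross: np.ndarray
    t_bar: float
    # record groupings (CSR indptr/indices)
    b_grp: tuple[np.ndarray, np.ndarray]
    u_grp: tuple[np.ndarray, np.ndarray]
    p_grp: tuple[np.ndarray, np.ndarray]
    cross_grp: tuple[np.ndarray, np.ndarray]
    A_inv: sp.csr_matrix
    _logdet_A: float | None = None

    @property
    def n_records(self) -> int:
        return len(self.sb)

    @property
    def logdet_A(self) -> float:
        if self._logdet_A is None:
            sign, val = np.linalg.slogdet(self.rel.A)
            if sign <= 0:
                raise np.linalg.LinAlgError("relationship matrix not positive definite")
            self._logdet_A = float(val)
        return self._logdet_A


def _csc_groups(Z: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    c = Z.tocsc()
    return c.indptr.astype(np.int64), c.indices.astype(np.int64)


def prepare_data(
    records: list[FarrowingRecord],
    pedigree: Pedigree,
    spec: ModelSpec,
    rel: RelationshipMatrix | None = None,
) -> PreparedData:
    """Build design groupings and flat arrays; fixes t_bar on the spec.

    If ``spec.t_bar`` is unset (None), it is frozen to the unweighted mean
    of the observed litter sizes across all records.
    """
    X, Z_u, Z_p, levels = build_designs(records, pedigree)
    tnb = np.array([r.tnb for r in records], dtype=np.int64)
    if spec.t_bar is None:
        spec.t_bar = float(tnb.mean())
    if rel is None:
        rel = build_relationship(pedigree)
    d = tnb.astype(float) - spec.t_bar
    cross = np.array([CROSSES.index(r.cross) for r in records], dtype=np.int64)
    cross_Z = sp.csr_matrix(
        (np.ones(len(records)), (np.arange(len(records)), cross)), shape=(len(records), 9)
    )
    return PreparedData(
        records=records,
        pedigree=pedigree,
        rel=rel,
        levels=levels,
        sb=np.array([r.sb for r in records], dtype=np.int64),
        tnb=tnb,
        t_obs=tnb.astype(float),
        d=d,
        d2=d * d,
        cross=cross,
        t_bar=spec.t_bar,
        b_grp=_csc_groups(X),
        u_grp=_csc_groups(Z_u),
        p_grp=_csc_groups(Z_p),
        cross_grp=_csc_groups(cross_Z),
        A_inv=rel.A_inv.tocsr(),
    )


def _lambda_columns(spec: ModelSpec) -> list[str]:
    names = []
    if spec.model_id in ("II", "III"):
        names.append("lambda1")
    if spec.model_id == "III":
        names.append("lambda2")
    if spec.model_id in ("IV", "V"):
        names += [f"lambda1_{c}" for c in CROSSES]
    if spec.model_id == "V":
        names += [f"lambda2_{c}" for c in CROSSES]
    return names


class GibbsSampler:
    """Sampler over a prepared dataset.  See the module docstring for the cycle."""

    def __init__(
        self,
        data: PreparedData,
        spec: ModelSpec,
        config: McmcConfig | None = None,
        init: McmcState | None = None,
    ):
        self.data = data
        self.spec = spec
        self.config = config or McmcConfig()
        self.rng = np.random.default_rng(self.config.seed)
        lv = data.levels
        n_b, n_u, n_p = lv.n_b, len(data.pedigree), len(lv.sow_ids)
        if init is not None:
            self.b_t = init.effects_t.b.copy(); self.u_t = init.effects_t.u.copy()
            self.p_t = init.effects_t.p.copy()
            self.b_l = init.effects_l.b.copy(); self.u_l = init.effects_l.u.copy()
            self.p_l = init.effects_l.p.copy()
            self.vc = init.vc.copy()
            self.lam1 = _init_lam(init.spec, 1)
            self.lam2 = _init_lam(init.spec, 2)
        else:
            self.b_t = np.zeros(n_b); self.u_t = np.zeros(n_u); self.p_t = np.zeros(n_p)
            self.b_l = np.zeros(n_b); self.u_l = np.zeros(n_u); self.p_l = np.zeros(n_p)
            # start cross effects of t at the raw cross means, logit side at the
            # empirical overall logit, for a finite, central starting state
            for k, c in enumerate(CROSSES):
                mask = data.cross == k
                if mask.any():
                    self.b_t[k] = data.t_obs[mask].mean()
            rate = max(data.sb.sum(), 0.5) / max(data.tnb.sum(), 1)
            self.b_l[:9] = math.log(rate / (1.0 - rate))
            self.vc = VarianceComponents(
                G=np.diag([0.1, 0.4]), P=np.diag([0.4, 0.4]),
                sigma2_et=max(float(np.var(data.t_obs)) / 2.0, 0.5), theta=1.0,
            )
            self.lam1 = _init_lam(spec, 1)
            self.lam2 = _init_lam(spec, 2)
        self.ltheta = np.array([math.log(self.vc.theta)])
        self.iteration = 0
        self._refresh_predictors()
        self._refresh_precisions()
        self.steps = {
            "b_l": self.config.step_b_l,
            "u_l": self.config.step_u_l,
            "p_l": self.config.step_p_l,
            "lam": self.config.step_lambda,
            "theta": self.config.step_theta,
        }
        self._acc = {k: [0, 0] for k in self.steps}
        self._acc_total = {k: [0, 0] for k in self.steps}
        self._prop_ll = np.empty(data.n_records)
        self._all_ptr = np.array([0, data.n_records], dtype=np.int64)
        self._all_idx = np.arange(data.n_records, dtype=np.int64)

    # -- state <-> arrays -------------------------------------------------

    @property
    def state(self) -> McmcState:
        lv = self.data.levels
        spec = ModelSpec(
            model_id=self.spec.model_id,
            t_bar=self.spec.t_bar,
            lambda1=float(self.lam1[0]) if self.spec.model_id in ("II", "III") else 0.0,
            lambda2=float(self.lam2[0]) if self.spec.model_id == "III" else 0.0,
            lambda1_by_cross=self.lam1.copy() if self.spec.model_id in ("IV", "V") else None,
            lambda2_by_cross=self.lam2.copy() if self.spec.model_id == "V" else None,
        )
        return McmcState(
            effects_t=EffectsBlock(self.b_t.copy(), self.u_t.copy(), self.p_t.copy(), lv),
            effects_l=EffectsBlock(self.b_l.copy(), self.u_l.copy(), self.p_l.copy(), lv),
            spec=spec,
            vc=self.vc.copy(),
            iteration=self.iteration,
        )

    def _recursion(self) -> np.ndarray:
        d, d2, cr = self.data.d, self.data.d2, self.data.cross
        m = self.spec.model_id
        if m == "I":
            return np.zeros_like(d)
        if m == "II":
            return self.lam1[0] * d
        if m == "III":
            return self.lam1[0] * d + self.lam2[0] * d2
        if m == "IV":
            return self.lam1[cr] * d
        return self.lam1[cr] * d + self.lam2[cr] * d2

    def _systematic(self, b: np.ndarray) -> np.ndarray:
        out = np.zeros(self.data.n_records)
        ptr, idx = self.data.b_grp
        for c in range(len(b)):
            out[idx[ptr[c]:ptr[c + 1]]] += b[c]
        return out

    def _refresh_predictors(self) -> None:
        data = self.data
        uZ = np.zeros(data.n_records)
        pZ = np.zeros(data.n_records)
        ptr, idx = data.u_grp
        for j in range(len(self.u_t)):
            uZ[idx[ptr[j]:ptr[j + 1]]] = self.u_t[j]
        ptr, idx = data.p_grp
        for j in range(len(self.p_t)):
            pZ[idx[ptr[j]:ptr[j + 1]]] = self.p_t[j]
        self.eta_t = self._systematic(self.b_t) + uZ + pZ
        ptr, idx = data.u_grp
        uZ = np.zeros(data.n_records)
        for j in range(len(self.u_l)):
            uZ[idx[ptr[j]:ptr[j + 1]]] = self.u_l[j]
        ptr, idx = data.p_grp
        pZ = np.zeros(data.n_records)
        for j in range(len(self.p_l)):
            pZ[idx[ptr[j]:ptr[j + 1]]] = self.p_l[j]
        self.lp = self._systematic(self.b_l) + uZ + pZ + self._recursion()
        self.cur_ll = np.empty(data.n_records)
        K.total_loglik(self.data.sb, self.data.tnb, self.lp, self.ltheta[0], self.cur_ll)

    def _refresh_precisions(self) -> None:
        Gi = np.linalg.inv(self.vc.G)
        Pi = np.linalg.inv(self.vc.P)
        self.g_ll, self.g_lt, self.g_tt = Gi[0, 0], Gi[0, 1], Gi[1, 1]
        self.q_ll, self.q_lt, self.q_tt = Pi[0, 0], Pi[0, 1], Pi[1, 1]

    # -- update blocks ----------------------------------------------------

    def update_location_t(self) -> None:
        data, cfg, rng = self.data, self.config, self.rng
        ai = data.A_inv
        if "b_t" in cfg.update:
            K.gibbs_scan_b_t(
                self.b_t, self.eta_t, data.t_obs, *data.b_grp,
                self.vc.sigma2_et, rng.standard_normal(len(self.b_t)),
            )
        if "u_t" in cfg.update:
            K.gibbs_scan_u_t(
                self.u_t, self.u_l, self.eta_t, data.t_obs, *data.u_grp,
                ai.indptr.astype(np.int64), ai.indices.astype(np.int64), ai.data,
                self.g_tt, self.g_lt, self.vc.sigma2_et,
                rng.standard_normal(len(self.u_t)),
            )
        if "p_t" in cfg.update:
            K.gibbs_scan_p_t(
                self.p_t, self.p_l, self.eta_t, data.t_obs, *data.p_grp,
                self.q_tt, self.q_lt, self.vc.sigma2_et,
                rng.standard_normal(len(self.p_t)),
            )

    def update_location_l(self) -> None:
        data, cfg, rng = self.data, self.config, self.rng
        ai = data.A_inv
        lt = self.ltheta[0]
        if "b_l" in cfg.update:
            acc, tot = K.mh_scan_b_l(
                self.b_l, self.lp, self.cur_ll, data.sb, data.tnb, lt, *data.b_grp,
                self.steps["b_l"], rng.standard_normal(len(self.b_l)),
                rng.random(len(self.b_l)),
            )
            self._count("b_l", acc, tot)
        if "u_l" in cfg.update:
            acc = K.mh_scan_u_l(
                self.u_l, self.u_t, self.lp, self.cur_ll, data.sb, data.tnb, lt,
                *data.u_grp,
                ai.indptr.astype(np.int64), ai.indices.astype(np.int64), ai.data,
                self.g_ll, self.g_lt, self.steps["u_l"],
                rng.standard_normal(len(self.u_l)), rng.random(len(self.u_l)),
            )
            self._count("u_l", acc, len(self.u_l))
        if "p_l" in cfg.update:
            acc = K.mh_scan_p_l(
                self.p_l, self.p_t, self.lp, self.cur_ll, data.sb, data.tnb, lt,
                *data.p_grp, self.q_ll, self.q_lt, self.steps["p_l"],
                rng.standard_normal(len(self.p_l)), rng.random(len(self.p_l)),
            )
            self._count("p_l", acc, len(self.p_l))
        if "lam" in cfg.update:
            self._update_lambdas()

    def _update_lambdas(self) -> None:
        data, rng = self.data, self.rng
        lt = self.ltheta[0]
        m = self.spec.model_id
        acc = tot = 0
        if m in ("II", "III"):
            acc += K.mh_lambda(
                self.lam1, 0, data.d, self.lp, self.cur_ll, data.sb, data.tnb, lt,
                self._all_ptr, self._all_idx, self.steps["lam"],
                rng.standard_normal(), rng.random(),
            )
            tot += 1
        if m == "III":
            acc += K.mh_lambda(
                self.lam2, 0, data.d2, self.lp, self.cur_ll, data.sb, data.tnb, lt,
                self._all_ptr, self._all_idx, self.steps["lam"],
                rng.standard_normal(), rng.random(),
            )
            tot += 1
        if m in ("IV", "V"):
            ptr, idx = data.cross_grp
            for k in range(9):
                sel = np.array([ptr[k], ptr[k + 1]], dtype=np.int64)
                acc += K.mh_lambda(
                    self.lam1, k, data.d, self.lp, self.cur_ll, data.sb, data.tnb, lt,
                    sel, idx, self.steps["lam"], rng.standard_normal(), rng.random(),
                )
                tot += 1
                if m == "V":
                    acc += K.mh_lambda(
                        self.lam2, k, data.d2, self.lp, self.cur_ll, data.sb, data.tnb,
                        lt, sel, idx, self.steps["lam"],
                        rng.standard_normal(), rng.random(),
                    )
                    tot += 1
        if tot:
            self._count("lam", acc, tot)

    def update_theta(self) -> None:
        if "theta" not in self.config.update:
            return
        acc = K.mh_theta(
            self.ltheta, self.lp, self.cur_ll, self.data.sb, self.data.tnb,
            self.steps["theta"], self.rng.standard_normal(), self.rng.random(),
            self.config.theta_lo, self.config.theta_hi, self._prop_ll,
        )
        self.vc.theta = math.exp(self.ltheta[0])
        self._count("theta", acc, 1)

    def update_variances(self) -> None:
        cfg, rng = self.config, self.rng
        if "sigma2_et" in cfg.update:
            e = self.data.t_obs - self.eta_t
            ssr = float(e @ e)
            n = self.data.n_records
            self.vc.sigma2_et = self._truncated_draw(
                lambda: ssr / rng.chisquare(max(n - 2, 1)),
                lambda v: cfg.var_lo < v < cfg.var_hi,
                "sigma2_et",
            )
        if "G" in cfg.update:
            U = np.column_stack([self.u_l, self.u_t])
            S = U.T @ (self.data.A_inv @ U)
            self.vc.G = self._draw_cov(S, len(self.data.pedigree), "G")
        if "P" in cfg.update:
            Pm = np.column_stack([self.p_l, self.p_t])
            S = Pm.T @ Pm
            self.vc.P = self._draw_cov(S, len(self.data.levels.sow_ids), "P")
        self._refresh_precisions()

    def _draw_cov(self, S: np.ndarray, q: int, name: str) -> np.ndarray:
        cfg, rng = self.config, self.rng
        df = q - 3
        if df < 2 or np.trace(S) < 1e-8:
            # degenerate sufficient statistic (e.g. effects frozen at zero):
            # posterior ~ |G|^(-q/2) truncated to the bounds, which piles up at
            # the lower bound; sample the diagonal from that power law directly.
            out = np.zeros((2, 2))
            for i in range(2):
                out[i, i] = _power_law_draw(rng, q, cfg.var_lo, cfg.var_hi)
            return out

        def ok(M: np.ndarray) -> bool:
            return (
                cfg.var_lo < M[0, 0] < cfg.var_hi
                and cfg.var_lo < M[1, 1] < cfg.var_hi
                and np.linalg.eigvalsh(M)[0] > 0
            )

        return self._truncated_draw(
            lambda: stats.invwishart.rvs(df=df, scale=S, random_state=rng),
            ok, name,
        )

    def _truncated_draw(self, draw, ok, name: str):
        for _ in range(self.config.max_tries):
            v = draw()
            if ok(v):
                return v
        raise RuntimeError(
            f"{name}: {self.config.max_tries} consecutive draws fell outside the "
            "prior bounds; widen var_lo/var_hi (or theta bounds) in McmcConfig"
        )

    # -- bookkeeping ------------------------------------------------------

    def _count(self, block: str, acc: int, tot: int) -> None:
        self._acc[block][0] += acc
        self._acc[block][1] += tot
        self._acc_total[block][0] += acc
        self._acc_total[block][1] += tot

    def _adapt(self) -> None:
        cfg = self.config
        for block, (acc, tot) in self._acc.items():
            if tot == 0:
                continue
            rate = acc / tot
            self.steps[block] = max(
                cfg.min_step, self.steps[block] * math.exp(0.3 * (rate - cfg.target_accept))
            )
            self._acc[block] = [0, 0]

    def iterate(self) -> None:
        self.update_location_t()
        self.update_location_l()
        self.update_variances()
        self.update_theta()
        self.iteration += 1
        if self.iteration <= self.config.burn_in and self.iteration % self.config.adapt_interval == 0:
            self._adapt()

    def run(self) -> Chain:
        cfg = self.config
        data = self.data
        n_store = (cfg.n_iter - cfg.burn_in) // cfg.thin
        lam_cols = _lambda_columns(self.spec)
        b_names = data.levels.b_names
        columns = (
            ["iteration"]
            + [f"b_t_{n}" for n in b_names]
            + [f"b_l_{n}" for n in b_names]
            + lam_cols
            + ["theta", "sigma2_et",
               "sigma2_al", "sigma_alt", "sigma2_at",
               "sigma2_pl", "sigma_plt", "sigma2_pt"]
        )
        out = np.empty((n_store, len(columns)))
        loglik = np.empty((data.n_records, n_store))
        loglik_gauss = np.empty((data.n_records, n_store))
        stored = 0
        for _ in range(cfg.n_iter):
            self.iterate()
            k = self.iteration - cfg.burn_in
            if k > 0 and k % cfg.thin == 0 and stored < n_store:
                lam_vals = list(self.lam1[: self.spec.n_lambda1]) + list(
                    self.lam2[: self.spec.n_lambda2]
                )
                vc = self.vc
                out[stored] = (
                    [self.iteration]
                    + list(self.b_t) + list(self.b_l) + lam_vals
                    + [vc.theta, vc.sigma2_et,
                       vc.G[0, 0], vc.G[0, 1], vc.G[1, 1],
                       vc.P[0, 0], vc.P[0, 1], vc.P[1, 1]]
                )
                loglik[:, stored] = self.cur_ll
                e = data.t_obs - self.eta_t
                loglik_gauss[:, stored] = -0.5 * (
                    math.log(2.0 * math.pi * vc.sigma2_et) + e * e / vc.sigma2_et
                )
                stored += 1
        accept = {
            b: (a / t if t else float("nan")) for b, (a, t) in self._acc_total.items()
        }
        return Chain(
            draws=pd.DataFrame(out[:stored], columns=columns),
            loglik=loglik[:, :stored],
            loglik_gauss=loglik_gauss[:, :stored],
            accept_rates=accept,
            spec=self.spec,
            levels=data.levels,
            config=cfg,
        )


def _init_lam(spec: ModelSpec, which: int) -> np.ndarray:
    if which == 1:
        if spec.model_id in ("II", "III"):
            return np.array([spec.lambda1], dtype=float)
        if spec.model_id in ("IV", "V"):
            return np.array(spec.lambda1_by_cross, dtype=float)
    else:
        if spec.model_id == "III":
            return np.array([spec.lambda2], dtype=float)
        if spec.model_id == "V":
            return np.array(spec.lambda2_by_cross, dtype=float)
    return np.zeros(9)


def _power_law_draw(rng: np.random.Generator, q: int, lo: float, hi: float) -> float:
    """Inverse-CDF draw from density ~ x^(-q/2) on [lo, hi]."""
    a = q / 2.0
    u = rng.random()
    if abs(a - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    p = 1.0 - a
    return float((lo ** p + u * (hi ** p - lo ** p)) ** (1.0 / p))


def run_chain(
    records: list[FarrowingRecord],
    pedigree: Pedigree,
    spec: ModelSpec,
    config: McmcConfig | None = None,
    rel: RelationshipMatrix | None = None,
    init: McmcState | None = None,
) -> Chain:
    """Fit the model: prepare data, run the Gibbs/MH cycle, return the chain."""
    data = prepare_data(records, pedigree, spec, rel=rel)
    sampler = GibbsSampler(data, spec, config, init=init)
    return sampler.run()


def log_joint(
    data: PreparedData,
    state: McmcState,
    config: McmcConfig | None = None,
    return_parts: bool = False,
):
    """Log of the joint density of data and parameters at ``state``.

    Parts: (i) MBN likelihood of the stillbirth counts, (ii) Gaussian
    likelihood of litter size, (iii) N(0, A (x) G) prior of (u_l, u_t),
    (iv) N(0, I (x) P) prior of (p_l, p_t); flat priors contribute 0 inside
    their bounds and -inf outside; non-positive-definite G or P gives -inf.
    """
    cfg = config or McmcConfig()
    vc = state.vc
    for M in (vc.G, vc.P):
        if np.linalg.eigvalsh(M)[0] <= 0:
            return -np.inf
    inside = (
        cfg.var_lo < vc.sigma2_et < cfg.var_hi
        and cfg.theta_lo < vc.theta <= cfg.theta_hi
        and all(cfg.var_lo < M[i, i] < cfg.var_hi for M in (vc.G, vc.P) for i in range(2))
    )
    if not inside:
        return -np.inf

    et, el, spec = state.effects_t, state.effects_l, state.spec
    # predictors via record-level evaluation (small-data diagnostic path)
    eta_t = np.array([et.predictor(r) for r in data.records])
    from .design import logit_phi as _lphi

    lp = np.array([_lphi(spec, el, r) for r in data.records])
    ll_mbn = 0.0
    for i, r in enumerate(data.records):
        ll_mbn += K.mbn_loglik(r.sb, r.tnb, lp[i], math.log(vc.theta))
    e = data.t_obs - eta_t
    ll_gauss = float(
        -0.5 * (len(e) * math.log(2.0 * math.pi * vc.sigma2_et) + (e @ e) / vc.sigma2_et)
    )
    q = len(data.pedigree)
    U = np.column_stack([el.u, et.u])
    Gi = np.linalg.inv(vc.G)
    quad = float(np.trace(Gi @ (U.T @ (data.A_inv @ U))))
    lp_u = -0.5 * (
        2.0 * q * math.log(2.0 * math.pi)
        + 2.0 * data.logdet_A
        + q * math.log(np.linalg.det(vc.G))
        + quad
    )
    qp = len(data.levels.sow_ids)
    Pm = np.column_stack([el.p, et.p])
    Pi = np.linalg.inv(vc.P)
    lp_p = -0.5 * (
        2.0 * qp * math.log(2.0 * math.pi)
        + qp * math.log(np.linalg.det(vc.P))
        + float(np.trace(Pi @ (Pm.T @ Pm)))
    )
    total = ll_mbn + ll_gauss + lp_u + lp_p
    if return_parts:
        return total, {"mbn": ll_mbn, "gauss": ll_gauss, "prior_u": lp_u, "prior_p": lp_p}
    return total
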