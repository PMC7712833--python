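"""Synthetic diallel-cross data with the statistical structure the model assumes.

The generator emulates a 3-variety diallel among closed pig populations
(E, R, T): founders per variety, one intermediate generation of purebred
matings, and a sow generation covering all nine sire-x-dam breed
combinations.  Phenotypes follow the generative reading of the fitted
model: breeding values (u_l, u_t) ~ N(0, A (x) G) drawn by gene-dropping
down the pedigree (Mendelian-sampling recursion, exact without forming A),
permanent-environment values ~ N(0, I (x) P), Gaussian litter size rounded
to an integer (floored at 1), and stillbirth counts from the MBN with the
configured recursion on the logit scale.

Default sizes and parameter magnitudes are those of the study system this
package targets: 2110 sows over the nine crosses producing ~10k litters,
mean litter size 8.46 (sd ~2.27), per-event stillbirth rate ~0.03,
overdispersion theta = 0.816 and recursion slope lambda1 = 0.257; the
``scale`` knob shrinks the design proportionally for desk-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .design import EffectsBlock, ModelSpec, build_designs
from .io import CROSSES, FarrowingRecord
from .mbn import MbnParams, mbn_pmf_vector, mbn_success_prob  # noqa: F401  (success-prob used via _success_prob_vec oracle)
from .mcmc import McmcState, VarianceComponents
from .pedigree import MISSING, Pedigree, inbreeding_coefficients

__all__ = ["SimConfig", "SimResult", "simulate_pedigree", "simulate_phenotypes", "simulate"]

#: sows per cross as surveyed in the source diallel (sire breed x dam breed).
DEFAULT_SOWS_PER_CROSS = {
    "EE": 100, "ER": 527, "ET": 177, "RE": 196, "RR": 175,
    "RT": 488, "TE": 36, "TR": 343, "TT": 68,
}
#: founders per variety: (sires, dams).
DEFAULT_FOUNDERS = {"E": (13, 34), "R": (18, 62), "T": (38, 69)}

#: cross means of litter size used as the true cross effects for t.
DEFAULT_CROSS_MEANS_T = {
    "EE": 7.95, "ER": 8.53, "ET": 8.02, "RE": 8.84, "RR": 8.38,
    "RT": 8.60, "TE": 8.69, "TR": 8.53, "TT": 7.28,
}
#: cross deviations on the logit-phi scale (unreported crosses at 0).
DEFAULT_CROSS_DEV_L = {
    "EE": 0.237, "ER": -0.135, "ET": -0.143, "RE": 0.0, "RR": 0.0,
    "RT": 0.0, "TE": 0.136, "TR": -0.196, "TT": 0.0,
}


def _default_vc() -> VarianceComponents:
    # magnitudes of the best-fitting recursive model on the source data
    s2al, s2at, ra = 0.050, 0.397, 0.203
    s2pl, s2pt, rp = 0.418, 0.368, 0.028
    return VarianceComponents(
        G=np.array([[s2al, ra * math.sqrt(s2al * s2at)], [ra * math.sqrt(s2al * s2at), s2at]]),
        P=np.array([[s2pl, rp * math.sqrt(s2pl * s2pt)], [rp * math.sqrt(s2pl * s2pt), s2pt]]),
        sigma2_et=4.497,
        theta=0.816,
    )


@dataclass
class SimConfig:
    """Study-design and true-parameter settings of the generator."""

    sows_per_cross: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SOWS_PER_CROSS))
    founders: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_FOUNDERS))
    scale: float = 1.0
    records_per_sow: tuple[int, int] = (3, 6)   # uniform inclusive range
    n_ys: int = 30
    t_bar: float = 8.46
    model_id: str = "II"
    lambda1: float = 0.257
    lambda2: float = 0.0
    lambda1_by_cross: np.ndarray | None = None
    lambda2_by_cross: np.ndarray | None = None
    mean_success_prob: float = 0.0296            # mean SB / mean TNB of the survey
    cross_means_t: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CROSS_MEANS_T))
    cross_dev_l: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CROSS_DEV_L))
    parity_effects_t: tuple[float, ...] = (0.0, 0.35, 0.55, 0.55, 0.40, 0.15)
    parity_effects_l: tuple[float, ...] = (0.0, -0.10, 0.0, 0.10, 0.20, 0.30)
    ys_sd_t: float = 0.30
    ys_sd_l: float = 0.10
    vc: VarianceComponents = field(default_factory=_default_vc)
    seed: int = 2024

    def scaled_counts(self) -> dict[str, int]:
        return {c: max(2, round(n * self.scale)) for c, n in self.sows_per_cross.items()}

    def scaled_founders(self) -> dict[str, tuple[int, int]]:
        return {
            p: (max(2, round(s * self.scale)), max(2, round(d * self.scale)))
            for p, (s, d) in self.founders.items()
        }

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            model_id=self.model_id,
            t_bar=self.t_bar,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            lambda1_by_cross=self.lambda1_by_cross,
            lambda2_by_cross=self.lambda2_by_cross,
        )


@dataclass
class SimResult:
    """Generated data plus the generating ('true') parameter state."""

    pedigree: Pedigree
    records: list[FarrowingRecord]
    truth: McmcState
    sow_ids: list[str]


def simulate_pedigree(config: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Founders, one purebred intermediate generation, then the sow generation.

    A sow's cross code takes the sire's breed letter first and the dam's
    second (an ER sow has an E sire and an R dam).
    """
    counts = config.scaled_counts()
    founders = config.scaled_founders()
    ids: list[str] = []
    sires: list[int] = []
    dams: list[int] = []
    pops: list[str | None] = []

    f_males: dict[str, list[int]] = {}
    f_females: dict[str, list[int]] = {}
    for pop, (ns, nd) in founders.items():
        f_males[pop], f_females[pop] = [], []
        for k in range(ns):
            ids.append(f"{pop}S{k}"); sires.append(MISSING); dams.append(MISSING)
            pops.append(pop); f_males[pop].append(len(ids) - 1)
        for k in range(nd):
            ids.append(f"{pop}D{k}"); sires.append(MISSING); dams.append(MISSING)
            pops.append(pop); f_females[pop].append(len(ids) - 1)

    # intermediate generation: purebred offspring used as parents of the sows
    need_sires = {p: 0 for p in founders}
    need_dams = {p: 0 for p in founders}
    for cross, n in counts.items():
        need_sires[cross[0]] += n
        need_dams[cross[1]] += n
    g1_males: dict[str, list[int]] = {p: [] for p in founders}
    g1_females: dict[str, list[int]] = {p: [] for p in founders}
    for pop in founders:
        n_m = max(5, math.ceil(need_sires[pop] / 8))    # a boar sires ~8 sows
        n_f = max(10, math.ceil(need_dams[pop] / 3))    # a dam produces ~3 sows
        for k in range(n_m + n_f):
            ids.append(f"{pop}G1_{k}")
            sires.append(int(rng.choice(f_males[pop])))
            dams.append(int(rng.choice(f_females[pop])))
            pops.append(pop)
            (g1_males[pop] if k < n_m else g1_females[pop]).append(len(ids) - 1)

    for cross in CROSSES:
        sire_pop, dam_pop = cross[0], cross[1]
        for k in range(counts[cross]):
            ids.append(f"{cross}_{k}")
            sires.append(int(rng.choice(g1_males[sire_pop])))
            dams.append(int(rng.choice(g1_females[dam_pop])))
            pops.append(None)
    return Pedigree(ids=ids, sires=np.array(sires), dams=np.array(dams), populations=pops)


def _gene_drop(
    ped: Pedigree, G: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(u_l, u_t) ~ N(0, A (x) G) by the Mendelian-sampling recursion."""
    n = len(ped)
    F = inbreeding_coefficients(ped)
    L = np.linalg.cholesky(G)
    u = np.zeros((n, 2))
    for i in range(n):
        s, d = ped.sires[i], ped.dams[i]
        if s != MISSING and d != MISSING:
            delta = 0.5 - 0.25 * (F[s] + F[d])
            mid = 0.5 * (u[s] + u[d])
        elif s != MISSING or d != MISSING:
            par = s if s != MISSING else d
            delta = 0.75 - 0.25 * F[par]
            mid = 0.5 * u[par]
        else:
            delta = 1.0
            mid = 0.0
        u[i] = mid + math.sqrt(delta) * (L @ rng.standard_normal(2))
    return u


def _success_prob_vec(nb_arr: np.ndarray, lphi: np.ndarray, theta: float) -> np.ndarray:
    """Per-event success probability phi*K_{nb-1}/K_nb, vectorized by litter size."""
    from scipy.special import gammaln, logsumexp as lse

    out = np.empty(len(nb_arr), dtype=float)
    logphi = lphi - np.logaddexp(0.0, lphi)
    log1m = -np.logaddexp(0.0, lphi)
    lt = math.log(theta)
    for nbv in np.unique(nb_arr):
        m = nb_arr == nbv
        j = np.arange(nbv + 1)
        lc = gammaln(nbv + 1) - gammaln(j + 1) - gammaln(nbv - j + 1)
        w0 = (
            lc[None, :]
            + np.outer(logphi[m], j)
            + np.outer(log1m[m], nbv - j)
            + (j * (nbv - j) * lt)[None, :]
        )
        j1 = np.arange(nbv)
        lc1 = gammaln(nbv) - gammaln(j1 + 1) - gammaln(nbv - j1)
        w1 = (
            lc1[None, :]
            + np.outer(logphi[m], j1)
            + np.outer(log1m[m], nbv - 1 - j1)
            + ((j1 + 1) * (nbv - 1 - j1) * lt)[None, :]
        )
        out[m] = np.exp(logphi[m] + lse(w1, axis=1) - lse(w0, axis=1))
    return out


def simulate_phenotypes(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator
) -> tuple[list[FarrowingRecord], McmcState]:
    """Draw farrowing records from the generative model; returns (records, truth).

    The systematic constants are calibrated against the realized random
    effects: after drawing breeding values, permanent-environment values and
    the record skeleton, a single constant per trait scale centres the
    record-weighted mean predictor on the configured targets (overall litter
    size t_bar; overall per-event stillbirth rate).  Random effects keep
    their exact N(0, A (x) G) / N(0, I (x) P) distributions — only fixed
    constants absorb the realized drift, exactly as the cross effects of a
    fitted model would.
    """
    spec = config.model_spec()
    u = _gene_drop(pedigree, config.vc.G, rng)
    sow_pos = [i for i, ind in enumerate(pedigree.ids) if ind[:2] in CROSSES and "_" in ind]
    sow_ids = [pedigree.ids[i] for i in sow_pos]
    Lp = np.linalg.cholesky(config.vc.P)
    p = (Lp @ rng.standard_normal((2, len(sow_pos)))).T  # sows x (l, t)

    ys_levels = [f"ys{k:02d}" for k in range(config.n_ys)]
    # year-season treated as balanced deviations (centred draws)
    ys_t = rng.normal(0.0, config.ys_sd_t, size=config.n_ys)
    ys_t -= ys_t.mean()
    ys_l = rng.normal(0.0, config.ys_sd_l, size=config.n_ys)
    ys_l -= ys_l.mean()
    lo, hi = config.records_per_sow

    # record skeleton: sow, parity, year-season
    rec_si, rec_pi, rec_par, rec_ys, rec_k = [], [], [], [], []
    for si, pi in enumerate(sow_pos):
        for j in range(int(rng.integers(lo, hi + 1))):
            rec_si.append(si)
            rec_pi.append(pi)
            rec_par.append(min(j + 1, 6))
            rec_ys.append(int(rng.integers(config.n_ys)))
            rec_k.append(CROSSES.index(sow_ids[si][:2]))
    rec_si = np.array(rec_si); rec_pi = np.array(rec_pi)
    rec_par = np.array(rec_par); rec_ys = np.array(rec_ys); rec_k = np.array(rec_k)
    n = len(rec_si)

    par_t = np.asarray(config.parity_effects_t)
    par_l = np.asarray(config.parity_effects_l)
    cross_t = np.array([config.cross_means_t[c] for c in CROSSES])
    cross_l = np.array([config.cross_dev_l[c] for c in CROSSES])

    z_t = cross_t[rec_k] + par_t[rec_par - 1] + ys_t[rec_ys] + u[rec_pi, 1] + p[rec_si, 1]
    t_adjust = config.t_bar - float(z_t.mean())
    tnb = np.maximum(1, np.rint(rng.normal(z_t + t_adjust, math.sqrt(config.vc.sigma2_et)))).astype(int)
    d = tnb - config.t_bar
    recursion = spec.recursion_term(d, rec_k)

    z_l = cross_l[rec_k] + par_l[rec_par - 1] + ys_l[rec_ys] + u[rec_pi, 0] + p[rec_si, 0]
    # solve the baseline so the expected overall rate sum(sb)/sum(tnb) over
    # the realized design equals the target (litter-size weighted; exact up
    # to the Monte Carlo noise of the count draws)
    p0 = config.mean_success_prob
    z_full = z_l + recursion
    wt = tnb / tnb.sum()

    def weighted_rate_gap(base: float) -> float:
        return float(wt @ _success_prob_vec(tnb, base + z_full, config.vc.theta)) - p0

    base_l = brentq(weighted_rate_gap, -15.0, 5.0)

    lphi = base_l + z_l + recursion
    phi = expit(lphi)
    records: list[FarrowingRecord] = []
    for i in range(n):
        pmf = mbn_pmf_vector(MbnParams(int(tnb[i]), float(phi[i]), config.vc.theta))
        sb = int(rng.choice(tnb[i] + 1, p=pmf / pmf.sum()))
        records.append(
            FarrowingRecord(
                sow_id=sow_ids[rec_si[i]],
                cross=CROSSES[rec_k[i]],
                parity=int(rec_par[i]),
                year_season=ys_levels[rec_ys[i]],
                tnb=int(tnb[i]),
                sb=sb,
            )
        )
    truth = _truth_state(pedigree, records, config, u, p, sow_ids, base_l, ys_t, ys_l, t_adjust)
    return records, truth


def _truth_state(pedigree, records, config, u, p, sow_ids, base_l, ys_t, ys_l, t_adjust) -> McmcState:
    """Package the generating parameters in the fitted model's layout."""
    _, _, _, levels = build_designs(records, pedigree)
    et = EffectsBlock.zeros(levels)
    el = EffectsBlock.zeros(levels)
    nc = 9
    # the dropped first parity / year-season levels are absorbed into the
    # cross effects under the fitting convention, so fold them in here
    ys_index = {f"ys{k:02d}": k for k in range(config.n_ys)}
    ref_par = levels.parity_levels[0]
    ref_ys = ys_index[levels.ys_levels[0]]
    abs_t = config.parity_effects_t[ref_par - 1] + ys_t[ref_ys]
    abs_l = config.parity_effects_l[ref_par - 1] + ys_l[ref_ys]
    for k, c in enumerate(levels.cross_levels):
        et.b[k] = config.cross_means_t[c] + t_adjust + abs_t
        el.b[k] = base_l + config.cross_dev_l[c] + abs_l
    for i, par in enumerate(levels.parity_levels[1:], start=1):
        et.b[nc + i - 1] = (
            config.parity_effects_t[par - 1] - config.parity_effects_t[ref_par - 1]
        )
        el.b[nc + i - 1] = (
            config.parity_effects_l[par - 1] - config.parity_effects_l[ref_par - 1]
        )
    npar = len(levels.parity_levels) - 1
    for i, ys in enumerate(levels.ys_levels[1:], start=1):
        et.b[nc + npar + i - 1] = ys_t[ys_index[ys]] - ys_t[ref_ys]
        el.b[nc + npar + i - 1] = ys_l[ys_index[ys]] - ys_l[ref_ys]
    et.u = u[:, 1].copy()
    el.u = u[:, 0].copy()
    sow_order = {s: i for i, s in enumerate(sow_ids)}
    for j, s in enumerate(levels.sow_ids):
        et.p[j] = p[sow_order[s], 1]
        el.p[j] = p[sow_order[s], 0]
    return McmcState(
        effects_t=et, effects_l=el, spec=config.model_spec(), vc=config.vc.copy()
    )


def simulate(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """One full synthetic dataset (pedigree + records + truth)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ped = simulate_pedigree(config, rng)
    records, truth = simulate_phenotypes(ped, config, rng)
    sow_ids = list(dict.fromkeys(r.sow_id for r in records))
    return SimResult(pedigree=ped, records=records, truth=truth, sow_ids=sow_ids)
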