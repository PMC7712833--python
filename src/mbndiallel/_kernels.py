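"""Numba kernels for the per-iteration Gibbs/Metropolis scans.

Everything here operates on flat arrays prepared by :mod:`mbndiallel.mcmc`:

* records: ``sb``, ``tnb`` (int), ``d`` (tnb - t_bar), ``cross`` (0..8) plus
  three systematic-effect column indices per record (-1 = absorbed level),
  a pedigree slot and a sow slot;
* grouping (CSR-style ``indptr``/``indices``) of records by systematic
  column, by pedigree individual, and by sow;
* the sparse rows of A^-1.

The Gaussian (litter size) side uses exact conjugate single-site Gibbs
draws; the logit side uses single-site Gaussian random-walk Metropolis with
one adapted proposal sd per block.  The MBN log-likelihood of each record at
the current state is cached in ``cur_ll`` so each proposal costs a single
pmf evaluation.

State mutated in place: ``b_t, u_t, p_t, b_l, u_l, p_l, lam1, lam2,
eta_t`` (Gaussian predictor per record), ``lp`` (logit phi per record),
``cur_ll``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MAXN = 64  # litters never approach this


@njit(cache=True, inline="always")
def _softplus(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return 0.0
    return math.log1p(math.exp(x))


@njit(cache=True)
def mbn_loglik(y, nb, lp, ltheta):
    """log MBN(y | nb, phi=expit(lp), theta=exp(ltheta)), stable in log space."""
    if nb == 0:
        return 0.0
    logphi = lp - _softplus(lp)
    log1mphi = -_softplus(lp)
    # unnormalized log weight of j, and running log-sum-exp for the normalizer
    m = -1.0e300
    lc = 0.0  # log C(nb, j), updated multiplicatively
    # first pass: find max
    w = np.empty(nb + 1)
    for j in range(nb + 1):
        w[j] = lc + j * logphi + (nb - j) * log1mphi + j * (nb - j) * ltheta
        if w[j] > m:
            m = w[j]
        if j < nb:
            lc += math.log((nb - j) / (j + 1.0))
    s = 0.0
    for j in range(nb + 1):
        s += math.exp(w[j] - m)
    return w[y] - (m + math.log(s))


@njit(cache=True)
def total_loglik(sb, tnb, lp, ltheta, out):
    tot = 0.0
    for i in range(sb.shape[0]):
        out[i] = mbn_loglik(sb[i], tnb[i], lp[i], ltheta)
        tot += out[i]
    return tot


@njit(cache=True)
def gibbs_scan_b_t(b_t, eta_t, t_obs, grp_ptr, grp_idx, sigma2_et, z):
    """Exact conjugate draw for each systematic-effect column of the t model.

    ``z`` holds one standard-normal innovation per column.
    """
    for c in range(b_t.shape[0]):
        lo, hi = grp_ptr[c], grp_ptr[c + 1]
        n = hi - lo
        if n == 0:
            continue
        s = 0.0
        for k in range(lo, hi):
            i = grp_idx[k]
            s += t_obs[i] - eta_t[i] + b_t[c]
        mean = s / n
        sd = math.sqrt(sigma2_et / n)
        new = mean + sd * z[c]
        delta = new - b_t[c]
        b_t[c] = new
        for k in range(lo, hi):
            eta_t[grp_idx[k]] += delta


@njit(cache=True)
def gibbs_scan_u_t(
    u_t, u_l, eta_t, t_obs, grp_ptr, grp_idx,
    ai_ptr, ai_idx, ai_val, g_tt, g_lt, sigma2_et, z,
):
    """Single-site Gibbs for additive genetic values on the t scale.

    Prior coupling to u_l through the 2x2 G inverse (entries g_tt, g_lt).
    """
    for j in range(u_t.shape[0]):
        rd_t = 0.0  # (A^-1 u_t)_j excluding the diagonal term
        rd_l = 0.0  # (A^-1 u_l)_j including diagonal
        ajj = 0.0
        for k in range(ai_ptr[j], ai_ptr[j + 1]):
            m = ai_idx[k]
            a = ai_val[k]
            rd_l += a * u_l[m]
            if m == j:
                ajj = a
            else:
                rd_t += a * u_t[m]
        lo, hi = grp_ptr[j], grp_ptr[j + 1]
        n = hi - lo
        s = 0.0
        for k in range(lo, hi):
            i = grp_idx[k]
            s += t_obs[i] - eta_t[i] + u_t[j]
        prec = n / sigma2_et + ajj * g_tt
        mean = (s / sigma2_et - g_tt * rd_t - g_lt * rd_l) / prec
        new = mean + math.sqrt(1.0 / prec) * z[j]
        delta = new - u_t[j]
        u_t[j] = new
        for k in range(lo, hi):
            eta_t[grp_idx[k]] += delta


@njit(cache=True)
def gibbs_scan_p_t(p_t, p_l, eta_t, t_obs, grp_ptr, grp_idx, q_tt, q_lt, sigma2_et, z):
    """Single-site Gibbs for permanent-environment values on the t scale."""
    for j in range(p_t.shape[0]):
        lo, hi = grp_ptr[j], grp_ptr[j + 1]
        n = hi - lo
        s = 0.0
        for k in range(lo, hi):
            i = grp_idx[k]
            s += t_obs[i] - eta_t[i] + p_t[j]
        prec = n / sigma2_et + q_tt
        mean = (s / sigma2_et - q_lt * p_l[j]) / prec
        new = mean + math.sqrt(1.0 / prec) * z[j]
        delta = new - p_t[j]
        p_t[j] = new
        for k in range(lo, hi):
            eta_t[grp_idx[k]] += delta


@njit(cache=True)
def mh_scan_b_l(b_l, lp, cur_ll, sb, tnb, ltheta, grp_ptr, grp_idx, step, z, uacc):
    """Random-walk Metropolis for each systematic-effect column of the logit model.

    Returns (accepted, proposed); columns with no records are not proposed.
    """
    acc = 0
    tot = 0
    for c in range(b_l.shape[0]):
        lo, hi = grp_ptr[c], grp_ptr[c + 1]
        if hi == lo:
            continue
        tot += 1
        delta = step * z[c]
        logr = 0.0
        for k in range(lo, hi):
            i = grp_idx[k]
            logr += mbn_loglik(sb[i], tnb[i], lp[i] + delta, ltheta) - cur_ll[i]
        if logr >= 0.0 or uacc[c] < math.exp(logr):
            acc += 1
            b_l[c] += delta
            for k in range(lo, hi):
                i = grp_idx[k]
                lp[i] += delta
                cur_ll[i] = mbn_loglik(sb[i], tnb[i], lp[i], ltheta)
    return acc, tot


@njit(cache=True)
def mh_scan_u_l(
    u_l, u_t, lp, cur_ll, sb, tnb, ltheta, grp_ptr, grp_idx,
    ai_ptr, ai_idx, ai_val, g_ll, g_lt, step, z, uacc,
):
    """Random-walk Metropolis for additive genetic values on the logit scale.

    The Gaussian prior term couples u_l to u_t through G^-1; individuals
    without records still move (prior-only update, exact Gibbs would also
    work but a shared kernel keeps the scan uniform).
    """
    acc = 0
    for j in range(u_l.shape[0]):
        rd_l = 0.0
        rd_t = 0.0
        ajj = 0.0
        for k in range(ai_ptr[j], ai_ptr[j + 1]):
            m = ai_idx[k]
            a = ai_val[k]
            rd_t += a * u_t[m]
            if m == j:
                ajj = a
            else:
                rd_l += a * u_l[m]
        cur = u_l[j]
        new = cur + step * z[j]
        # prior log-density difference in u_l[j]
        logr = -0.5 * g_ll * ajj * (new * new - cur * cur) - (g_ll * rd_l + g_lt * rd_t) * (
            new - cur
        )
        lo, hi = grp_ptr[j], grp_ptr[j + 1]
        delta = new - cur
        for k in range(lo, hi):
            i = grp_idx[k]
            logr += mbn_loglik(sb[i], tnb[i], lp[i] + delta, ltheta) - cur_ll[i]
        if logr >= 0.0 or uacc[j] < math.exp(logr):
            acc += 1
            u_l[j] = new
            for k in range(lo, hi):
                i = grp_idx[k]
                lp[i] += delta
                cur_ll[i] = mbn_loglik(sb[i], tnb[i], lp[i], ltheta)
    return acc


@njit(cache=True)
def mh_scan_p_l(p_l, p_t, lp, cur_ll, sb, tnb, ltheta, grp_ptr, grp_idx, q_ll, q_lt, step, z, uacc):
    """Random-walk Metropolis for permanent-environment values on the logit scale."""
    acc = 0
    for j in range(p_l.shape[0]):
        cur = p_l[j]
        new = cur + step * z[j]
        logr = -0.5 * q_ll * (new * new - cur * cur) - q_lt * p_t[j] * (new - cur)
        lo, hi = grp_ptr[j], grp_ptr[j + 1]
        delta = new - cur
        for k in range(lo, hi):
            i = grp_idx[k]
            logr += mbn_loglik(sb[i], tnb[i], lp[i] + delta, ltheta) - cur_ll[i]
        if logr >= 0.0 or uacc[j] < math.exp(logr):
            acc += 1
            p_l[j] = new
            for k in range(lo, hi):
                i = grp_idx[k]
                lp[i] += delta
                cur_ll[i] = mbn_loglik(sb[i], tnb[i], lp[i], ltheta)
    return acc


@njit(cache=True)
def mh_lambda(lam, which, covar, lp, cur_ll, sb, tnb, ltheta, rec_sel_ptr, rec_sel_idx, step, z, uacc):
    """Random-walk Metropolis for one recursion coefficient.

    ``lam`` is the scalar array holding the coefficient at ``which``;
    ``covar[i]`` is its per-record multiplier (d or d^2, zero when the
    record's cross is out of scope); ``rec_sel_*`` indexes the records
    whose covariate is nonzero.
    """
    cur = lam[which]
    new = cur + step * z
    delta = new - cur
    logr = 0.0
    for k in range(rec_sel_ptr[0], rec_sel_ptr[1]):
        i = rec_sel_idx[k]
        logr += mbn_loglik(sb[i], tnb[i], lp[i] + delta * covar[i], ltheta) - cur_ll[i]
    if logr >= 0.0 or uacc < math.exp(logr):
        lam[which] = new
        for k in range(rec_sel_ptr[0], rec_sel_ptr[1]):
            i = rec_sel_idx[k]
            lp[i] += delta * covar[i]
            cur_ll[i] = mbn_loglik(sb[i], tnb[i], lp[i], ltheta)
        return 1
    return 0


@njit(cache=True)
def mh_theta(ltheta_arr, lp, cur_ll, sb, tnb, step, z, uacc, lo_bound, hi_bound, prop_ll):
    """Random-walk Metropolis on log theta; flat prior on theta within bounds.

    The log-scale walk carries a Jacobian term log(theta'/theta).
    """
    cur = ltheta_arr[0]
    new = cur + step * z
    theta_new = math.exp(new)
    if theta_new <= lo_bound or theta_new > hi_bound:
        return 0
    logr = new - cur  # Jacobian of the log transform under a flat prior on theta
    tot = 0.0
    for i in range(sb.shape[0]):
        prop_ll[i] = mbn_loglik(sb[i], tnb[i], lp[i], new)
        tot += prop_ll[i] - cur_ll[i]
    logr += tot
    if logr >= 0.0 or uacc < math.exp(logr):
        ltheta_arr[0] = new
        for i in range(sb.shape[0]):
            cur_ll[i] = prop_ll[i]
        return 1
    return 0
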