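"""Multiplicative binomial (MBN) distribution.

The MBN generalizes the binomial by the factor ``theta**(x*(nb-x))``:

.. math::

    \\Pr(x \\mid nb, \\phi, \\theta) =
        \\binom{nb}{x} \\phi^x (1-\\phi)^{nb-x} \\theta^{x(nb-x)} / K_{nb},

where the normalizer ``K_nb`` sums the unnormalized weights over
``x = 0..nb``.  ``theta = 1`` recovers Binomial(nb, phi); ``theta < 1``
inflates the tails (overdispersion, positively dependent Bernoulli events)
and ``theta > 1`` shrinks them (underdispersion).  The per-event success
probability is no longer ``phi`` but ``phi * K_{nb-1} / K_nb``.

All arithmetic is carried out in log space with log-sum-exp: the factor
``theta**(x*(nb-x))`` spans hundreds of orders of magnitude already at
litter sizes of a few dozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "MbnParams",
    "mbn_log_pmf",
    "mbn_pmf_vector",
    "mbn_normalizer",
    "mbn_log_normalizer",
    "mbn_success_prob",
    "mbn_mean_var",
    "mbn_sample",
]


@dataclass(frozen=True)
class MbnParams:
    """Parameters of one litter's stillbirth distribution.

    Attributes
    ----------
    nb : int
        Number of Bernoulli events (total number born in the litter).
    phi : float
        Location parameter in (0, 1); equals the per-event success
        probability only when ``theta == 1``.
    theta : float
        Dispersion parameter (> 0); 1 = binomial, < 1 = overdispersed.
    """

    nb: int
    phi: float
    theta: float

    def __post_init__(self) -> None:
        if not (isinstance(self.nb, (int, np.integer)) and self.nb >= 0):
            raise ValueError(f"nb must be a non-negative integer, got {self.nb!r}")
        if not (np.isfinite(self.phi) and 0.0 < self.phi < 1.0):
            raise ValueError(f"phi must lie in (0, 1), got {self.phi!r}")
        if not (np.isfinite(self.theta) and self.theta > 0.0):
            raise ValueError(f"theta must be > 0, got {self.theta!r}")


def _log_unnormalized(n: int, phi: float, theta: float, shift: int = 0) -> np.ndarray:
    """Log weights log[C(n,j) phi^j (1-phi)^(n-j) theta^((j+shift)(n-j))], j=0..n."""
    j = np.arange(n + 1)
    log_binom = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
    return (
        log_binom
        + j * math.log(phi)
        + (n - j) * math.log1p(-phi)
        + (j + shift) * (n - j) * math.log(theta)
    )


def mbn_log_normalizer(params: MbnParams, a: int = 0) -> float:
    """Log of the normalizer K_{nb-a}(phi, theta).

    ``a = 0`` gives K_nb (the pmf normalizer, equal to 1 when theta = 1);
    ``a = 1`` gives K_{nb-1}, whose exponent is shifted to (j+1)(nb-1-j),
    as required by the per-event success probability.
    """
    if a not in (0, 1):
        raise ValueError(f"a must be 0 or 1, got {a!r}")
    n = params.nb - a
    if n < 0:
        raise ValueError(f"nb - a must be >= 0, got nb={params.nb}, a={a}")
    return float(logsumexp(_log_unnormalized(n, params.phi, params.theta, shift=a)))


def mbn_normalizer(params: MbnParams, a: int = 0) -> float:
    """Normalizer K_{nb-a}(phi, theta) on the natural scale."""
    return math.exp(mbn_log_normalizer(params, a))


def mbn_log_pmf(x: int, params: MbnParams) -> float:
    """Log probability of ``x`` stillborn among ``nb`` piglets."""
    nb = params.nb
    if not (0 <= x <= nb):
        raise ValueError(f"x must lie in [0, nb]=[0, {nb}], got {x!r}")
    logw = _log_unnormalized(nb, params.phi, params.theta)
    return float(logw[x] - logsumexp(logw))


def mbn_pmf_vector(params: MbnParams) -> np.ndarray:
    """Full pmf over 0..nb (sums to 1)."""
    logw = _log_unnormalized(params.nb, params.phi, params.theta)
    logw -= logsumexp(logw)
    return np.exp(logw)


def mbn_success_prob(params: MbnParams) -> float:
    """Per-event success probability p = phi * K_{nb-1} / K_nb.

    Equals E[x]/nb; equals phi exactly when theta = 1.
    """
    if params.nb < 1:
        raise ValueError("per-event success probability requires nb >= 1")
    return params.phi * math.exp(
        mbn_log_normalizer(params, a=1) - mbn_log_normalizer(params, a=0)
    )


def mbn_mean_var(params: MbnParams) -> tuple[float, float]:
    """Mean and variance of the count, by direct summation of the pmf."""
    pmf = mbn_pmf_vector(params)
    x = np.arange(params.nb + 1)
    mean = float(pmf @ x)
    return mean, float(pmf @ (x - mean) ** 2)


def mbn_sample(
    params: MbnParams,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> int | np.ndarray:
    """Draw from the exact pmf by CDF inversion over the nb+1 support points.

    Litter sizes are small, so full enumeration is both exact and cheap.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if params.nb == 0:
        return 0 if size is None else np.zeros(size, dtype=np.int64)
    cdf = np.cumsum(mbn_pmf_vector(params))
    cdf[-1] = 1.0
    u = rng.random(size if size is not None else 1)
    out = np.searchsorted(cdf, u, side="right").astype(np.int64)
    np.clip(out, 0, params.nb, out=out)
    return int(out[0]) if size is None else out
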