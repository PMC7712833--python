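"""Conditional predictive ordinate (CPO) model comparison.

The CPO of record i is the leave-one-out predictive density
p(y_i | y_-i).  Its harmonic-mean Monte Carlo estimator from Nm posterior
draws is

    CPO_i = Nm / sum_j 1 / p(y_i | theta^j),

computed here via log-sum-exp of the negated per-draw log-likelihoods.
The summed log, LogCPO = sum_i ln CPO_i, is a pseudo log-marginal; larger
is better, and models are ranked by their difference from the best.

The likelihood entering CPO is the MBN probability of the stillbirth count
given litter size and the draw's parameters, conditional on the sampled
random effects (the Gaussian litter-size density is excluded by default:
the five candidate predictors differ only on the logit side, so they are
compared on the same response).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["CpoResult", "cpo_estimate", "compare_models"]


@dataclass
class CpoResult:
    """Per-record CPO estimates and their summed log."""

    per_record_cpo: np.ndarray
    log_cpo_sum: float
    n_draws: int

    @property
    def n_records(self) -> int:
        return len(self.per_record_cpo)


def cpo_estimate(loglik_matrix: np.ndarray) -> CpoResult:
    """Harmonic-mean CPO from a records x draws matrix of log p(y_i | theta^j)."""
    L = np.asarray(loglik_matrix, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("loglik_matrix must be records x draws with >= 2 draws")
    if np.isnan(L).any() or (L == np.inf).any():
        raise ValueError("log-likelihoods must be finite or -inf")
    nm = L.shape[1]
    neg_inf_rows = np.where(np.isneginf(L).any(axis=1))[0]
    with np.errstate(over="ignore"):
        log_cpo = np.log(nm) - logsumexp(-L, axis=1)
    if len(neg_inf_rows):
        warnings.warn(
            "records with a zero-likelihood draw have CPO 0: "
            f"{neg_inf_rows.tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
        log_cpo[neg_inf_rows] = -np.inf
    return CpoResult(
        per_record_cpo=np.exp(log_cpo),
        log_cpo_sum=float(log_cpo.sum()),
        n_draws=nm,
    )


def compare_models(results: dict[str, CpoResult]) -> pd.DataFrame:
    """Rank models by LogCPO; best gets difference 0, others <= 0."""
    if not results:
        raise ValueError("no models to compare")
    counts = {name: r.n_records for name, r in results.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"models were scored on different record sets: {counts}")
    table = pd.DataFrame(
        {
            "log_cpo": {name: r.log_cpo_sum for name, r in results.items()},
            "n_records": pd.Series(counts),
            "n_draws": {name: r.n_draws for name, r in results.items()},
        }
    ).sort_values("log_cpo", ascending=False)
    table["delta_log_cpo"] = table["log_cpo"] - table["log_cpo"].iloc[0]
    return table
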