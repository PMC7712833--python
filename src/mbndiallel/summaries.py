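"""Posterior summaries: mean, sd, shortest 95% HPD interval, derived correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["hpd_interval", "summarize_draws"]


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (empirical HPD)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty draws")
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def summarize_draws(draws: pd.DataFrame, prob: float = 0.95) -> pd.DataFrame:
    """Per-column posterior mean, sd and shortest HPD interval.

    Adds the derived genetic and permanent-environmental correlations
    r_a = sigma_alt / sqrt(sigma2_al * sigma2_at) (and r_p analogously)
    when the covariance columns are present, and reports cross effects as
    deviations from their 9-level mean (columns ``*_dev``) so crosses are
    compared on a common baseline.
    """
    if len(draws) == 0:
        raise ValueError("empty chain")
    work = draws.copy()
    for r, (v1, cv, v2) in {
        "r_a": ("sigma2_al", "sigma_alt", "sigma2_at"),
        "r_p": ("sigma2_pl", "sigma_plt", "sigma2_pt"),
    }.items():
        if {v1, cv, v2} <= set(work.columns):
            work[r] = work[cv] / np.sqrt(work[v1] * work[v2])
    for trait in ("t", "l"):
        cols = [c for c in draws.columns if c.startswith(f"b_{trait}_cross_")]
        if len(cols) == 9:
            mean9 = work[cols].mean(axis=1)
            for c in cols:
                work[c + "_dev"] = work[c] - mean9
    rows = []
    for col in work.columns:
        x = work[col].to_numpy(dtype=float)
        lo, hi = hpd_interval(x, prob)
        rows.append(
            {
                "parameter": col,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                f"hpd{int(prob * 100)}_low": lo,
                f"hpd{int(prob * 100)}_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
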