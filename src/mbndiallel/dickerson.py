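"""Dickerson crossbreeding decomposition of the 9 cross effects.

Each diallel-cross effect b(k) is written as direct line (D), maternal (M)
and heterosis (H) contributions, e.g. b(ER) = 0.5 D_E + 0.5 D_R + M_R + H_ER
for a sow with an E sire and an R dam.  The 9x9 coefficient matrix is
singular: adding a constant to every D and subtracting it from every M
leaves all cross effects unchanged (rank 8, null vector D=+1, M=-1, H=0).
Only contrasts are data-identified — every heterosis effect and every
within-block difference D_i - D_j, M_i - M_j — so the solver returns the
minimum-norm least-squares solution together with its rank and residual,
and the summaries emphasize the estimable contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CROSSES
from .summaries import hpd_interval

__all__ = [
    "DICKERSON_MATRIX",
    "PARAM_NAMES",
    "DickersonParams",
    "dickerson_forward",
    "dickerson_solve",
    "heterosis_contrasts",
    "dickerson_chain",
]

PARAM_NAMES = ("D_E", "D_R", "D_T", "M_E", "M_R", "M_T", "H_ER", "H_ET", "H_RT")

#: Rows in cross order EE,ER,ET,RE,RR,RT,TE,TR,TT; columns in PARAM_NAMES order.
DICKERSON_MATRIX = np.array(
    [
        # D_E  D_R  D_T  M_E  M_R  M_T  H_ER H_ET H_RT
        [1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # EE
        [0.5, 0.5, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0],  # ER
        [0.5, 0.0, 0.5, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0],  # ET
        [0.5, 0.5, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0],  # RE
        [0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0],  # RR
        [0.0, 0.5, 0.5, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0],  # RT
        [0.5, 0.0, 0.5, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0],  # TE
        [0.0, 0.5, 0.5, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0],  # TR
        [0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0],  # TT
    ]
)


@dataclass
class DickersonParams:
    """Direct, maternal and heterosis effects for one trait scale."""

    D: np.ndarray  # (E, R, T)
    M: np.ndarray  # (E, R, T)
    H: np.ndarray  # (ER, ET, RT)
    trait: str = "t"
    rank: int | None = None
    residual: float | None = None

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.D, self.M, self.H])


def dickerson_forward(params: DickersonParams) -> np.ndarray:
    """Cross effects b (order EE..TT) implied by Dickerson parameters."""
    return DICKERSON_MATRIX @ params.as_vector()


def dickerson_solve(b: np.ndarray, trait: str = "t") -> DickersonParams:
    """Minimum-norm least-squares Dickerson parameters for cross effects b.

    The returned ``rank`` is the numerical rank of the system (8) and
    ``residual`` the norm of W x - b; both ~0 residual and invariant
    contrasts are guaranteed for any b in the row space.
    """
    b = np.asarray(b, dtype=float)
    if b.shape != (9,):
        raise ValueError("b must hold the 9 cross effects in order " + ",".join(CROSSES))
    x, _, rank, _ = np.linalg.lstsq(DICKERSON_MATRIX, b, rcond=None)
    resid = float(np.linalg.norm(DICKERSON_MATRIX @ x - b))
    return DickersonParams(D=x[:3], M=x[3:6], H=x[6:], trait=trait, rank=int(rank), residual=resid)


def heterosis_contrasts(b: np.ndarray) -> dict[str, float]:
    """Closed-form heterosis effects as contrasts of cross effects.

    H_ER = (b_ER + b_RE - b_EE - b_RR)/2 and the cyclic analogues; these are
    the estimable quantities, independent of any solver convention.
    """
    bb = dict(zip(CROSSES, np.asarray(b, dtype=float)))
    return {
        "H_ER": 0.5 * (bb["ER"] + bb["RE"] - bb["EE"] - bb["RR"]),
        "H_ET": 0.5 * (bb["ET"] + bb["TE"] - bb["EE"] - bb["TT"]),
        "H_RT": 0.5 * (bb["RT"] + bb["TR"] - bb["RR"] - bb["TT"]),
    }


def dickerson_chain(cross_draws: pd.DataFrame | np.ndarray, trait: str = "t") -> pd.DataFrame:
    """Posterior summaries of Dickerson parameters from cross-effect draws.

    Parameters
    ----------
    cross_draws
        Draws x 9 array (or DataFrame whose columns contain the cross codes
        in any order) of the cross-effect samples for one trait.

    Returns
    -------
    DataFrame indexed by parameter/contrast name with posterior mean, sd,
    95% HPD bounds and the posterior probability of a negative value.
    D and M are additionally reported as deviations from their own 3-level
    mean (``D_E_dev`` etc.), which are estimable.
    """
    if isinstance(cross_draws, pd.DataFrame):
        cols = []
        for c in CROSSES:
            match = [col for col in cross_draws.columns if col == c or col.endswith(c)]
            if not match:
                raise ValueError(f"cross level {c} missing from chain columns")
            cols.append(match[0])
        B = cross_draws[cols].to_numpy(dtype=float)
    else:
        B = np.asarray(cross_draws, dtype=float)
        if B.ndim != 2 or B.shape[1] != 9:
            raise ValueError("cross_draws must be draws x 9")
    # min-norm solve per draw: pinv is draw-independent
    W_pinv = np.linalg.pinv(DICKERSON_MATRIX)
    sols = B @ W_pinv.T  # draws x 9 in PARAM_NAMES order
    table = {name: sols[:, i] for i, name in enumerate(PARAM_NAMES)}
    for i, name in enumerate(("D_E_dev", "D_R_dev", "D_T_dev")):
        table[name] = sols[:, i] - sols[:, :3].mean(axis=1)
    for i, name in enumerate(("M_E_dev", "M_R_dev", "M_T_dev")):
        table[name] = sols[:, 3 + i] - sols[:, 3:6].mean(axis=1)
    rows = []
    for name, draws in table.items():
        lo, hi = hpd_interval(draws, 0.95)
        rows.append(
            {
                "parameter": name,
                "trait": trait,
                "mean": draws.mean(),
                "sd": draws.std(ddof=1) if len(draws) > 1 else 0.0,
                "hpd95_low": lo,
                "hpd95_high": hi,
                "prob_negative": float(np.mean(draws < 0.0)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
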