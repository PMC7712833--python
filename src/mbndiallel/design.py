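"""Design matrices and the five linear predictors.

Litter size t follows a Gaussian mixed model

    t = X b_t + Z u_t + Z p_t + e_t,

and the logit of the MBN location parameter phi follows one of five
predictors sharing the same X and Z:

    I    X b_l + Z u_l + Z p_l
    II   ...  + lambda1 * d
    III  ...  + lambda1 * d + lambda2 * d^2
    IV   ...  + lambda1[k] * d              (k = the record's cross)
    V    ...  + lambda1[k] * d + lambda2[k] * d^2

with d_i = t_i - t_bar the deviation of the observed litter size from the
average litter size.  The recursion is phenotypic: the observed integer
t_i enters d_i, not its model prediction.

Identifiability: the predictors carry no global intercept; all 9 cross
levels are kept (so cross effects absorb the mean and are directly
comparable) while the first parity and first year-season level are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CROSSES, FarrowingRecord
from .pedigree import Pedigree

__all__ = ["ModelSpec", "LevelMaps", "EffectsBlock", "build_designs", "logit_phi", "linear_predictor_t"]

MODEL_IDS = ("I", "II", "III", "IV", "V")


@dataclass
class ModelSpec:
    """Which predictor to use for logit phi, and its recursion coefficients."""

    model_id: str = "II"
    t_bar: float | None = None
    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda1_by_cross: np.ndarray | None = None
    lambda2_by_cross: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}, got {self.model_id!r}")
        if self.model_id in ("IV", "V") and self.lambda1_by_cross is None:
            self.lambda1_by_cross = np.zeros(9)
        if self.model_id == "V" and self.lambda2_by_cross is None:
            self.lambda2_by_cross = np.zeros(9)
        for name in ("lambda1_by_cross", "lambda2_by_cross"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (9,):
                    raise ValueError(f"{name} must have 9 entries (one per cross)")
                setattr(self, name, v)

    def recursion_term(self, d: np.ndarray, cross_idx: np.ndarray) -> np.ndarray:
        """lambda-part of logit phi for deviations d, per record cross index."""
        d = np.asarray(d, dtype=float)
        if self.model_id == "I":
            return np.zeros_like(d)
        if self.model_id == "II":
            return self.lambda1 * d
        if self.model_id == "III":
            return self.lambda1 * d + self.lambda2 * d * d
        l1 = self.lambda1_by_cross[cross_idx]
        if self.model_id == "IV":
            return l1 * d
        return l1 * d + self.lambda2_by_cross[cross_idx] * d * d

    @property
    def n_lambda1(self) -> int:
        return {"I": 0, "II": 1, "III": 1, "IV": 9, "V": 9}[self.model_id]

    @property
    def n_lambda2(self) -> int:
        return {"I": 0, "II": 0, "III": 1, "IV": 0, "V": 9}[self.model_id]


@dataclass
class LevelMaps:
    """Frozen factor-level conventions behind a built design."""

    cross_levels: tuple[str, ...]
    parity_levels: tuple[int, ...]       # first entry absorbed (no column)
    ys_levels: tuple[str, ...]           # first entry absorbed (no column)
    sow_ids: tuple[str, ...]
    ped_index: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def b_names(self) -> list[str]:
        return (
            [f"cross_{c}" for c in self.cross_levels]
            + [f"parity_{p}" for p in self.parity_levels[1:]]
            + [f"ys_{y}" for y in self.ys_levels[1:]]
        )

    @property
    def n_b(self) -> int:
        return len(self.cross_levels) + len(self.parity_levels) - 1 + len(self.ys_levels) - 1

    def b_columns(self, rec: FarrowingRecord) -> list[int]:
        """Columns of X that are 1 for this record."""
        cols = [self.cross_levels.index(rec.cross)]
        nc = len(self.cross_levels)
        if rec.parity != self.parity_levels[0]:
            cols.append(nc + self.parity_levels.index(rec.parity) - 1)
        npar = len(self.parity_levels) - 1
        if rec.year_season != self.ys_levels[0]:
            cols.append(nc + npar + self.ys_levels.index(rec.year_season) - 1)
        return cols


@dataclass
class EffectsBlock:
    """Location effects on one trait scale (t or l)."""

    b: np.ndarray          # systematic effects, X columns
    u: np.ndarray          # additive genetic values, pedigree order
    p: np.ndarray          # permanent environmental values, sow order
    levels: LevelMaps

    @classmethod
    def zeros(cls, levels: LevelMaps) -> "EffectsBlock":
        return cls(
            b=np.zeros(levels.n_b),
            u=np.zeros(len(levels.ped_index)),
            p=np.zeros(len(levels.sow_ids)),
            levels=levels,
        )

    def systematic(self, rec: FarrowingRecord) -> float:
        return float(sum(self.b[c] for c in self.levels.b_columns(rec)))

    def predictor(self, rec: FarrowingRecord) -> float:
        """X b + Z u + Z p for one record."""
        u = self.u[self.levels.ped_index[rec.sow_id]]
        p = self.p[self.levels.sow_ids.index(rec.sow_id)]
        return self.systematic(rec) + float(u) + float(p)


def build_designs(
    records: list[FarrowingRecord], pedigree: Pedigree
) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix, LevelMaps]:
    """Incidence matrices (X, Z_u, Z_p) and the frozen level maps.

    X maps records to retained systematic-effect columns, Z_u to the sow's
    slot in the pedigree, Z_p to the sow's permanent-environment slot.
    """
    if not records:
        raise ValueError("no records")
    ped_index = pedigree.index
    for rec in records:
        if rec.sow_id not in ped_index:
            raise ValueError(f"sow {rec.sow_id!r} has records but is absent from the pedigree")
    levels = LevelMaps(
        cross_levels=CROSSES,
        parity_levels=tuple(sorted({r.parity for r in records})),
        ys_levels=tuple(sorted({r.year_season for r in records})),
        sow_ids=tuple(dict.fromkeys(r.sow_id for r in records)),
        ped_index=ped_index,
    )
    n = len(records)
    sow_pos = {s: i for i, s in enumerate(levels.sow_ids)}
    xr, xc = [], []
    for i, rec in enumerate(records):
        for c in levels.b_columns(rec):
            xr.append(i)
            xc.append(c)
    X = sp.csr_matrix((np.ones(len(xr)), (xr, xc)), shape=(n, levels.n_b))
    Z_u = sp.csr_matrix(
        (np.ones(n), (np.arange(n), [ped_index[r.sow_id] for r in records])),
        shape=(n, len(pedigree)),
    )
    Z_p = sp.csr_matrix(
        (np.ones(n), (np.arange(n), [sow_pos[r.sow_id] for r in records])),
        shape=(n, len(levels.sow_ids)),
    )
    return X, Z_u, Z_p, levels


def logit_phi(spec: ModelSpec, effects: EffectsBlock, rec: FarrowingRecord) -> float:
    """Predictor of logit phi_i for one record under the given model."""
    k = effects.levels.cross_levels.index(rec.cross)
    if spec.model_id != "I" and spec.t_bar is None:
        raise ValueError("spec.t_bar must be set before evaluating a recursive model")
    d = np.array([rec.tnb - (spec.t_bar or 0.0)])
    return effects.predictor(rec) + float(spec.recursion_term(d, np.array([k]))[0])


def linear_predictor_t(effects: EffectsBlock, rec: FarrowingRecord) -> float:
    """Conditional mean of litter size t_i (residual variance lives in the sampler)."""
    return effects.predictor(rec)
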