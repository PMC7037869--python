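"""DEMATEL: from a direct-relation matrix to cause/effect structure.

The Decision-Making Trial and Evaluation Laboratory technique converts a
matrix Z of pairwise direct influences into the *total*-relation matrix

    T = D (I - D)^{-1},   D = Z / S,   S = max_i sum_j Z_ij,

which accumulates direct plus all indirect influence paths (the geometric
series I + D + D^2 + ... converges whenever the spectral radius of D is
below one). Row sums R measure influence dispatched by each department,
column sums C influence received; R+C is prominence, R-C the net relation.
Departments with R-C > 0 form the cause group (net transmitters of
cross-infection), R-C < 0 the effect group (net receivers). The extremes of
R-C are flagged master dispatcher and master receiver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConvergenceError, ValidationError
from .panel import ConsensusMatrix

__all__ = [
    "NormalizedMatrix",
    "TotalRelationResult",
    "CauseEffectProfile",
    "normalize_direct_relation",
    "total_relation",
    "relation_scores",
    "classify_cause_effect",
    "run_dematel",
]

logger = logging.getLogger(__name__)

#: absolute tolerance for comparisons against zero (R-C sign, ties)
ZERO_TOL = 1e-9


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized direct-relation matrix D = Z / S with its scale constant S."""

    matrix: pd.DataFrame
    scale_constant: float


@dataclass(frozen=True)
class TotalRelationResult:
    """Total-relation matrix T and its marginal statistics."""

    T: pd.DataFrame
    R: pd.Series
    C: pd.Series
    prominence: pd.Series  # R + C
    relation: pd.Series  # R - C

    @property
    def department_ids(self) -> list[str]:
        return list(self.T.index)


@dataclass(frozen=True)
class CauseEffectProfile:
    """Sign-based grouping of departments plus the R-C extremes.

    ``group`` maps each department to "cause" (R-C > 0), "effect"
    (R-C < 0) or "neutral" (|R-C| <= tolerance). The department with the
    largest R-C is the master dispatcher, the smallest the master receiver;
    exact ties resolve to the first department in canonical order.
    """

    group: pd.Series
    master_dispatcher: str
    master_receiver: str

    def is_master_dispatcher(self, department: str) -> bool:
        return department == self.master_dispatcher

    def is_master_receiver(self, department: str) -> bool:
        return department == self.master_receiver


def _as_frame(Z: ConsensusMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(Z, ConsensusMatrix):
        return Z.matrix
    return Z


def normalize_direct_relation(
    Z: ConsensusMatrix | pd.DataFrame, *, include_columns: bool = False
) -> NormalizedMatrix:
    """Normalize Z by its largest row sum.

    With ``include_columns=True`` the scale constant is
    max(max row sum, max column sum), a common variant; the default follows
    the plain row-sum rule.
    """
    zf = _as_frame(Z)
    z = zf.to_numpy(dtype=float)
    if z.shape[0] != z.shape[1]:
        raise ValidationError("direct-relation matrix must be square")
    if np.any(z < 0):
        raise ValidationError("direct-relation matrix must be non-negative")
    s = z.sum(axis=1).max()
    if include_columns:
        s = max(s, z.sum(axis=0).max())
    if s <= 0:
        raise ValidationError(
            "direct-relation matrix is all-zero; normalization undefined"
        )
    return NormalizedMatrix(matrix=zf / s, scale_constant=float(s))


def total_relation(D: NormalizedMatrix | pd.DataFrame) -> TotalRelationResult:
    """Compute T = D (I - D)^{-1} and its marginals.

    Requires spectral radius of D strictly below 1 so that the influence
    series converges. Uses a dense solve of (I - D) T = D rather than an
    explicit inverse.
    """
    df = D.matrix if isinstance(D, NormalizedMatrix) else D
    d = df.to_numpy(dtype=float)
    n = d.shape[0]
    rho = np.max(np.abs(np.linalg.eigvals(d)))
    if rho >= 1 - ZERO_TOL:
        raise ConvergenceError(
            f"spectral radius of normalized matrix is {rho:.6f} >= 1; the "
            "total-relation series I + D + D^2 + ... does not converge"
        )
    t = scipy.linalg.solve(np.eye(n) - d, d)
    T = pd.DataFrame(t, index=df.index, columns=df.columns)
    R = T.sum(axis=1)
    C = pd.Series(T.sum(axis=0).to_numpy(), index=T.index)
    return TotalRelationResult(
        T=T, R=R, C=C, prominence=R + C, relation=R - C
    )


def relation_scores(res: TotalRelationResult) -> pd.DataFrame:
    """Per-department marginals as a table with columns R, C, R+C, R-C."""
    return pd.DataFrame(
        {
            "R": res.R,
            "C": res.C,
            "R+C": res.prominence,
            "R-C": res.relation,
        },
        index=res.department_ids,
    )


def classify_cause_effect(res: TotalRelationResult) -> CauseEffectProfile:
    """Partition departments into cause/effect groups and flag the extremes."""
    rel = res.relation
    group = pd.Series(
        np.where(rel > ZERO_TOL, "cause", np.where(rel < -ZERO_TOL, "effect", "neutral")),
        index=rel.index,
        name="group",
    )
    # ties within tolerance resolve to the first department in canonical order
    at_max = rel >= rel.max() - ZERO_TOL
    at_min = rel <= rel.min() + ZERO_TOL
    dispatcher = str(rel.index[at_max.to_numpy()][0])
    receiver = str(rel.index[at_min.to_numpy()][0])
    if at_max.sum() > 1:
        logger.warning("tie at max R-C; first department in order chosen: %s", dispatcher)
    if at_min.sum() > 1:
        logger.warning("tie at min R-C; first department in order chosen: %s", receiver)
    return CauseEffectProfile(
        group=group, master_dispatcher=dispatcher, master_receiver=receiver
    )


def run_dematel(
    Z: ConsensusMatrix | pd.DataFrame, *, include_columns: bool = False
) -> tuple[TotalRelationResult, CauseEffectProfile]:
    """Full DEMATEL chain: normalize, total relation, classification."""
    D = normalize_direct_relation(Z, include_columns=include_columns)
    res = total_relation(D)
    return res, classify_cause_effect(res)
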