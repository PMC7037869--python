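"""Expert-panel validation and rank-weighted aggregation.

A panel of experts scores pairwise influence between hospital departments on
an integer 0-4 scale (0 = no effect ... 4 = very high effect), and scores
managerial criteria for each department on a 0-100 scale. Experts carry
integer rank weights ("unbalanced expertise": a rank-3 expert's judgment
counts three times as much as a rank-1 expert's). Aggregation is the
rank-weighted arithmetic mean

    Z_ij = sum_k r_k * X_ij^k / sum_k r_k

which keeps the consensus on the original scale and reduces to the plain
mean when all ranks are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Expert",
    "InfluenceAssessment",
    "ConsensusMatrix",
    "validate_assessment",
    "aggregate_influence",
    "aggregate_decision_values",
]

INFLUENCE_SCALE = (0, 4)
VALUE_SCALE = (0.0, 100.0)

CLUSTERS = ("infection", "managerial")


@dataclass(frozen=True)
class Expert:
    """One panel member.

    Parameters
    ----------
    expert_id:
        Short unique identifier, e.g. ``"I1"``.
    cluster:
        ``"infection"`` (scores pairwise cross-infection influence) or
        ``"managerial"`` (scores elimination criteria).
    rank:
        Positive integer expertise weight; the case study uses 1-3.
    """

    expert_id: str
    cluster: str
    rank: int

    def __post_init__(self) -> None:
        if self.cluster not in CLUSTERS:
            raise ValidationError(
                f"expert {self.expert_id!r}: cluster must be one of {CLUSTERS}, "
                f"got {self.cluster!r}"
            )
        if not (isinstance(self.rank, (int, np.integer)) and self.rank >= 1):
            raise ValidationError(
                f"expert {self.expert_id!r}: rank must be a positive integer, "
                f"got {self.rank!r}"
            )


@dataclass(frozen=True)
class InfluenceAssessment:
    """One expert's pairwise influence matrix.

    ``matrix`` is a labeled square DataFrame; entry (i, j) is the influence
    of row department i on column department j, an integer in 0-4 with a
    zero diagonal.
    """

    expert_id: str
    matrix: pd.DataFrame


@dataclass(frozen=True)
class ConsensusMatrix:
    """Rank-weighted consensus direct-relation matrix Z."""

    matrix: pd.DataFrame
    aggregation_note: str = ""

    @property
    def department_ids(self) -> list[str]:
        return list(self.matrix.index)


def _check_panel(panel: Sequence[Expert]) -> dict[str, Expert]:
    if not panel:
        raise ValidationError("panel is empty")
    by_id: dict[str, Expert] = {}
    for e in panel:
        if e.expert_id in by_id:
            raise ValidationError(f"duplicate expert_id {e.expert_id!r} in panel")
        by_id[e.expert_id] = e
    return by_id


def validate_assessment(
    a: InfluenceAssessment, departments: Sequence[str]
) -> InfluenceAssessment:
    """Check one influence assessment against the structural invariants.

    The matrix must be square over exactly `departments`, integer-valued in
    {0..4}, with a zero diagonal. Returns the assessment unchanged on
    success; raises :class:`ValidationError` naming the offending cell
    otherwise.
    """
    m = a.matrix
    departments = list(departments)
    if len(departments) < 2:
        raise ValidationError("need at least 2 departments")
    if list(m.index) != departments or list(m.columns) != departments:
        raise ValidationError(
            f"assessment {a.expert_id!r}: matrix labels do not match the "
            f"department list ({len(m.index)}x{len(m.columns)} vs "
            f"{len(departments)} departments)"
        )
    values = m.to_numpy()
    if values.shape[0] != values.shape[1]:
        raise ValidationError(f"assessment {a.expert_id!r}: matrix is not square")
    lo, hi = INFLUENCE_SCALE
    for i, row_label in enumerate(m.index):
        for j, col_label in enumerate(m.columns):
            v = values[i, j]
            if not float(v).is_integer() or not (lo <= v <= hi):
                raise ValidationError(
                    f"assessment {a.expert_id!r}: entry ({row_label}, {col_label})"
                    f"={v} outside {lo}-{hi} integer scale"
                )
            if i == j and v != 0:
                raise ValidationError(
                    f"assessment {a.expert_id!r}: diagonal ({row_label}, "
                    f"{col_label}) must be 0, got {v}"
                )
    return a


def _rank_weights(
    ids: Iterable[str], by_id: dict[str, Expert]
) -> np.ndarray:
    ranks = []
    for expert_id in ids:
        if expert_id not in by_id:
            raise ValidationError(f"assessment from unknown expert {expert_id!r}")
        ranks.append(by_id[expert_id].rank)
    return np.asarray(ranks, dtype=float)


def aggregate_influence(
    assessments: Sequence[InfluenceAssessment], panel: Sequence[Expert]
) -> ConsensusMatrix:
    """Aggregate validated assessments into the consensus matrix Z.

    Each expert's matrix is multiplied by their rank and the rank-weighted
    mean is taken cell-wise (divisor = sum of ranks). Department order is
    taken from the first assessment; all others must match by label.
    """
    if not assessments:
        raise ValidationError("no assessments to aggregate")
    by_id = _check_panel(panel)
    departments = list(assessments[0].matrix.index)
    for a in assessments:
        validate_assessment(a, departments)
    ranks = _rank_weights((a.expert_id for a in assessments), by_id)
    stack = np.stack([a.matrix.to_numpy(dtype=float) for a in assessments])
    z = np.tensordot(ranks, stack, axes=1) / ranks.sum()
    note = (
        f"rank-weighted mean of {len(assessments)} assessments, "
        f"divisor sum(ranks)={ranks.sum():g}"
    )
    return ConsensusMatrix(
        matrix=pd.DataFrame(z, index=departments, columns=departments),
        aggregation_note=note,
    )


def aggregate_decision_values(
    tables: Sequence[pd.DataFrame], panel: Sequence[Expert]
) -> pd.DataFrame:
    """Rank-weighted mean of per-expert criteria x alternatives value tables.

    Tables must share identical labels (criteria rows, alternative columns)
    with values on the 0-100 scale; the first table's expert order defines
    nothing — aggregation is symmetric in the experts. Each table's position
    k corresponds to panel[k] if `tables` and `panel` align by order; to
    avoid ambiguity the tables must be passed in the same order as the
    panel sequence.
    """
    if not tables:
        raise ValidationError("no value tables to aggregate")
    by_id = _check_panel(panel)
    if len(tables) != len(panel):
        raise ValidationError(
            f"{len(tables)} tables but {len(panel)} experts; pass one table "
            "per expert in panel order"
        )
    ref = tables[0]
    lo, hi = VALUE_SCALE
    for k, t in enumerate(tables):
        if list(t.index) != list(ref.index) or list(t.columns) != list(ref.columns):
            raise ValidationError(f"table {k}: labels do not match the first table")
        vals = t.to_numpy(dtype=float)
        if np.any(vals < lo) or np.any(vals > hi):
            bad = np.argwhere((vals < lo) | (vals > hi))[0]
            raise ValidationError(
                f"table {k}: value {vals[tuple(bad)]} at "
                f"({t.index[bad[0]]}, {t.columns[bad[1]]}) outside {lo:g}-{hi:g}"
            )
    ranks = _rank_weights((e.expert_id for e in panel), by_id)
    stack = np.stack([t.to_numpy(dtype=float) for t in tables])
    out = np.tensordot(ranks, stack, axes=1) / ranks.sum()
    return pd.DataFrame(out, index=ref.index, columns=ref.columns)
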