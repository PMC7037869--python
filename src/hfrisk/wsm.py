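"""Weighted sum model over elimination criteria.

Alternatives (departments) are scored on each criterion from 0 to 100,
where 100 is the strongest case for elimination. Raw criterion weights
(0-100) are normalized to sum to one, each value is multiplied by its
criterion's normalized weight, and the per-alternative column sums give the
weighted score WS. Departments are ranked by descending WS; the top of the
ranking is proposed for elimination or reinforced hygiene policy.

All criteria point the same way ("elimination pressure"); there is no
benefit/cost direction flipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CriterionSet",
    "DecisionMatrix",
    "WSMResult",
    "normalize_weights",
    "weighted_scores",
    "rank_alternatives",
]

logger = logging.getLogger(__name__)

WEIGHT_SOURCES = ("managerial_panel", "dematel_derived", "manual")


@dataclass(frozen=True)
class CriterionSet:
    """Ordered criteria with raw (0-100) and normalized weights.

    ``normalized_weights`` is ``None`` until :func:`normalize_weights` has
    been applied.
    """

    criterion_ids: tuple[str, ...]
    raw_weights: tuple[float, ...]
    normalized_weights: tuple[float, ...] | None = None
    source: str = "manual"

    def __post_init__(self) -> None:
        if len(self.criterion_ids) != len(self.raw_weights):
            raise ValidationError("criterion_ids and raw_weights differ in length")
        if len(set(self.criterion_ids)) != len(self.criterion_ids):
            raise ValidationError("duplicate criterion ids")
        if any(w < 0 for w in self.raw_weights):
            raise ValidationError("raw weights must be non-negative")
        if self.source not in WEIGHT_SOURCES:
            raise ValidationError(f"source must be one of {WEIGHT_SOURCES}")


@dataclass(frozen=True)
class DecisionMatrix:
    """Criteria x alternatives table of 0-100 values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v < 0) or np.any(v > 100):
            raise ValidationError("decision-matrix values must lie in [0, 100]")

    @property
    def criterion_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def alternative_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class WSMResult:
    """Weighted cells, per-alternative totals, and the descending ranking."""

    weighted_cells: pd.DataFrame
    totals: pd.Series
    ranking: tuple[str, ...]


def normalize_weights(raw: CriterionSet) -> CriterionSet:
    """Normalize raw weights to proportions summing to one (W' = W / sum W)."""
    total = float(sum(raw.raw_weights))
    if total <= 0:
        raise ValidationError("all criterion weights are zero; cannot normalize")
    norm = tuple(w / total for w in raw.raw_weights)
    return CriterionSet(
        criterion_ids=raw.criterion_ids,
        raw_weights=raw.raw_weights,
        normalized_weights=norm,
        source=raw.source,
    )


def weighted_scores(weights: CriterionSet, values: DecisionMatrix) -> WSMResult:
    """Multiply each criterion row by its normalized weight and sum columns.

    The ranking sorts alternatives by descending total; exact ties keep the
    canonical (input) alternative order via a stable sort.
    """
    if weights.normalized_weights is None:
        raise ValidationError("weights are not normalized; call normalize_weights")
    if list(weights.criterion_ids) != values.criterion_ids:
        raise ValidationError(
            "criterion ids of the weight set and the decision matrix differ"
        )
    w = np.asarray(weights.normalized_weights, dtype=float)
    cells = values.values.mul(w, axis=0)
    totals = cells.sum(axis=0)
    ranking = _stable_descending(totals)
    return WSMResult(weighted_cells=cells, totals=totals, ranking=ranking)


def from_weighted_cells(cells: pd.DataFrame) -> WSMResult:
    """Build a result from already-weighted cells (W' * V products).

    Used for ingesting externally computed WSM tables whose cells are
    already weight-scaled; totals are recomputed as column sums.
    """
    totals = cells.sum(axis=0)
    return WSMResult(
        weighted_cells=cells, totals=totals, ranking=_stable_descending(totals)
    )


def _stable_descending(totals: pd.Series) -> tuple[str, ...]:
    order = np.argsort(-totals.to_numpy(), kind="stable")
    ranked = tuple(str(totals.index[i]) for i in order)
    vals = totals.to_numpy()
    if len(np.unique(vals)) < len(vals):
        logger.info("ties in weighted sums; stable canonical order applied")
    return ranked


def rank_alternatives(res: WSMResult, top_k: int) -> list[tuple[str, float]]:
    """Return the top_k alternatives by descending weighted sum with scores."""
    if top_k < 1 or top_k > len(res.ranking):
        raise ValidationError(
            f"top_k must be in 1..{len(res.ranking)}, got {top_k}"
        )
    return [(a, float(res.totals[a])) for a in res.ranking[:top_k]]
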