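"""Synthetic expert panels and assessment data.

Emulates the structure the pipeline assumes — a two-cluster panel
(infection-control and managerial experts) with integer rank weights in
{1, 2, 3}, pairwise influence matrices on the 0-4 scale over 20
departments, and 12 managerial criteria weighted and scored on 0-100 —
so every stage is testable without external data. Defaults mirror the
case-study dimensions (7 experts per cluster, 20 departments, 12
criteria). Distributions are uniform/categorical: the field data only
fixes the scales, not the shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import Expert, InfluenceAssessment

__all__ = ["SynthConfig", "SynthCase", "generate_case", "generate_planted_structure"]


@dataclass(frozen=True)
class SynthConfig:
    """Shape and distribution parameters of a synthetic case.

    rank_distribution gives the probabilities of drawing expert ranks
    1, 2, 3; influence_sparsity is the probability that an off-diagonal
    pairwise influence is exactly 0.
    """

    n_departments: int = 20
    n_infection_experts: int = 7
    n_managerial_experts: int = 7
    rank_distribution: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_criteria: int = 12
    influence_sparsity: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_departments < 2:
            raise ValidationError("n_departments must be >= 2")
        if self.n_infection_experts < 1 or self.n_managerial_experts < 1:
            raise ValidationError("need at least one expert per cluster")
        if self.n_criteria < 1:
            raise ValidationError("n_criteria must be >= 1")
        p = np.asarray(self.rank_distribution, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValidationError("rank_distribution must be 3 probabilities summing to 1")
        if not 0.0 <= self.influence_sparsity <= 1.0:
            raise ValidationError("influence_sparsity must lie in [0, 1]")

    @property
    def department_ids(self) -> list[str]:
        return [f"ED{i}" for i in range(1, self.n_departments + 1)]

    @property
    def criterion_ids(self) -> list[str]:
        return [f"MR{i}" for i in range(1, self.n_criteria + 1)]


@dataclass(frozen=True)
class SynthCase:
    """One generated case: panel, assessments, and managerial tables."""

    panel: list[Expert]
    assessments: list[InfluenceAssessment]
    weight_tables: list[pd.Series]  # one 0-100 weight vector per managerial expert
    value_tables: list[pd.DataFrame]  # criteria x departments, per managerial expert


def _draw_ranks(rng: np.random.Generator, n: int, p: Sequence[float]) -> np.ndarray:
    return rng.choice([1, 2, 3], size=n, p=np.asarray(p, dtype=float))


def _influence_matrix(
    rng: np.random.Generator, departments: Sequence[str], sparsity: float
) -> pd.DataFrame:
    n = len(departments)
    m = rng.integers(1, 5, size=(n, n))
    zero_mask = rng.random((n, n)) < sparsity
    m = np.where(zero_mask, 0, m)
    np.fill_diagonal(m, 0)
    return pd.DataFrame(m, index=list(departments), columns=list(departments))


def generate_case(cfg: SynthConfig) -> SynthCase:
    """Generate a full synthetic case, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    deps = cfg.department_ids
    crits = cfg.criterion_ids

    inf_ranks = _draw_ranks(rng, cfg.n_infection_experts, cfg.rank_distribution)
    man_ranks = _draw_ranks(rng, cfg.n_managerial_experts, cfg.rank_distribution)
    panel = [
        Expert(f"I{k + 1}", "infection", int(r)) for k, r in enumerate(inf_ranks)
    ] + [
        Expert(f"M{k + 1}", "managerial", int(r)) for k, r in enumerate(man_ranks)
    ]

    assessments = [
        InfluenceAssessment(
            expert_id=f"I{k + 1}",
            matrix=_influence_matrix(rng, deps, cfg.influence_sparsity),
        )
        for k in range(cfg.n_infection_experts)
    ]

    weight_tables = [
        pd.Series(rng.uniform(0, 100, size=len(crits)), index=crits, name="raw_weight")
        for _ in range(cfg.n_managerial_experts)
    ]
    value_tables = [
        pd.DataFrame(
            rng.uniform(0, 100, size=(len(crits), len(deps))),
            index=crits,
            columns=deps,
        )
        for _ in range(cfg.n_managerial_experts)
    ]
    return SynthCase(
        panel=panel,
        assessments=assessments,
        weight_tables=weight_tables,
        value_tables=value_tables,
    )


def generate_planted_structure(
    cfg: SynthConfig,
    dispatcher_ids: Sequence[str],
    receiver_ids: Sequence[str],
    *,
    noise_level: float = 0.0,
) -> list[InfluenceAssessment]:
    """Generate assessments with planted net transmitters and receivers.

    Planted dispatchers rate high (3-4) on every outgoing influence and
    receive nothing; planted receivers receive high (3-4) from everyone and
    dispatch nothing. Remaining off-diagonal entries are 0 except with
    probability ``noise_level`` they are a low rating in {1, 2}. With zero
    noise the planted departments are provably the extremes of R-C, which
    makes recovery an exact oracle for the cause/effect classification.
    """
    deps = cfg.department_ids
    d_set, r_set = set(dispatcher_ids), set(receiver_ids)
    if d_set & r_set:
        raise ValidationError(
            f"dispatcher and receiver sets overlap: {sorted(d_set & r_set)}"
        )
    unknown = (d_set | r_set) - set(deps)
    if unknown:
        raise ValidationError(f"planted ids not in department list: {sorted(unknown)}")
    if not 0.0 <= noise_level <= 1.0:
        raise ValidationError("noise_level must lie in [0, 1]")

    rng = np.random.default_rng(cfg.seed)
    n = len(deps)
    out: list[InfluenceAssessment] = []
    for k in range(cfg.n_infection_experts):
        m = np.where(rng.random((n, n)) < noise_level, rng.integers(1, 3, size=(n, n)), 0)
        for i, di in enumerate(deps):
            for j, dj in enumerate(deps):
                if i == j:
                    continue
                if di in d_set or dj in r_set:
                    m[i, j] = rng.integers(3, 5)
                if dj in d_set or di in r_set:
                    m[i, j] = 0
        # dispatcher -> receiver is high under both rules; receiver -> dispatcher low
        for i, di in enumerate(deps):
            for j, dj in enumerate(deps):
                if di in d_set and dj in r_set:
                    m[i, j] = rng.integers(3, 5)
        np.fill_diagonal(m, 0)
        out.append(
            InfluenceAssessment(
                expert_id=f"I{k + 1}",
                matrix=pd.DataFrame(m, index=deps, columns=deps),
            )
        )
    return out
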