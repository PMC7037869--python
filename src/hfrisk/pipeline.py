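"""Hybrid DEMATEL + WSM pipeline.

The four-stage decision algorithm for rearchitecting a healthcare
facility:

1. aggregate each expert cluster's judgments with rank weights;
2. run DEMATEL on the consensus influence matrix to quantify each
   department's net role in cross-infection (R-C);
3. map R-C onto a 0-100 infection-risk criterion;
4. append that criterion (default raw weight 100) to the managerial
   decision matrix, re-normalize all weights jointly, and rank the
   departments by weighted sum — the top of the ranking is proposed for
   elimination or reinforced hygiene policy.

Both cause departments (strong transmitters) and effect departments
(strong receivers) are risky, so the default risk mapping scores the
*magnitude* of R-C. The published case-study tables can be replayed via
``fixture="bahonar"``, which ingests the printed total-relation marginals
and the printed weighted WSM cells directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .dematel import (
    CauseEffectProfile,
    TotalRelationResult,
    classify_cause_effect,
    run_dematel,
)
from .errors import PipelineError, ValidationError
from .fixtures import load_fixture
from .panel import aggregate_decision_values, aggregate_influence
from .wsm import (
    CriterionSet,
    DecisionMatrix,
    WSMResult,
    from_weighted_cells,
    normalize_weights,
    rank_alternatives,
    weighted_scores,
)

__all__ = [
    "RiskScoreVector",
    "HybridRanking",
    "PipelineConfig",
    "dematel_to_risk_scores",
    "inject_risk_criterion",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

RISK_MODES = ("abs_minmax", "rank_based", "manual")

RISK_CRITERION_ID = "Infection Risk"


@dataclass(frozen=True)
class RiskScoreVector:
    """Per-department infection-risk scores on the 0-100 scale."""

    scores: pd.Series
    mapping_mode: str
    weight_raw: float = 100.0


@dataclass(frozen=True)
class HybridRanking:
    """Full pipeline output with provenance sufficient to re-run."""

    dematel_result: TotalRelationResult | None
    cause_effect: CauseEffectProfile
    risk: RiskScoreVector | None
    wsm_result: WSMResult
    shortlist: tuple[str, ...]
    provenance: dict


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration.

    Either ``fixture`` names a packaged case ("bahonar") or ``input_dir``
    points at a case directory containing ``panel.csv``,
    ``influence_<expert>.csv`` per infection expert, and
    ``weights_<expert>.csv`` / ``values_<expert>.csv`` per managerial
    expert (the layout the ``simulate`` command writes).
    """

    fixture: str | None = None
    input_dir: str | None = None
    risk_mode: str = "abs_minmax"
    risk_overrides: Mapping[str, float] | None = None
    risk_weight: float = 100.0
    top_k: int = 4
    output_dir: str | None = None
    include_columns: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.fixture is None) == (self.input_dir is None):
            raise ValidationError("exactly one of fixture/input_dir must be set")
        if self.risk_mode not in RISK_MODES:
            raise ValidationError(f"risk_mode must be one of {RISK_MODES}")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(cfg))


def dematel_to_risk_scores(
    res: TotalRelationResult,
    mode: str = "abs_minmax",
    overrides: Mapping[str, float] | None = None,
) -> RiskScoreVector:
    """Map the DEMATEL relation (R-C) onto a 0-100 risk criterion.

    abs_minmax (default): linear min-max rescaling of |R-C| — both strong
    causes and strong receivers score high. rank_based: departments ranked
    by |R-C|, scores evenly spaced on [0, 100]. manual: caller-provided
    scores returned verbatim (must cover every department).
    """
    deps = res.department_ids
    if mode == "manual":
        if overrides is None:
            raise ValidationError("manual risk mode requires override scores")
        missing = [d for d in deps if d not in overrides]
        if missing:
            raise ValidationError(f"manual risk scores missing for {missing}")
        s = pd.Series({d: float(overrides[d]) for d in deps}, name="risk")
        if (s < 0).any() or (s > 100).any():
            raise ValidationError("manual risk scores must lie in [0, 100]")
        return RiskScoreVector(scores=s, mapping_mode=mode)
    if mode not in RISK_MODES:
        raise ValidationError(f"unknown risk mode {mode!r}")
    mag = res.relation.abs()
    if mode == "abs_minmax":
        spread = mag.max() - mag.min()
        if spread <= 1e-12:
            logger.warning("degenerate |R-C| spread; assigning all risk scores 50")
            scores = pd.Series(50.0, index=mag.index, name="risk")
        else:
            scores = 100.0 * (mag - mag.min()) / spread
    else:  # rank_based
        order = np.argsort(mag.to_numpy(), kind="stable")
        n = len(order)
        scores = pd.Series(0.0, index=mag.index, name="risk")
        for pos, idx in enumerate(order):
            scores.iloc[idx] = 100.0 * pos / (n - 1) if n > 1 else 50.0
    return RiskScoreVector(scores=scores.rename("risk"), mapping_mode=mode)


def inject_risk_criterion(
    matrix: DecisionMatrix, weights: CriterionSet, risk: RiskScoreVector
) -> tuple[DecisionMatrix, CriterionSet]:
    """Append the risk criterion row and jointly re-normalize all weights."""
    missing = [a for a in matrix.alternative_ids if a not in risk.scores.index]
    if missing:
        raise ValidationError(f"risk scores missing for alternatives {missing}")
    row = risk.scores.reindex(matrix.alternative_ids)
    merged_values = pd.concat(
        [matrix.values, row.to_frame(RISK_CRITERION_ID).T]
    )
    merged = DecisionMatrix(values=merged_values)
    merged_weights = CriterionSet(
        criterion_ids=tuple(weights.criterion_ids) + (RISK_CRITERION_ID,),
        raw_weights=tuple(weights.raw_weights) + (float(risk.weight_raw),),
        source=weights.source,
    )
    return merged, normalize_weights(merged_weights)


# ---------------------------------------------------------------------------
# pipeline driver


def _stage(label: str):
    """Decorator-free stage wrapper: re-raise errors with the stage label."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {label!r}: {exc}") from exc
            return False

    return _Ctx()


def _load_case_dir(path: Path):
    panel = hio.read_panel_csv(path / "panel.csv")
    infection = [e for e in panel if e.cluster == "infection"]
    managerial = [e for e in panel if e.cluster == "managerial"]
    from .panel import InfluenceAssessment

    assessments = [
        InfluenceAssessment(e.expert_id, hio.read_matrix_csv(path / f"influence_{e.expert_id}.csv"))
        for e in infection
    ]
    weight_tables = [
        hio.read_weights_csv(path / f"weights_{e.expert_id}.csv") for e in managerial
    ]
    value_tables = [
        hio.read_matrix_csv(path / f"values_{e.expert_id}.csv") for e in managerial
    ]
    return panel, infection, managerial, assessments, weight_tables, value_tables


def _run_fixture_pipeline(cfg: PipelineConfig) -> HybridRanking:
    """Replay the published case study from the printed tables.

    The printed total-relation marginals stand in for stage 2 and the
    printed weighted cells (which already include the manually curated
    infection-risk row) for stages 3-4.
    """
    if cfg.fixture != "bahonar":
        raise ValidationError(f"unknown pipeline fixture {cfg.fixture!r}")
    t2 = load_fixture("bahonar_table2")
    t3 = load_fixture("bahonar_table3")
    R, C, RC = t2.tables["R"], t2.tables["C"], t2.tables["R-C"]
    res = TotalRelationResult(
        T=t2.tables["T"], R=R, C=pd.Series(C.to_numpy(), index=R.index),
        prominence=R + pd.Series(C.to_numpy(), index=R.index), relation=RC,
    )
    profile = classify_cause_effect(res)
    wsm_res = from_weighted_cells(t3.tables["weighted_cells"])
    shortlist = tuple(a for a, _ in rank_alternatives(wsm_res, cfg.top_k))
    risk_row = t3.tables["weighted_cells"].loc[RISK_CRITERION_ID]
    risk_weight = float(t3.tables["weights"][RISK_CRITERION_ID])
    risk = RiskScoreVector(
        scores=(risk_row / risk_weight).rename("risk"),
        mapping_mode="manual",
        weight_raw=100.0,
    )
    provenance = {
        "config": dataclasses.asdict(cfg),
        "inputs": {"fixture": "bahonar", "notes": list(t2.notes) + list(t3.notes)},
    }
    return HybridRanking(
        dematel_result=res,
        cause_effect=profile,
        risk=risk,
        wsm_result=wsm_res,
        shortlist=shortlist,
        provenance=provenance,
    )


def _run_file_pipeline(cfg: PipelineConfig) -> HybridRanking:
    path = Path(cfg.input_dir)
    with _stage("panel_aggregation"):
        panel, infection, managerial, assessments, weight_tables, value_tables = (
            _load_case_dir(path)
        )
        Z = aggregate_influence(assessments, infection)
        values = aggregate_decision_values(value_tables, managerial)
        weight_frames = [w.to_frame().T for w in weight_tables]
        raw_weights = aggregate_decision_values(weight_frames, managerial).iloc[0]
    with _stage("dematel"):
        res, profile = run_dematel(Z, include_columns=cfg.include_columns)
    with _stage("risk_mapping"):
        risk = dematel_to_risk_scores(res, cfg.risk_mode, cfg.risk_overrides)
        risk = RiskScoreVector(
            scores=risk.scores, mapping_mode=risk.mapping_mode,
            weight_raw=float(cfg.risk_weight),
        )
    with _stage("wsm"):
        matrix = DecisionMatrix(values=values)
        weights = CriterionSet(
            criterion_ids=tuple(values.index),
            raw_weights=tuple(float(raw_weights[c]) for c in values.index),
            source="managerial_panel",
        )
        merged_matrix, merged_weights = inject_risk_criterion(matrix, weights, risk)
        wsm_res = weighted_scores(merged_weights, merged_matrix)
    with _stage("ranking"):
        shortlist = tuple(a for a, _ in rank_alternatives(wsm_res, cfg.top_k))
    checksums = {
        p.name: hio.file_checksum(p) for p in sorted(path.glob("*.csv"))
    }
    provenance = {
        "config": dataclasses.asdict(cfg),
        "inputs": {"input_dir": str(path), "checksums": checksums},
    }
    return HybridRanking(
        dematel_result=res,
        cause_effect=profile,
        risk=risk,
        wsm_result=wsm_res,
        shortlist=shortlist,
        provenance=provenance,
    )


def run_pipeline(config: PipelineConfig | Mapping) -> HybridRanking:
    """Execute the full hybrid pipeline; deterministic given the config.

    Writes per-stage artifacts (T matrix CSV, marginals report JSON, WSM
    table CSV, ranking JSON, provenance snapshot) under
    ``config.output_dir`` when set.
    """
    cfg = (
        config
        if isinstance(config, PipelineConfig)
        else PipelineConfig.from_mapping(config)
    )
    ranking = (
        _run_fixture_pipeline(cfg) if cfg.fixture else _run_file_pipeline(cfg)
    )
    if cfg.output_dir:
        _write_artifacts(ranking, Path(cfg.output_dir))
    return ranking


def report_dict(ranking: HybridRanking) -> dict:
    """JSON-serializable report of a pipeline run."""
    res = ranking.dematel_result
    profile = ranking.cause_effect
    per_department = {}
    for d in res.department_ids:
        per_department[d] = {
            "R": float(res.R[d]),
            "C": float(res.C[d]),
            "prominence": float(res.prominence[d]),
            "relation": float(res.relation[d]),
            "group": str(profile.group[d]),
            "is_master_dispatcher": profile.is_master_dispatcher(d),
            "is_master_receiver": profile.is_master_receiver(d),
        }
    return {
        "departments": per_department,
        "master_dispatcher": profile.master_dispatcher,
        "master_receiver": profile.master_receiver,
        "risk_scores": (
            {k: float(v) for k, v in ranking.risk.scores.items()}
            if ranking.risk is not None
            else None
        ),
        "weighted_sums": {
            k: round(float(v), 2) for k, v in ranking.wsm_result.totals.items()
        },
        "ranking": list(ranking.wsm_result.ranking),
        "shortlist": list(ranking.shortlist),
        "provenance": ranking.provenance,
    }


def _write_artifacts(ranking: HybridRanking, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    hio.write_matrix_csv(ranking.dematel_result.T, out / "total_relation.csv")
    hio.write_matrix_csv(ranking.wsm_result.weighted_cells, out / "wsm_weighted_cells.csv")
    (out / "report.json").write_text(
        json.dumps(report_dict(ranking), indent=2, sort_keys=True), encoding="utf-8"
    )
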