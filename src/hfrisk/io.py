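"""CSV/JSON/YAML readers and writers.

CSV dialect: UTF-8, comma separated, '.' decimal separator, labels in the
first row and first column. Matrix cell (i, j) holds the influence of row
department i on column department j. Unicode minus (U+2212) is normalized
to ASCII '-' on read so values copied from typeset tables parse cleanly.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import ValidationError
from .panel import Expert

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_panel_csv",
    "write_panel_csv",
    "read_weights_csv",
    "write_weights_csv",
    "load_config",
    "file_checksum",
]

_MINUS = "−"


def _read_text(path: str | Path) -> str:
    return Path(path).read_text(encoding="utf-8").replace(_MINUS, "-")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a labeled numeric matrix (first row/column are labels).

    Raises :class:`ValidationError` for ragged rows, duplicate labels,
    empty cells or non-numeric cells, naming the offending row/column.
    """
    text = _read_text(path)
    try:
        df = pd.read_csv(_stdio.StringIO(text), index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate row label {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate column label {dup!r}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for row in df.index:
        for col in df.columns:
            cell = df.at[row, col]
            if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
                raise ValidationError(f"{path}: empty cell at ({row}, {col})")
            try:
                out.at[row, col] = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at ({row}, {col})"
                ) from exc
    return out


def write_matrix_csv(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a labeled matrix in the dialect :func:`read_matrix_csv` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, encoding="utf-8")
    return path


def read_panel_csv(path: str | Path) -> list[Expert]:
    """Read an expert panel from a CSV with columns expert_id, cluster, rank."""
    df = pd.read_csv(_stdio.StringIO(_read_text(path)))
    required = {"expert_id", "cluster", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: panel file missing columns {sorted(missing)}")
    experts = [
        Expert(expert_id=str(r.expert_id), cluster=str(r.cluster), rank=int(r.rank))
        for r in df.itertuples()
    ]
    if len({e.expert_id for e in experts}) != len(experts):
        raise ValidationError(f"{path}: duplicate expert_id in panel file")
    return experts


def write_panel_csv(panel: Sequence[Expert], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "expert_id": [e.expert_id for e in panel],
            "cluster": [e.cluster for e in panel],
            "rank": [e.rank for e in panel],
        }
    ).to_csv(path, index=False, encoding="utf-8")
    return path


def read_weights_csv(path: str | Path) -> pd.Series:
    """Read criterion weights from a CSV with columns criterion_id, raw_weight."""
    df = pd.read_csv(_stdio.StringIO(_read_text(path)))
    required = {"criterion_id", "raw_weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: weights file missing columns {sorted(missing)}")
    s = pd.Series(
        df["raw_weight"].astype(float).to_numpy(),
        index=df["criterion_id"].astype(str),
        name="raw_weight",
    )
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate criterion_id {dup!r}")
    return s


def write_weights_csv(weights: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"criterion_id": weights.index, "raw_weight": weights.to_numpy()}
    ).to_csv(path, index=False, encoding="utf-8")
    return path


def load_config(path: str | Path) -> dict:
    """Load a run configuration from JSON or YAML (by file suffix)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for provenance records."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
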