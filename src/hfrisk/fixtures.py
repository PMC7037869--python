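"""Packaged case-study fixtures.

The Bahonar hospital case study (a 400-bed accident and trauma hospital
with 20 diagnostic/therapeutic departments, ED1-ED20) ships as two
fixtures transcribed exactly as printed, including their mixed cell
precision and known inconsistencies; values are never "corrected".

``bahonar_table2``
    The published total-relation (DEMATEL) matrix: 20x20 inner T cells,
    the R (row-sum) and R-C columns, and the C (column-sum) row. Inner
    cells are printed at 4 decimals in the ED20/ED19/ED18/ED17/ED8/ED1
    columns and 2 decimals elsewhere, so tests against inner cells need a
    loose tolerance; the R column is 4-decimal throughout.

``bahonar_table3``
    The published WSM table: normalized criterion weights (12 managerial
    criteria MR1-MR12 plus the DEMATEL-derived "Infection Risk" row at
    weight 0.12019) and already-weighted cells W'*V, plus the printed Ws
    totals row. Known anomalies, preserved as printed: the weights column
    sums to ~1.368 (MR10's 0.40865 is a suspected decimal-shift misprint
    of 0.04086), and the ED16 column's cells sum to 35.63 against a
    printed total of 36.05.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import FixtureError

__all__ = ["FixtureBundle", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("bahonar_table2", "bahonar_table3")

DEPARTMENTS = tuple(f"ED{i}" for i in range(1, 21))

DEPARTMENT_NAMES = {
    "ED1": "Neurology 1",
    "ED2": "Neurology 2",
    "ED3": "General Surgery",
    "ED4": "ICU1",
    "ED5": "ICU2",
    "ED6": "ICU3",
    "ED7": "CCU",
    "ED8": "Orthopedics (men)",
    "ED9": "Orthopedics (women)",
    "ED10": "Hematology/Oncology 1",
    "ED11": "Hematology/Oncology 2",
    "ED12": "Jaw and face surgery",
    "ED13": "Urology",
    "ED14": "Internal surgery",
    "ED15": "Emergency",
    "ED16": "Laboratory",
    "ED17": "CT scanning",
    "ED18": "Radiology",
    "ED19": "Pathology",
    "ED20": "Physiotherapy",
}


@dataclass(frozen=True)
class FixtureBundle:
    """Labeled tables of one packaged fixture, exactly as printed."""

    name: str
    tables: dict[str, pd.DataFrame | pd.Series]
    notes: tuple[str, ...] = field(default_factory=tuple)


def _read_packaged_csv(filename: str) -> pd.DataFrame:
    text = resources.files("hfrisk.data").joinpath(filename).read_text(encoding="utf-8")
    return pd.read_csv(_stdio.StringIO(text), index_col=0)


def _load_table2() -> FixtureBundle:
    raw = _read_packaged_csv("bahonar_table2.csv")
    C = raw.loc["C"].drop(["R", "R-C"]).astype(float)
    body = raw.drop(index="C")
    T = body.drop(columns=["R", "R-C"]).astype(float)
    R = body["R"].astype(float)
    RC = body["R-C"].astype(float)
    return FixtureBundle(
        name="bahonar_table2",
        tables={"T": T, "R": R, "C": C, "R-C": RC},
        notes=(
            "inner T cells carry mixed printed precision: 4 decimals in the "
            "ED20/ED19/ED18/ED17/ED8/ED1 columns, 2 decimals elsewhere",
            "printed R-C does not always equal printed R minus printed C "
            "because most C entries are truncated to 2 decimals",
            "department order as printed: ED20 down to ED1",
        ),
    )


def _load_table3() -> FixtureBundle:
    raw = _read_packaged_csv("bahonar_table3.csv")
    ws = raw.loc["Ws"].drop("weight").astype(float)
    body = raw.drop(index="Ws")
    weights = body["weight"].astype(float)
    cells = body.drop(columns="weight").astype(float)
    return FixtureBundle(
        name="bahonar_table3",
        tables={"weighted_cells": cells, "weights": weights, "Ws": ws},
        notes=(
            "cells are already-weighted products W' * V, not raw 0-100 values",
            "weights column sums to ~1.368; MR10's 0.40865 is a suspected "
            "decimal-shift misprint of 0.04086 — kept as printed",
            "the ED16 column's printed cells sum to 35.63 but the printed Ws "
            "total is 36.05 — kept as printed",
        ),
    )


def load_fixture(name: str) -> FixtureBundle:
    """Load a packaged fixture by name.

    Raises :class:`FixtureError` listing the available fixture names when
    the name is unknown.
    """
    if name == "bahonar_table2":
        return _load_table2()
    if name == "bahonar_table3":
        return _load_table3()
    raise FixtureError(
        f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURE_NAMES)}"
    )
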