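"""Packaged example tables: a five-level resistance scheme for a 13-factor
alpine landscape, and class-area tables for one present-day baseline and
four future climate scenarios."""

from __future__ import annotations

from importlib import resources
from typing import Dict

import pandas as pd

from ..suitability import AreaTable

SCENARIO_COLUMNS = (
    "present_2020",
    "ssp245_2030",
    "ssp585_2030",
    "ssp245_2050",
    "ssp585_2050",
)


def example_resistance_scheme_path() -> str:
    return str(resources.files(__name__) / "example_resistance_scheme.csv")


def example_area_table_path() -> str:
    return str(resources.files(__name__) / "example_area_table.csv")


def load_example_area_tables() -> Dict[str, AreaTable]:
    """One AreaTable per scenario column of the packaged table."""
    df = pd.read_csv(example_area_table_path())
    out: Dict[str, AreaTable] = {}
    for col in SCENARIO_COLUMNS:
        areas = {int(row["class"]): float(row[col]) for _, row in df.iterrows()}
        areas.setdefault(0, 0.0)
        out[col] = AreaTable(areas, scenario=col)
    return out
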