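"""Schema and invariant validation for the pipeline's input tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .intensity import COST_CATEGORIES
from .species_traits import HABITAT_CLASSES

__all__ = ["Violation", "ValidationReport", "validate_tables", "TABLE_SCHEMAS"]

#: Required columns per known table kind.
TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "counts": ("site_id", "point_id", "visit", "year", "species_id", "count", "habitat_class"),
    "farms": ("farm_id", "sar_id", "production_type", "year", "utilised_area", *COST_CATEGORIES),
    "edges": ("unit_a", "unit_b"),
    "centroids": ("sar_id", "x_km", "y_km"),
    "clc_areas": ("site_id", "category", "area_km2"),
    "climate": ("sar_id", "year", "temp_c", "precip_mm"),
    "altitude": ("site_id", "altitude_m"),
    "sar_landuse": ("sar_id", "arable_km2", "grassland_km2"),
    "site_sar": ("site_id", "sar_id"),
}


@dataclass(frozen=True)
class Violation:
    table: str
    rule: str
    row: int | None = None          # 0-based data row, None for table-level issues

    def __str__(self) -> str:
        where = f" (row {self.row})" if self.row is not None else ""
        return f"{self.table}: {self.rule}{where}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, rule: str, row: int | None = None) -> None:
        self.violations.append(Violation(table, rule, row))

    def __str__(self) -> str:
        if self.ok:
            return "all tables valid"
        return "\n".join(str(v) for v in self.violations)


def _row_check(report, table, frame, mask, rule) -> None:
    for idx in frame.index[mask]:
        report.add(table, rule, row=int(idx))


def validate_tables(paths: dict[str, str | Path]) -> ValidationReport:
    """Validate every supplied input table; returns the collected violations.

    ``paths`` maps a table kind (a key of :data:`TABLE_SCHEMAS`) to a
    delimited-text file.  Schema problems are reported per table,
    value-level problems per row.  Unreadable files raise ``OSError``.
    """
    report = ValidationReport()
    for kind, path in paths.items():
        if kind not in TABLE_SCHEMAS:
            report.add(kind, f"unknown table kind {kind!r}")
            continue
        frame = pd.read_csv(path, sep=None, engine="python")
        missing = [c for c in TABLE_SCHEMAS[kind] if c not in frame.columns]
        if missing:
            report.add(kind, f"missing columns {missing}")
            continue
        if kind == "counts":
            _row_check(report, kind, frame, frame["count"] < 0, "negative count")
            _row_check(report, kind, frame,
                       ~frame["habitat_class"].isin(HABITAT_CLASSES), "unknown habitat class")
            _row_check(report, kind, frame, ~frame["visit"].isin((1, 2)), "visit not in {1,2}")
            _row_check(report, kind, frame,
                       ~frame["point_id"].between(1, 10), "point_id outside 1..10")
        elif kind == "farms":
            _row_check(report, kind, frame, frame["utilised_area"] <= 0, "non-positive area")
            for c in COST_CATEGORIES:
                _row_check(report, kind, frame, frame[c] < 0, f"negative cost {c}")
        elif kind == "edges":
            _row_check(report, kind, frame, frame["unit_a"] == frame["unit_b"], "self-edge")
        elif kind == "clc_areas":
            _row_check(report, kind, frame, frame["area_km2"] < 0, "negative area")
        elif kind == "sar_landuse":
            _row_check(report, kind, frame, frame["arable_km2"] < 0, "negative arable area")
            _row_check(report, kind, frame, frame["grassland_km2"] < 0, "negative grassland area")
    return report
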