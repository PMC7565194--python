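"""Phenotype gating and population statistics on cell tables.

Phenotypes are conjunctions of marker positivity signs (e.g. Kupffer cell =
IBA1+ AND CLEC4F+, monocyte-derived macrophage = IBA1+ AND CLEC4F-).
Rules are applied in priority order and the first match wins, so the
assignment is always a partition: every cell gets exactly one label, with
"other" as the fall-through.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, PanelConfigError
from .io import GatingRule, cell_table_markers

__all__ = [
    "UNASSIGNED_LABEL",
    "PopulationFraction",
    "apply_gates",
    "proliferation_fraction",
    "population_summary",
    "stained_area_stats",
    "intensity_scatter",
    "mask_and",
    "mask_and_not",
]

UNASSIGNED_LABEL = "other"


def apply_gates(
    table: pd.DataFrame, rules: Sequence[GatingRule]
) -> pd.DataFrame:
    """Assign each cell the first matching rule's phenotype (by priority).

    Returns a copy with the ``phenotype`` column filled; unmatched cells get
    ``"other"``.
    """
    for rule in rules:
        for marker, _ in rule.terms:
            if f"pos_{marker}" not in table.columns:
                raise PanelConfigError(
                    f"gating rule {rule.phenotype!r} references marker "
                    f"{marker!r} not measured in the table"
                )
    out = table.copy()
    labels = np.full(len(out), UNASSIGNED_LABEL, dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for rule in sorted(rules, key=lambda r: r.priority):
        match = np.ones(len(out), dtype=bool)
        for marker, sign in rule.terms:
            pos = out[f"pos_{marker}"].to_numpy(dtype=bool)
            match &= pos if sign == "+" else ~pos
        take = match & unassigned
        labels[take] = rule.phenotype
        unassigned &= ~take
    out["phenotype"] = labels
    return out


@dataclass
class PopulationFraction:
    """A fraction with its counts; undefined (empty population) is NaN with
    ``n_total == 0`` rather than an exception, so batch runs keep going."""

    fraction: float
    n_positive: int
    n_total: int

    @property
    def defined(self) -> bool:
        return self.n_total > 0


_CONDITION_RE = re.compile(r"^(?P<marker>\w+)(?P<sign>[+-])$")


def _population_mask(table: pd.DataFrame, population: str) -> np.ndarray:
    """Cells in a population given either a phenotype label or a marker
    condition like ``"IBA1+"`` / ``"CK19-"``."""
    m = _CONDITION_RE.match(population)
    if m and f"pos_{m.group('marker')}" in table.columns:
        pos = table[f"pos_{m.group('marker')}"].to_numpy(dtype=bool)
        return pos if m.group("sign") == "+" else ~pos
    if "phenotype" not in table.columns:
        raise InputError("table has no phenotype column; run apply_gates first")
    return (table["phenotype"] == population).to_numpy()


def proliferation_fraction(
    table: pd.DataFrame,
    population: str,
    proliferation_marker: str = "PCNA",
) -> PopulationFraction:
    """Fraction of a population positive for the proliferation marker."""
    col = f"pos_{proliferation_marker}"
    if col not in table.columns:
        raise ParameterError(
            f"proliferation marker {proliferation_marker!r} not in table"
        )
    sel = _population_mask(table, population)
    n_total = int(sel.sum())
    if n_total == 0:
        return PopulationFraction(float("nan"), 0, 0)
    n_pos = int(table.loc[sel, col].to_numpy(dtype=bool).sum())
    return PopulationFraction(n_pos / n_total, n_pos, n_total)


def population_summary(
    table: pd.DataFrame,
    proliferation_marker: str | None = "PCNA",
) -> pd.DataFrame:
    """One row per phenotype: count, fraction of all cells, proliferating
    fraction, and mean marker intensities."""
    if "phenotype" not in table.columns:
        raise InputError("table has no phenotype column; run apply_gates first")
    markers = cell_table_markers(table)
    rows = []
    n_all = len(table)
    for pheno, group in table.groupby("phenotype", sort=True):
        row: dict[str, object] = {
            "phenotype": pheno,
            "n_cells": len(group),
            "fraction_of_all": len(group) / n_all if n_all else float("nan"),
        }
        if proliferation_marker and f"pos_{proliferation_marker}" in table.columns:
            frac = proliferation_fraction(table, str(pheno), proliferation_marker)
            row[f"{proliferation_marker.lower()}_positive_fraction"] = frac.fraction
        for m in markers:
            row[f"mean_{m}"] = float(group[f"mean_{m}"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def mask_and(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Co-staining mask A AND B (e.g. IBA1+CLEC4F+ area)."""
    return np.asarray(a, bool) & np.asarray(b, bool)


def mask_and_not(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mask A AND NOT B (e.g. IBA1+CLEC4F- area)."""
    return np.asarray(a, bool) & ~np.asarray(b, bool)


def stained_area_stats(
    masks: Mapping[str, np.ndarray],
    tissue_mask: np.ndarray,
) -> pd.DataFrame:
    """Stained area per mask within the tissue, as pixels and tissue
    fraction, plus all pairwise area ratios.

    Compound populations (A AND B, A AND NOT B) are built with
    :func:`mask_and` / :func:`mask_and_not` before calling. Zero-denominator
    ratios are reported as NaN.
    """
    tissue = np.asarray(tissue_mask, bool)
    tissue_px = int(tissue.sum())
    if tissue_px == 0:
        raise InputError("tissue mask is empty")
    names = list(masks)
    areas = {}
    for name in names:
        m = np.asarray(masks[name], bool)
        if m.shape != tissue.shape:
            raise InputError(f"mask {name!r} frame differs from tissue mask")
        areas[name] = int((m & tissue).sum())
    rows = []
    for name in names:
        row: dict[str, object] = {
            "mask": name,
            "area_px": areas[name],
            "tissue_fraction": areas[name] / tissue_px,
        }
        for other in names:
            if other == name:
                continue
            row[f"ratio_vs_{other}"] = (
                areas[name] / areas[other] if areas[other] else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def intensity_scatter(
    table: pd.DataFrame,
    marker_x: str,
    marker_y: str,
    thresholds: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Per-cell (x, y) mean intensities and quadrant counts at thresholds.

    Quadrant keys are ``"++", "+-", "-+", "--"`` (sign of x then y, where
    ``+`` means >= threshold); the four counts always sum to the table size.
    """
    for m in (marker_x, marker_y):
        if f"mean_{m}" not in table.columns:
            raise ParameterError(f"marker {m!r} not measured in the table")
    x = table[f"mean_{marker_x}"].to_numpy(dtype=float)
    y = table[f"mean_{marker_y}"].to_numpy(dtype=float)
    tx, ty = thresholds
    xpos = x >= tx
    ypos = y >= ty
    quadrants = {
        "++": int((xpos & ypos).sum()),
        "+-": int((xpos & ~ypos).sum()),
        "-+": int((~xpos & ypos).sum()),
        "--": int((~xpos & ~ypos).sum()),
    }
    return x, y, quadrants
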