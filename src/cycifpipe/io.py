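"""Panel configuration, image and cell-table I/O.

Conventions used throughout the package:

* images are 2-D ``float64`` arrays of nonnegative fluorescence intensities,
  indexed ``(row, col)`` with 0-based indices and the pixel-center convention
  for sub-pixel coordinates such as centroids;
* intensities are preserved exactly as stored in the source TIFF — no
  rescaling happens on load, so quantitative comparisons across staining
  cycles remain meaningful;
* a "cycle" is one staining round; all channels acquired in one cycle share
  a single pixel grid and one rigid mounting of the section, hence a single
  affine transform to the reference cycle.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InputError, PanelConfigError

__all__ = [
    "ChannelImage",
    "GatingRule",
    "PanelConfig",
    "load_panel",
    "panel_from_dict",
    "read_cycle_images",
    "write_image",
    "read_image",
    "write_cell_table",
    "read_cell_table",
    "cell_table_columns",
    "cell_table_markers",
]

#: float format used when writing tables; round-trips are exact to 6
#: significant digits.
FLOAT_FORMAT = "%.6g"


@dataclass
class ChannelImage:
    """One 2-D fluorescence channel with its acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D nonnegative intensity grid (arbitrary fluorescence units).
    cycle_index:
        0-based staining-cycle index.
    channel_name:
        Marker name imaged in this channel (e.g. ``"DAPI"``, ``"IBA1"``).
    pixel_size_um:
        Physical pixel size in micrometres; default 1.0.
    """

    pixels: np.ndarray
    cycle_index: int
    channel_name: str
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError(
                f"channel {self.channel_name!r}: expected 2-D image, "
                f"got ndim={self.pixels.ndim}"
            )
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise InputError(
                f"channel {self.channel_name!r}: negative intensities present"
            )
        if self.cycle_index < 0:
            raise InputError("cycle_index must be >= 0")
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this channel with new pixel data, same metadata."""
        return ChannelImage(
            pixels=pixels,
            cycle_index=self.cycle_index,
            channel_name=self.channel_name,
            pixel_size_um=self.pixel_size_um,
        )


@dataclass(frozen=True)
class GatingRule:
    """A conjunctive phenotype gate, e.g. Kupffer cell = IBA1+ AND CLEC4F+.

    ``terms`` is an ordered tuple of ``(marker, sign)`` pairs with sign in
    ``{"+", "-"}``. Rules are evaluated in increasing ``priority`` and the
    first matching rule wins.
    """

    phenotype: str
    terms: tuple[tuple[str, str], ...]
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.terms:
            raise PanelConfigError(
                f"gating rule {self.phenotype!r} has no terms"
            )
        seen = set()
        for marker, sign in self.terms:
            if sign not in ("+", "-"):
                raise PanelConfigError(
                    f"gating rule {self.phenotype!r}: sign must be '+' or '-', "
                    f"got {sign!r} for marker {marker!r}"
                )
            if marker in seen:
                raise PanelConfigError(
                    f"gating rule {self.phenotype!r}: marker {marker!r} repeated"
                )
            seen.add(marker)

    def matches(self, positivity: Mapping[str, bool]) -> bool:
        """True if a cell with the given per-marker positivity satisfies the rule."""
        return all(
            bool(positivity[marker]) == (sign == "+")
            for marker, sign in self.terms
        )


@dataclass
class PanelConfig:
    """Experiment panel: which marker sits in which channel of which cycle.

    ``cycles`` is an ordered list; each element is the ordered list of
    ``(channel_name, marker_name)`` pairs for that staining round. The
    nuclear counterstain must be present in every cycle because it anchors
    the cross-cycle registration.
    """

    cycles: list[list[tuple[str, str]]]
    nuclear_channel: str = "DAPI"
    gating_rules: list[GatingRule] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- introspection -------------------------------------------------
    def markers(self) -> list[str]:
        """All marker names in panel order (cycle by cycle, channel by channel)."""
        out: list[str] = []
        for cyc in self.cycles:
            for _, marker in cyc:
                out.append(marker)
        return out

    def cycle_markers(self, cycle_index: int) -> list[str]:
        return [marker for _, marker in self.cycles[cycle_index]]

    def non_nuclear_markers(self) -> list[str]:
        return [m for m in self.markers() if m != self.nuclear_channel]

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if not self.cycles:
            raise PanelConfigError("panel must define at least one cycle")
        seen: set[str] = set()
        for i, cyc in enumerate(self.cycles):
            names = [marker for _, marker in cyc]
            if self.nuclear_channel not in names:
                raise PanelConfigError(
                    f"cycle {i} lacks the nuclear channel "
                    f"{self.nuclear_channel!r}"
                )
            for marker in names:
                if marker != self.nuclear_channel and marker in seen:
                    raise PanelConfigError(
                        f"marker {marker!r} appears in more than one cycle"
                    )
                seen.add(marker)
        known = set(self.markers())
        for rule in self.gating_rules:
            for marker, _ in rule.terms:
                if marker not in known:
                    raise PanelConfigError(
                        f"gating rule {rule.phenotype!r} references marker "
                        f"{marker!r} absent from the panel"
                    )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nuclear_channel": self.nuclear_channel,
            "cycles": [
                [{"channel": ch, "marker": m} for ch, m in cyc]
                for cyc in self.cycles
            ],
            "gating": [
                {
                    "phenotype": r.phenotype,
                    "terms": {m: s for m, s in r.terms},
                    "priority": r.priority,
                }
                for r in self.gating_rules
            ],
            "params": dict(self.params),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_PANEL_KEYS = {"nuclear_channel", "cycles", "gating", "params"}


def panel_from_dict(data: Mapping) -> PanelConfig:
    """Build and validate a :class:`PanelConfig` from a parsed mapping."""
    if not isinstance(data, Mapping):
        raise PanelConfigError("panel file must contain a mapping at top level")
    unknown = sorted(set(data) - _PANEL_KEYS)
    if unknown:
        raise PanelConfigError(
            "unknown panel configuration keys: " + ", ".join(map(repr, unknown))
        )
    raw_cycles = data.get("cycles")
    if not raw_cycles:
        raise PanelConfigError("panel must list at least one cycle")
    cycles: list[list[tuple[str, str]]] = []
    for i, cyc in enumerate(raw_cycles):
        parsed: list[tuple[str, str]] = []
        for j, entry in enumerate(cyc):
            if isinstance(entry, str):
                parsed.append((f"ch{j}", entry))
            elif isinstance(entry, Mapping) and "marker" in entry:
                parsed.append((str(entry.get("channel", f"ch{j}")), str(entry["marker"])))
            else:
                raise PanelConfigError(
                    f"cycle {i} entry {j}: expected a marker name or a "
                    "{channel, marker} mapping"
                )
        cycles.append(parsed)
    rules = []
    for spec in data.get("gating") or []:
        if not isinstance(spec, Mapping) or "phenotype" not in spec or "terms" not in spec:
            raise PanelConfigError(
                "each gating rule needs 'phenotype' and 'terms' entries"
            )
        terms = tuple((str(m), str(s)) for m, s in dict(spec["terms"]).items())
        rules.append(
            GatingRule(
                phenotype=str(spec["phenotype"]),
                terms=terms,
                priority=int(spec.get("priority", 0)),
            )
        )
    return PanelConfig(
        cycles=cycles,
        nuclear_channel=str(data.get("nuclear_channel", "DAPI")),
        gating_rules=rules,
        params=dict(data.get("params") or {}),
    )


def load_panel(path: str | Path) -> PanelConfig:
    """Read and validate a panel/gating configuration from a YAML file."""
    path = Path(path)
    if not path.is_file():
        raise PanelConfigError(f"panel file not found: {path}")
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:  # pragma: no cover - rare parse failure
        raise PanelConfigError(f"cannot parse panel file {path}: {exc}") from exc
    return panel_from_dict(data)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a 2-D array (or stack of channels) to TIFF, dtype preserved."""
    tifffile.imwrite(str(path), np.asarray(pixels))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def read_cycle_images(
    paths: Sequence[str | Path], panel: PanelConfig
) -> list[dict[str, ChannelImage]]:
    """Load one TIFF per staining cycle into per-cycle channel sets.

    Each TIFF holds that cycle's channels either as pages of a multi-page
    file or as the leading axis of a 3-D array; the page order must follow
    the panel's channel order for the cycle. Returns a list (one entry per
    cycle) of ``{marker_name: ChannelImage}`` dicts. Intensities are widened
    to float64 without rescaling.
    """
    if len(paths) != panel.n_cycles:
        raise InputError(
            f"got {len(paths)} image files for {panel.n_cycles} panel cycles"
        )
    cycles: list[dict[str, ChannelImage]] = []
    for idx, path in enumerate(paths):
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise InputError(f"{path}: expected 2-D or 3-D TIFF, got {arr.ndim}-D")
        expected = panel.cycle_markers(idx)
        if arr.shape[0] != len(expected):
            raise InputError(
                f"{path}: cycle {idx} has {arr.shape[0]} channel pages but the "
                f"panel lists {len(expected)} channels"
            )
        shapes = {page.shape for page in arr}
        if len(shapes) != 1:  # pragma: no cover - tifffile already enforces
            raise InputError(f"{path}: pages of one cycle differ in shape")
        cycles.append(
            {
                marker: ChannelImage(
                    pixels=page.astype(np.float64),
                    cycle_index=idx,
                    channel_name=marker,
                )
                for marker, page in zip(expected, arr)
            }
        )
    ref_shape = None
    for cyc in cycles:
        for img in cyc.values():
            if ref_shape is None:
                ref_shape = img.shape
            elif img.shape != ref_shape:
                raise InputError(
                    "all cycles must share one grid shape; got "
                    f"{img.shape} vs {ref_shape}"
                )
    return cycles


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["cell_id", "centroid_row", "centroid_col", "area_px"]


def cell_table_columns(markers: Iterable[str]) -> list[str]:
    """Stable column order of a cell table for the given panel markers."""
    markers = list(markers)
    return (
        _BASE_COLUMNS
        + [f"mean_{m}" for m in markers]
        + [f"pos_{m}" for m in markers]
        + ["phenotype", "region"]
    )


def cell_table_markers(table: pd.DataFrame) -> list[str]:
    """Markers measured in a cell table, inferred from its mean_* columns."""
    return [c[len("mean_"):] for c in table.columns if c.startswith("mean_")]


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV with the stable column order.

    Floats are rendered with 6 significant digits; positivity flags as 0/1.
    """
    markers = cell_table_markers(table)
    cols = cell_table_columns(markers)
    out = table.copy()
    for col in cols:
        if col not in out.columns:
            out[col] = "" if col in ("phenotype", "region") else np.nan
    out = out[cols]
    for m in markers:
        out[f"pos_{m}"] = out[f"pos_{m}"].astype(bool).astype(int)
    buf = _stdio.StringIO()
    out.to_csv(buf, index=False, float_format=FLOAT_FORMAT)
    Path(path).write_text(buf.getvalue())


def read_cell_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=["nan", "NaN", ""])
    for col in [c for c in table.columns if c.startswith("pos_")]:
        table[col] = table[col].astype(float).astype(bool)
    for col in ("phenotype", "region"):
        if col in table.columns:
            table[col] = table[col].fillna("").astype(str)
    return table
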