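"""Data model, I/O and aspatial structural summaries for mapped tree stands.

A stem map is a census of tree locations and attributes (species, diameter
at breast height, height, crown base height) inside a rectangular plot.
Internally trees live in a :class:`pandas.DataFrame`; the :class:`StemMap`
wrapper pairs the table with its :class:`PlotWindow` and validates the
invariants every downstream statistic relies on (unique ids, positive dbh,
coordinates inside the window).

Units: coordinates in meters (0-based, lower-left origin by convention),
dbh in centimeters, heights in meters, plot area in hectares.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlotWindow",
    "StemMap",
    "StructureSummary",
    "StemMapError",
    "SchemaError",
    "ValidationError",
    "read_stem_map",
    "write_stem_map",
    "summarize_structure",
]

#: columns every stem-map table must provide
REQUIRED_COLUMNS = ("id", "x", "y", "species", "dbh")
#: optional per-tree attributes carried through the pipeline when present
OPTIONAL_COLUMNS = ("height", "crown_base_height", "crown_consumption", "status")

STATUS_ALIVE = "alive"
STATUS_KILLED = "killed"


class StemMapError(Exception):
    """Base class for stem-map I/O and validation problems."""


class SchemaError(StemMapError):
    """A required column is missing or the file cannot be parsed."""


class ValidationError(StemMapError):
    """Row-level content violates a stem-map invariant."""


@dataclass(frozen=True)
class PlotWindow:
    """Axis-aligned rectangular observation window, in meters."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must have positive extent on both axes")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area_m2(self) -> float:
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        """Window area in hectares (1 ha = 10,000 m^2)."""
        return self.area_m2 / 1e4

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    def translate(self, dx: float, dy: float) -> "PlotWindow":
        return PlotWindow(
            self.x_min + dx, self.x_max + dx, self.y_min + dy, self.y_max + dy
        )

    @classmethod
    def from_mapping(cls, spec: Mapping[str, float]) -> "PlotWindow":
        """Build a window from config keys x_min/x_max/y_min/y_max.

        Also accepts ``width``/``height`` with an implicit origin at 0.
        """
        if "x_max" in spec:
            return cls(
                float(spec.get("x_min", 0.0)),
                float(spec["x_max"]),
                float(spec.get("y_min", 0.0)),
                float(spec["y_max"]),
            )
        if "width" in spec and "height" in spec:
            return cls(0.0, float(spec["width"]), 0.0, float(spec["height"]))
        raise ValueError(
            "window spec needs x_min/x_max/y_min/y_max or width/height"
        )


@dataclass
class StemMap:
    """A marked point pattern of trees inside a rectangular plot window.

    ``trees`` is a DataFrame with at least the columns in
    :data:`REQUIRED_COLUMNS`.  Optional marks (height, crown_base_height,
    crown_consumption, status) are carried when present.  ``label`` is free
    text identifying the plot / era / scenario.
    """

    trees: pd.DataFrame
    window: PlotWindow
    label: str = ""

    def __post_init__(self) -> None:
        self.trees = self.trees.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        df = self.trees
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"stem map missing required column {col!r}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].unique()[:5].tolist()
            raise ValidationError(f"duplicate tree ids: {dups}")
        bad_dbh = df.index[~(pd.to_numeric(df["dbh"], errors="coerce") > 0)]
        if len(bad_dbh):
            raise ValidationError(
                f"non-positive or non-numeric dbh at rows {bad_dbh[:5].tolist()}"
            )
        inside = self.window.contains(df["x"].to_numpy(), df["y"].to_numpy())
        if not inside.all():
            out = df.index[~inside][:5].tolist()
            raise ValidationError(f"trees outside window at rows {out}")
        if "crown_consumption" in df.columns:
            cc = df["crown_consumption"].dropna()
            if ((cc < 0) | (cc > 1)).any():
                raise ValidationError("crown_consumption must lie in [0, 1]")
        if "status" in df.columns:
            ok = df["status"].isin([STATUS_ALIVE, STATUS_KILLED]) | df["status"].isna()
            if not ok.all():
                raise ValidationError(
                    "status must be 'alive' or 'killed' when present"
                )

    # -- conveniences ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.trees)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) float array of tree locations."""
        return self.trees[["x", "y"]].to_numpy(dtype=float)

    def marks(self, column: str = "dbh") -> np.ndarray:
        return self.trees[column].to_numpy(dtype=float)

    def has_statuses(self) -> bool:
        return "status" in self.trees.columns and self.trees["status"].notna().all()

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StemMap":
        return StemMap(
            self.trees.loc[np.asarray(mask)].copy(),
            self.window,
            label if label is not None else self.label,
        )

    def with_columns(self, **cols: np.ndarray) -> "StemMap":
        df = self.trees.copy()
        for name, values in cols.items():
            df[name] = values
        return StemMap(df, self.window, self.label)

    def alive(self) -> "StemMap":
        return self.subset(
            (self.trees["status"] == STATUS_ALIVE).to_numpy(), self.label + "/alive"
        )

    def killed(self) -> "StemMap":
        return self.subset(
            (self.trees["status"] == STATUS_KILLED).to_numpy(), self.label + "/killed"
        )


@dataclass(frozen=True)
class StructureSummary:
    """Aspatial stand-structure summary.

    tph
        stem density, trees per hectare.
    ba
        basal area, m^2 per hectare (sum of stem cross-sections at 1.37 m).
    qmd
        quadratic mean diameter, cm: sqrt(mean of dbh^2).  Satisfies
        qmd = sqrt(ba / (k * tph)) with k = pi/40000.
    cbh10
        tenth-percentile crown base height, m (linear-interpolation
        quantile); ``None`` when the map carries no crown base heights.
    """

    tph: float
    ba: float
    qmd: float
    cbh10: float | None
    n_trees: int = 0


# ---------------------------------------------------------------------------
# I/O


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_stem_map(
    path: str | Path | io.IOBase,
    window: PlotWindow | Mapping[str, float],
    *,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
    min_dbh: float | None = None,
    label: str = "",
    on_outside: str = "error",
) -> StemMap:
    """Read a delimited stem-map table (comma or tab) into a StemMap.

    Parameters
    ----------
    path
        File path or open text buffer.  Header must name (directly or via
        ``column_map``) at least id, x, y, species, dbh.
    window
        PlotWindow or config mapping; coordinates in meters.
    sep
        Field delimiter; ``None`` sniffs comma vs tab from the header line.
    column_map
        Mapping from canonical name to the file's column name, for deposits
        whose header dialect differs (e.g. ``{"dbh": "DBH_CM"}``).
    min_dbh
        Optional minimum-diameter census filter in cm (inclusive); field
        censuses often truncate small stems (e.g. 9.1 or 10 cm).
    on_outside
        "error" (default) rejects rows outside the window with a report;
        "drop" silently removes them.
    """
    if not isinstance(window, PlotWindow):
        window = PlotWindow.from_mapping(window)
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except Exception as exc:  # noqa: BLE001 - surface as schema error
        raise SchemaError(f"cannot parse stem-map table: {exc}") from exc
    df = _apply_column_map(df, column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(
                f"missing required column {col!r}; present: {list(df.columns)}"
            )
    for col in ("x", "y", "dbh"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(f"non-numeric {col!r} at row index {bad[0]}")
        df[col] = numeric
    if min_dbh is not None:
        df = df[df["dbh"] >= min_dbh]
    inside = window.contains(df["x"].to_numpy(), df["y"].to_numpy())
    if not inside.all():
        report = df.index[~inside].tolist()
        if on_outside == "error":
            raise ValidationError(f"rows outside window: {report}")
        df = df[inside]
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    return StemMap(df[keep].reset_index(drop=True), window, label)


def write_stem_map(stem_map: StemMap, path: str | Path, *, sep: str = ",") -> None:
    """Write the stem map in the same dialect :func:`read_stem_map` accepts."""
    stem_map.trees.to_csv(path, sep=sep, index=False)


def join_consumption(
    stem_map: StemMap, table: pd.DataFrame | str | Path
) -> StemMap:
    """Attach per-tree crown-consumption fractions from an id-keyed table.

    The table (two columns: id, crown_consumption) typically comes from an
    external fire-behavior simulation; fractions must lie in [0, 1].
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    if not {"id", "crown_consumption"}.issubset(table.columns):
        raise SchemaError("consumption table needs columns id, crown_consumption")
    merged = stem_map.trees.drop(columns=["crown_consumption"], errors="ignore").merge(
        table[["id", "crown_consumption"]], on="id", how="left"
    )
    missing = merged.loc[merged["crown_consumption"].isna(), "id"].tolist()
    if missing:
        raise ValidationError(f"no consumption value for ids {missing[:5]}")
    return StemMap(merged, stem_map.window, stem_map.label)


# ---------------------------------------------------------------------------
# structural summaries


def summarize_structure(stem_map: StemMap) -> StructureSummary:
    """Stand-structure summary: density, basal area, QMD, canopy base height.

    Basal area per tree is pi*(dbh/200)^2 m^2 for dbh in cm.  The stand-level
    canopy base height is reported as the 10th percentile of per-tree crown
    base heights (linear interpolation between order statistics); it is
    ``None``, not zero, when the map has no crown_base_height column.
    """
    if stem_map.n == 0:
        raise ValidationError("cannot summarize an empty stem map")
    dbh = stem_map.marks("dbh")
    area_ha = stem_map.window.area_ha
    tph = stem_map.n / area_ha
    ba = float(np.sum(np.pi * (dbh / 200.0) ** 2) / area_ha)
    qmd = float(np.sqrt(np.mean(dbh**2)))
    cbh10: float | None = None
    if "crown_base_height" in stem_map.trees.columns:
        cbh = stem_map.trees["crown_base_height"].dropna().to_numpy(dtype=float)
        if len(cbh):
            cbh10 = float(np.quantile(cbh, 0.10))  # linear-interpolation quantile
    return StructureSummary(tph=tph, ba=ba, qmd=qmd, cbh10=cbh10, n_trees=stem_map.n)
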