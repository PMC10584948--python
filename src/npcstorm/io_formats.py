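"""On-disk formats: localization CSVs, ROI polygons, FRAP traces, images, config.

All lengths are nanometres in memory; unit conversion happens once, at the I/O
boundary, driven by the dialect a file declares. Areas are reported in µm².

The canonical localization dialect mirrors the de-facto CSV export of common
single-molecule localization software: comma-separated with header tokens
``frame``, ``x [nm]``, ``y [nm]``, ``sigma [nm]`` and optionally
``intensity [photon]`` and ``uncertainty [nm]``. Unknown columns are preserved
opaquely through a read/write round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Polygon

from .errors import FormatError, GeometryError, ParseError

NM2_PER_UM2 = 1e6

#: internal column name -> canonical CSV header token
CANONICAL_COLUMNS = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "sigma": "sigma [nm]",
    "intensity": "intensity [photon]",
    "uncertainty": "uncertainty [nm]",
}

REQUIRED_FIELDS = ("frame", "x", "y", "sigma")
LENGTH_FIELDS = ("x", "y", "sigma", "uncertainty")


@dataclass(frozen=True)
class Dialect:
    """A localization-CSV dialect: header tokens plus a length unit.

    ``length_scale`` is the factor converting the file's length unit to nm
    (1.0 for nm files, 1000.0 for µm files).
    """

    name: str
    columns: Mapping[str, str]
    length_scale: float = 1.0


DIALECTS: dict[str, Dialect] = {
    "thunderstorm": Dialect("thunderstorm", CANONICAL_COLUMNS, 1.0),
    "thunderstorm-um": Dialect(
        "thunderstorm-um",
        {
            "frame": "frame",
            "x": "x [µm]",
            "y": "y [µm]",
            "sigma": "sigma [µm]",
            "intensity": "intensity [photon]",
            "uncertainty": "uncertainty [µm]",
        },
        1000.0,
    ),
}


def _resolve_dialect(dialect: str | Dialect) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise FormatError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


@dataclass
class LocalizationTable:
    """An ordered table of single-molecule localizations for one nucleus.

    ``df`` holds canonical columns (``frame``, ``x``, ``y``, ``sigma`` and,
    when present, ``intensity``, ``uncertainty``) in nm, plus any extra
    columns carried through from the source file. Row order is meaningful
    and preserved by every operation.
    """

    df: pd.DataFrame
    source_id: str = ""
    frame_count: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in REQUIRED_FIELDS:
            if col not in self.df.columns:
                raise FormatError(f"localization table missing column {col!r}")
        if len(self.df):
            frame = self.df["frame"].to_numpy()
            if (frame < 1).any():
                raise FormatError("frame indices must be >= 1")
            if self.frame_count and frame.max() > self.frame_count:
                raise FormatError("record frame exceeds frame_count")
            if (self.df["sigma"].to_numpy() <= 0).any():
                raise FormatError("sigma must be positive")
            xy = self.df[["x", "y"]].to_numpy(float)
            if not np.isfinite(xy).all():
                raise FormatError("x, y must be finite")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocalizationTable):
            return NotImplemented
        return (
            self.source_id == other.source_id
            and self.frame_count == other.frame_count
            and self.df.columns.tolist() == other.df.columns.tolist()
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )

    def coords(self) -> np.ndarray:
        """(n, 2) float array of x, y in nm, in row order."""
        return self.df[["x", "y"]].to_numpy(float)

    def replace(self, df: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(df, source_id=self.source_id, frame_count=self.frame_count)


def polygon_area(polygon: Sequence[Sequence[float]]) -> float:
    """Area of a simple polygon with vertices in nm, returned in µm².

    Shoelace formula via shapely; vertex order (CW/CCW) does not matter.
    """
    verts = np.asarray(polygon, float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise GeometryError("polygon needs >= 3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_simple or not poly.is_valid:
        raise GeometryError("polygon must be simple (non-self-intersecting)")
    return poly.area / NM2_PER_UM2


@dataclass
class NucleusROI:
    """A nuclear outline as an ordered vertex list in nm; area in µm²."""

    polygon: np.ndarray

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, float)
        self.area  # validates

    @property
    def area(self) -> float:
        a = polygon_area(self.polygon)
        if a <= 0:
            raise GeometryError("ROI area must be positive")
        return a

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) inside the polygon."""
        pts = np.asarray(xy, float)
        return shapely.contains_xy(Polygon(self.polygon), pts[:, 0], pts[:, 1])


def disk_roi(radius_nm: float = 5000.0, n_vertices: int = 64) -> NucleusROI:
    """Regular-polygon approximation to a disk, the default test-field ROI."""
    th = 2 * np.pi * np.arange(n_vertices) / n_vertices
    return NucleusROI(radius_nm * np.c_[np.cos(th), np.sin(th)])


# -- localization CSV ---------------------------------------------------------


def read_localizations(
    path: str | Path,
    dialect: str | Dialect = "thunderstorm",
    source_id: str | None = None,
    frame_count: int | None = None,
) -> LocalizationTable:
    """Read a localization CSV in the given dialect, normalizing units to nm.

    Row order is preserved. Columns not named by the dialect are carried
    through untouched. Raises :class:`FormatError` for a missing required
    column and :class:`ParseError` (with the 1-based data row number) for a
    non-numeric cell.
    """
    path = Path(path)
    d = _resolve_dialect(dialect)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    header_to_internal = {v: k for k, v in d.columns.items()}

    for col in REQUIRED_FIELDS:
        if d.columns[col] not in raw.columns:
            raise FormatError(f"{path.name}: missing required column {d.columns[col]!r}")

    out = {}
    for header in raw.columns:
        internal = header_to_internal.get(header)
        series = raw[header]
        probe = pd.to_numeric(series, errors="coerce")
        bad = probe.isna() & series.notna() & (series.str.strip() != "")
        if internal is None:
            # opaque passthrough; numeric columns come back as float64 so a
            # write/read cycle is lossless, anything else stays text
            out[header] = series if bad.any() else series.astype(np.float64)
            continue
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(
                f"{path.name}: non-numeric value {series[bad.idxmax()]!r} in column "
                f"{header!r} at data row {row}"
            )
        # astype goes through Python's exact float parser (to_numeric does not
        # guarantee bit-level round trips)
        values = series.astype(np.float64)
        if internal in LENGTH_FIELDS and d.length_scale != 1.0:
            values = values * d.length_scale
        if internal == "frame":
            values = values.astype(np.int64)
        out[internal] = values
    df = pd.DataFrame(out)
    if frame_count is None:
        frame_count = int(df["frame"].max()) if len(df) else 0
    return LocalizationTable(df, source_id=source_id or path.stem, frame_count=frame_count)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table in the canonical nm dialect, losslessly re-readable."""
    df = table.df.rename(columns=CANONICAL_COLUMNS)
    # %.17g guarantees bit-exact float round trips
    df.to_csv(path, index=False, float_format="%.17g")


# -- ROI / FRAP / image / mask ------------------------------------------------


def read_roi(path: str | Path) -> NucleusROI:
    """ROI from a JSON array of [x_nm, y_nm] vertices."""
    verts = json.loads(Path(path).read_text())
    return NucleusROI(np.asarray(verts, float))


def write_roi(roi: NucleusROI, path: str | Path) -> None:
    Path(path).write_text(json.dumps(roi.polygon.tolist()))


def read_frap_trace(path: str | Path):
    """FRAP trace from a CSV with columns ``t [s]`` and ``intensity``."""
    from .frap import FRAPTrace  # local import: frap does not import io_formats

    df = pd.read_csv(path)
    for col in ("t [s]", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    return FRAPTrace(df["t [s]"].to_numpy(float), df["intensity"].to_numpy(float))


def write_frap_trace(trace, path: str | Path) -> None:
    pd.DataFrame({"t [s]": trace.t, "intensity": trace.intensity}).to_csv(path, index=False)


def read_image(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_image(image: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image))


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Boolean mask from a label/binary TIFF or a polygon-vertex JSON.

    For a JSON polygon (vertices in pixel coordinates, [x, y] order) the
    target image ``shape`` is required and the polygon is rasterized.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        if shape is None:
            raise GeometryError("shape required to rasterize a polygon mask")
        verts = np.asarray(json.loads(path.read_text()), float)
        return rasterize_polygon(verts, shape)
    return read_image(path).astype(bool)


def rasterize_polygon(vertices_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    from matplotlib.path import Path as MplPath

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.c_[xx.ravel() + 0.5, yy.ravel() + 0.5]
    return MplPath(vertices_xy).contains_points(pts).reshape(h, w)


# -- run configuration --------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def config_get(cfg: Mapping, dotted_key: str, default=None):
    """Fetch ``cfg["a"]["b"]`` via ``"a.b"``; missing keys yield *default*."""
    node = cfg
    for part in dotted_key.split("."):
        if not isinstance(node, Mapping) or part not in node:
            return default
        node = node[part]
    return node


def config_set(cfg: dict, dotted_key: str, value) -> None:
    parts = dotted_key.split(".")
    node = cfg
    for part in parts[:-1]:
        node = node.setdefault(part, {})
    node[parts[-1]] = value
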