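"""Localization-table I/O, detection filtering and neighbor-density rendering.

Tables follow the de-facto SMLM dialect (comma-separated, quoted
unit-bearing headers such as ``"x [nm]"``) produced by common
localizer software.  All coordinates are normalized to nanometres on
read.  Rendering produces a super-resolution neighbor-density map:
each localization carries the count of other localizations within a
fixed radius (100 nm by default), rasterized onto a pixel grid.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "LocalizationTable",
    "DensityMap",
    "SchemaError",
    "read_localizations",
    "write_localizations",
    "filter_by_intensity",
    "local_neighbor_density",
    "render_density_map",
    "write_density_map",
]

_UNIT_SCALE_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "micron": 1000.0, "px": None}


class SchemaError(ValueError):
    """Raised when a localization file lacks required columns."""


@dataclass
class LocalizationTable:
    """Time-stamped 2-D emitter detections; the universal pipeline input.

    frame: integer frame indices (>= 0), sorted ascending.
    x, y: nm.  intensity: photons.  uncertainty: nm (optional, NaN if absent).
    """

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None
    frame_interval: float | None = None  # s
    temperature_c: float | None = None
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        n = len(self.frame)
        if not (len(self.x) == len(self.y) == len(self.intensity) == n):
            raise ValueError("column length mismatch")
        if n and (np.any(self.frame < 0)):
            raise ValueError("frame indices must be non-negative")
        if n and not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if n and np.any(np.diff(self.frame) < 0):
            order = np.argsort(self.frame, kind="stable")
            self._reorder(order)
        if self.frame_interval is not None and not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    def _reorder(self, order: np.ndarray) -> None:
        self.frame = self.frame[order]
        self.x = self.x[order]
        self.y = self.y[order]
        self.intensity = self.intensity[order]
        if self.uncertainty is not None:
            self.uncertainty = self.uncertainty[order]
        if self.extra is not None:
            self.extra = self.extra.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of x, y in nm."""
        return np.column_stack([self.x, self.y])

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        return LocalizationTable(
            frame=self.frame[mask], x=self.x[mask], y=self.y[mask],
            intensity=self.intensity[mask],
            uncertainty=None if self.uncertainty is None else self.uncertainty[mask],
            frame_interval=self.frame_interval, temperature_c=self.temperature_c,
            extra=None if self.extra is None else self.extra.loc[mask].reset_index(drop=True),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "frame": self.frame, "x [nm]": self.x, "y [nm]": self.y,
            "intensity [photon]": self.intensity,
        })
        if self.uncertainty is not None:
            df["uncertainty [nm]"] = self.uncertainty
        if self.extra is not None:
            for c in self.extra.columns:
                df[c] = self.extra[c].to_numpy()
        return df


@dataclass
class DensityMap:
    """Rasterized neighbor-count map.

    counts[row, col] holds the maximum per-localization neighbor count
    among localizations falling in that pixel (half-open bins).
    """

    counts: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float]
    radius_nm: float


_COL_RE = re.compile(r'^\s*"?\s*(?P<name>[A-Za-z_][\w .-]*?)\s*(?:\[(?P<unit>[^\]]+)\])?\s*"?\s*$')

_CANONICAL = {
    "frame": "frame", "t": "frame",
    "x": "x", "y": "y",
    "intensity": "intensity", "photons": "intensity",
    "uncertainty": "uncertainty", "uncertainty_xy": "uncertainty",
    "precision": "uncertainty",
}


def _parse_header(col: str) -> tuple[str | None, float]:
    m = _COL_RE.match(col)
    if not m:
        return None, 1.0
    name = m.group("name").strip().lower()
    unit = (m.group("unit") or "").strip().lower()
    canon = _CANONICAL.get(name)
    scale = 1.0
    if canon in ("x", "y", "uncertainty") and unit:
        scale = _UNIT_SCALE_NM.get(unit, 1.0) or 1.0
    return canon, scale


def read_localizations(
    path: str | Path,
    frame_interval: float | None = None,
    temperature_c: float | None = None,
) -> LocalizationTable:
    """Read a delimited localization table, normalizing coordinates to nm.

    Recognizes headers of the form ``"x [nm]"`` / ``"x [um]"`` etc.;
    micrometre columns are scaled by 1000.  Unrecognized columns are
    preserved verbatim in ``table.extra``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise SchemaError(f"{path}: cannot parse as delimited table: {exc}") from exc
    mapping: dict[str, str] = {}
    scales: dict[str, float] = {}
    for col in df.columns:
        canon, scale = _parse_header(str(col))
        if canon and canon not in mapping:
            mapping[canon] = col
            scales[canon] = scale
    missing = [c for c in ("frame", "x", "y") if c not in mapping]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; headers were {list(df.columns)}"
        )
    frame = df[mapping["frame"]].to_numpy()
    if not np.all(np.isfinite(frame)):
        bad = int(np.flatnonzero(~np.isfinite(np.asarray(frame, float)))[0])
        raise SchemaError(f"{path}: non-finite frame index at row {bad}")
    x = df[mapping["x"]].to_numpy(float) * scales["x"]
    y = df[mapping["y"]].to_numpy(float) * scales["y"]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        bad = int(np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))[0])
        raise SchemaError(f"{path}: non-finite coordinate at row {bad}")
    if "intensity" in mapping:
        intensity = df[mapping["intensity"]].to_numpy(float)
    else:
        intensity = np.ones(len(df))
    unc = None
    if "uncertainty" in mapping:
        unc = df[mapping["uncertainty"]].to_numpy(float) * scales["uncertainty"]
    used = set(mapping.values())
    extra_cols = [c for c in df.columns if c not in used]
    extra = df[extra_cols].reset_index(drop=True) if extra_cols else None
    return LocalizationTable(frame, x, y, intensity, unc,
                             frame_interval=frame_interval,
                             temperature_c=temperature_c, extra=extra)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write the table in the quoted-unit-header CSV dialect."""
    df = table.to_dataframe()
    df.to_csv(path, index=False, quoting=2)  # QUOTE_NONNUMERIC


def filter_by_intensity(table: LocalizationTable, min_intensity: float) -> LocalizationTable:
    """Drop rows below the intensity threshold, preserving order."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    return table.select(table.intensity >= min_intensity)


def local_neighbor_density(table: LocalizationTable, radius: float = 100.0) -> np.ndarray:
    """Per-localization count of OTHER localizations within ``radius`` nm.

    The localization itself is excluded so a lone detection reads as
    zero density.  Counting is a 2-D disk query on the x/y plane.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(table) == 0:
        return np.zeros(0, dtype=np.int64)
    tree = cKDTree(table.points)
    counts = tree.query_ball_point(table.points, r=radius, return_length=True)
    return np.asarray(counts, dtype=np.int64) - 1


def render_density_map(
    table: LocalizationTable,
    pixel: float = 20.0,
    radius: float = 100.0,
) -> DensityMap:
    """Rasterize per-localization neighbor counts onto a pixel grid.

    Pixels are half-open bins [k*pixel, (k+1)*pixel); localizations
    sharing a pixel accumulate by maximum, preserving per-localization
    density semantics.
    """
    if pixel <= 0:
        raise ValueError("pixel must be positive")
    counts = local_neighbor_density(table, radius)
    if len(table) == 0:
        return DensityMap(np.zeros((1, 1), dtype=np.float32), pixel, (0.0, 0.0), radius)
    x0, y0 = float(table.x.min()), float(table.y.min())
    ix = np.floor((table.x - x0) / pixel).astype(np.int64)
    iy = np.floor((table.y - y0) / pixel).astype(np.int64)
    grid = np.zeros((int(iy.max()) + 1, int(ix.max()) + 1), dtype=np.float32)
    np.maximum.at(grid, (iy, ix), counts.astype(np.float32))
    return DensityMap(grid, pixel, (x0, y0), radius)


def write_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Write the map as 32-bit float TIFF plus a JSON geometry sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, dmap.counts.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "pixel_nm": dmap.pixel_nm,
        "origin_nm": list(dmap.origin_nm),
        "radius_nm": dmap.radius_nm,
        "shape": list(dmap.counts.shape),
    }, indent=2))
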