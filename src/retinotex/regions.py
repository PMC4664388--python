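"""Macular region geometry and per-layer regions of interest.

The macula is partitioned into four concentric zones around the foveal
centre, defined by their diameters: the foveolar disc (0.375 mm), and the
foveal (1.85 mm), parafoveal (2.85 mm) and perifoveal (5.85 mm) annuli.
Radial membership is half-open ``[inner, outer)``; columns farther than the
perifoveal radius (2.925 mm) belong to no region.

Within the foveolar disc the inner retinal layers are displaced sideways by
the pit, so metric extraction there is restricted to the outer layers
(ONL+IS, OS, RPE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import BScan, INNER_LAYERS, LAYER_BOUNDS, LayerSegmentation

__all__ = [
    "MacularRegion",
    "REGIONS",
    "REGION_NAMES",
    "LayerROI",
    "region_of_column",
    "region_columns",
    "build_layer_roi",
]


@dataclass(frozen=True)
class MacularRegion:
    """A concentric macular zone, delimited by radial distance from the fovea."""

    name: str
    inner_radius_mm: float
    outer_radius_mm: float

    def contains(self, radius_mm: float | np.ndarray) -> bool | np.ndarray:
        return (radius_mm >= self.inner_radius_mm) & (radius_mm < self.outer_radius_mm)


REGIONS: dict[str, MacularRegion] = {
    "foveolar": MacularRegion("foveolar", 0.0, 0.375 / 2),
    "foveal": MacularRegion("foveal", 0.375 / 2, 1.85 / 2),
    "parafoveal": MacularRegion("parafoveal", 1.85 / 2, 2.85 / 2),
    "perifoveal": MacularRegion("perifoveal", 2.85 / 2, 5.85 / 2),
}

#: Region names in order, plus the pooled "across_all" aggregate.
REGION_NAMES: tuple[str, ...] = ("foveolar", "foveal", "parafoveal", "perifoveal")


def region_of_column(
    column: int, fovea_column: int, lateral_extent_mm: float, n_columns: int
) -> str | None:
    """Assign a column to its macular region, or ``None`` outside all zones.

    The radial distance is ``|column - fovea_column| * lateral_extent_mm /
    (n_columns - 1)``; zones are half-open in radius, so a column exactly on
    the perifoveal outer radius (2.925 mm) is outside.
    """
    if not 0 <= column < n_columns:
        raise ValueError(f"column {column} outside [0, {n_columns})")
    d = abs(column - fovea_column) * lateral_extent_mm / (n_columns - 1)
    for region in REGIONS.values():
        if region.contains(d):
            return region.name
    return None


def region_columns(scan: BScan, region_name: str) -> np.ndarray:
    """All column indices of ``scan`` lying radially inside a region."""
    region = REGIONS[region_name]
    cols = np.arange(scan.n_columns)
    d = np.abs(cols - scan.fovea_column) * scan.column_spacing_mm
    return cols[region.contains(d)]


@dataclass
class LayerROI:
    """The pixel set of one layer within one macular region of one scan.

    ``columns`` lists the included column indices (region columns minus
    exclusions minus zero-height columns); ``top_rows``/``bottom_rows`` give
    the half-open pixel row interval of the layer in each included column.
    """

    layer_name: str
    region_name: str
    columns: np.ndarray
    top_rows: np.ndarray
    bottom_rows: np.ndarray
    scan: BScan

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.top_rows = np.asarray(self.top_rows, dtype=int)
        self.bottom_rows = np.asarray(self.bottom_rows, dtype=int)
        if not (len(self.columns) == len(self.top_rows) == len(self.bottom_rows)):
            raise ValueError("columns, top_rows and bottom_rows must align")
        if np.any(self.bottom_rows < self.top_rows):
            raise ValueError("layer interval has negative height")

    @property
    def is_empty(self) -> bool:
        return len(self.columns) == 0

    @property
    def heights_px(self) -> np.ndarray:
        return self.bottom_rows - self.top_rows

    def column_profiles(self) -> list[np.ndarray]:
        """Axial reflectivity profile of each included column."""
        img = self.scan.reflectivity
        return [
            img[t:b, c] for c, t, b in zip(self.columns, self.top_rows, self.bottom_rows)
        ]

    def mask(self) -> np.ndarray:
        """Boolean pixel mask of the ROI on the scan grid."""
        m = np.zeros(self.scan.reflectivity.shape, dtype=bool)
        for c, t, b in zip(self.columns, self.top_rows, self.bottom_rows):
            m[t:b, c] = True
        return m


def build_layer_roi(
    scan: BScan,
    segmentation: LayerSegmentation,
    layer_name: str,
    region_name: str,
    excluded_columns: set[int] | frozenset[int] | None = None,
) -> LayerROI:
    """Assemble the ROI of one layer within one macular region.

    Columns are the region's columns minus ``excluded_columns`` (typically
    vessel shadows) minus columns where the layer has zero pixel height.
    Inner layers requested in the foveolar region yield an empty ROI by
    design (the pit displaces them).  A fully excluded region is an empty
    ROI, not an error.
    """
    if layer_name not in LAYER_BOUNDS:
        raise KeyError(f"unknown layer name: {layer_name!r}")
    if region_name not in REGIONS:
        raise KeyError(f"unknown region name: {region_name!r}")
    excluded = frozenset() if excluded_columns is None else frozenset(excluded_columns)

    if region_name == "foveolar" and layer_name in INNER_LAYERS:
        empty = np.array([], dtype=int)
        return LayerROI(layer_name, region_name, empty, empty, empty, scan)

    cols = region_columns(scan, region_name)
    cols = np.array([c for c in cols if c not in excluded], dtype=int)
    top_all, bottom_all = segmentation.layer_interval(layer_name)
    top, bottom = top_all[cols], bottom_all[cols]
    keep = bottom > top
    return LayerROI(layer_name, region_name, cols[keep], top[keep], bottom[keep], scan)
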