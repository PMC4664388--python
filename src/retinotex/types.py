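"""Core domain types and coordinate conventions for macular OCT analysis.

Conventions used throughout the package:

* A B-scan is stored as a 2-D array of non-negative reflectivity values with
  rows indexing axial depth (row 0 = vitreous / inner side) and columns
  indexing lateral position.
* Layer boundaries are per-column row positions; fractional rows are allowed.
  A layer occupies the half-open row interval ``[top, bottom)``.  Fractional
  boundaries are resolved so that pixel ``j`` belongs to the layer whose
  interval contains ``j + 0.5`` — i.e. both endpoints are rounded with
  ``ceil(b - 0.5)``.  This conserves the per-column sum of layer heights.
* Total retinal thickness spans the ILM to the OS/RPE junction; the
  RPE/choroid boundary exists only to delimit the RPE layer itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOUNDARY_NAMES",
    "LAYER_BOUNDS",
    "LAYER_NAMES",
    "INNER_LAYERS",
    "OUTER_LAYERS",
    "GROUP_LABELS",
    "METRIC_NAMES",
    "BScan",
    "LayerSegmentation",
    "RadialScanSet",
    "QualityReport",
    "pixel_row",
]

#: The eight segmented boundary curves, ordered from the vitreous outward.
BOUNDARY_NAMES: tuple[str, ...] = (
    "ILM",
    "RNFL/GCL+IPL",
    "GCL+IPL/INL",
    "INL/OPL",
    "OPL/ONL+IS",
    "ONL+IS/OS",
    "OS/RPE",
    "RPE/choroid",
)

#: Layer name -> (top boundary index, bottom boundary index).  GCC is the
#: ganglion cell complex, a composite spanning RNFL plus GCL+IPL.
LAYER_BOUNDS: dict[str, tuple[int, int]] = {
    "RNFL": (0, 1),
    "GCL+IPL": (1, 2),
    "GCC": (0, 2),
    "INL": (2, 3),
    "OPL": (3, 4),
    "ONL+IS": (4, 5),
    "OS": (5, 6),
    "RPE": (6, 7),
}

LAYER_NAMES: tuple[str, ...] = tuple(LAYER_BOUNDS)

#: Layers displaced away from the foveal pit; excluded from the foveolar zone.
INNER_LAYERS: frozenset[str] = frozenset({"RNFL", "GCL+IPL", "GCC", "INL", "OPL"})
OUTER_LAYERS: frozenset[str] = frozenset({"ONL+IS", "OS", "RPE"})

#: Study arms: healthy controls, MS without / with an optic-neuritis history.
GROUP_LABELS: tuple[str, ...] = ("H", "MSON-", "MSON+")

METRIC_NAMES: tuple[str, ...] = (
    "thickness_um",
    "contrast_au",
    "fractal_dimension_au",
    "layer_index_au",
    "total_reflectance_db",
)

#: Boundary indices of the total-retina span (ILM to OS/RPE junction).
TOTAL_RETINA_BOUNDS: tuple[int, int] = (0, 6)


def pixel_row(boundary: np.ndarray | float) -> np.ndarray | int:
    """Resolve a fractional boundary row to an integer pixel row.

    Pixel ``j`` belongs to the layer whose half-open interval contains
    ``j + 0.5``, so both interval endpoints map through ``ceil(b - 0.5)``
    (the smallest pixel whose centre lies at or beyond the boundary).
    Applying the same rule to top and bottom conserves per-column height
    sums across adjacent layers.
    """
    r = np.ceil(np.asarray(boundary) - 0.5).astype(int)
    return int(r) if np.isscalar(boundary) or np.ndim(boundary) == 0 else r


@dataclass
class BScan:
    """One radial cross-sectional reflectivity image with calibration.

    Parameters
    ----------
    reflectivity
        2-D array of non-negative intensities (rows = axial depth from the
        vitreous, columns = lateral position), arbitrary device units.
    axial_spacing_um
        Micrometres per row (the device's axial pixel resolution, Δy).
    lateral_extent_mm
        Transverse length of the scan in millimetres.
    fovea_column
        Column index of the foveal centre.
    scan_angle_deg
        Radial direction of this scan within the macular map.
    signal_strength
        Device signal-strength score, 0–10.
    """

    reflectivity: np.ndarray
    axial_spacing_um: float
    lateral_extent_mm: float
    fovea_column: int
    scan_angle_deg: float = 0.0
    signal_strength: int = 10
    eye_id: str = ""
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        if self.reflectivity.ndim != 2:
            raise ValueError("reflectivity must be a 2-D matrix")
        if not np.all(np.isfinite(self.reflectivity)):
            raise ValueError("reflectivity contains non-finite values")
        if np.any(self.reflectivity < 0):
            raise ValueError("reflectivity values must be non-negative")
        if self.axial_spacing_um <= 0:
            raise ValueError("axial_spacing_um must be positive")
        if self.lateral_extent_mm <= 0:
            raise ValueError("lateral_extent_mm must be positive")
        if not 0 <= self.fovea_column < self.n_columns:
            raise ValueError(
                f"fovea_column {self.fovea_column} outside [0, {self.n_columns})"
            )
        if not 0 <= self.signal_strength <= 10:
            raise ValueError("signal_strength must lie in 0..10")

    @property
    def n_rows(self) -> int:
        return self.reflectivity.shape[0]

    @property
    def n_columns(self) -> int:
        return self.reflectivity.shape[1]

    @property
    def column_spacing_mm(self) -> float:
        """Lateral millimetres per column step."""
        return self.lateral_extent_mm / (self.n_columns - 1)


@dataclass
class LayerSegmentation:
    """Eight boundary curves delimiting seven retinal layers per column.

    ``boundaries`` has shape ``(8, n_columns)``; row order follows
    :data:`BOUNDARY_NAMES`.  Rows must be monotonically non-decreasing from
    the ILM outward in every column — a layer may collapse to zero height
    (as the inner layers do in the foveal pit) but never to negative height.
    """

    boundaries: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.ndim != 2 or self.boundaries.shape[0] != len(BOUNDARY_NAMES):
            raise ValueError(
                f"boundaries must have shape (8, n_columns), got {self.boundaries.shape}"
            )
        diffs = np.diff(self.boundaries, axis=0)
        if np.any(diffs < 0):
            b, col = np.argwhere(diffs < 0)[0]
            where = f" in scan '{self.label}'" if self.label else ""
            raise ValueError(
                f"non-monotone boundaries{where}: '{BOUNDARY_NAMES[b + 1]}' lies above "
                f"'{BOUNDARY_NAMES[b]}' at column {col}"
            )

    @property
    def n_columns(self) -> int:
        return self.boundaries.shape[1]

    def boundary(self, name: str) -> np.ndarray:
        return self.boundaries[BOUNDARY_NAMES.index(name)]

    def layer_interval(self, layer_name: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-column integer pixel interval ``[top, bottom)`` of a layer."""
        if layer_name not in LAYER_BOUNDS:
            raise KeyError(f"unknown layer name: {layer_name!r}")
        ti, bi = LAYER_BOUNDS[layer_name]
        return pixel_row(self.boundaries[ti]), pixel_row(self.boundaries[bi])

    def layer_height_um(self, layer_name: str, axial_spacing_um: float) -> np.ndarray:
        """Per-column layer thickness in micrometres (fractional boundaries)."""
        if layer_name not in LAYER_BOUNDS:
            raise KeyError(f"unknown layer name: {layer_name!r}")
        ti, bi = LAYER_BOUNDS[layer_name]
        return (self.boundaries[bi] - self.boundaries[ti]) * axial_spacing_um

    def total_retina_um(self, axial_spacing_um: float) -> np.ndarray:
        """Per-column total retinal thickness, ILM to OS/RPE junction."""
        ti, bi = TOTAL_RETINA_BOUNDS
        return (self.boundaries[bi] - self.boundaries[ti]) * axial_spacing_um


@dataclass
class RadialScanSet:
    """The six fovea-centred radial B-scans of one eye with segmentations."""

    scans: list[BScan]
    segmentations: list[LayerSegmentation]

    N_SCANS = 6

    def __post_init__(self) -> None:
        if len(self.scans) != self.N_SCANS or len(self.segmentations) != self.N_SCANS:
            raise ValueError(
                f"a radial scan set holds exactly {self.N_SCANS} scans and segmentations"
            )
        ref = self.scans[0]
        for s in self.scans[1:]:
            if s.axial_spacing_um != ref.axial_spacing_um:
                raise ValueError("axial_spacing_um differs between scans of one eye")
            if s.lateral_extent_mm != ref.lateral_extent_mm:
                raise ValueError("lateral_extent_mm differs between scans of one eye")
        for scan, seg in zip(self.scans, self.segmentations):
            if seg.n_columns != scan.n_columns:
                raise ValueError("segmentation width does not match its scan")

    @property
    def axial_spacing_um(self) -> float:
        return self.scans[0].axial_spacing_um

    @property
    def lateral_extent_mm(self) -> float:
        return self.scans[0].lateral_extent_mm

    @property
    def eye_id(self) -> str:
        return self.scans[0].eye_id


@dataclass
class QualityReport:
    """Scan-quality summary of one radial scan set.

    ``sqf`` (scan quality factor) is 1 when the percent standard deviation of
    the foveal centre-point thickness across the six radial scans is at most
    10%, flagging acquisitions free of gross motion/boundary errors.
    """

    cpt_values_um: list[float] = field(default_factory=list)
    cpt_sd_percent: float = 0.0
    sqf: int = 1
    min_signal_strength: int = 10

    def __post_init__(self) -> None:
        if self.sqf not in (0, 1):
            raise ValueError("sqf must be 0 or 1")
        if self.cpt_sd_percent < 0:
            raise ValueError("cpt_sd_percent must be non-negative")
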