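"""Readers and writers for scan sets and feature tables.

On-disk layout of one eye's radial scan set (one directory per eye):

* ``<eye>_scan<k>.tif`` for ``k`` in 0..5 — 16-bit single-channel TIFFs,
  rows = axial depth from the vitreous.
* ``<eye>_scan<k>_boundaries.csv`` — long table ``scan,column,boundary,row``
  with the eight boundary names of :data:`retinotex.types.BOUNDARY_NAMES`.
* ``<eye>_metadata.json`` — keys ``axial_spacing_um``, ``lateral_extent_mm``,
  ``fovea_column``, ``signal_strength``, ``eye_id``, ``subject_id``,
  ``group`` (one of H, MSON-, MSON+), optionally ``scan_angles_deg``.

Feature tables are long-format CSVs with columns
``eye, subject, group, layer, region, metric, value, n_columns_used``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import BOUNDARY_NAMES, BScan, LayerSegmentation, RadialScanSet

__all__ = [
    "read_scan_set",
    "write_scan_set",
    "read_feature_table",
    "write_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "eye",
    "subject",
    "group",
    "layer",
    "region",
    "metric",
    "value",
    "n_columns_used",
]


def _boundaries_from_frame(df: pd.DataFrame, label: str) -> np.ndarray:
    n_cols = int(df["column"].max()) + 1
    arr = np.full((len(BOUNDARY_NAMES), n_cols), np.nan)
    for name, sub in df.groupby("boundary"):
        if name not in BOUNDARY_NAMES:
            raise ValueError(f"unknown boundary name {name!r} in {label}")
        arr[BOUNDARY_NAMES.index(name), sub["column"].to_numpy()] = sub["row"].to_numpy()
    if np.any(np.isnan(arr)):
        b, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing boundary '{BOUNDARY_NAMES[b]}' at column {c} in {label}"
        )
    return arr


def read_scan_set(directory_path: str | Path) -> RadialScanSet:
    """Read one eye's six radial scans, boundary tables and metadata.

    Raises
    ------
    FileNotFoundError
        If any expected TIFF, boundary CSV or the metadata JSON is absent.
    ValueError
        If a boundary table violates monotonicity (the message names the
        scan and column).
    """
    directory = Path(directory_path)
    meta_files = sorted(directory.glob("*_metadata.json"))
    if not meta_files:
        raise FileNotFoundError(f"no *_metadata.json found in {directory}")
    meta = json.loads(meta_files[0].read_text())
    eye = meta["eye_id"]
    angles = meta.get("scan_angles_deg", [k * 30.0 for k in range(RadialScanSet.N_SCANS)])

    scans: list[BScan] = []
    segmentations: list[LayerSegmentation] = []
    for k in range(RadialScanSet.N_SCANS):
        tif = directory / f"{eye}_scan{k}.tif"
        csv = directory / f"{eye}_scan{k}_boundaries.csv"
        for path in (tif, csv):
            if not path.exists():
                raise FileNotFoundError(f"missing scan file: {path}")
        img = tifffile.imread(tif).astype(float)
        label = f"{eye}_scan{k}"
        seg = LayerSegmentation(
            _boundaries_from_frame(pd.read_csv(csv), label), label=label
        )
        scans.append(
            BScan(
                reflectivity=img,
                axial_spacing_um=float(meta["axial_spacing_um"]),
                lateral_extent_mm=float(meta["lateral_extent_mm"]),
                fovea_column=int(meta["fovea_column"]),
                scan_angle_deg=float(angles[k]),
                signal_strength=int(meta["signal_strength"]),
                eye_id=eye,
                subject_id=meta["subject_id"],
                group_label=meta["group"],
            )
        )
        segmentations.append(seg)
    return RadialScanSet(scans=scans, segmentations=segmentations)


def write_scan_set(scan_set: RadialScanSet, directory_path: str | Path) -> Path:
    """Write a scan set in the directory layout that :func:`read_scan_set` reads.

    Reflectivity is stored as 16-bit TIFF, so values are rounded to integers
    in 0..65535; generators producing integral intensities round-trip exactly.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    first = scan_set.scans[0]
    eye = first.eye_id or "eye"

    for k, (scan, seg) in enumerate(zip(scan_set.scans, scan_set.segmentations)):
        img = np.clip(np.round(scan.reflectivity), 0, 65535).astype(np.uint16)
        tifffile.imwrite(directory / f"{eye}_scan{k}.tif", img)
        rows = []
        for bi, bname in enumerate(BOUNDARY_NAMES):
            for col in range(seg.n_columns):
                rows.append((k, col, bname, seg.boundaries[bi, col]))
        pd.DataFrame(rows, columns=["scan", "column", "boundary", "row"]).to_csv(
            directory / f"{eye}_scan{k}_boundaries.csv", index=False
        )

    meta = {
        "axial_spacing_um": first.axial_spacing_um,
        "lateral_extent_mm": first.lateral_extent_mm,
        "fovea_column": first.fovea_column,
        "signal_strength": min(s.signal_strength for s in scan_set.scans),
        "eye_id": eye,
        "subject_id": first.subject_id,
        "group": first.group_label,
        "scan_angles_deg": [s.scan_angle_deg for s in scan_set.scans],
    }
    (directory / f"{eye}_metadata.json").write_text(json.dumps(meta, indent=1))
    return directory


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write an eye × layer × region × metric long table as CSV."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    path = Path(path)
    table.to_csv(path, index=False, columns=FEATURE_COLUMNS)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    return df
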