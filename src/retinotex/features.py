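"""Per-layer tissue metrics: thickness, GLCM contrast, power-spectrum fractal
dimension, layer index and total reflectance.

All reflectance-derived metrics expect NRPE-normalized input (see
:mod:`retinotex.preprocess`) and are then invariant to any global gain
applied to the raw image:

* the fractal dimension depends only on the log-spectrum slope;
* layer index divides by the image's own 99th-percentile reflectivity;
* total reflectance in dB shifts by a constant under gain, which NRPE
  removes;
* contrast is computed on a quantization grid anchored to the image's own
  99th percentile.

Undefined metrics (empty ROI, no valid pixel pairs, non-positive mean
reflectance) are reported as NaN sentinels, never as 0 — zero is a valid
contrast value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import REGION_NAMES, LayerROI, build_layer_roi
from .types import (
    BScan,
    INNER_LAYERS,
    LAYER_NAMES,
    LayerSegmentation,
    RadialScanSet,
)

__all__ = [
    "MetricValue",
    "FeatureConfig",
    "thickness",
    "glcm_contrast",
    "fractal_dimension",
    "total_reflectance",
    "layer_index",
    "extract_features",
    "build_across_all_roi",
]

_UNDEFINED = float("nan")


@dataclass(frozen=True)
class MetricValue:
    """One metric evaluated on one ROI; NaN value means undefined."""

    metric: str
    value: float
    n_columns_used: int

    @property
    def is_defined(self) -> bool:
        return np.isfinite(self.value)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the texture/optics metrics."""

    #: number of gray levels for co-occurrence quantization
    glcm_levels: int = 64
    #: pixel offsets pooled into one symmetric co-occurrence matrix
    glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0))
    #: quantile of the scan image anchoring the quantization range
    glcm_range_quantile: float = 0.99
    #: minimum axial profile length (samples) admissible for the FD fit
    fd_min_len: int = 8
    #: quantile defining the saturation reflectivity I_sa of the layer index
    isa_quantile: float = 0.99


def thickness(roi: LayerROI, axial_spacing_um: float) -> MetricValue:
    """Mean layer thickness over the ROI's columns, in micrometres."""
    if roi.is_empty:
        return MetricValue("thickness_um", _UNDEFINED, 0)
    value = float(roi.heights_px.mean()) * axial_spacing_um
    return MetricValue("thickness_um", value, len(roi.columns))


def glcm_contrast(
    roi: LayerROI,
    n_levels: int = 64,
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0)),
    range_quantile: float = 0.99,
) -> MetricValue:
    """Second-order (co-occurrence) texture contrast of the ROI.

    Reflectivity is quantized to ``n_levels`` equal-width bins over the fixed
    range ``[0, q]`` where ``q`` is the scan image's ``range_quantile``
    quantile (values above ``q`` saturate into the top bin).  A single
    symmetric co-occurrence matrix is accumulated over all ``offsets``,
    counting only pixel pairs that both lie inside the ROI; contrast is
    ``sum((i - j)**2 * p(i, j))`` with ``p`` normalized to total 1.
    """
    if roi.is_empty:
        return MetricValue("contrast_au", _UNDEFINED, 0)
    img = roi.scan.reflectivity
    q = float(np.quantile(img, range_quantile))
    if q <= 0:
        return MetricValue("contrast_au", _UNDEFINED, 0)
    levels = np.minimum((img / q * n_levels).astype(int), n_levels - 1)
    mask = roi.mask()

    glcm = np.zeros((n_levels, n_levels))
    n_pairs = 0
    for dr, dc in offsets:
        a_rows = slice(None, -dr if dr else None)
        b_rows = slice(dr, None)
        a_cols = slice(None, -dc if dc else None)
        b_cols = slice(dc, None)
        pair_mask = mask[a_rows, a_cols] & mask[b_rows, b_cols]
        i = levels[a_rows, a_cols][pair_mask]
        j = levels[b_rows, b_cols][pair_mask]
        np.add.at(glcm, (i, j), 1)
        np.add.at(glcm, (j, i), 1)
        n_pairs += i.size
    if n_pairs == 0:
        return MetricValue("contrast_au", _UNDEFINED, 0)

    p = glcm / glcm.sum()
    idx = np.arange(n_levels)
    contrast = float((((idx[:, None] - idx[None, :]) ** 2) * p).sum())
    return MetricValue("contrast_au", contrast, len(roi.columns))


def _fd_of_profile(profile: np.ndarray) -> float | None:
    """Power-spectrum fractal dimension of one axial profile, or None."""
    x = profile - profile.mean()
    if np.allclose(x, 0):
        return None
    power = np.abs(np.fft.rfft(x)) ** 2
    # positive frequencies only: the DC bin is zero after mean removal
    omega = np.arange(1, len(power))
    p = power[1:]
    keep = p > 0
    if keep.sum() < 2:
        return None
    slope, _ = np.polyfit(np.log(omega[keep]), np.log(p[keep]), 1)
    beta = -slope
    return (5.0 - beta) / 2.0


def fractal_dimension(roi: LayerROI, min_len: int = 8) -> MetricValue:
    """Mean power-spectrum fractal dimension of the ROI's axial profiles.

    For each included column the layer-internal reflectance profile is
    mean-detrended and Fourier transformed; a least-squares line fitted to
    ``ln P(omega)`` versus ``ln omega`` over the positive discrete
    frequencies gives the spectral exponent ``beta`` (the negated slope),
    and the profile's fractal dimension is ``(5 - beta) / 2``.  Columns
    shorter than ``min_len`` samples or with zero variance are skipped; the
    ROI value is the unweighted mean over admissible columns.
    """
    if roi.is_empty:
        return MetricValue("fractal_dimension_au", _UNDEFINED, 0)
    fds = []
    for profile in roi.column_profiles():
        if len(profile) < min_len:
            continue
        fd = _fd_of_profile(profile)
        if fd is not None:
            fds.append(fd)
    if not fds:
        return MetricValue("fractal_dimension_au", _UNDEFINED, 0)
    return MetricValue("fractal_dimension_au", float(np.mean(fds)), len(fds))


def total_reflectance(roi: LayerROI, axial_spacing_um: float | None = None) -> MetricValue:
    """Total reflectance of the layer in decibels.

    Per column ``k`` the total reflectance is the sum of (normalized)
    reflectivity values over the layer interval — equivalently the column's
    mean reflectance times its pixel height ``H_k / dy``.  The ROI value is
    ``10 * log10`` of the mean of the per-column sums.
    """
    if roi.is_empty:
        return MetricValue("total_reflectance_db", _UNDEFINED, 0)
    sums = np.array([p.sum() for p in roi.column_profiles()])
    mean_tr = sums.mean()
    if mean_tr <= 0:
        return MetricValue("total_reflectance_db", _UNDEFINED, 0)
    return MetricValue(
        "total_reflectance_db", float(10.0 * np.log10(mean_tr)), len(roi.columns)
    )


def layer_index(
    roi: LayerROI, scan: BScan | None = None, isa_quantile: float = 0.99
) -> MetricValue:
    """Layer index: column-summed reflectance normalized by ``I_sa``.

    ``I_sa`` is the reflectivity value at the ``isa_quantile`` (99th
    percentile) of the whole scan image — a robust stand-in for the
    saturation level.  Per column, ``LI_k = MR_k * H_k / I_sa`` with the
    height in pixels, which reduces to the column's reflectivity sum divided
    by ``I_sa``; the ROI value is the mean over included columns.
    """
    if roi.is_empty:
        return MetricValue("layer_index_au", _UNDEFINED, 0)
    scan = scan if scan is not None else roi.scan
    isa = float(np.quantile(scan.reflectivity, isa_quantile))
    if isa == 0:
        raise ValueError("I_sa is zero: image has no signal")
    lis = np.array([p.sum() / isa for p in roi.column_profiles()])
    return MetricValue("layer_index_au", float(lis.mean()), len(roi.columns))


def build_across_all_roi(
    scan: BScan,
    segmentation: LayerSegmentation,
    layer_name: str,
    excluded_columns: frozenset[int] | set[int] | None = None,
) -> LayerROI:
    """ROI pooling the union of all macular regions permitted for a layer.

    Inner layers draw from the foveal, parafoveal and perifoveal annuli;
    outer layers additionally include the foveolar disc.  Pooling columns
    (rather than averaging region means) keeps the across-regions value
    consistent with the pooled per-column mean.
    """
    region_names = [
        r
        for r in REGION_NAMES
        if not (r == "foveolar" and layer_name in INNER_LAYERS)
    ]
    parts = [
        build_layer_roi(scan, segmentation, layer_name, r, excluded_columns)
        for r in region_names
    ]
    columns = np.concatenate([p.columns for p in parts])
    order = np.argsort(columns)
    return LayerROI(
        layer_name=layer_name,
        region_name="across_all",
        columns=columns[order],
        top_rows=np.concatenate([p.top_rows for p in parts])[order],
        bottom_rows=np.concatenate([p.bottom_rows for p in parts])[order],
        scan=scan,
    )


def _roi_metrics(
    roi: LayerROI, axial_spacing_um: float, config: FeatureConfig
) -> list[MetricValue]:
    return [
        thickness(roi, axial_spacing_um),
        glcm_contrast(
            roi, config.glcm_levels, config.glcm_offsets, config.glcm_range_quantile
        ),
        fractal_dimension(roi, config.fd_min_len),
        total_reflectance(roi),
        layer_index(roi, isa_quantile=config.isa_quantile),
    ]


def extract_features(
    scan_set: RadialScanSet,
    shadow_columns: list[frozenset[int]] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Eye-level feature table from a preprocessed (gated, NRPE) scan set.

    Every permitted layer × region pair — the four macular zones under the
    foveolar outer-layer restriction, plus the pooled ``across_all``
    aggregate — is evaluated per scan for all five metrics, then averaged
    across the six radial scans into one row per (layer, region, metric).
    GCC rows are computed on the composite ILM → GCL+IPL/INL interval, not
    by summing sub-layer metrics.  Metrics undefined in every scan are
    reported as missing (NaN).
    """
    if shadow_columns is None:
        shadow_columns = [frozenset()] * len(scan_set.scans)
    first = scan_set.scans[0]
    dy = scan_set.axial_spacing_um

    rows = []
    for layer in LAYER_NAMES:
        regions = [
            r for r in REGION_NAMES if not (r == "foveolar" and layer in INNER_LAYERS)
        ]
        for region in [*regions, "across_all"]:
            per_metric: dict[str, list[MetricValue]] = {}
            for scan, seg, shadow in zip(
                scan_set.scans, scan_set.segmentations, shadow_columns
            ):
                if region == "across_all":
                    roi = build_across_all_roi(scan, seg, layer, shadow)
                else:
                    roi = build_layer_roi(scan, seg, layer, region, shadow)
                for mv in _roi_metrics(roi, dy, config):
                    per_metric.setdefault(mv.metric, []).append(mv)
            for metric, values in per_metric.items():
                defined = [v for v in values if v.is_defined]
                rows.append(
                    {
                        "eye": first.eye_id,
                        "subject": first.subject_id,
                        "group": first.group_label,
                        "layer": layer,
                        "region": region,
                        "metric": metric,
                        "value": float(np.mean([v.value for v in defined]))
                        if defined
                        else _UNDEFINED,
                        "n_columns_used": int(sum(v.n_columns_used for v in values)),
                    }
                )
    return pd.DataFrame(rows)
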