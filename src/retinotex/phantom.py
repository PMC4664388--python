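"""Synthetic layered B-scan phantom: a testable stand-in for patient scans.

The generator emulates the macular map acquisition protocol — six
fovea-centred radial scans of 6 mm transverse length, 1024 axial pixels at
2 μm spacing — over a radially symmetric seven-layer retina with a foveal
pit (inner layers taper to zero thickness through a raised-cosine profile)
and a modest outer-layer thickening at the centre.

Reflectivity in each layer is its base level modulated by per-column 1/f^β
axial texture, multiplied by gamma-distributed speckle (mean 1), with
vessel shadows applied multiplicatively beneath the inner vasculature.  The
generator rounds intensities to integer device units so that writing and
re-reading 16-bit TIFFs is an exact round trip, and a fixed seed reproduces
the scan set bit-exactly.

Alongside the scan set a ground-truth sidecar records the true per-layer /
per-region thicknesses, the planted shadow columns and the per-layer
spectral exponents, so downstream stages can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import REGION_NAMES, REGIONS
from .types import (
    BOUNDARY_NAMES,
    BScan,
    INNER_LAYERS,
    LayerSegmentation,
    RadialScanSet,
)

__all__ = ["PhantomSpec", "generate_phantom_eye", "power_law_profile"]

#: The seven anatomical layers in axial order (GCC is a composite, not drawn).
_DRAWN_LAYERS = ("RNFL", "GCL+IPL", "INL", "OPL", "ONL+IS", "OS", "RPE")


def _default_thickness() -> dict[str, float]:
    # peripheral thicknesses (μm), healthy-macula magnitudes
    return {
        "RNFL": 38.0,
        "GCL+IPL": 76.0,
        "INL": 35.0,
        "OPL": 41.0,
        "ONL+IS": 86.0,
        "OS": 16.0,
        "RPE": 13.0,
    }


def _default_reflectivity() -> dict[str, float]:
    # base reflectivity relative to the RPE (the brightest band)
    return {
        "RNFL": 0.85,
        "GCL+IPL": 0.45,
        "INL": 0.35,
        "OPL": 0.55,
        "ONL+IS": 0.30,
        "OS": 0.65,
        "RPE": 1.00,
    }


def _default_beta() -> dict[str, float]:
    # axial-texture spectral exponents; mid-range roughness everywhere
    return {name: 1.0 for name in _DRAWN_LAYERS}


def _default_bump() -> dict[str, float]:
    # outer layers thicken under the pit (photoreceptor packing at the fovea)
    return {"ONL+IS": 37.0, "OS": 10.0}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic eye; the defaults are the study geometry."""

    n_columns: int = 512
    n_rows: int = 1024
    axial_spacing_um: float = 2.0
    lateral_extent_mm: float = 6.0
    fovea_column: int | None = None  # defaults to the centre column
    ilm_offset_um: float = 300.0
    #: peripheral thickness per layer, μm
    layer_thickness_um: dict[str, float] = field(default_factory=_default_thickness)
    #: full pit radius, mm: inner layers reach zero thickness at the centre
    pit_radius_mm: float = 0.75
    #: extra central thickness of outer layers, μm
    foveal_bump_um: dict[str, float] = field(default_factory=_default_bump)
    #: base reflectivity per layer, relative units (RPE = 1)
    layer_reflectivity: dict[str, float] = field(default_factory=_default_reflectivity)
    vitreous_reflectivity: float = 0.03
    choroid_reflectivity: float = 0.25
    #: spectral exponent of the per-column 1/f^β axial texture, per layer
    layer_beta: dict[str, float] = field(default_factory=_default_beta)
    texture_amplitude: float = 0.25
    #: gamma shape of multiplicative speckle (mean 1); larger = milder,
    #: ``None`` disables speckle entirely
    speckle_shape: float | None = 8.0
    #: columns darkened by vessel shadows, and the multiplicative depth factor
    shadow_columns: tuple[int, ...] = (96, 97, 98, 99, 100, 330, 331, 332, 333)
    shadow_depth_factor: float = 0.45
    #: device gain mapping relative reflectivity to 16-bit counts
    gain: float = 380.0
    signal_strength: int = 9
    eye_id: str = "phantom"
    subject_id: str = "subject"
    group_label: str = "H"
    seed: int = 0


def power_law_profile(
    n: int, beta: float, rng: np.random.Generator, amplitude_noise: bool = False
) -> np.ndarray:
    """Zero-mean profile whose power spectrum follows ``P(ω) ∝ ω**-beta``.

    Built by inverse-transforming spectral amplitudes ``|A(ω)| ∝ ω**(-beta/2)``
    with uniformly random phases.  With ``amplitude_noise`` the amplitudes are
    additionally Rayleigh-distributed around the power law, mimicking a
    stochastic (rather than exactly scale-free) texture.
    """
    n_freq = n // 2 + 1
    omega = np.arange(1, n_freq)
    amp = omega ** (-beta / 2.0)
    if amplitude_noise:
        amp = amp * rng.rayleigh(scale=1.0, size=amp.shape)
    phases = rng.uniform(0, 2 * np.pi, size=amp.shape)
    spectrum = np.zeros(n_freq, dtype=complex)
    spectrum[1:] = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _thickness_profiles(spec: PhantomSpec, radius_mm: np.ndarray) -> dict[str, np.ndarray]:
    """True per-layer thickness (μm) as a function of radial distance."""
    profiles: dict[str, np.ndarray] = {}
    w = spec.pit_radius_mm
    taper = np.where(
        radius_mm < w, 0.5 * (1.0 - np.cos(np.pi * np.minimum(radius_mm / w, 1.0))), 1.0
    )
    bump = np.where(
        radius_mm < w, 0.5 * (1.0 + np.cos(np.pi * np.minimum(radius_mm / w, 1.0))), 0.0
    )
    for name in _DRAWN_LAYERS:
        base = spec.layer_thickness_um[name]
        if name in INNER_LAYERS:
            profiles[name] = base * taper
        else:
            profiles[name] = base + spec.foveal_bump_um.get(name, 0.0) * bump
    return profiles


def _texture_field(
    shape: tuple[int, int], beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1/f^β noise along the axial direction, independent columns."""
    n_rows, n_cols = shape
    n_freq = n_rows // 2 + 1
    omega = np.arange(1, n_freq)[:, None]
    amp = omega ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_freq - 1, n_cols))
    spectrum = np.zeros((n_freq, n_cols), dtype=complex)
    spectrum[1:] = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n_rows, axis=0)
    return x / x.std(axis=0, keepdims=True)


def generate_phantom_eye(spec: PhantomSpec) -> tuple[RadialScanSet, dict]:
    """Six synthetic radial B-scans of one eye plus a ground-truth sidecar.

    Raises ``ValueError`` when the stacked layers exceed the image depth.
    """
    rng = np.random.default_rng(spec.seed)
    fovea = spec.n_columns // 2 if spec.fovea_column is None else spec.fovea_column
    cols = np.arange(spec.n_columns)
    spacing_mm = spec.lateral_extent_mm / (spec.n_columns - 1)
    radius_mm = np.abs(cols - fovea) * spacing_mm

    thickness_um = _thickness_profiles(spec, radius_mm)
    # boundary rows (fractional): cumulative depth from the ILM offset
    boundaries = np.empty((len(BOUNDARY_NAMES), spec.n_columns))
    boundaries[0] = spec.ilm_offset_um / spec.axial_spacing_um
    for i, name in enumerate(_DRAWN_LAYERS):
        boundaries[i + 1] = boundaries[i] + thickness_um[name] / spec.axial_spacing_um
    if boundaries[-1].max() >= spec.n_rows:
        raise ValueError(
            "inconsistent geometry: layers exceed the image depth "
            f"({boundaries[-1].max():.1f} rows ≥ {spec.n_rows})"
        )

    shadow_rows_start = np.ceil(boundaries[2] - 0.5).astype(int)  # below GCL+IPL/INL
    shadow_cols = [c for c in spec.shadow_columns if 0 <= c < spec.n_columns]

    scans: list[BScan] = []
    segmentations: list[LayerSegmentation] = []
    for k in range(RadialScanSet.N_SCANS):
        img = np.full((spec.n_rows, spec.n_columns), spec.vitreous_reflectivity)
        rows = np.arange(spec.n_rows)[:, None]
        pixel_bounds = np.ceil(boundaries - 0.5).astype(int)
        img[rows >= pixel_bounds[-1][None, :]] = spec.choroid_reflectivity
        for i, name in enumerate(_DRAWN_LAYERS):
            in_layer = (rows >= pixel_bounds[i][None, :]) & (
                rows < pixel_bounds[i + 1][None, :]
            )
            texture = _texture_field(img.shape, spec.layer_beta[name], rng)
            # centre the texture within the layer interval of every column:
            # the base level alone sets the layer's radiance (laterally
            # smooth, as in real tissue) and the texture contributes purely
            # zero-mean axial roughness
            top, bot = pixel_bounds[i], pixel_bounds[i + 1]
            csum = np.vstack([np.zeros(img.shape[1]), np.cumsum(texture, axis=0)])
            height = np.maximum(bot - top, 1)
            col_idx = np.arange(img.shape[1])
            band_mean = (csum[bot, col_idx] - csum[top, col_idx]) / height
            texture = texture - band_mean[None, :]
            level = spec.layer_reflectivity[name] * (
                1.0 + spec.texture_amplitude * texture
            )
            img[in_layer] = np.maximum(level, 0.02)[in_layer]
        if spec.speckle_shape is not None:
            speckle = rng.gamma(
                shape=spec.speckle_shape, scale=1.0 / spec.speckle_shape, size=img.shape
            )
            img *= speckle
        for c in shadow_cols:
            img[shadow_rows_start[c] :, c] *= spec.shadow_depth_factor
        img = np.clip(np.round(img * spec.gain), 0, 65535)

        scans.append(
            BScan(
                reflectivity=img,
                axial_spacing_um=spec.axial_spacing_um,
                lateral_extent_mm=spec.lateral_extent_mm,
                fovea_column=fovea,
                scan_angle_deg=k * 30.0,
                signal_strength=spec.signal_strength,
                eye_id=spec.eye_id,
                subject_id=spec.subject_id,
                group_label=spec.group_label,
            )
        )
        segmentations.append(
            LayerSegmentation(boundaries.copy(), label=f"{spec.eye_id}_scan{k}")
        )

    truth = {
        "thickness_um": _true_region_thickness(spec, radius_mm, thickness_um),
        "shadow_columns": sorted(shadow_cols),
        "shadow_depth_factor": spec.shadow_depth_factor,
        "layer_beta": dict(spec.layer_beta),
        "fovea_column": fovea,
    }
    return RadialScanSet(scans=scans, segmentations=segmentations), truth


def _true_region_thickness(
    spec: PhantomSpec, radius_mm: np.ndarray, thickness_um: dict[str, np.ndarray]
) -> dict[str, dict[str, float]]:
    """Ground-truth mean thickness per layer × region (μm), plus GCC."""
    profiles = dict(thickness_um)
    profiles["GCC"] = profiles["RNFL"] + profiles["GCL+IPL"]
    out: dict[str, dict[str, float]] = {}
    for layer, prof in profiles.items():
        out[layer] = {}
        permitted = [
            r for r in REGION_NAMES if not (r == "foveolar" and layer in INNER_LAYERS)
        ]
        pooled_mask = np.zeros_like(radius_mm, dtype=bool)
        for rname in permitted:
            mask = REGIONS[rname].contains(radius_mm)
            pooled_mask |= mask
            if mask.any():
                out[layer][rname] = float(prof[mask].mean())
        out[layer]["across_all"] = float(prof[pooled_mask].mean())
    return out
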