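"""Published group-level parameters used to drive cohort simulations.

These are the reported per-group summaries (mean ± dispersion) of each
metric in the RNFL-to-RPE layers, pooled across all macular regions, for
three study arms: healthy controls (H), MS eyes without an optic-neuritis
history (MSON-) and MS eyes with one (MSON+).  The printed dispersions are
on the order of the standard error of the group mean, not of between-eye
standard deviations (e.g. < 1 μm for thickness), so the cohort generator
treats them as SEs by default and rescales to eye-level SDs via
``sigma = dispersion * sqrt(n_eyes)``.

The values serve as inputs to :mod:`retinotex.cohort`; nothing in the
package fits or reproduces them from images.
"""

from __future__ import annotations

__all__ = ["GROUP_SIZES", "ACROSS_ALL_PARAMS", "across_all_cell"]

#: group -> (n_eyes, n_subjects)
GROUP_SIZES: dict[str, tuple[int, int]] = {
    "H": (29, 24),
    "MSON-": (31, 25),
    "MSON+": (36, 26),
}

#: metric -> layer -> group -> (mean, dispersion); values pooled across all
#: macular regions.  Thickness in μm, contrast and layer index in arbitrary
#: units, fractal dimension dimensionless, total reflectance in dB (NRPE).
ACROSS_ALL_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "thickness_um": {
        "RNFL": {"H": (38.16, 0.55), "MSON-": (35.44, 0.54), "MSON+": (32.32, 0.54)},
        "GCL+IPL": {"H": (76.06, 1.44), "MSON-": (67.87, 1.40), "MSON+": (58.1, 1.40)},
        "GCC": {"H": (114.23, 1.85), "MSON-": (103.28, 1.80), "MSON+": (90.45, 1.95)},
        "INL": {"H": (35.19, 0.35), "MSON-": (35.38, 0.35), "MSON+": (35.26, 0.36)},
        "OPL": {"H": (41.70, 0.58), "MSON-": (41.58, 0.55), "MSON+": (39.92, 0.59)},
        "ONL+IS": {"H": (86.23, 1.21), "MSON-": (88.20, 1.11), "MSON+": (89.62, 1.19)},
        "OS": {"H": (16.48, 0.59), "MSON-": (16.58, 0.57), "MSON+": (16.28, 0.62)},
        "RPE": {"H": (13.15, 0.18), "MSON-": (13.58, 0.17), "MSON+": (13.21, 0.19)},
    },
    "contrast_au": {
        "RNFL": {"H": (1562, 26), "MSON-": (1663, 25), "MSON+": (1820, 27)},
        "GCL+IPL": {"H": (1531, 21), "MSON-": (1587, 21), "MSON+": (1727, 22)},
        "GCC": {"H": (3093, 43), "MSON-": (3251, 42), "MSON+": (3546, 46)},
        "INL": {"H": (1394, 31), "MSON-": (1428, 30), "MSON+": (1577, 32)},
        "OPL": {"H": (1314, 21), "MSON-": (1325, 20), "MSON+": (1426, 21)},
        "ONL+IS": {"H": (851, 15), "MSON-": (862, 14), "MSON+": (839, 15)},
        "OS": {"H": (3506, 70), "MSON-": (3561, 67), "MSON+": (3650, 73)},
        "RPE": {"H": (5264, 82), "MSON-": (5222, 80), "MSON+": (5353, 86)},
    },
    "fractal_dimension_au": {
        "RNFL": {"H": (1.621, 0.009), "MSON-": (1.637, 0.009), "MSON+": (1.655, 0.009)},
        "GCL+IPL": {"H": (1.699, 0.002), "MSON-": (1.695, 0.002), "MSON+": (1.690, 0.002)},
        "GCC": {"H": (3.321, 0.008), "MSON-": (3.332, 0.008), "MSON+": (3.344, 0.008)},
        "INL": {"H": (1.779, 0.002), "MSON-": (1.785, 0.002), "MSON+": (1.788, 0.002)},
        "OPL": {"H": (1.508, 0.002), "MSON-": (1.502, 0.002), "MSON+": (1.503, 0.002)},
        "ONL+IS": {"H": (1.778, 0.006), "MSON-": (1.788, 0.006), "MSON+": (1.794, 0.006)},
        "OS": {"H": (1.701, 0.003), "MSON-": (1.712, 0.003), "MSON+": (1.712, 0.004)},
        "RPE": {"H": (1.669, 0.002), "MSON-": (1.666, 0.002), "MSON+": (1.668, 0.002)},
    },
    "layer_index_au": {
        "RNFL": {"H": (11.06, 0.25), "MSON-": (9.28, 0.25), "MSON+": (7.90, 0.27)},
        "GCL+IPL": {"H": (13.49, 0.33), "MSON-": (11.32, 0.32), "MSON+": (9.84, 0.34)},
        "GCC": {"H": (24.56, 0.55), "MSON-": (20.62, 0.53), "MSON+": (17.70, 0.57)},
        "INL": {"H": (4.37, 0.13), "MSON-": (3.97, 0.13), "MSON+": (3.98, 0.14)},
        "OPL": {"H": (6.39, 0.20), "MSON-": (5.84, 0.20), "MSON+": (5.57, 0.21)},
        "ONL+IS": {"H": (7.49, 0.23), "MSON-": (6.67, 0.22), "MSON+": (6.83, 0.24)},
        "OS": {"H": (6.05, 0.14), "MSON-": (5.70, 0.13), "MSON+": (5.67, 0.14)},
        "RPE": {"H": (6.47, 0.08), "MSON-": (6.55, 0.07), "MSON+": (6.45, 0.08)},
    },
    "total_reflectance_db": {
        "RNFL": {"H": (21.52, 0.26), "MSON-": (19.90, 0.26), "MSON+": (18.54, 0.28)},
        "GCL+IPL": {"H": (22.50, 0.29), "MSON-": (20.76, 0.28), "MSON+": (19.62, 0.30)},
        "GCC": {"H": (45.72, 0.53), "MSON-": (42.14, 0.51), "MSON+": (39.4, 0.56)},
        "INL": {"H": (13.03, 0.30), "MSON-": (12.10, 0.29), "MSON+": (12.17, 0.31)},
        "OPL": {"H": (14.30, 0.29), "MSON-": (13.52, 0.28), "MSON+": (13.48, 0.30)},
        "ONL+IS": {"H": (16.98, 0.32), "MSON-": (15.99, 0.31), "MSON+": (16.28, 0.34)},
        "OS": {"H": (15.89, 0.21), "MSON-": (15.3, 0.20), "MSON+": (15.20, 0.22)},
        "RPE": {"H": (16.43, 0.10), "MSON-": (16.58, 0.09), "MSON+": (16.45, 0.10)},
    },
}


def across_all_cell(metric: str, layer: str) -> dict[str, tuple[float, float]]:
    """Group parameters (mean, dispersion) of one metric × layer cell."""
    return ACROSS_ALL_PARAMS[metric][layer]
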