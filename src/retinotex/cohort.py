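"""Cohort-level feature simulation with within-subject (inter-eye) correlation.

Eye-level metric values are drawn from a random-intercept model: each
subject receives a shared intercept with variance ``rho * sigma**2`` and
each eye an independent residual with variance ``(1 - rho) * sigma**2``, so
the marginal eye-level variance is ``sigma**2`` and two eyes of one subject
correlate at ``rho``.  This is exactly the dependence structure that the
mixed-model comparison stage is designed to absorb.

Published group summaries print dispersions on the scale of standard errors
of the group mean; with ``dispersion_is_se`` (the default) they are rescaled
to eye-level standard deviations via ``sigma = dispersion * sqrt(n_eyes)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_params import ACROSS_ALL_PARAMS, GROUP_SIZES

__all__ = ["CohortSpec", "generate_cohort_features", "default_across_all_cells"]


def default_across_all_cells() -> dict[tuple[str, str, str], dict[str, tuple[float, float]]]:
    """All published across-all-regions cells as (layer, region, metric) keys."""
    cells = {}
    for metric, per_layer in ACROSS_ALL_PARAMS.items():
        for layer, groups in per_layer.items():
            cells[(layer, "across_all", metric)] = dict(groups)
    return cells


@dataclass
class CohortSpec:
    """Group sizes and per-cell group parameters driving the simulation.

    ``cells`` maps ``(layer, region, metric)`` to ``{group: (mean,
    dispersion)}``.  ``group_sizes`` maps group to ``(n_eyes, n_subjects)``
    with ``n_subjects <= n_eyes <= 2 * n_subjects`` (eyes beyond one per
    subject are second eyes of the first subjects).
    """

    group_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(GROUP_SIZES)
    )
    cells: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = field(
        default_factory=default_across_all_cells
    )
    #: between-eye within-subject correlation of each metric
    rho: float = 0.5
    #: printed dispersions are standard errors; rescale by sqrt(n_eyes)
    dispersion_is_se: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        for group, (n_eyes, n_subjects) in self.group_sizes.items():
            if n_subjects > n_eyes:
                raise ValueError(f"group {group}: more subjects than eyes")
            if n_eyes > 2 * n_subjects:
                raise ValueError(f"group {group}: more than two eyes per subject")


def _eye_roster(group: str, n_eyes: int, n_subjects: int) -> list[tuple[str, str]]:
    """(eye_id, subject_id) pairs; the first eyes' subjects contribute both eyes."""
    roster = []
    n_bilateral = n_eyes - n_subjects
    eye_counter = 0
    for s in range(n_subjects):
        n = 2 if s < n_bilateral else 1
        for _ in range(n):
            roster.append((f"{group}_eye{eye_counter:03d}", f"{group}_subj{s:03d}"))
            eye_counter += 1
    return roster


def generate_cohort_features(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate an eye-level feature table plus the generating ground truth.

    Returns a long table in the standard feature schema and a dict recording
    the eye-level SD used per cell and group, the rosters, and ``rho``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sigmas: dict[str, dict[str, float]] = {}

    rosters = {
        g: _eye_roster(g, n_eyes, n_subj)
        for g, (n_eyes, n_subj) in spec.group_sizes.items()
    }

    for (layer, region, metric), groups in spec.cells.items():
        cell_key = f"{layer}|{region}|{metric}"
        sigmas[cell_key] = {}
        for group, (mean, dispersion) in groups.items():
            if group not in rosters:
                continue
            n_eyes, _ = spec.group_sizes[group]
            sigma = dispersion * np.sqrt(n_eyes) if spec.dispersion_is_se else dispersion
            if sigma <= 0:
                raise ValueError(
                    f"non-positive dispersion for {cell_key} in group {group}"
                )
            sigmas[cell_key][group] = float(sigma)
            roster = rosters[group]
            subjects = sorted({subj for _, subj in roster})
            intercepts = dict(
                zip(
                    subjects,
                    rng.normal(0.0, np.sqrt(spec.rho) * sigma, size=len(subjects)),
                )
            )
            residuals = rng.normal(0.0, np.sqrt(1.0 - spec.rho) * sigma, size=len(roster))
            for (eye, subj), resid in zip(roster, residuals):
                rows.append(
                    {
                        "eye": eye,
                        "subject": subj,
                        "group": group,
                        "layer": layer,
                        "region": region,
                        "metric": metric,
                        "value": mean + intercepts[subj] + resid,
                        "n_columns_used": 0,
                    }
                )

    truth = {
        "rho": spec.rho,
        "sigma_eye_level": sigmas,
        "group_sizes": dict(spec.group_sizes),
        "dispersion_is_se": spec.dispersion_is_se,
    }
    return pd.DataFrame(rows), truth
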