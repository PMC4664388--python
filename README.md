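# retinotex

Layer-resolved **texture and optical-property analysis of macular OCT
B-scans**, built around the question of whether reflectance-based tissue
descriptors — not just thickness — separate the retinas of multiple-sclerosis
patients from healthy controls, and eyes with an optic-neuritis (ON) history
from those without.

The package takes segmented radial scan sets (six fovea-centred B-scans per
eye, eight boundary curves delimiting seven intraretinal layers), applies a
standardized preprocessing chain, and quantifies every layer within four
concentric macular zones (foveolar 0.375 mm, foveal 1.85 mm, parafoveal
2.85 mm, perifoveal 5.85 mm diameters) with five metrics:

| metric | definition |
| --- | --- |
| thickness | mean boundary separation × axial pixel pitch Δy (μm) |
| contrast | co-occurrence (second-order) texture contrast Σ (i−j)² p(i,j) |
| fractal dimension | FD = (5 − β)/2, with β the slope of ln P(ω) vs ln ω of each A-scan's within-layer reflectance profile |
| total reflectance | TRₖ = MRₖ·Hₖ/Δy (column-summed NRPE reflectance), reported as 10·log₁₀(TR) dB |
| layer index | LIₖ = MRₖ·Hₖ / I_sa, with I_sa the image's 99th-percentile reflectivity |

Preprocessing: complex-diffusion speckle denoising → blood-vessel shadow
exclusion via a shadowgram over the outer-retina band → normalization of the
image to the mean reflectance of the RPE reference layer (NRPE) → a scan
quality gate (centre-point-thickness SD ≤ 10% across the six radial scans
and device signal strength ≥ 7).

Group inference mirrors the clinical study design: each (layer, region,
metric) cell is compared across healthy (H), MSON− and MSON+ arms with a
linear mixed model (`value ~ group` + random intercept per subject, REML) to
absorb inter-eye correlation, with pairwise Wald contrasts at the strict
threshold p < 0.001.

No raw patient scans are available, so the package ships two synthetic
generators that make every stage testable offline:

* a **B-scan phantom** (`retinotex.phantom`) — seven layers with a
  raised-cosine foveal pit, per-layer 1/fᵝ axial texture with controllable
  spectral exponent, multiplicative gamma speckle, planted vessel shadows,
  and a ground-truth sidecar;
* a **cohort generator** (`retinotex.cohort`) — eye-level metric draws around
  published group means with subject-level random intercepts (inter-eye
  correlation ρ), using the printed group dispersions rescaled from standard
  errors to eye-level SDs.

## Worked example

```sh
python analysis/01_simulate_phantom.py
python analysis/02_extract_features.py
python analysis/03_simulate_cohort.py
python analysis/04_group_comparison.py
```

Script 01 writes a synthetic eye at the full acquisition geometry (512
columns over 6 mm, 1024 axial pixels at 2 μm) and reports its quality gate:

```
CPT values (um): [149.0, 149.0, 149.0, 149.0, 149.0, 149.0], sd% = 0.00, SQF = 1
quality gate: accepted
planted shadow columns: [96, 97, 98, 99, 100, 330, 331, 332, 333]
```

Script 02 runs the preprocessing chain and recovers the planted anatomy; the
detected shadow set covers every planted column (the extra entries are the
one-column dilation at each run edge), and thickness errors stay within one
axial pixel:

```
detected shadow columns (union over scans): [95, 96, ..., 101, 329, ..., 334]
  RNFL     across_all  measured   35.13  true   35.21
  GCL+IPL  across_all  measured   70.27  true   70.42
  GCC      across_all  measured  105.40  true  105.64
```

Scripts 03–04 simulate the three-arm cohort from the published group
parameters and run the mixed-model comparison. The ganglion-cell-family
separations come out exactly as in the clinical data — e.g. for RNFL across
all macular regions:

```
thickness_um           RNFL  H vs MSON+: diff= -6.19 p= 7.78e-12  significant (p<0.001)
layer_index_au         RNFL  H vs MSON+: diff= -2.79 p= 9.34e-14  significant (p<0.001)
total_reflectance_db   RNFL  H vs MSON+: diff= -3.27 p= 3.22e-16  significant (p<0.001)
```

i.e. the MSON+ retinas are thinner, darker (lower layer index) and less
reflective in the nerve-fibre layer, while null cells (e.g. INL thickness)
stay non-significant.

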