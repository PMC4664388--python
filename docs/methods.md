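# Methods

## Data model and coordinate conventions

A B-scan is a matrix of non-negative reflectivity values, rows indexing
axial depth with row 0 on the vitreous side, columns indexing lateral
position. Eight named boundary curves (ILM, RNFL/GCL+IPL, GCL+IPL/INL,
INL/OPL, OPL/ONL+IS, ONL+IS/OS, OS/RPE, RPE/choroid) delimit seven layers;
boundary rows are fractional and must be monotonically non-decreasing from
the ILM outward in every column (a layer may collapse to zero height, as the
inner layers do in the foveal pit, but never to negative height). The
composite GCC (ganglion cell complex) spans the ILM to the GCL+IPL/INL
boundary and is always computed on that composite interval, never by summing
sub-layer metrics (thickness is the one metric for which the two agree, and
that identity is tested).

Fractional boundaries resolve to pixels through one rule applied to both
interval endpoints: pixel *j* belongs to the layer whose half-open interval
contains *j* + 0.5, i.e. endpoints map through ⌈b − 0.5⌉. Because top and
bottom use the same rule, per-column pixel heights of adjacent layers sum
exactly to the total span — no pixel is double-counted or dropped.

Total retinal thickness spans the ILM to the OS/RPE junction; the
RPE/choroid boundary exists only to delimit the RPE layer itself.

Macular zones are concentric around the foveal centre column with radii
0.1875 / 0.925 / 1.425 / 2.925 mm (foveolar, foveal, parafoveal,
perifoveal), half-open in radial distance; columns at or beyond 2.925 mm
belong to no zone. Radial distance uses the column pitch
`lateral_extent_mm / (n_columns − 1)`. In the foveolar disc only the outer
layers (ONL+IS, OS, RPE) are quantified, because the pit displaces the inner
retina sideways. The "across all macular regions" aggregate pools the
*columns* of all permitted zones (inner layers: foveal + parafoveal +
perifoveal; outer layers: + foveolar) rather than averaging zone means —
pooling is the only convention under which the aggregate is consistent with
the per-column mean. The dataset description leaves this averaging
unspecified; this is our choice.

## Preprocessing

Order: denoise → vessel-shadow detection → NRPE normalization → metrics.
Shadows are found before normalization so attenuated columns cannot bias the
RPE reference mean.

**Speckle denoising** uses nonlinear complex diffusion: the image evolves
under dI/dt = div(c·∇I) with c = e^{iθ} / (1 + (Im(I)/kθ)²), θ = π/30, and
k = `edge_threshold` × image maximum. For small θ the imaginary part
approximates a smoothed second derivative, so diffusivity drops at ramp
edges and layer boundaries are not displaced. The scheme computes one flux
per pixel edge with zero-flux borders, so the image mean is conserved
exactly; a constant image and zero iterations are both identities. Defaults
(10 iterations, time step 0.2, edge threshold 0.1 of the image maximum) were
chosen for stability — the source this filter comes from does not publish
parameters — and are exposed as function arguments.

**Vessel shadows**: the shadowgram s(k) is the per-column mean reflectivity
over the outer-retina band (OPL/ONL+IS boundary to RPE/choroid), where
shadows cast by the inner vasculature attenuate everything. A column is
flagged when s(k) < 0.75 × median(s); contiguous flagged runs are dilated by
one column per side to catch the penumbra. The threshold factor is a design
default (no published rule exists); at the phantom's default shadow depth
(×0.45) detection is complete with false positives confined to the dilation
allowance.

**NRPE**: every pixel is divided by the scan's mean RPE-layer reflectivity
(shadow columns excluded from the reference). Normalization is per scan, not
per eye — the study does not say which; per-scan is the choice here because
it also cancels scan-to-scan gain drift within an eye. NRPE is idempotent
and makes all reflectance metrics invariant to global gain.

**Quality gate**: the centre-point thickness (CPT) is the total retinal
thickness at the foveal centre column of each of the six radial scans; the
scan quality factor SQF is 1 iff 100·SD(CPT)/mean(CPT) ≤ 10% with the
*sample* SD (the published worked value 24.49/210 implies ddof = 1). A scan
set is accepted iff SQF = 1 and every scan's signal strength is ≥ 7.

## Metrics

* **Thickness**: mean over included columns of the pixel-interval height ×
  Δy (μm).
* **Contrast**: reflectivity is quantized to 64 equal-width bins over
  [0, q99] of the scan image (values above q99 saturate); a single symmetric
  co-occurrence matrix pooled over offsets (0,1) and (1,0) counts only pairs
  with both pixels inside the ROI; contrast = Σ (i−j)² p(i,j). Anchoring the
  range to the image's own quantile makes the quantization gain-free.
* **Fractal dimension**: per column, the within-layer profile is
  mean-detrended, its discrete power spectrum fitted by least squares in
  log-log over all positive frequencies up to Nyquist (no window — profiles
  are short), β = −slope, FD = (5 − β)/2; the ROI value is the unweighted
  mean over admissible columns (length-weighting is a road not taken;
  unweighted matches per-A-scan averaging). Columns shorter than 8 samples
  or with zero variance are skipped. Consequence: at 2 μm pitch the ~13 μm
  RPE is 6–7 px and its FD is reported missing.
* **Total reflectance**: per column the sum of NRPE reflectivity over the
  layer interval (= MRₖ·Hₖ/Δy); the ROI value is 10·log₁₀ of the *linear*
  mean of per-column sums, converted to dB after averaging (the alternative,
  averaging dB values, is not used; the published definition sums first).
* **Layer index**: I_sa is the 99th-percentile reflectivity of the whole
  scan image; LIₖ = column sum / I_sa, i.e. MRₖ·Hₖ/I_sa with H in pixels —
  the published identity N_k = H_k forces the pixel-unit reading.

Undefined metrics (empty ROI, no co-occurring pairs, non-positive mean
reflectance) are missing values, never 0 — zero is a valid contrast.
Eye-level values average each metric over the six radial scans, defined
scans only.

## Synthetic phantom

The phantom emulates the acquisition protocol: six fovea-centred radial
scans, 6 mm transverse, 512 columns (≈11.7 μm/column), 1024 axial pixels at
2 μm. Peripheral layer thicknesses default to healthy-macula magnitudes
(RNFL 38, GCL+IPL 76, INL 35, OPL 41, ONL+IS 86, OS 16, RPE 13 μm); inner
layers taper to zero inside the pit (radius 0.75 mm) through a raised
cosine; ONL+IS and OS thicken toward the centre (+37/+10 μm) so the foveal
depression has realistic outer-retina anatomy and a sensible CPT.

Reflectivity in each layer is base level × (1 + a·g) × speckle, with g a
unit-variance per-column 1/fᵝ field (a = 0.25), speckle multiplicative
gamma noise with mean 1 and shape 8 (contrast ≈ 0.35), and vessel shadows
applied multiplicatively (×0.45 by default) to everything beneath the
GCL+IPL/INL boundary at the planted columns. The 1/fᵝ field is re-centred
within each layer's interval per column, so the base level alone sets layer
radiance: without this, the texture's low-frequency power appears as
lateral brightness jitter between columns — unphysical for real tissue and
enough to confound the shadowgram. Intensities are rounded to integer
device counts (gain 380), so writing/reading 16-bit TIFFs is an exact round
trip and a fixed seed reproduces a scan set bit-exactly.

What the phantom does *not* model: optical physics (coherence, depth-
dependent attenuation, defocus), motion and tilt, pathology (microcystic
edema), laterally correlated speckle, curved retinal geometry. Passing
tests therefore demonstrate the correctness of the measurement chain on
data with known truth, not performance on device images.

### Limitations of the texture chain

Two effects bound what the planted spectral exponent can show downstream.
First, multiplicative speckle adds an (approximately) white spectral floor
to every within-layer profile; in the short windows a layer affords
(≈20–60 samples) the floor dominates the power-law tail above β ≈ 1, so at
full defaults the measured FD as a function of planted β is U-shaped rather
than monotone. Second, the diffusion denoiser preferentially removes
rough (low-β) fluctuation and smears boundary transitions, which distorts —
and can invert — spectral ordering between layers. The β-tracking property
is therefore validated where it is well-posed: speckle-free phantoms,
NRPE-normalized but not diffusion-smoothed, where mean measured FD decreases
strictly with planted β across 0.5–2.5. The estimator itself is validated
separately on pure power-law profiles, where it recovers (5 − β)/2 to
within 0.05 across the same range.

## Cohort generator

Eye-level values follow a random-intercept model: subject intercept with
variance ρσ², eye residual with variance (1−ρ)σ², so the marginal variance
is σ² and two eyes of one subject correlate at ρ (default 0.5 — the true
inter-eye correlation is unreported; 0.5 is a mid-range clinical
assumption). Group sizes default to the published 29/31/36 eyes from
24/25/26 subjects; extra eyes are second eyes of the first subjects.
Printed group dispersions (< 2 μm for thickness) are implausible as
between-eye SDs and are treated as standard errors of the group mean,
rescaled to eye-level SDs via σ = dispersion·√n_eyes (`dispersion_is_se`
exposes the switch).

## Group comparison

Each (layer, region, metric) cell is fitted independently (whether the
original analysis shared one model across regions is unstated; independent
fits are simpler and make no cross-region homogeneity assumption). The
model is value ~ group with a per-subject random intercept, REML, pairwise
Wald contrasts, significance at p < 0.001 with no further multiplicity
correction (the strict α *is* the correction in this design).

Degenerate designs bypass REML, which is numerically unreliable at the
boundary of the parameter space: with one eye per subject the contrast is
computed as the exact one-way ANOVA contrast it reduces to, and when the
within-subject variance collapses (duplicate eyes) or the REML standard
error falls below the i.i.d. OLS bound — impossible under non-negative
intra-class correlation, hence diagnostic of a failed fit — the contrast
falls back to subject means, with a logged warning. Interior fits are
calibration-checked by simulation: under a common null distribution with
bilateral subjects at ρ = 0.5, the rejection rate at α = 0.001 stays at its
nominal level.

Power, as designed, is asymmetric across contrasts: at the published effect
sizes with SE→SD dispersion scaling, the H vs MSON+ separations of
RNFL/GCL+IPL/GCC are detected essentially always, while the weaker
H vs MSON− and MSON− vs MSON+ separations have analytic power between
roughly 0.5 and 0.95 at α = 0.001 — a single simulated cohort will
occasionally miss them, exactly as a single clinical cohort of this size
would. The power property test asserts certainty only for the H vs MSON+
contrasts and requires the weaker contrasts to reject far above the nominal
rate.

## Problem sizes

The full-loop validation runs one eye at the complete acquisition geometry
(6 × 1024 × 512). Unit and property tests use reduced phantoms (128 × 512
or 96 × 384 columns × rows) that preserve the anatomy, texture and shadow
structure. Replicated statistical checks use 200 cohort replicates per
target (500 for the null calibration), sizes at which the binomial noise on
the checked rates is well below the asserted margins.
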