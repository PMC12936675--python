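# Methods

`kneeqmri` reproduces, on synthetic data, a complete longitudinal analysis
of femorotibial cartilage after anterior cruciate ligament (ACL) injury:
subregional cartilage thickness and laminar transverse relaxation time
(T2) are measured per knee and visit, 2-year changes are compared between
ACL-injured knees (ACL_in), the contralateral uninjured knees (ACL_unin)
and healthy control knees (HEA) with linear mixed models, and
location-independent ordered values summarize the extremes of subregional
change.  This note documents the model, the synthetic-data design, the
numerical choices, and their limits.

## Study design emulated by the generator

Four cells: ACL-injured and healthy participants in a 20–30-year and a
40–60-year band (default sizes 20/23/14/21, 78 participants).  Every
participant contributes two knees (injured + contralateral for ACL,
left + right for HEA) at two visits ~24 months apart.  Demographics
(sex ratios, body mass, height, follow-up interval, injured-side counts)
are drawn per cell from the cohort characteristic summaries stored in
`config.STUDY_CHARACTERISTICS`; ages are uniform within the band.

Per knee and subregion the generator injects a truth trajectory

    change_um = Δ(group, subregion)
              + β_age (age − ā) + β_Δt (t_fu − t_bl) + β_base (b − b̄)
              + u_participant + ε,

with `Δ` the group-level 2-year change target (defaults are the published
estimated marginal means per subregion, roughly −75…+21 μm),
`u ~ N(0, τ²)` a participant intercept shared by both knees,
`ε ~ N(0, σ²)` a knee × subregion residual, and covariates centered at
their population values so that the injected `Δ` is the estimand of the
downstream EMMs.  Defaults: τ = 40 μm, σ = 58 μm, chosen once so the EMM
95 % CI half-widths at the default group sizes are ≈ 24 μm for the ACL
groups (n = 34) and ≈ 21 μm for HEA (n = 44), matching the reported
subregional precision; β_age = −1 μm/yr, β_Δt = −3 μm/h,
β_base = −0.02 μm/μm (mild regression to the mean).  Laminar T2 is
generated analogously per region × layer (deep baselines ≈ 20–23 ms,
superficial ≈ 38–41 ms, injected 2-year changes −0.1…+1.6 ms, layer
residual SDs 1.3 / 3.5 ms, participant intercept 0.5 ms).

Baseline subregional thickness defaults sit in the 1.5–3.0 mm range and
are anchored where the published relative changes fix them (for example
the interior lateral tibia at 2.19 mm from −46 μm ≙ 2.1 %); the rest were
set once to plausible values and never tuned.

## Rendered images

Rendered knees are deliberately idealized: each plate (MT, LT, cMF, cLF)
is an axis-aligned voxel slab whose per-column height is the subregional
truth plus a smooth sinusoidal modulation (±0.25 mm), Gaussian-blended
across subregion boundaries (σ = 1.2 mm — real cartilage has no thickness
steps, and the blend also dithers whole-voxel rounding), then rounded to
whole voxels.  The bone–cartilage interface is the flat low-z face for
tibial and the high-z face for femoral plates.  Echo volumes follow the
ideal-spoiling two-echo steady-state forward model
`s1 = A`, `s2 = A·exp(−2(TR−TE)/T2)` with a two-layer T2 field split at
50 % of local column height, plus independent Gaussian noise on each echo
(default 1 % of A; Rician noise is omitted — cartilage SNR in this regime
makes the difference negligible, and the noise model is a config
extension point).  The exact voxelized column heights, the atlas labels
and the layer T2 values are recorded at render time as auxiliary truth,
giving exact oracles for the measurement chain.

What this does *not* emulate: real anatomy and segmentation error, partial
volume at oblique interfaces, B1/T1-dependent corrections of the analytic
T2 estimate, bone marrow lesions, scanner drift.  Passing tests therefore
validate the computational chain, not robustness to real segmentations.

## Thickness and the subregion atlas

Thickness at every interface position is the 3-D nearest distance to the
articular surface, both surfaces discretized as exposed voxel-face
centers; the lateral cartilage margin is excluded from the articular
surface.  On slabs this reduces exactly to column count × slice spacing;
on a hemispherical cap over a flat base the analytic value at in-plane
radius r is R − r, and the voxelized measurement agrees within 2 % at
interior positions (r ≤ 0.6 R at 0.1 mm spacing).  Positions without an
opposing surface are excluded from means and counted in a QC log.

Tibial plates split into a central ellipse with the bounding-box aspect
ratio holding 20 % of the plate area (by pixel count), plus
anterior/posterior/interior/exterior ring sectors cut by the bounding-box
diagonals; central femoral plates split into three equal-width
mediolateral bands.  "Interior" faces the intercondylar notch for both
left and right knees (resolved from laterality).  The 20 % fraction and
the diagonal cut are configurable conventions; with a rectangular
footprint they make all five tibial subregions equal-area.  Aggregation:
region mean = area-weighted mean over positions; MFTC = MT + cMF,
LFTC = LT + cLF, FTJ = (MFTC + LFTC)/2.

## T2 and laminae

Voxel T2 = −2(TR − TE)/ln(s2/s1), valid for 0 < s2 < s1; invalid voxels
(non-positive echoes or non-decaying ratio) are excluded from means and
reported as a QC fraction, never imputed.  The full steady-state analytic
correction is a plug-in hook (identity by default) because the forward
model is built to match the core estimator.  A voxel is *deep* iff its
center depth fraction (interface → surface, along the same correspondence
used for thickness) is < 0.5; a center exactly at 50 % counts as
superficial (a stated tie rule, one of the two defensible readings).
Compartment T2 is the unweighted mean of member *region* values, not a
voxel pool.  The "total" layer pools all valid voxels of a region, so for
odd voxel stacks it is not exactly the deep/superficial midpoint.

## Ordered values

Per knee the 16 subregional changes are sorted by signed value: OV1 =
most negative (greatest thinning), OV16 = most positive (greatest
thickening).  Signed — not absolute-magnitude — ordering is what makes
OV16/OV15 the thickening extremes.  Ties break by the fixed subregion
listing order and are logged.  Occurrence tables count, per group and
reported rank (default OV1, OV2, OV15, OV16), how often each subregion
supplies that rank.  Because OV ranks are extreme-value statistics, their
group means are dominated by the residual SD rather than by the injected
subregion means; the generator reproduces their magnitude scale
(≈ −100…−150 μm for OV1) but not the published group ordering, which is
not among the quantities the acceptance checks assert.

## Statistical layer

For each location (and layer for T2) the change score is modeled by REML
with `statsmodels.MixedLM`:

    change ~ knee_group + age + Δdaytime + baseline + (1 | participant)

Healthy participants contribute one knee, drawn by `select_control_knee`
to balance left/right within every age-band × sex stratum (⌊n/2⌋ or
⌈n/2⌉ left, seeded).  Covariates are centered at the grand means of the
analysis sample, so EMMs are the intercept + group effects; 95 % CIs and
the three pairwise contrasts use a t reference with residual degrees of
freedom (n − rank X) — Satterthwaite is not available for this backend,
and the `df_method` column records the choice.  Contrast p-values are
Sidak-adjusted, p' = 1 − (1 − p)^3, per location family (no pooling
across locations).  A singular or non-converging mixed fit (including a
non-positive-definite fixed-effect covariance) falls back to an ordinary
linear model with τ² = 0, flagged in the output.  Effect size is the
change-score Cohen's d: EMM difference divided by the pooled SD of
observed changes, with a percentile bootstrap CI that resamples
participants and recomputes the raw mean-difference/pooled-SD ratio
(refitting the mixed model per replicate is deliberately avoided; the CI
is an approximation and labelled as such).  Time since injury is
deliberately not a covariate; it can be examined with the covariate
screening utility (univariate OLS + scatter export), as can any candidate
confounder.

Operating characteristics at the default study conditions (500 simulated
cohorts, computed by `scripts/acceptance.py`): EMM bias < 2 μm per group,
95 % CI coverage ≈ 95 %, family-wise Sidak type-I rate ≈ 0.04–0.05.

## Numerical and reproducibility choices

* Units fixed throughout: mm (thickness), μm (thickness change), ms (T2),
  hours (daytime), 0-based voxel indices, positions at voxel centers.
* All randomness flows from `numpy.random.default_rng` seeds recorded in
  the config; every report CSV carries a header block with the config
  hash and seeds, and a rerun is byte-identical.
* The cohort statistics run on regional means computed from the truth
  trajectories; the rendered-image path validates the measurement chain
  on a subset.  At clinically realistic voxel sizes, per-column
  quantization (hundreds of μm) would otherwise swamp 2-year changes of
  tens of μm — exactly why the underlying study measures thickness with
  sub-voxel surface reconstructions, which the slab renderer does not
  attempt to emulate.
* Simulation studies use 500 replicates and the default group sizes;
  the end-to-end determinism check uses a reduced cohort (11
  participants, one rendered knee) — sizes chosen as the smallest that
  exercise every code path with stable Monte-Carlo summaries.
* TR/TE of the two-echo sequence are placeholders (20/6 ms) exposed in
  the config; the published protocol states only the voxel size, and all
  oracles are invariant to the actual values.

## Known limitations

* Slab geometry cannot probe curvature- or normal-direction-dependent
  thickness bias; the hemisphere phantom covers only a convex case.
* The nearest-surface measure dips where the thickness field changes
  rapidly (surface "shadowing"); with the default smoothing this keeps
  image-derived subregional means within ~0.1 mm of the voxelized truth.
* Between-reader segmentation variability, reader unblinding to scan
  order, and dropout are not modeled.
* OV analysis is implemented for thickness only; subregional T2 means are
  not produced at the 16-label level (T2 is summarized per region /
  compartment × layer).
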