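# kneeqmri

Longitudinal femorotibial cartilage morphometry and laminar qDESS T2
analysis on fully synthetic cohorts.

After an anterior cruciate ligament (ACL) rupture, knees are at high risk
of posttraumatic osteoarthritis, and quantitative MRI is the main hope
for catching the disease while it is still early: cartilage *thickness*
tracks structural loss, and the transverse relaxation time *T2* tracks
cartilage composition (hydration, collagen organization), separately in
the deep and superficial half of the cartilage.  `kneeqmri` implements the
complete analysis chain such a study needs — and, because clinical MRI
data of this kind are rarely shareable, pairs it with a synthetic-cohort
generator so every stage is testable end to end:

* **Synthetic cohort** — four demographic cells (ACL-injured / healthy ×
  20–30 / 40–60 years), both knees, baseline and ~24-month follow-up;
  ground-truth subregional thickness and laminar T2 trajectories with a
  participant random intercept and covariate effects; idealized segmented
  two-echo steady-state (qDESS) volumes rendered as NIfTI.
* **Morphometry** — nearest-surface cartilage thickness maps from
  segmentation masks; the 16-subregion atlas of the femorotibial joint
  (central/exterior/interior/anterior/posterior tibial subregions,
  three mediolateral femoral bands); aggregation to regions (MT, cMF, LT,
  cLF), compartments (MFTC = MT + cMF, LFTC = LT + cLF) and the joint
  (FTJ = (MFTC + LFTC)/2).
* **T2 mapping** — analytic voxel-wise inversion of the two echoes,
  T2 = −2(TR − TE)/ln(s2/s1), and a laminar split at 50 % of local
  thickness into deep and superficial cartilage.
* **Ordered values** — per knee, the 16 subregional 2-year changes sorted
  ascending (OV1 = greatest thinning … OV16 = greatest thickening), a
  location-independent statistic for heterogeneous degeneration, plus
  occurrence tables of which subregions supply the extremes.
* **Longitudinal statistics** — change scores (follow-up − baseline, μm
  and ms), balanced control-knee selection, REML linear mixed models
  `change ~ group + age + Δdaytime + baseline + (1 | participant)`,
  estimated marginal means (EMMs) with 95 % CIs, Sidak-adjusted pairwise
  contrasts (p' = 1 − (1 − p)³), standardized mean differences and
  change-score effect sizes.

See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study; each is a
thin driver over the package.

```bash
python analysis/01_simulate.py
python analysis/02_morphometry.py
python analysis/03_t2_mapping.py
python analysis/04_ordered_values.py
python analysis/05_mixed_models.py
```

Output of the run committed here (seed 2026):

```
cohort: 78 participants (34 ACL-injured, 44 healthy)
measure table: 13728 rows over 156 knees x 2 visits
baseline FTJ thickness 3.77 +/- 0.13 mm
...
subregional mean vs voxelized truth: median |error| 23 um, max 83 um
4 knees; laminar region means vs truth: median |error| 0.018 ms, max 0.072 ms
depth gradient reproduced: deep 21.2 ms < superficial 40.7 ms
...
thickness change iLT (um): ACL_in -36 [-59, -13], ACL_unin -34 [-58, -11], HEA -18 [-38, 3]
thickness change OV1 (um): ACL_in -128 [-144, -111], ACL_unin -124 [-140, -107], HEA -145 [-159, -130]
significant Sidak-adjusted thickness contrasts: 9
  ecMF ACL_in-HEA: 64 um (p_adj=0.001, d=0.85)
  ...
```

Reading this: the measurement chain reproduces the rendered ground truth
(thickness to tens of μm, laminar T2 to hundredths of a ms and with the
correct deep < superficial gradient).  The statistical layer then
estimates, per location, the mean 2-year change per knee group with its
95 % CI — e.g. the interior lateral tibia (iLT) thins by ~35 μm in both
knees of ACL participants versus ~18 μm in healthy controls — and tests
the three pairwise group contrasts with Sidak adjustment.  OV1, the
per-knee greatest subregional thinning, is several times larger in
magnitude than any location-specific mean, which is exactly why the
location-independent ranking is reported alongside.  Report tables in
`results/` mirror the four standard layouts: cohort characteristics with
SMDs, thickness EMMs/contrasts, OV occurrences, T2 EMMs/contrasts.

The same pipeline is scriptable via the CLI:

```bash
kneeqmri all --seed 7 --out out/run      # simulate → morphometry → t2map → analyze
kneeqmri simulate --config cfg.yaml --out out/run
```

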