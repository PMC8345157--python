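# Methods

## The problem

Texture features extracted from a 3D dose distribution ("dosiomics") are only
usable in multicentre outcome models if their variation across planning
systems, machines and dose-grid settings is known. The package quantifies that
variation on controlled cohorts: identical plans recomputed by different
"centres" (reproducibility), same-technique plans on different machine
generations (stability), and genuinely different delivery techniques rendered
at two grid resolutions (sensitivity). Because clinical multicentre dose
exports are not publicly shareable, the package ships a synthetic generator
that reproduces the *statistical* structure of such cohorts; real DICOM
RT-Dose/RT-Struct data can be substituted at any point through `rt_io`.

## Synthetic phantom and dose model

The phantom is an analytic cylinder (full scale: radius 100 mm, length 160 mm,
PMMA-like background, four rectangular inserts with lung/bone/muscle/adipose
relative densities). Seven structures are rasterised on the same grid:

* PTV — ellipsoid placed laterally (mono-lateral head-and-neck design),
  semi-axes 40×35×30 mm;
* right parotid — ellipsoid abutting the PTV on its lateral side, inside the
  dose-gradient region; left parotid mirrored on the far side;
* spinal canal — posterior cylinder (radius 8 mm); PRV_SC — its isotropic 4 mm
  expansion by Euclidean-distance-transform thresholding;
* trachea — anterior central cylinder (radius 10 mm);
* RING — `dilate(PTV, 30 mm) \ PTV`, clipped to the phantom body: the shell
  that captures the dose fall-off.

`PhantomSpec.scale_factor` (default 0.5) shrinks the phantom body and the ROI
solids uniformly so a full 30-distribution study runs in well under a minute
per cohort at the default 2 mm voxels. Clinical margins (4 mm PRV, 30 mm ring)
and the dose-model length scales are *not* scaled: margins and penumbra widths
are absolute quantities, not anatomy. The density grid is returned for
completeness but does not influence the dose model.

Dose is a sum of separable smooth fields, not beam transport: the prescription
(66 Gy) exactly inside the PTV, an exponential radial fall-off
`exp(-d/gradient_scale_mm)` outside it (d = Euclidean distance to the PTV),
multiplicative Gaussian sparing wells centred on each OAR, and additive
spatially correlated noise. Only the plateau/gradient/texture structure of the
dose matters for feature-variability analysis, and this model reproduces it at
a tiny fraction of the cost of a TPS calculation. Every generated plan is
verified against the protocol DVH constraints (`check_constraints`); the QA
table is part of every run's output.

Noise is white Gaussian noise drawn on a canonical fine lattice
(`noise_lattice_mm`, default 2 mm), smoothed to `texture_corr_len_mm`, rescaled
to `noise_sd_Gy`, then trilinearly sampled at the dose-grid voxel centres.
Drawing on a fixed lattice makes the perturbation resolution-independent: the
fine and coarse renderings of one sensitivity plan see the *same* underlying
field, so cross-resolution differences reflect sampling, not an independent
redraw.

### Cohort designs and their parameters

| design          | plans | technique kernels | noise sd (Gy) | extra variation |
|-----------------|-------|-------------------|---------------|-----------------|
| reproducibility | 4     | 1                 | 0.4           | seed only |
| stability       | 8     | 1                 | 0.4           | plans 5–8: ±15 % fall-off scale, ±10 % sparing jitter |
| sensitivity     | 11×2  | 6 distinct        | 0.8           | kernel differences; fine + coarse grids |

The reproducibility plans are the first four plans of the stability cohort
(same per-plan seeds, no jitter): one set of 8 + 22 = 30 distinct dose
distributions covers all three studies, and the bookkeeping totals
(212 × 6 ROIs × 30 = 38,160 values; 5,088 / 10,176 / 27,984 per study) follow
by construction. Technique kernels differ in fall-off scale (7–15 mm), noise
correlation length (5–10 mm) and sparing strength (±10 %); six kernels mimic
the spread of delivery techniques and dose engines across centres. The default
noise levels were chosen so that reproducibility CVs sit well below the 0.3
stability threshold while sensitivity cohorts spread far above it — the
qualitative regime such a study is designed to create — while every plan still
passes the DVH QA. The coarse sensitivity resolution is twice the fine spacing
(default 2 mm / 4 mm), preserving the 1:2 ratio of the fine/coarse design; the
study tags keep the conventional `sensitivity_1mm` / `sensitivity_2mm` names
for the fine/coarse pair even when the absolute spacings are configured
differently.

All randomness flows from a single base seed expanded per plan through
`numpy.random.SeedSequence([base_seed, plan_index])`; every output is a pure
function of (spec, seed).

## Feature extraction

* **Discretisation** — `level(d) = min(G, ⌊d/d_max·G⌋ + 1)` with G = 100:
  left-closed/right-open bins, top level closed, so 0 Gy → level 1 and
  d_max → level G. `d_max` is the per-ROI maximum by default (`roi_max`),
  keeping level occupancy comparable across ROIs; a `global_max` mode is
  provided because either reading of "zero to max dose" is defensible. The
  choice is recorded in each feature vector's provenance.
* **STAT (17)** operates on raw dose in Gy with the population (biased)
  variance convention; skewness/kurtosis of constant input are NaN.
* **GLCM (25 × 4 = 100)** — symmetrised co-occurrence at Chebyshev distance 1;
  aggregations: per-slice-per-direction averaged (2D_avg), per-slice merged
  over the 4 in-plane directions (2D_merge), per-direction volumetric averaged
  over the 13 unique 3D directions (3D_avg), and all directions merged
  (3D_merge).
* **GLRLM (16 × 4 − 1 = 63)** — maximal equal-level runs truncated at mask
  gaps, same four aggregations. Sixteen base features times four aggregations
  gives 64; the registry drops one configured entry to match the canonical
  63-feature count. The default drop is `run_entropy` under 2D_avg — an
  arbitrary but documented choice, configurable via
  `default_registry(glrlm_drop=...)`; the per-family counts, not the identity
  of the dropped entry, are the binding constraint.
* **GLSZM (16 × 2 = 32)** — zones are connected equal-level components,
  26-connectivity in 3D and 8-connectivity within slices (2D matrices merged
  over slices).

Degenerate matrices (single grey level, no valid pairs) yield NaN for the
affected features (e.g. GLCM correlation, information correlations); NaNs are
carried as flagged missing values, dropped pairwise in CV computation and
counted in all reports. Feature averages over per-slice/per-direction matrices
skip empty matrices and NaN values. Texture matrices are computed on the ROI
bounding box (crop-invariant by construction). No resegmentation or outlier
clipping of dose values is applied, and morphological/shape features are out
of scope.

Because all texture families operate on the `roi_max` discretisation, they are
exactly invariant under positive rescaling of the dose; STAT features scale
accordingly. Extraction is a pure function — repeated runs are bit-identical,
which is the package's software-reproducibility check (max-abs difference of
two independent extraction passes, expected 0).

## Variability analysis

* `cv = s/|x̄|` with the sample (n−1) standard deviation — cohorts have 4–11
  plans, so the unbiased convention was chosen; it is recorded in every CV
  report since either convention is seen in practice. `x̄ = 0` and n < 2 yield
  flagged undefined records.
* Selection uses strict inequalities (`cv < 0.3` stable, `cv > 1.0` / `> 0.8`
  sensitive); undefined CVs belong to neither set. Percentages always use the
  full registry size as denominator (the number of defined CVs is reported
  alongside). Sensitivity is analysed separately per grid resolution, and
  intersections (reproducibility∩stability, fine∩coarse sensitivity,
  stability∩sensitivity) are reported per ROI to one decimal place.
* Family summaries give the mean CV per family plus box-plot statistics
  (median, quartiles, Tukey 1.5×IQR whiskers) as plotting *data*, not figures.
* ICC(2,1) — two-way random effects, absolute agreement, single rater — is
  provided as a secondary metric with its variance components; negative
  moment estimates are truncated at zero and flagged. Because the ROIs of a
  phantom study have wildly different dose levels (high between-subject
  variance), CV rather than ICC is the primary metric, and reports using ICC
  across heterogeneous ROI groups should be read with that caveat.

## Numerical and I/O choices

* Axis convention (z, y, x), 0-based, patient coordinates in mm, voxel-centre
  geometry throughout; documented once in `core.py`.
* RT-Dose writing picks the dose-grid scaling as `max_dose / (2³² − 1)`
  (quantisation ≤ 0.001 Gy guaranteed with large margin); reading accepts Gy
  and cGy and rejects tilted orientations, non-uniform frame offsets and other
  unsupported dialects loudly.
* Contour rasterisation uses voxel-centre even-odd inclusion (orientation
  invariant); masks are rasterised on the dose grid, and when grids differ the
  dose is resampled trilinearly to the mask grid — mask interpolation would
  invent texture. Resampling never extrapolates: target voxels outside the
  source voxel-centre hull get 0 Gy and are counted in a coverage report.
* Dilations (PRV, RING) threshold the Euclidean distance transform with
  physical spacing — the "isotropic expansion" semantics.

## Test strategy and what passing shows

Texture matrices are verified exactly against brute-force oracles (ordered
pair enumeration, line-walking run enumeration, BFS component labelling) on
hundreds of random ≤4³ masked arrays; CV and ICC against closed-form/ANOVA
recomputation (and pingouin's ICC as an external cross-check); rasterisation
against a ray-casting oracle. Cohort-level properties (median CV ordering
reproducibility ≤ stability ≤ sensitivity, monotonicity in the noise level,
QA pass) are checked over three seeds at the default study conditions.

The generator emulates the plateau/gradient/correlated-texture structure of
clinical dose and the relative variance regimes between study designs. It does
not emulate beam/arc geometry, MLC sequencing, optimiser behaviour, CT
Hounsfield realism or algorithm-specific dose artefacts — so passing tests
demonstrate correctness and the designed qualitative behaviour of the
*analysis*, not the specific CV magnitudes real multicentre cohorts would
produce. The ROI geometry is plausible rather than calibrated (phantom
dimensions and ROI volumes are free parameters).

## Known limitations

* Only axial, uniformly spaced DICOM grids are supported (by design).
* The run-length registry's 63rd/64th-entry choice is conventional.
* CV magnitudes on synthetic cohorts depend on the chosen noise levels; only
  orderings and invariances, not absolute CV values, are asserted.
* ICC grouping across ROIs with very different dose levels is biased by
  between-subject heterogeneity; the implementation reports it but the
  pipeline's primary metric is CV.
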