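# Methods note

This note documents the models implemented in `pvsquant`, the parameter
defaults with units and rationale, what the synthetic generators emulate
(and deliberately do not), the numerical choices, and known limitations.
It makes no empirical claims beyond what the package itself computes on
its own synthetic data.

## 1. Segmentation chain

Input: a T2-weighted 3D image and a tissue label map (codes: background 0,
white matter 1, gray matter 2, basal ganglia 3, CSF 4, ventricle 5,
WMH 6). All mm-parameterized operations convert mm to voxels through the
per-axis spacing derived from the NIfTI affine, so anisotropic grids are
supported.

### 1.1 Denoising

Non-local means (`skimage.restoration.denoise_nl_means`, fast mode),
suited to the Rician noise of magnitude MRI.

| parameter | default | unit | rationale |
|---|---|---|---|
| `patch_radius` | 1 | voxels | 3³ patches: smallest patch that captures local texture |
| `search_radius` | 3 | voxels | 7³ search window; larger windows give little gain at high cost |
| `h` | `None` → 0.8 × estimated σ | intensity | smoothing strength tied to a wavelet noise estimate |

A constant (noise-free) image is returned unchanged.

### 1.2 Analysis region

The region of interest (ROI) is the union of white matter and basal
ganglia labels, smoothed with an edge-preserving binary median filter
(ball radius 1 mm), with enclosed holes filled (PVS mislabelled as CSF
would otherwise punch holes in the region), minus the ventricle mask
dilated by 1 mm (a guard rim against CSF partial-volume voxels). WMH are
returned as a separate mask: they are excluded from PVS foreground but,
by default, kept in the volume-fraction denominator because they remain
analyzed tissue.

### 1.3 Vesselness

Multiscale Frangi vesselness for bright tubular structures. At scale
*s* the image is smoothed with a Gaussian of width *s* and the Hessian
eigenvalues are ordered |λ₁| ≤ |λ₂| ≤ |λ₃|. With

- R_A = |λ₂|/|λ₃| (plate vs line discriminator),
- R_B = |λ₁|/√(|λ₂λ₃|) (blobness),
- S = √(λ₁² + λ₂² + λ₃²) (structureness),

the response is

V_s = (1 − e^(−R_A²/2α²)) · e^(−R_B²/2β²) · (1 − e^(−S²/2c²))

when λ₂ < 0 and λ₃ < 0 (structures brighter than their surroundings, as
CSF-filled PVS are on T2), else 0. The final map is the voxelwise maximum
of V_s over geometrically spaced scales; it lies in [0, 1).

| parameter | default | unit | rationale |
|---|---|---|---|
| α | 0.5 | – | standard weighting of the plate/line term |
| β | 0.5 | – | standard weighting of the blob term |
| c | 500 | intensity | structureness constant matched to raw T2 scanner units (tissue ≈ 1000); rescale for data on another intensity scale |
| s_min, s_max | 0.1, 5 | mm | radius range from sub-voxel PVS to large enlarged PVS |
| n_scales | 5 | – | geometric sampling of the scale range |

**Numerical choice.** The Hessian is computed by central finite
differences of the Gaussian-smoothed image (Gaussian truncated at 4σ,
reflective boundaries), scale-normalized by s². Convolving with analytic
Gaussian-derivative kernels instead degenerates when the scale falls
below the grid spacing: at s = 0.1 mm on a 1 mm grid the derivative
kernel collapses to a single voxel, the Hessian approaches −I(x)/σ² at
every voxel, and the vesselness acquires a uniform non-zero floor across
the whole region. Differentiating the smoothed image keeps sub-voxel
scales well-behaved: they simply contribute a negligible response.

### 1.4 Standardization and thresholding

The vesselness map is divided by the interquartile range (IQR) of its
positive in-ROI values, so one threshold transfers across subjects with
different contrast. The default threshold is **2.7** IQR units, selected
by the calibration sweep (section 3). A `robust_z` variant (median
subtracted before dividing) is available. Voxels at or above threshold,
inside the ROI and outside WMH, are grouped into 26-connected components;
components smaller than 5 voxels are discarded as noise. Metrics: PVS
volume (cm³), ROI volume (cm³), volume fraction (%), component count.

## 2. Statistical models

All longitudinal models are linear mixed models (REML, `statsmodels
MixedLM`) with a random intercept for site and a random intercept for
participant nested in site. The outcome is PVS volume fraction in
percentage points; `timepoint` is 0 (baseline) / 1 (follow-up), `arm` is
0 (standard) / 1 (intensive).

- **Baseline model** — OLS of baseline fraction on sex, brain parenchymal
  fraction, age, CVD history, baseline SBP, CKD, race and logWMH, with
  fixed site indicators; standardized coefficients b·SD(x)/SD(y).
- **Model 1** — fixed effects: timepoint, arm, arm×timepoint (headline
  coefficient: the between-arm difference in change over follow-up), plus
  the baseline covariates.
- **Model 2** — Model 1 with logWMH and total brain volume each split
  into a participant mean ("between") and a within-participant deviation
  ("within"), to verify the treatment effect is not carried by WMH growth
  or atrophy.
- **Model 3** — per-class antihypertensive exposures (fraction of
  follow-up days on ACEi/ARB, beta-blocker, calcium-channel blocker,
  diuretic) with exposure×time interactions, plus covariates including
  achieved SBP.
- **Contrasts** — within-arm changes and between-arm differences at each
  timepoint as linear combinations of the fixed effects, normal-theory
  95% CIs, Bonferroni correction with family size 4.
- **Age equivalence** — |Δ fraction| / |age coefficient| converts a
  within-arm change into years of age-related enlargement.

Derived measures: logWMH = ln(1 + WMH volume / intracranial volume);
brain parenchymal fraction = (WM + GM) / intracranial volume; achieved
SBP = trapezoidal area under the visit-wise SBP curve divided by the day
span; medication exposure = length of the union of on-drug intervals
(overlaps merged) divided by follow-up days, clipped to [0, 1].

## 3. Threshold calibration

For each subject the standardized map is re-thresholded over an inclusive
arithmetic grid (default 0.5 to 3.3, step 0.1) with the full
component-size filtering applied at every threshold, and the resulting
volume fractions are correlated (Pearson by default, Spearman optional)
with ordinal 0–8 visual PVS ratings. The reported optimum is the argmax
of the correlation curve; thresholds where fractions are constant across
subjects have undefined correlation and are excluded; ties resolve to the
smallest (most sensitive) threshold. Retained PVS volume is
mathematically non-increasing in the threshold, because every retained
component at a higher threshold is contained in a retained component at
any lower one.

## 4. Synthetic generators

### 4.1 Image phantoms

A brain ellipsoid of gray matter containing a white-matter ellipsoid
(shell fraction 0.88, so the ROI boundary has tissue–tissue contrast as
in a real brain), optional ventricle and WMH blobs, and bright capsule
"PVS" tubes clipped to white matter. Intensities are on a raw-scanner-like
T2 scale — WM 1000, GM 1150, CSF/ventricle 2000, WMH 1500, PVS 2000
(CSF-isointense, since PVS are CSF-filled) — chosen so the vesselness
structureness constant c = 500 operates in its intended regime. Optional
low-order polynomial bias field; Rician noise (σ = 30 by default,
applied as √((x+n₁)² + n₂²)). Tubes are voxelized by center inclusion,
so the analytic cylinder volume πr²L is an oracle for the voxel count;
on a 1 mm grid, axis-aligned thin tubes overshoot the analytic volume by
tens of percent (4–5 voxels per slice versus π), while oblique tubes
average close to it — a discretization property, not a defect.

The phantoms exercise the pipeline's contracts; they do **not** emulate
MR physics (no k-space sampling, no partial-volume mixing beyond
voxelization, no motion or susceptibility artifacts) or real anatomy.

### 4.2 Longitudinal cohorts

Two-arm, two-timepoint tables generated from an explicit linear model:
baseline mean 1.23 percentage points; time slope +0.0017; group −0.0021;
group×time −0.029 (the injected treatment effect); covariate effects
(age +0.004/yr, male +0.081, black −0.065, CVD +0.067, CKD −0.021,
baseline SBP +0.00025/mmHg, logWMH −1.05) centered at their population
means; random intercepts for participant (SD 0.25) and site (SD 0.05,
7 sites) and residual SD 0.08. Achieved SBP comes from simulated visit
series (intensive arm 120 ± 8, standard 136 ± 7, visit SD 9 mmHg);
class exposures are Beta-distributed; covariate margins mirror an
elderly hypertensive cohort. With all random SDs set to zero the
difference-in-differences of the group means equals the injected
interaction exactly, which the tests use as an oracle.

### 4.3 Closed-loop demo

Each simulated participant has a fixed random tube layout; per visit the
tube lengths are rescaled about their midpoints so the true volume
fraction follows baseline 1.2% + participant effect (SD 0.2) + injected
group×time effect (−0.03) on the intensive arm; every visit image gets an
independent noise realization and is segmented with the full chain; the
treatment mixed model then runs on the measured fractions. Keeping the
layout fixed within participant mirrors longitudinal imaging, where
measurement idiosyncrasies largely cancel in within-participant change.

## 5. Limitations

- The phantoms are geometric scenes, not MR simulations; absolute
  segmentation accuracy on clinical data cannot be inferred from them.
- Thin (≈1 voxel) tubes are at the resolution limit: recovered volumes
  systematically undershoot truth by roughly 10–20% at the reference
  noise level, and sub-voxel Frangi scales contribute essentially
  nothing on a 1 mm grid.
- The mixed models assume two visits per participant for the
  within/between decomposition and use normal-theory inference; with few
  sites the site variance component is weakly identified (the nested
  participant intercept carries most of the clustering).
- The visual-rating simulator is a monotone latent-score model with
  Gaussian rater noise, not a model of any specific rating protocol.
- The threshold default (2.7) and the structureness constant (c = 500)
  are tied to the raw T2 intensity convention above; data on other
  intensity scales require recalibration.
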