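# Methods note

This note records the generative model, the analysis conventions, and the
numerical choices behind `plexdia`. Everything here is a property of this
package; where a quantity is a calibration choice rather than an external
fact, it says so.

## 1. Synthetic cohort generator

### Case level

For each case the generator draws, in order (all from
`numpy.random.default_rng([seed, stream, case_id])` streams, so any case is
reproducible in isolation):

* **MSI status**: Bernoulli(`frac_msi`, default 0.14).
* **CDX2-low membership**: Bernoulli with MSI-dependent probability. The
  coupling is the exact closed form P(low | MSI) = s·f/m and
  P(low | MSS) = (1−s)·f/(1−m), where f = `frac_cdx2_low` (0.11),
  m = `frac_msi`, and s = `msi_share_of_low` (0.47) is the target share of
  CDX2-low cases that are MSI. This preserves the marginal low fraction
  exactly; infeasible combinations are rejected at config time.
* **Case-mean CDX2**: two-component lognormal mixture — low component
  median 0.02 (σ_log 0.7), high component median 1.5 (σ_log 0.55). The
  medians/σ are calibration constants chosen so the two components are
  well separated (bimodality) and the low fraction lands near the 11th
  percentile of the mixture.
* **Case-mean SOX2**: Gaussian copula on the CDX2 normal scores. The
  latent correlation uses the exact Spearman relation for bivariate
  normals, r = 2·sin(π·ρ/6), with target ρ = −0.5. Marginal: lognormal,
  median 0.15, σ_log 1.2.
* **Covariates** (gender, age ~ N(71, 11) clipped to 30–96, grade, stage,
  tumor location): categorical draws whose conditional distributions shift
  with CDX2-low and MSI status in the directions typical of colorectal
  cohorts. These are cosmetic structure for the association tests, not
  calibration targets.
* **Survival**: exponential proportional hazards. Baseline rate
  λ0 = −ln(`baseline_survival`)/`followup_months` (default: 55% survival
  at 60 months), hazard multiplied by `hr_cdx2_low` (1.6) for CDX2-low
  cases. Administrative censoring at the horizon only — follow-up is
  complete by construction, so `event = 0` implies `time = 60`.
* **Technical artifacts**: tissue-fold and necrosis flags (2% each) as
  table columns; they drive case exclusion but are not rendered as image
  artifacts.

### Cell level

Per-cell expression is the case mean times mean-one lognormal noise
(σ = `cell_sigma`, default 0.4). The CDX2 and SOX2 log-noise terms share
the same latent correlation as the case level, so the single-cell rank
correlation matches the case-level target (~ −0.5) rather than being
diluted by independent noise.

### Geometry

Nuclei are placed by dart throwing (Poisson-disc-like: candidates sampled
uniformly in the allowed region, accepted if at least
`min_nucleus_spacing_px` from all accepted points; a background grid of
cell side d/√2 makes the check O(1)). The epithelial region is a smooth
3-lobed blob inside a circular core. Cell territories are the
nearest-nucleus (Voronoi) partition of the epithelium; nuclei are discs of
`nucleus_radius_px`; the membrane is the ribbon of territory pixels within
`membrane_band_px`/2 of a differently-labeled or out-of-mask pixel
(image borders do **not** count as boundary; out-of-mask pixels do, so
edge cells keep a band); cytoplasm is the remainder. Compartments are
disjoint and cover the territory by construction. Under a tight spacing
constraint dart throwing can place slightly fewer cells than the Poisson
target; the truth table always reflects placed cells.

### Detection model

* **Fluorescence** is strictly linear: per-fluorophore abundance =
  `gain`·E painted into the marker's home compartment (CDX2, SOX2:
  nucleus; BCAT: cytoplasm — deliberately *not* membrane, see §5; PANCK:
  membrane-weighted through the cell body; DAPI: nucleus), pixel spectrum
  = library × abundances + autofluorescence + Gaussian read noise
  (sd 0.15). No count ceiling unless `clip_counts` is set.
* **Chromogenic** OD is a Hill response with coefficient 1:
  OD(E) = `od_max`·E/(E + `k_half`), defaults od_max = 2.0, k_half = 0.5 —
  the simplest monotone saturating two-parameter form. Additive Gaussian
  noise, sd 0.02.
* **Simulated visual scorer thresholds** sit at fixed fractions of od_max
  (0.05, 0.15, 0.40, 0.70 → t_pos 0.10, t_weak 0.30, t_mod 0.80,
  t_strong 1.40). These are calibration parameters of the simulated
  scorer; they are not measured quantities.

## 2. Unmixing

Libraries are unit-column-sum, nonnegative, full column rank (rank
deficiency is rejected naming the collinear fluorophores); abundances
therefore carry the intensity scale. Unmixing solves an independent
nonnegative least-squares problem per pixel with a vectorized active-set
scheme: pixels are grouped by active-set bitmask, each group is solved via
a cached pseudoinverse (the cache is keyed by library matrix and persists
across cores), the most negative coefficient is dropped per infeasible
pixel, and the loop repeats. Optimality is then verified through the KKT
conditions (inactive-gradient ≤ 1e-8·scale); violations are repaired by
re-adding the most violated component, with an exact per-pixel
`scipy.optimize.nnls` solve as last resort. Tests check the solver against
two independent oracles: brute-force enumeration of KKT sign patterns, and
scipy's NNLS.

## 3. Segmentation

Transparent classical operators stand in for trainable commercial
classifiers: Otsu threshold + binary closing (disc radius 2) + hole
filling + small-object removal (min 64 px) for epithelium; Otsu within the
epithelium + Euclidean distance transform + peak seeds (min separation
4 px) + watershed for nuclei; seeded watershed on a topography combining
normalized pan-cytokeratin signal with distance from the nucleus-centroid
seeds for territories; the membrane/cytoplasm split reuses the geometric
band rule above. All steps are deterministic. Cases with fewer than 50
epithelial cells (strict less-than), segmentation QC flags, or simulated
fold/necrosis flags are excluded with the reason recorded.

On default-noise synthetic cores the internal quality gates are: epithelium
Jaccard ≥ 0.9, nucleus count within ±10% with per-nucleus matching
F1 ≥ 0.9 at IoU 0.5, and mean territory IoU ≥ 0.8. These are package
quality gates, not reproductions of any instrument's accuracy.

## 4. Scoring and statistics conventions

* **DIA score**: unweighted mean over cells of the per-cell compartment
  mean abundance; empty compartments are missing, never zero; cells with
  missing values are skipped.
* **Allred**: proportion bins (0]→0, (0, 1%]→1, (1%, 10%]→2, (10%, ⅓]→3,
  (⅓, ⅔]→4, (⅔, 1]→5; intensity categories left-closed at t_weak/t_mod/
  t_strong; a cell is positive when compartment mean OD > t_pos; the
  intensity score is computed over positive cells only (standard Allred
  practice; set to 0 when there are none).
* **Percentile bins** (per-cell visualization): competition ("min") ranks,
  bin = rank // ⌈n/10⌉ + 1, so ties share the bin of their lowest member
  and all-equal input lands in bin 1.
* **Percentile cutoff**: threshold = linear-interpolation quantile at the
  11th percentile over all scored cases; negative iff strictly below. With
  100 distinct scores this yields exactly 11 negatives; all-equal scores
  yield none.
* **Rank correlation**: Spearman with average ranks, two-sided p,
  pairwise deletion, ≥ 3 complete pairs. Convention adopted for
  comparisons: a scorer that is *constant* on a subgroup has zero rank
  discrimination there and is treated as rho = 0 in the top-quartile
  comparison (the saturated Allred scorer regularly produces an all-8
  top quartile).
* **Group tests**: Wilcoxon rank-sum (exact when the larger group has
  ≤ 25 members, asymptotic otherwise) for two groups, Kruskal–Wallis for
  more; scores enter unbinned.
* **Colocalization**: seeded uniform downsample without replacement to
  10,000 cells before the Spearman correlation, mirroring scatter-plot
  practice.
* **Survival**: administrative censoring at the horizon, Kaplan–Meier
  per group with a 12-month risk table, log-rank test, Cox with Efron tie
  handling (the lifelines default); missing covariates dropped case-wise
  in multivariable fits; the reported HR is oriented low-vs-high; a group
  without events yields a missing HR plus a warning, with KM curves still
  produced. All tests two-sided at α = 0.05.

## 5. The membrane-contamination failure mode

True β-catenin-like signal is painted **only** into the cytoplasm
compartment. Any signal measured in the segmented membrane band therefore
comes from segmentation geometry: the band is thin, hugs the cytoplasm,
and picks up diffuse cytoplasmic staining through boundary misalignment
and shared pixels at compartment borders. The acceptance check (membrane
DIA score vs cytoplasmic ground truth, Spearman rho > 0.5 across a
cohort) demonstrates that a "membrane score" of a diffuse cytoplasmic
marker is largely a cytoplasm readout — the documented caveat for
membrane-region scoring of such markers.

## 6. Problem sizes and runtime

These sizes are this package's own choices, made for a single-CPU desk
machine, and are fixed in the tests:

| check | size | approx. runtime |
| --- | --- | --- |
| full end-to-end cohort (criteria 3, 6) | 600 cases, 256 px, ~300 cells/core, seed 7, shared session fixture | ~3 min |
| colocalization recovery | 20 seeds × 600 cases, cell tables only | ~1 min |
| survival calibration | 200 cohorts × 600 cases, table-only path | ~15 s |
| end-to-end hazard direction | 20 cohorts × 600 cases at reduced image scale (96 px, ~70 cells, spacing 6 px, nucleus radius 2 px) | ~10 min |
| everything else | analytic fixtures and single cores | seconds |

The reduced image scale for the hazard-direction check preserves the
per-case pipeline (render → unmix → segment → score → label → Cox) while
keeping 20 × 600 cores tractable; the included-case count (~570/600) and
DIA-vs-truth fidelity (rho ≈ 0.997) at that scale were verified before the
pass threshold was frozen.

## 7. Limitations

* The generator's expression scales, noise levels and visual-scorer
  thresholds are calibration constants, not measurements; only the
  *structural* targets (low fraction, rank correlations, HR, saturation)
  are meaningful reproduction targets.
* Geometry is deliberately schematic (circular cores, Voronoi cells,
  disc nuclei); no texture, no 3D, no staining chemistry, no image-level
  artifacts (folds/necrosis are table flags only).
* Cohort-specific numeric results of any real study (particular
  correlation coefficients, hazard ratios) depend on patient data and are
  not reproducible here; directional/structural properties are what the
  acceptance suite asserts.
* The original analyses' quantile convention, Cox tie handling, and the
  visual scorer's effective thresholds are unknown; the conventions above
  are explicit package choices, documented rather than inferred.
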