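# plexdia

Digital image analysis (DIA) of multiplex fluorescence immunohistochemistry
versus visual Allred scoring of chromogenic staining, rebuilt as a tested,
reusable pipeline on synthetic tissue-microarray (TMA) cores with known
ground truth.

## The problem

Chromogenic IHC read visually with the Allred scheme (a 0–5 proportion
score plus a 0–3 intensity score, total 0–8) is the routine way to grade
marker expression such as nuclear CDX2 in colorectal cancer. Multiplexed
fluorescence IHC with spectral unmixing and per-cell image analysis
promises a continuous, higher-resolution readout of the same biology: DAB
chromogen saturates (a narrow dynamic range at the top of the expression
scale), while fluorescence counts stay linear in expression.

Comparing the two scoring approaches on patient material is confounded by
the absence of ground truth. This package instead builds a **synthetic
cohort generator** that emulates the statistical structure of such a
cohort — a bimodal case-level CDX2 distribution with a small low-expressing
component, CDX2–SOX2 anticorrelation at the case and single-cell level, an
MSI association, a survival disadvantage for CDX2-low cases, and paired
chromogenic renderings with a saturating response — and runs the complete
analysis chain against the known truth:

1. **synthdata** — synthetic TMA cores: geometry (Poisson-disc nuclei,
   nearest-nucleus cell territories, membrane band, cytoplasm), per-cell
   expression, multichannel fluorescence render, chromogenic OD render,
   cohort covariate and survival tables.
2. **unmix** — spectral libraries (five fluorophores plus autofluorescence)
   and per-pixel nonnegative least-squares unmixing into abundance maps.
3. **segment** — epithelium (Otsu + morphology), nuclei (distance-transform
   watershed on DAPI), cell territories and membrane/cytoplasm compartments
   (seeded watershed guided by pan-cytokeratin); case exclusion below 50
   epithelial cells.
4. **score** — per-cell compartment means; continuous DIA case scores;
   simulated-visual Allred scores from the chromogenic image; per-cell
   percentile bins; the predetermined 11th-percentile positivity cutoff.
5. **stats** — Spearman correlations, Wilcoxon/Kruskal–Wallis covariate
   tests, single-cell colocalization with 10,000-cell downsampling,
   Kaplan–Meier / log-rank / Cox 5-year survival comparisons.
6. **io / cli** — TIFF and CSV artifacts with provenance headers, YAML
   configuration, and a `plexdia` command chaining the stages.

## Worked example

`examples/04_cohort_analysis.py` runs the full image pipeline on a reduced
120-case cohort (96 px cores, ~70 cells each) and prints:

```
120 cases, 111 included (9 excluded), 7241 cells

correlations (Spearman):
     dia_vs_allred: rho +0.917 (n=111)
      dia_vs_truth: rho +0.994 (n=111)
   allred_vs_truth: rho +0.910 (n=111)
  cdx2_vs_sox2_dia: rho -0.551 (n=111)

11th-percentile DIA cutoff: 0.218

single-cell CDX2-SOX2 colocalization: rho -0.504 (n=7241)

dia_cdx2_nucleus: low-vs-high HR 2.04 [1.03, 4.05], log-rank p 0.038, 55 events / 111 cases

allred_cdx2_total: low-vs-high HR 2.03 [0.99, 4.16], log-rank p 0.047, 55 events / 111 cases
```

The qualitative pattern the package is built to demonstrate is visible
directly: the continuous DIA score tracks ground-truth expression more
faithfully than the discrete, saturating Allred score (rho 0.994 vs
0.910), the generator's single-cell CDX2–SOX2 anticorrelation (target
−0.5) is recovered from the segmented cells, and the 11th-percentile
CDX2-low group carries an elevated hazard. At full scale (600 cases,
256 px cores, ~300 cells/core, seed 7) the same chain gives DIA-vs-truth
rho 0.999 against Allred-vs-truth rho 0.903, with the Allred distribution
piled at the top of its range (min–max-scaled median 1.00 vs 0.17 for
DIA) — the saturation signature.

The other examples are smaller bites: `01_simulate_core.py` (one core and
its ground truth), `02_unmix.py` (noiseless unmixing is exact to ~1e-6),
`03_segment_and_score.py` (per-core DIA + Allred scores).

### Command line

```bash
plexdia pipeline config.yaml --seed 1 --output-dir out
```

runs simulate → unmix → segment → score → analyze, writing TIFF/CSV
artifacts, `analysis/report.json` and a JSON-lines log under `out/`. A
minimal config:

```yaml
cohort:
  n_cases: 60
  seed: 1
```

Any field of the cohort, detection, segmentation, scoring or stats blocks
can be set in the file or overridden with `--set BLOCK.KEY=VALUE`; unknown
keys are rejected. Every output table carries a `# provenance:` header with
the config hash and seed.

## Reproduction

The analytic acceptance targets (the Allred proportion score of a core
with 25% positive cells, and the intensity score of staining in the
strongest category) are computed end to end — synthetic core, fluorescence
render, unmixing, segmentation, chromogenic Allred scoring — by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints `{"t2": {"n": 129, "value": 3}, "t3": {"n": 32, "value": 3}}`:
both targets score 3, as the standard Allred bin definitions require. The value
is invariant to the seed; `n` (number of scored / positive cells) varies
with the geometry draw.

The full acceptance suite (`tests/test_acceptance.py`) checks, one test per
criterion: the Allred bin lookups; noiseless unmixing against a brute-force
KKT sign-pattern oracle (1e-6 on 1,000 pixels); the end-to-end 600-case
cohort properties above; single-cell colocalization recovery (−0.5 ± 0.05
over 20 seeds); survival calibration (200 cohorts: mean log-HR bias < 0.05,
95% CI coverage in [0.92, 0.98]) plus end-to-end hazard-direction recovery
(HR > 1 in ≥ 95% of 20 image cohorts); and the membrane-contamination
failure mode (membrane score vs cytoplasmic truth, rho > 0.5). See
`docs/methods.md` for the generator model, parameter choices, and
numerical conventions.
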