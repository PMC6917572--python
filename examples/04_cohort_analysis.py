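"""A small end-to-end cohort: scores, correlations, cutoff, survival.

Runs the full image pipeline over a reduced cohort (small cores keep this
example fast; use the defaults for study-scale behavior), then reproduces
the comparison layer: DIA vs Allred vs ground truth correlations, the
predetermined 11th-percentile CDX2 cutoff, and the 5-year survival
comparison of the resulting groups.
"""

from plexdia import CohortConfig, analyze_cohort, run_cohort

config = CohortConfig(
    seed=5,
    n_cases=120,
    image_size_px=96,
    cells_per_core=70,
    min_nucleus_spacing_px=6.0,
    nucleus_radius_px=2.0,
)
result = run_cohort(config, keep_cells=True)
cases = result.cases
print(f"{len(cases)} cases, {cases['included'].sum()} included "
      f"({(~cases['included']).sum()} excluded), "
      f"{len(result.cells)} cells")

report = analyze_cohort(cases, result.cells)
print("\ncorrelations (Spearman):")
for row in report.correlations.itertuples():
    print(f"  {row.comparison:>16}: rho {row.rho:+.3f} (n={row.n})")

print(f"\n11th-percentile DIA cutoff: {report.thresholds['dia_cdx2_nucleus']:.3f}")
print("\nsingle-cell CDX2-SOX2 colocalization: "
      f"rho {report.colocalization['rho']:+.3f} (n={report.colocalization['n']})")

for col, fit in report.survival.items():
    hr = f"{fit.hazard_ratio:.2f}" if fit.hazard_ratio else "n/a"
    ci = (f"[{fit.ci_low:.2f}, {fit.ci_high:.2f}]"
          if fit.hazard_ratio else "")
    print(f"\n{col}: low-vs-high HR {hr} {ci}, "
          f"log-rank p {fit.logrank_p:.3f}, "
          f"{fit.n_events} events / {fit.n} cases")
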