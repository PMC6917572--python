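"""Segment one core and score it both ways.

DIA score: mean over epithelial cells of the per-cell mean fluorescence
abundance in the marker's compartment (continuous, linear).
Allred score: proportion score (0-5, fraction of positive cells) plus
intensity score (0-3, mean OD of positive cells) on the chromogenic image.
"""

from plexdia import CohortConfig, DetectionModel, default_spectral_library
from plexdia.pipeline import process_core
from plexdia.synthdata import build_core, render_chromogenic, render_fluorescence, simulate_cohort_table

config = CohortConfig(seed=1, n_cases=5)
model = DetectionModel()
library = default_spectral_library()

cases = simulate_cohort_table(config)
for i in range(3):
    case = cases.iloc[i]
    truth = build_core(case, config)
    fluor = render_fluorescence(truth, library, model, config)
    chrom = {"CDX2": render_chromogenic(truth, model, config, marker="CDX2")}
    res = process_core(fluor, chrom, library, model)
    s = res.case_scores
    print(
        f"case {res.case_id}: {res.n_cells} cells detected "
        f"(true {truth.n_cells}), included={res.included}; "
        f"true CDX2 {case['cdx2_truth']:.3f}, "
        f"DIA nuclear CDX2 {s['dia_cdx2_nucleus']:.3f}, "
        f"Allred {s['allred_cdx2_ps']}+{s['allred_cdx2_is']}="
        f"{s['allred_cdx2_total']}"
    )
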