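"""Simulate one TMA core and look at its ground truth.

The generator draws a case-level cohort table first (expression means,
covariates, survival), then builds per-core geometry and per-cell
expression, and finally renders a multichannel fluorescence image plus a
chromogenic DAB optical-density image of the same core.
"""

import numpy as np

from plexdia import CohortConfig, DetectionModel, default_spectral_library
from plexdia.synthdata import build_core, render_chromogenic, render_fluorescence, simulate_cohort_table

config = CohortConfig(seed=1, n_cases=5)
model = DetectionModel()
library = default_spectral_library()

cases = simulate_cohort_table(config)
print("cohort table columns:", ", ".join(cases.columns))
case = cases.iloc[0]
print(f"case 0: CDX2 mean {case['cdx2_truth']:.3f}, SOX2 mean {case['sox2_truth']:.3f}, "
      f"MSI {case['msi_status']}, event {case['event']} at {case['time_months']:.1f} months")

truth = build_core(case, config)
print(f"placed {truth.n_cells} cells "
      f"(target {case['n_cells']}) in a {config.image_size_px}px core")
print(f"compartment pixels: nucleus {np.count_nonzero(truth.nucleus_labels)}, "
      f"membrane {np.count_nonzero(truth.membrane_labels)}, "
      f"cytoplasm {np.count_nonzero(truth.cytoplasm_labels)}")

fluor = render_fluorescence(truth, library, model, config)
chrom = render_chromogenic(truth, model, config, marker="CDX2")
print(f"fluorescence image: {fluor.pixels.shape} (bands, H, W), "
      f"counts up to {fluor.pixels.max():.1f}")
print(f"chromogenic OD image: max {chrom.max():.2f} "
      f"(bounded by od_max={model.od_max} by saturation)")
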