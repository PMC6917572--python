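"""Per-cell and per-case scoring: continuous DIA scores and Allred scores.

Two score families are computed on the same segmented cells:

* **DIA score** — the digital image analysis readout: the unweighted mean,
  over included epithelial cells, of each cell's mean marker intensity
  within a cellular compartment (nucleus/cytoplasm/membrane), measured on
  the unmixed fluorescence abundance maps. Continuous, linear in signal.

* **Allred score** — the simulated visual readout of the chromogenic stain:
  proportion score PS in 0..5 from the fraction of positive cells, plus
  intensity score IS in 0..3 from the mean optical density over positive
  cells, total 0..8. A cell is positive when its compartment mean OD
  exceeds the positivity threshold of the detection model.

Also provided: equal-frequency 10-bin percentile binning of per-cell scores
(for single-cell visualization) and the percentile-based case
classification used for the predetermined CDX2-positivity cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import SegmentationResult
from .synthdata import DetectionModel

__all__ = [
    "CaseScore",
    "cell_compartment_means",
    "dia_case_score",
    "allred_proportion_score",
    "allred_intensity_score",
    "allred_case_score",
    "percentile_bins",
    "classify_by_percentile",
]

COMPARTMENTS = ("nucleus", "cytoplasm", "membrane")

# Allred proportion-score bin upper edges (half-open on the left):
# 0 -> 0, (0, 1%] -> 1, (1%, 10%] -> 2, (10%, 33%] -> 3, (33%, 66%] -> 4,
# (66%, 100%] -> 5
_PS_EDGES = (0.0, 0.01, 0.10, 1.0 / 3.0, 2.0 / 3.0, 1.0)


@dataclass(frozen=True)
class CaseScore:
    """Case-level scores for one marker/compartment."""

    case_id: int
    marker: str
    compartment: str
    dia_score: float | None
    proportion_score: int
    intensity_score: int

    @property
    def allred_total(self) -> int:
        return self.proportion_score + self.intensity_score


def cell_compartment_means(
    channel: np.ndarray, seg: SegmentationResult
) -> pd.DataFrame:
    """Mean intensity of one channel per cell and compartment.

    Cells whose compartment is empty get a missing value (NaN), never zero.

    Parameters
    ----------
    channel : 2D ndarray
        One abundance map (fluorescence) or OD image (chromogenic).
    seg : SegmentationResult

    Returns
    -------
    DataFrame indexed by cell_id with columns ``nucleus``, ``cytoplasm``,
    ``membrane``.
    """
    channel = np.asarray(channel, dtype=float)
    n = seg.n_epithelial_cells
    out: dict[str, np.ndarray] = {}
    for comp, labels in (
        ("nucleus", seg.nucleus_labels),
        ("cytoplasm", seg.cytoplasm_labels),
        ("membrane", seg.membrane_labels),
    ):
        flat = labels.ravel()
        sums = np.bincount(flat, weights=channel.ravel(), minlength=n + 1)
        counts = np.bincount(flat, minlength=n + 1)
        with np.errstate(invalid="ignore"):
            means = sums / counts
        out[comp] = means[1:]
    return pd.DataFrame(out, index=pd.RangeIndex(1, n + 1, name="cell_id"))


def dia_case_score(cell_values: np.ndarray | pd.Series) -> float | None:
    """Case-level DIA score: unweighted mean of per-cell compartment means.

    Cells with a missing compartment value are skipped. Returns ``None``
    when no usable cell remains.
    """
    vals = np.asarray(cell_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return None
    return float(vals.mean())


def allred_proportion_score(frac_positive: float) -> int:
    """Allred proportion score PS in 0..5 from the positive-cell fraction.

    Bins: 0 = none, 1 for fractions up to 1%, 2 for 1-10%, 3 for 11-33%,
    4 for 34-66%, 5 for 67-100% (left-open, right-closed bins).
    """
    f = float(frac_positive)
    if not 0.0 <= f <= 1.0 or math.isnan(f):
        raise ValueError(f"positive fraction {f} outside [0, 1]")
    if f == 0.0:
        return 0
    for score in range(1, 6):
        if f <= _PS_EDGES[score] + 1e-12:
            return score
    return 5


def allred_intensity_score(mean_positive_od: float, model: DetectionModel) -> int:
    """Allred intensity score IS in 0..3 from the mean OD of positive cells.

    0 = negative (below the weak threshold), 1 = weak, 2 = intermediate,
    3 = strong; category thresholds are left-closed.
    """
    od = float(mean_positive_od)
    if od < 0:
        raise ValueError("mean OD must be >= 0")
    if od >= model.t_strong:
        return 3
    if od >= model.t_mod:
        return 2
    if od >= model.t_weak:
        return 1
    return 0


def allred_case_score(
    chromogenic: np.ndarray,
    seg: SegmentationResult,
    model: DetectionModel,
    case_id: int = 0,
    marker: str = "CDX2",
    compartment: str = "nucleus",
) -> CaseScore:
    """Simulated visual Allred score of one core from its chromogenic image.

    Per cell, the compartment mean OD is computed; a cell is positive when
    its OD exceeds the model's positivity threshold. PS comes from the
    positive fraction and IS from the mean OD over positive cells (0 when
    there are none); the total is PS + IS.
    """
    means = cell_compartment_means(chromogenic, seg)[compartment]
    vals = means.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no cells with a usable compartment to score")
    positive = vals > model.t_pos
    frac = positive.mean()
    ps = allred_proportion_score(frac)
    is_ = (
        allred_intensity_score(float(vals[positive].mean()), model)
        if positive.any()
        else 0
    )
    return CaseScore(
        case_id=case_id,
        marker=marker,
        compartment=compartment,
        dia_score=None,
        proportion_score=ps,
        intensity_score=is_,
    )


def percentile_bins(values: np.ndarray | pd.Series, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency percentile bin (1..n_bins) per value.

    Bin 1 is the lowest percentile. Ranks are competition ("min") ranks so
    tied values share the bin of their lowest-ranked member; each bin holds
    ``ceil(n / n_bins)`` ranks.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} values, got {n}")
    from scipy.stats import rankdata

    ranks = rankdata(vals, method="min").astype(int) - 1
    width = -(-n // n_bins)  # ceil(n / n_bins)
    return (ranks // width + 1).astype(int)


def classify_by_percentile(
    case_scores: np.ndarray | pd.Series, percentile: float = 11.0
) -> tuple[np.ndarray, float]:
    """Label cases positive/negative by a predetermined percentile cutoff.

    The threshold is the linear-interpolation empirical quantile at
    ``percentile``/100, computed over all scored cases; a case is negative
    iff its score is strictly below the threshold.

    Returns
    -------
    labels : ndarray of str, "positive"/"negative" (NaN scores get "").
    threshold : float
    """
    vals = np.asarray(case_scores, dtype=float)
    scored = np.isfinite(vals)
    if scored.sum() < 10:
        raise ValueError("need at least 10 scored cases for a percentile cutoff")
    threshold = float(np.quantile(vals[scored], percentile / 100.0))
    labels = np.full(vals.shape, "", dtype=object)
    labels[scored] = np.where(vals[scored] < threshold, "negative", "positive")
    return labels, threshold
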