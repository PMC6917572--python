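"""Tissue, nucleus and compartment segmentation from abundance maps.

The commercial trainable tissue classifier used in the original workflow is
replaced here by transparent classical operators: Otsu thresholding with
morphological cleanup for epithelium-vs-stroma/background, a
distance-transform watershed on the DAPI abundance for individual nuclei,
and a seeded watershed on pan-cytokeratin-weighted topography for cell
territories. The membrane is a fixed-width ribbon on territory boundaries
and the cytoplasm is the remainder of the territory.

All steps are deterministic given the input maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .synthdata import compartmentalize

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "segment_epithelium",
    "segment_nuclei",
    "segment_compartments",
    "segment_core",
    "apply_exclusions",
]

REASON_TOO_FEW_CELLS = "insufficient epithelial cells"


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components smaller than ``min_area`` pixels."""
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[labels]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters with desk-scale defaults."""

    closing_radius: int = 2
    min_object_area: int = 64
    otsu_offset: float = 0.0  # additive shift on the Otsu threshold
    min_peak_separation: int = 4
    nucleus_min_area: int = 4
    membrane_band_px: float = 2.0
    panck_weight: float = 1.0


@dataclass
class SegmentationResult:
    """Per-core segmentation output.

    Compartment label images share cell labels (contiguous positive
    integers); per-cell compartments are disjoint by construction.
    """

    epithelium_mask: np.ndarray
    nucleus_labels: np.ndarray
    territory_labels: np.ndarray
    membrane_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    qc_flags: list[str] = field(default_factory=list)
    flagged_cells: dict[int, str] = field(default_factory=dict)

    @property
    def n_epithelial_cells(self) -> int:
        return int(self.nucleus_labels.max())

    def cell_table(self) -> pd.DataFrame:
        """Per-cell geometry: centroid and compartment areas."""
        rows = []
        areas = {
            name: np.bincount(
                img.ravel(), minlength=self.n_epithelial_cells + 1
            )
            for name, img in (
                ("nucleus", self.nucleus_labels),
                ("membrane", self.membrane_labels),
                ("cytoplasm", self.cytoplasm_labels),
                ("territory", self.territory_labels),
            )
        }
        for prop in regionprops(self.nucleus_labels):
            cid = prop.label
            rows.append(
                {
                    "cell_id": cid,
                    "centroid_y": prop.centroid[0],
                    "centroid_x": prop.centroid[1],
                    "area_nucleus": int(areas["nucleus"][cid]),
                    "area_membrane": int(areas["membrane"][cid]),
                    "area_cytoplasm": int(areas["cytoplasm"][cid]),
                    "area_territory": int(areas["territory"][cid]),
                    "flag": self.flagged_cells.get(cid, ""),
                }
            )
        return pd.DataFrame(rows)


def segment_epithelium(
    epi_abundance: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> tuple[np.ndarray, list[str]]:
    """Binary epithelium mask from the epithelial-marker abundance map.

    Automatic global (Otsu) threshold, morphological closing, hole filling
    and small-object removal. A blank map yields an empty mask plus a QC
    flag rather than an exception.
    """
    amap = np.asarray(epi_abundance, dtype=float)
    if not np.all(np.isfinite(amap)):
        raise ValueError("abundance map must be finite")
    flags: list[str] = []
    if not np.any(amap > 0) or np.ptp(amap) == 0:
        flags.append("blank epithelial map")
        return np.zeros(amap.shape, dtype=bool), flags
    thr = threshold_otsu(amap) + params.otsu_offset
    mask = amap > thr
    if params.closing_radius > 0:
        mask = ndi.binary_closing(mask, structure=disk(params.closing_radius))
    mask = ndi.binary_fill_holes(mask)
    mask = _drop_small(mask, params.min_object_area)
    if not mask.any():
        flags.append("empty epithelium after cleanup")
    return mask, flags


def segment_nuclei(
    dapi_abundance: np.ndarray,
    epithelium_mask: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[np.ndarray, list[str]]:
    """Label individual nuclei from the DAPI abundance map.

    Otsu threshold restricted to the epithelium, then a distance-transform
    watershed seeded at local distance maxima (minimum peak separation is
    configurable) to split touching nuclei.
    """
    dapi = np.asarray(dapi_abundance, dtype=float)
    mask = np.asarray(epithelium_mask, dtype=bool)
    flags: list[str] = []
    fg = dapi[mask] if mask.any() else dapi.ravel()
    if fg.size == 0 or np.ptp(fg) == 0 or not np.any(fg > 0):
        flags.append("no nuclei detected")
        return np.zeros(dapi.shape, dtype=np.int32), flags
    thr = threshold_otsu(fg)
    nuclei_mask = (dapi > thr) & mask
    nuclei_mask = _drop_small(nuclei_mask, params.nucleus_min_area)
    if not nuclei_mask.any():
        flags.append("no nuclei detected")
        return np.zeros(dapi.shape, dtype=np.int32), flags
    dist = ndi.distance_transform_edt(nuclei_mask)
    peaks = peak_local_max(
        dist,
        min_distance=params.min_peak_separation,
        labels=nuclei_mask,
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=nuclei_mask)
    labels, _ = _relabel_sequential(labels)
    if labels.max() == 0:
        flags.append("no nuclei detected")
    return labels, flags


def _relabel_sequential(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel to contiguous 1..K preserving order of first appearance."""
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[labels], vals


def segment_compartments(
    nucleus_labels: np.ndarray,
    epithelium_mask: np.ndarray,
    panck_abundance: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationResult:
    """Partition the epithelium into per-cell territories and compartments.

    Cell territories come from a watershed seeded at nucleus centroids on a
    topography combining normalized pan-cytokeratin signal (high on
    membranes, so watershed lines settle on cell borders) with the distance
    from the seeds. The membrane band is a fixed-width ribbon centered on
    territory boundaries (out-of-mask pixels count as boundary, so edge
    cells keep a band); cytoplasm is territory minus nucleus minus band.
    Cells with an empty cytoplasm or band are flagged, not dropped.
    """
    mask = np.asarray(epithelium_mask, dtype=bool)
    nucleus_labels = np.asarray(nucleus_labels, dtype=np.int32)
    panck = np.asarray(panck_abundance, dtype=float)

    markers = np.zeros_like(nucleus_labels)
    for prop in regionprops(nucleus_labels):
        y, x = (int(round(c)) for c in prop.centroid)
        markers[y, x] = prop.label

    if panck.max() > 0:
        panck_norm = panck / panck.max()
    else:
        panck_norm = panck
    dist_from_seeds = ndi.distance_transform_edt(markers == 0)
    if dist_from_seeds.max() > 0:
        dist_from_seeds = dist_from_seeds / dist_from_seeds.max()
    elevation = params.panck_weight * panck_norm + dist_from_seeds

    territory = watershed(elevation, markers, mask=mask).astype(np.int32)
    # keep every nucleus inside its own territory
    nuc_in = nucleus_labels > 0
    territory[nuc_in] = nucleus_labels[nuc_in]
    nucleus = np.where(territory == nucleus_labels, nucleus_labels, 0).astype(np.int32)

    membrane, cytoplasm = compartmentalize(
        territory, nucleus, params.membrane_band_px
    )

    n_cells = int(nucleus_labels.max())
    counts = {
        name: np.bincount(img.ravel(), minlength=n_cells + 1)
        for name, img in (("membrane", membrane), ("cytoplasm", cytoplasm))
    }
    flagged: dict[int, str] = {}
    for cid in range(1, n_cells + 1):
        missing = [k for k in ("membrane", "cytoplasm") if counts[k][cid] == 0]
        if missing:
            flagged[cid] = "empty " + "+".join(missing)

    return SegmentationResult(
        epithelium_mask=mask,
        nucleus_labels=nucleus,
        territory_labels=territory,
        membrane_labels=membrane,
        cytoplasm_labels=cytoplasm,
        qc_flags=[],
        flagged_cells=flagged,
    )


def segment_core(
    abundance: dict[str, np.ndarray],
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationResult:
    """Full segmentation of one core from named abundance maps.

    Requires ``PANCK`` (epithelium + membrane guidance) and ``DAPI``
    (nuclei) maps.
    """
    epi_mask, epi_flags = segment_epithelium(abundance["PANCK"], params)
    nuclei, nuc_flags = segment_nuclei(abundance["DAPI"], epi_mask, params)
    result = segment_compartments(nuclei, epi_mask, abundance["PANCK"], params)
    result.qc_flags = epi_flags + nuc_flags
    return result


def apply_exclusions(
    seg: SegmentationResult,
    min_cells: int = 50,
    artifact_flags: dict[str, bool] | None = None,
) -> tuple[bool, str]:
    """Case-level inclusion decision.

    Cores with fewer than ``min_cells`` epithelial cells (strict
    less-than), segmentation QC flags, or simulated technical artifacts
    (tissue fold / necrosis table flags) are excluded; the reason string is
    recorded.

    Returns
    -------
    (include, reason) : include is True when the core passes all filters;
        reason is empty for included cores.
    """
    reasons = []
    if seg.n_epithelial_cells < min_cells:
        reasons.append(REASON_TOO_FEW_CELLS)
    if seg.qc_flags:
        reasons.append("; ".join(seg.qc_flags))
    for name, flagged in (artifact_flags or {}).items():
        if flagged:
            reasons.append(name)
    return (len(reasons) == 0), "; ".join(reasons)
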