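"""Segmentation tests: analytic fixtures with known geometry plus accuracy
gates on a rendered synthetic core."""

from __future__ import annotations

import numpy as np
import pytest

from plexdia.segment import (
    REASON_TOO_FEW_CELLS,
    SegmentationParams,
    SegmentationResult,
    apply_exclusions,
    segment_compartments,
    segment_core,
    segment_epithelium,
    segment_nuclei,
)
from plexdia.unmix import unmix_pixels


def _disc(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


# ---------------------------------------------------------------------------
# epithelium


def test_epithelium_bimodal_exact():
    amap = np.zeros((64, 64))
    region = _disc(amap.shape, 32, 32, 20)
    amap[region] = 10.0
    mask, flags = segment_epithelium(amap, SegmentationParams(closing_radius=0, min_object_area=1))
    np.testing.assert_array_equal(mask, region)
    assert flags == []


def test_epithelium_blank_map_flagged_not_raised():
    mask, flags = segment_epithelium(np.zeros((32, 32)))
    assert not mask.any()
    assert any("blank" in f for f in flags)


def test_epithelium_nonfinite_rejected():
    amap = np.zeros((8, 8))
    amap[0, 0] = np.nan
    with pytest.raises(ValueError):
        segment_epithelium(amap)


def test_epithelium_small_objects_removed():
    amap = np.zeros((64, 64))
    amap[_disc(amap.shape, 32, 32, 15)] = 10.0
    amap[2, 2] = 10.0  # speck
    mask, _ = segment_epithelium(amap, SegmentationParams(closing_radius=0, min_object_area=20))
    assert not mask[2, 2]
    assert mask[32, 32]


def test_epithelium_accuracy_on_synthetic_core(default_core, library):
    abund, _ = unmix_pixels(default_core["fluor"].pixels, library)
    amaps = {n: abund[i] for i, n in enumerate(library.names)}
    mask, _ = segment_epithelium(amaps["PANCK"])
    truth = default_core["truth"].epithelium_mask
    jaccard = (mask & truth).sum() / (mask | truth).sum()
    assert jaccard >= 0.9


# ---------------------------------------------------------------------------
# nuclei


def test_nuclei_two_separated_discs_exact():
    dapi = np.zeros((48, 48))
    a = _disc(dapi.shape, 12, 12, 4)
    b = _disc(dapi.shape, 34, 34, 4)
    dapi[a | b] = 5.0
    labels, flags = segment_nuclei(dapi, np.ones_like(dapi, dtype=bool))
    assert labels.max() == 2
    la, lb = labels[12, 12], labels[34, 34]
    assert {la, lb} == {1, 2}
    np.testing.assert_array_equal(labels == la, a)
    np.testing.assert_array_equal(labels == lb, b)
    assert flags == []


def test_nuclei_touching_discs_split_by_watershed():
    dapi = np.zeros((40, 60))
    a = _disc(dapi.shape, 20, 22, 6)
    b = _disc(dapi.shape, 20, 34, 6)
    dapi[a | b] = 5.0  # overlapping by a narrow neck
    labels, _ = segment_nuclei(dapi, np.ones_like(dapi, dtype=bool))
    assert labels.max() == 2
    assert labels[20, 22] != labels[20, 34]


def test_nuclei_blank_flagged():
    labels, flags = segment_nuclei(np.zeros((16, 16)), np.ones((16, 16), dtype=bool))
    assert labels.max() == 0
    assert any("no nuclei" in f for f in flags)


def test_nuclei_accuracy_on_synthetic_core(default_core, library):
    abund, _ = unmix_pixels(default_core["fluor"].pixels, library)
    amaps = {n: abund[i] for i, n in enumerate(library.names)}
    epi, _ = segment_epithelium(amaps["PANCK"])
    labels, _ = segment_nuclei(amaps["DAPI"], epi)
    truth = default_core["truth"]
    n_true = truth.n_cells
    n_det = labels.max()
    assert abs(n_det - n_true) <= 0.1 * n_true
    # per-nucleus matching F1 at IoU 0.5 against ground-truth nuclei
    from scipy import ndimage as ndi

    matches = 0
    for cid in truth.cells["cell_id"]:
        t_mask = truth.nucleus_labels == cid
        overlap_labels = labels[t_mask]
        overlap_labels = overlap_labels[overlap_labels > 0]
        if overlap_labels.size == 0:
            continue
        cand = np.bincount(overlap_labels).argmax()
        d_mask = labels == cand
        iou = (t_mask & d_mask).sum() / (t_mask | d_mask).sum()
        if iou >= 0.5:
            matches += 1
    precision = matches / n_det
    recall = matches / n_true
    f1 = 2 * precision * recall / (precision + recall)
    assert f1 >= 0.9
    del ndi


# ---------------------------------------------------------------------------
# compartments


def test_single_cell_whole_mask_no_band_flagged():
    nuclei = np.zeros((20, 20), dtype=np.int32)
    nuclei[9:12, 9:12] = 1
    mask = np.ones((20, 20), dtype=bool)
    panck = np.zeros((20, 20))
    res = segment_compartments(nuclei, mask, panck)
    assert not res.membrane_labels.any()
    assert 1 in res.flagged_cells
    assert "membrane" in res.flagged_cells[1]


def test_honeycomb_band_area_matches_analytic_ribbon():
    """Square-grid 'honeycomb': interior cells share straight boundaries, so
    the per-cell band area is analytic: a 1-px-deep frame of the territory."""
    size, step = 60, 15
    territory = np.zeros((size, size), dtype=np.int32)
    nucleus = np.zeros_like(territory)
    label = 0
    for gy in range(size // step):
        for gx in range(size // step):
            label += 1
            territory[gy * step : (gy + 1) * step, gx * step : (gx + 1) * step] = label
            nucleus[gy * step + step // 2, gx * step + step // 2] = label
    from plexdia.synthdata import compartmentalize

    membrane, _ = compartmentalize(territory, nucleus, band_px=2.0)
    # interior cell (no image-border sides): full 1-px frame
    interior_label = territory[step + 1, step + 1]
    analytic = step * step - (step - 2) * (step - 2)
    got = int((membrane == interior_label).sum())
    assert abs(got - analytic) <= 0.1 * analytic


def test_territory_iou_against_ground_truth(default_core, library):
    abund, _ = unmix_pixels(default_core["fluor"].pixels, library)
    amaps = {n: abund[i] for i, n in enumerate(library.names)}
    seg = segment_core(amaps)
    truth = default_core["truth"]
    ious = []
    for cid in truth.cells["cell_id"]:
        t_mask = truth.territory_labels == cid
        overlap = seg.territory_labels[t_mask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            ious.append(0.0)
            continue
        cand = np.bincount(overlap).argmax()
        d_mask = seg.territory_labels == cand
        ious.append((t_mask & d_mask).sum() / (t_mask | d_mask).sum())
    assert np.mean(ious) >= 0.8


def test_segmentation_compartments_disjoint(default_core, library):
    abund, _ = unmix_pixels(default_core["fluor"].pixels, library)
    amaps = {n: abund[i] for i, n in enumerate(library.names)}
    seg = segment_core(amaps)
    nuc = seg.nucleus_labels > 0
    mem = seg.membrane_labels > 0
    cyt = seg.cytoplasm_labels > 0
    assert not np.any(nuc & mem) and not np.any(nuc & cyt) and not np.any(mem & cyt)
    # full coverage within territory
    np.testing.assert_array_equal(nuc | mem | cyt, seg.territory_labels > 0)
    # labels contiguous 1..K
    present = np.unique(seg.nucleus_labels)
    assert present[0] == 0
    np.testing.assert_array_equal(present[1:], np.arange(1, seg.n_epithelial_cells + 1))


def test_segmentation_deterministic(default_core, library):
    abund, _ = unmix_pixels(default_core["fluor"].pixels, library)
    amaps = {n: abund[i] for i, n in enumerate(library.names)}
    a = segment_core(amaps)
    b = segment_core(amaps)
    np.testing.assert_array_equal(a.nucleus_labels, b.nucleus_labels)
    np.testing.assert_array_equal(a.territory_labels, b.territory_labels)
    np.testing.assert_array_equal(a.membrane_labels, b.membrane_labels)


def test_cell_table_shape(default_core, library):
    abund, _ = unmix_pixels(default_core["fluor"].pixels, library)
    amaps = {n: abund[i] for i, n in enumerate(library.names)}
    seg = segment_core(amaps)
    tab = seg.cell_table()
    assert len(tab) == seg.n_epithelial_cells
    assert set(tab.columns) >= {
        "cell_id",
        "centroid_y",
        "centroid_x",
        "area_nucleus",
        "area_membrane",
        "area_cytoplasm",
        "area_territory",
    }
    assert (tab["area_nucleus"] > 0).all()


# ---------------------------------------------------------------------------
# exclusions


def _seg_with_n_cells(n: int) -> SegmentationResult:
    labels = np.zeros((4, max(n, 1)), dtype=np.int32)
    labels[0, :n] = np.arange(1, n + 1)
    zeros = np.zeros_like(labels)
    return SegmentationResult(
        epithelium_mask=labels > 0,
        nucleus_labels=labels,
        territory_labels=labels,
        membrane_labels=zeros,
        cytoplasm_labels=zeros,
    )


def test_exclusion_49_cells():
    include, reason = apply_exclusions(_seg_with_n_cells(49))
    assert not include
    assert reason == REASON_TOO_FEW_CELLS


def test_inclusion_50_cells_boundary():
    include, reason = apply_exclusions(_seg_with_n_cells(50))
    assert include
    assert reason == ""


def test_exclusion_rule_over_three_cores():
    decisions = [apply_exclusions(_seg_with_n_cells(n))[0] for n in (30, 50, 120)]
    assert sum(decisions) == 2


def test_exclusion_artifact_flags():
    include, reason = apply_exclusions(
        _seg_with_n_cells(100), artifact_flags={"tissue fold": True, "necrosis": False}
    )
    assert not include
    assert "tissue fold" in reason
    assert "necrosis" not in reason


def test_exclusion_qc_flags():
    seg = _seg_with_n_cells(100)
    seg.qc_flags = ["blank epithelial map"]
    include, reason = apply_exclusions(seg)
    assert not include
    assert "blank epithelial map" in reason
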