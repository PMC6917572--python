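"""Generator tests: determinism, validation, forward-model identities, and
Monte-Carlo recovery of the statistical targets the generator emulates."""

from __future__ import annotations

import math

import numpy as np
import pytest

from plexdia.stats import spearman
from plexdia.synthdata import (
    CohortConfig,
    ConfigurationError,
    DetectionModel,
    build_core,
    compartmentalize,
    default_spectral_library,
    render_chromogenic,
    render_fluorescence,
    simulate_case_cells,
    simulate_cohort_table,
)
from plexdia.unmix import SpectralLibrary


# ---------------------------------------------------------------------------
# config validation


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_cases": 1},
        {"n_cases": 10, "frac_cdx2_low": -0.1},
        {"n_cases": 10, "frac_cdx2_low": 1.5},
        {"n_cases": 10, "hr_cdx2_low": 0.0},
        {"n_cases": 10, "hr_cdx2_low": -2.0},
        {"n_cases": 10, "rho_cdx2_sox2": -1.0},
        {"n_cases": 10, "followup_months": 0},
        {"n_cases": 10, "image_size_px": 8},
        # infeasible MSI coupling: share*frac_low > frac_msi
        {"n_cases": 10, "frac_msi": 0.01, "frac_cdx2_low": 0.5, "msi_share_of_low": 0.9},
    ],
)
def test_cohort_config_rejects_invalid(kwargs):
    with pytest.raises(ConfigurationError):
        CohortConfig(**kwargs)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"od_max": 0.0},
        {"k_half": -1.0},
        {"gain": 0.0},
        {"t_pos": 0.0},
        {"t_weak": 0.9, "t_mod": 0.8},  # misordered
        {"t_strong": 2.5},  # above od_max
        {"noise_sd": -0.1},
    ],
)
def test_detection_model_rejects_invalid(kwargs):
    with pytest.raises(ConfigurationError):
        DetectionModel(**kwargs)


# ---------------------------------------------------------------------------
# determinism


def test_cohort_table_deterministic():
    cfg = CohortConfig(seed=1, n_cases=50)
    a = simulate_cohort_table(cfg)
    b = simulate_cohort_table(cfg)
    assert a.equals(b)


def test_rendered_core_deterministic(library, model):
    cfg = CohortConfig(seed=1, n_cases=3, image_size_px=96, cells_per_core=40)
    cases = simulate_cohort_table(cfg)
    outs = []
    for _ in range(2):
        truth = build_core(cases.iloc[1], cfg)
        fluor = render_fluorescence(truth, library, model, cfg)
        chrom = render_chromogenic(truth, model, cfg)
        outs.append((fluor.pixels, chrom, truth.nucleus_labels))
    for a, b in zip(*outs, strict=True):
        np.testing.assert_array_equal(a, b)


def test_different_seeds_differ():
    a = simulate_cohort_table(CohortConfig(seed=1, n_cases=50))
    b = simulate_cohort_table(CohortConfig(seed=2, n_cases=50))
    assert not np.array_equal(a["cdx2_truth"], b["cdx2_truth"])


# ---------------------------------------------------------------------------
# chromogenic forward model (Hill response)


def test_chromogenic_zero_expression_zero_od(model):
    assert model.od(0.0) == 0.0


def test_chromogenic_half_saturation(model):
    assert model.od(model.k_half) == pytest.approx(model.od_max / 2)


def test_chromogenic_compression_at_high_expression(model):
    od1 = model.od(10 * model.k_half)
    od2 = model.od(100 * model.k_half)
    assert od2 / od1 < 1.1  # 10x expression, <10% OD change
    assert od2 < model.od_max


def test_chromogenic_monotone_concave_bounded(model):
    e = np.linspace(0, 50, 400)
    od = model.od(e)
    d1 = np.diff(od)
    assert np.all(d1 > 0)  # strictly increasing
    assert np.all(np.diff(d1) < 1e-12)  # concave
    assert np.all(od < model.od_max)


def test_render_chromogenic_noiseless_matches_truth_map(noiseless_core):
    core = noiseless_core
    od = render_chromogenic(core["truth"], core["model"], core["config"], noise=False)
    e_map = core["truth"].expression_map("CDX2")
    np.testing.assert_allclose(od, core["model"].od(e_map), atol=1e-6)


# ---------------------------------------------------------------------------
# fluorescence forward model


def test_fluorescence_linearity_doubling(library):
    cfg = CohortConfig(seed=5, n_cases=2, image_size_px=96, cells_per_core=30)
    model = DetectionModel(noise_sd=0.0)
    cases = simulate_cohort_table(cfg)
    truth = build_core(cases.iloc[0], cfg)
    base = render_fluorescence(truth, library, model, cfg, noise=False).pixels
    doubled_truth = build_core(cases.iloc[0], cfg)
    for col in ("E_CDX2", "E_SOX2", "E_BCAT", "E_PANCK", "E_DAPI"):
        doubled_truth.cells[col] *= 2.0
    doubled = render_fluorescence(doubled_truth, library, model, cfg, noise=False).pixels
    af = library.signatures[:, library.index("AF")]
    af_term = 0.5 * np.einsum("b,hw->bhw", af, truth.core_mask.astype(float))
    np.testing.assert_allclose(doubled - af_term, 2 * (base - af_term), atol=1e-5)


def test_fluorescence_stained_pixel_proportional_to_signature(library):
    """Noiseless, single expressed marker: nuclear pixels carry that
    signature (plus DAPI and the known AF term)."""
    cfg = CohortConfig(seed=5, n_cases=2, image_size_px=96, cells_per_core=30)
    model = DetectionModel(noise_sd=0.0)
    cases = simulate_cohort_table(cfg)
    truth = build_core(cases.iloc[0], cfg)
    for col in ("E_SOX2", "E_BCAT", "E_PANCK", "E_DAPI"):
        truth.cells[col] = 0.0
    img = render_fluorescence(truth, library, model, cfg, noise=False)
    cell = truth.cells.iloc[0]
    inside = truth.nucleus_labels == int(cell["cell_id"])
    spectrum = img.pixels[:, inside].mean(axis=1)
    af = 0.5 * library.signatures[:, library.index("AF")]
    expected = model.gain * cell["E_CDX2"] * library.signatures[:, library.index("CDX2")] + af
    np.testing.assert_allclose(spectrum, expected, atol=1e-5)


def test_fluorescence_zero_everything_blank_outside_structures(library):
    cfg = CohortConfig(seed=5, n_cases=2, image_size_px=96, cells_per_core=30)
    model = DetectionModel(noise_sd=0.0)
    cases = simulate_cohort_table(cfg)
    truth = build_core(cases.iloc[0], cfg)
    for col in ("E_CDX2", "E_SOX2", "E_BCAT"):
        truth.cells[col] = 0.0
    img = render_fluorescence(truth, library, model, cfg, noise=False)
    structures = (truth.territory_labels > 0) | truth.core_mask
    outside = ~structures
    assert np.all(np.abs(img.pixels[:, outside]) < 1e-9)


def test_fluorescence_unassigned_fluorophore_error(library, model):
    cfg = CohortConfig(seed=5, n_cases=2, image_size_px=96, cells_per_core=30)
    cases = simulate_cohort_table(cfg)
    truth = build_core(cases.iloc[0], cfg)
    extra = SpectralLibrary(
        library.names + ("MYSTERY",),
        np.column_stack([library.signatures, np.exp(-np.arange(8) / 2.0)]),
    )
    with pytest.raises(ConfigurationError, match="MYSTERY"):
        render_fluorescence(truth, extra, model, cfg)


def test_clip_counts_ceiling_applied(library):
    cfg = CohortConfig(seed=5, n_cases=2, image_size_px=96, cells_per_core=30)
    model = DetectionModel(noise_sd=0.0, clip_counts=0.5)
    cases = simulate_cohort_table(cfg)
    truth = build_core(cases.iloc[0], cfg)
    img = render_fluorescence(truth, library, model, cfg, noise=False)
    assert img.pixels.max() <= 0.5 + 1e-6


# ---------------------------------------------------------------------------
# geometry / ground-truth invariants


def test_ground_truth_compartments_disjoint_and_cover_territory(default_core):
    t = default_core["truth"]
    nuc = t.nucleus_labels > 0
    mem = t.membrane_labels > 0
    cyt = t.cytoplasm_labels > 0
    assert not np.any(nuc & mem)
    assert not np.any(nuc & cyt)
    assert not np.any(mem & cyt)
    covered = nuc | mem | cyt
    np.testing.assert_array_equal(covered, t.territory_labels > 0)


def test_every_cell_has_nonempty_nucleus(default_core):
    t = default_core["truth"]
    ids = t.cells["cell_id"].to_numpy()
    present = np.unique(t.nucleus_labels)
    assert set(ids) <= set(present)


def test_expression_finite_nonnegative(default_core):
    cells = default_core["truth"].cells
    for col in ("E_CDX2", "E_SOX2", "E_BCAT", "E_PANCK", "E_DAPI"):
        vals = cells[col].to_numpy()
        assert np.all(np.isfinite(vals))
        assert np.all(vals >= 0)


def test_nucleus_spacing_respected(default_core):
    t = default_core["truth"]
    cfg = default_core["config"]
    pts = t.cells[["y", "x"]].to_numpy()
    from scipy.spatial.distance import pdist

    assert pdist(pts).min() >= cfg.min_nucleus_spacing_px - 1e-9


def test_compartmentalize_band_width_straight_boundary():
    """Two half-plane territories: the band is band_px wide, split evenly."""
    territory = np.ones((20, 40), dtype=np.int32)
    territory[:, 20:] = 2
    nucleus = np.zeros_like(territory)
    membrane, cytoplasm = compartmentalize(territory, nucleus, band_px=2.0)
    # pixels within 1.0 of the other territory: one column each side
    assert set(np.unique(np.nonzero(membrane == 1)[1])) == {19}
    assert set(np.unique(np.nonzero(membrane == 2)[1])) == {20}
    # image borders are not boundaries
    assert membrane[0, 5] == 0 and cytoplasm[0, 5] == 1


def test_compartmentalize_whole_image_single_cell_has_no_band():
    territory = np.ones((16, 16), dtype=np.int32)
    nucleus = np.zeros_like(territory)
    membrane, cytoplasm = compartmentalize(territory, nucleus, band_px=2.0)
    assert not membrane.any()
    assert np.all(cytoplasm == 1)


# ---------------------------------------------------------------------------
# statistical structure (Monte Carlo, seeded)


def test_mixture_low_fraction_recovered():
    cfg = CohortConfig(seed=42, n_cases=2000)
    tab = simulate_cohort_table(cfg)
    assert abs(tab["cdx2_low_truth"].mean() - cfg.frac_cdx2_low) < 0.03


def test_degenerate_mixture_unimodal():
    cfg = CohortConfig(seed=42, n_cases=2000, frac_cdx2_low=0.0)
    tab = simulate_cohort_table(cfg)
    assert not tab["cdx2_low_truth"].any()
    # single lognormal: log values pass a normality check comfortably
    from scipy.stats import shapiro

    logs = np.log(tab["cdx2_truth"].to_numpy()[:500])
    assert shapiro(logs).pvalue > 0.01


def test_case_level_rank_correlation_target():
    rhos = []
    for seed in range(20):
        tab = simulate_cohort_table(CohortConfig(seed=seed, n_cases=600))
        rho, _ = spearman(tab["cdx2_truth"], tab["sox2_truth"])
        rhos.append(rho)
    rhos = np.asarray(rhos)
    assert np.all(np.abs(rhos + 0.5) < 0.08)
    assert abs(rhos.mean() + 0.5) < 0.03


def test_msi_enriched_in_cdx2_low():
    tab = simulate_cohort_table(CohortConfig(seed=9, n_cases=4000))
    low = tab[tab["cdx2_low_truth"]]
    share_msi = (low["msi_status"] == "MSI").mean()
    assert abs(share_msi - 0.47) < 0.08


def test_survival_marginal_rates():
    cfg = CohortConfig(seed=3, n_cases=5000, frac_cdx2_low=0.0)
    tab = simulate_cohort_table(cfg)
    # baseline exponential: survival at horizon ~ baseline_survival
    surv = 1.0 - tab["event"].mean()
    assert abs(surv - cfg.baseline_survival) < 0.03
    assert tab["time_months"].max() <= cfg.followup_months + 1e-9
    censored = tab[tab["event"] == 0]
    assert np.allclose(censored["time_months"], cfg.followup_months)


def test_saturation_separates_od_from_counts_in_top_quartile(model):
    """Fig.-4-style property: OD loses rank resolution at high expression."""
    tab = simulate_cohort_table(CohortConfig(seed=21, n_cases=600))
    e = tab["cdx2_truth"].to_numpy()
    rng = np.random.default_rng(21)
    od = model.od(e) + rng.normal(0, model.chrom_noise_sd, size=e.size)
    counts = model.gain * e + rng.normal(0, model.noise_sd, size=e.size)
    top = e >= np.quantile(e, 0.75)
    rho_od, _ = spearman(od[top], e[top])
    rho_counts, _ = spearman(counts[top], e[top])
    assert rho_od < rho_counts


def test_cell_level_noise_is_mean_one():
    cfg = CohortConfig(seed=2, n_cases=2, cells_per_core=20000)
    tab = simulate_cohort_table(cfg)
    cells = simulate_case_cells(tab.iloc[0], cfg)
    ratio = cells["E_CDX2"].mean() / tab.iloc[0]["cdx2_truth"]
    assert abs(ratio - 1.0) < 0.02
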