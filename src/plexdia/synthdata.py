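"""Synthetic TMA cores and cohorts with known ground truth.

This module emulates the statistical structure of a colorectal-cancer tissue
microarray cohort profiled by multiplex fluorescence IHC, so that the whole
downstream pipeline (unmixing, segmentation, scoring, survival statistics)
can be exercised against a known truth:

* case-level CDX2 expression follows a two-component lognormal mixture with
  a small low-expressing component (the bimodality that motivates a
  percentile cutoff for CDX2 positivity);
* SOX2 is drawn through a Gaussian copula on CDX2 normal scores to hit a
  target negative rank correlation, at the case level and, by reusing the
  same latent correlation for within-cell noise, at the single-cell level;
* microsatellite-instable (MSI) cases have an elevated probability of
  belonging to the CDX2-low component;
* overall survival follows a proportional-hazards model with an elevated
  hazard for CDX2-low cases and administrative censoring at the follow-up
  horizon;
* each core is rendered both as a multichannel fluorescence image (linear in
  expression) and as a chromogenic DAB optical-density image with a
  saturating Hill response, reproducing the narrow dynamic range of
  chromogenic detection.

Cell geometry is deliberately simple: nuclei are placed by dart-throwing
(Poisson-disc-like) sampling inside a smooth epithelial blob within a
circular core; cell territories are the nearest-nucleus partition; the
membrane is a fixed-width ribbon on territory boundaries and the cytoplasm
is the remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import ndtri
from scipy.stats import rankdata
from scipy import ndimage as ndi

from .unmix import SpectralLibrary

__all__ = [
    "CohortConfig",
    "DetectionModel",
    "GroundTruth",
    "CoreImage",
    "SimulatedCore",
    "MARKER_COMPARTMENT",
    "default_spectral_library",
    "simulate_cohort_table",
    "simulate_case_cells",
    "build_core",
    "render_fluorescence",
    "render_chromogenic",
    "simulate_cohort",
]

# marker -> compartment in which the true signal lives
MARKER_COMPARTMENT = {
    "CDX2": "nucleus",
    "SOX2": "nucleus",
    "BCAT": "cytoplasm",  # diffuse cytoplasmic, beta-catenin-like
}
#: structural channels present in every core
STRUCTURAL_MARKERS = ("PANCK", "DAPI")
FLUOROPHORES = ("CDX2", "SOX2", "BCAT", "PANCK", "DAPI", "AF")


class ConfigurationError(ValueError):
    """Invalid simulation or detection configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The defaults are the study conditions the generator emulates: ~600-case
    cohorts with an 11% CDX2-low fraction, a case- and cell-level CDX2-SOX2
    rank correlation of -0.5, 14% MSI prevalence, a true hazard ratio of 1.6
    for CDX2-low cases over a 60-month horizon, and ~300 epithelial cells
    per 256x256 px core at 1 um/px.
    """

    n_cases: int
    frac_cdx2_low: float = 0.11
    rho_cdx2_sox2: float = -0.5
    frac_msi: float = 0.14
    hr_cdx2_low: float = 1.6
    followup_months: float = 60.0
    cells_per_core: float = 300.0
    image_size_px: int = 256
    seed: int = 0

    # cell-level noise (lognormal sigma on true expression)
    cell_sigma: float = 0.4
    # survival: baseline (CDX2-high) survival fraction at the follow-up horizon
    baseline_survival: float = 0.55
    # fraction of CDX2-low cases that are MSI (Table-1-like calibration)
    msi_share_of_low: float = 0.47
    # simulated technical-artifact flags (excluded downstream, not rendered)
    frac_fold: float = 0.02
    frac_necrosis: float = 0.02

    # case-level expression marginals (arbitrary units)
    cdx2_high_median: float = 1.5
    cdx2_high_sigma: float = 0.55
    cdx2_low_median: float = 0.02
    cdx2_low_sigma: float = 0.7
    sox2_median: float = 0.15
    sox2_sigma: float = 1.2
    bcat_median: float = 4.0
    bcat_sigma: float = 0.6

    # core geometry
    core_radius_frac: float = 0.47
    epi_radius_frac: float = 0.80
    epi_wobble: float = 0.12
    nucleus_radius_px: float = 3.0
    min_nucleus_spacing_px: float = 8.0
    membrane_band_px: float = 2.0
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ConfigurationError("n_cases must be >= 2")
        for name in (
            "frac_cdx2_low",
            "frac_msi",
            "msi_share_of_low",
            "frac_fold",
            "frac_necrosis",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.hr_cdx2_low <= 0:
            raise ConfigurationError("hr_cdx2_low must be > 0")
        if not -1.0 < self.rho_cdx2_sox2 < 1.0:
            raise ConfigurationError("rho_cdx2_sox2 must lie in (-1, 1)")
        if not 0.0 < self.baseline_survival < 1.0:
            raise ConfigurationError("baseline_survival must lie in (0, 1)")
        if self.followup_months <= 0 or self.cells_per_core <= 0:
            raise ConfigurationError("followup/cells_per_core must be positive")
        if self.image_size_px < 32:
            raise ConfigurationError("image_size_px must be >= 32")
        # MSI coupling feasibility: P(low|MSI) and P(low|MSS) must be in [0,1]
        f, m, s = self.frac_cdx2_low, self.frac_msi, self.msi_share_of_low
        if f > 0 and m > 0 and s * f > m:
            raise ConfigurationError(
                "infeasible MSI coupling: msi_share_of_low * frac_cdx2_low "
                "exceeds frac_msi"
            )
        if f > 0 and m < 1 and (1 - s) * f > (1 - m):
            raise ConfigurationError("infeasible MSI coupling for MSS cases")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class DetectionModel:
    """Forward model of the two detection chemistries.

    Fluorescence is strictly linear in expression: counts = ``gain * E``
    plus Gaussian read noise per spectral band. Chromogenic DAB optical
    density saturates following a Hill response with coefficient 1,
    ``OD(E) = od_max * E / (E + k_half)``, which compresses the high end of
    the expression range. The ``t_*`` thresholds define the simulated visual
    scorer: a cell is positive when its compartment mean OD exceeds
    ``t_pos``, and intensity categories weak/intermediate/strong begin at
    ``t_weak``/``t_mod``/``t_strong``.
    """

    gain: float = 3.0
    noise_sd: float = 0.15
    od_max: float = 2.0
    k_half: float = 0.5
    t_pos: float = 0.10
    t_weak: float = 0.30
    t_mod: float = 0.80
    t_strong: float = 1.40
    chrom_noise_sd: float = 0.02
    clip_counts: float | None = None  # optional acquisition ceiling

    def __post_init__(self) -> None:
        if self.od_max <= 0 or self.k_half <= 0:
            raise ConfigurationError("od_max and k_half must be > 0")
        if self.gain <= 0:
            raise ConfigurationError("gain must be > 0")
        if not (0 < self.t_pos <= self.t_weak < self.t_mod < self.t_strong < self.od_max):
            raise ConfigurationError(
                "thresholds must satisfy 0 < t_pos <= t_weak < t_mod < "
                "t_strong < od_max"
            )
        if self.noise_sd < 0 or self.chrom_noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")

    def od(self, expression: np.ndarray) -> np.ndarray:
        """Noiseless chromogenic optical density for a given expression."""
        e = np.asarray(expression, dtype=float)
        return self.od_max * e / (e + self.k_half)

    def replace(self, **kwargs) -> "DetectionModel":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Latent truth for one simulated core."""

    case_id: int
    cells: pd.DataFrame  # cell_id, y, x, E_CDX2, E_SOX2, E_BCAT, E_PANCK, E_DAPI
    core_mask: np.ndarray
    epithelium_mask: np.ndarray
    territory_labels: np.ndarray
    nucleus_labels: np.ndarray
    membrane_labels: np.ndarray
    cytoplasm_labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def expression_map(self, marker: str) -> np.ndarray:
        """Paint per-cell true expression into the marker's compartment."""
        compartment = MARKER_COMPARTMENT[marker]
        labels = {
            "nucleus": self.nucleus_labels,
            "cytoplasm": self.cytoplasm_labels,
            "membrane": self.membrane_labels,
        }[compartment]
        return _paint(labels, self.cells["cell_id"], self.cells[f"E_{marker}"])


@dataclass
class CoreImage:
    """Multichannel pixel data for one core."""

    pixels: np.ndarray  # (n_channels, H, W) float32
    channel_names: tuple[str, ...]
    um_per_px: float = 1.0
    case_id: int | None = None
    truth: GroundTruth | None = None

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[self.channel_names.index(name)]


@dataclass
class SimulatedCore:
    case_id: int
    fluorescence: CoreImage
    chromogenic: dict[str, np.ndarray]
    truth: GroundTruth


def default_spectral_library(n_bands: int = 8) -> SpectralLibrary:
    """Gaussian emission bumps for the five fluorophores plus broad AF."""
    bands = np.arange(n_bands, dtype=float)
    peaks = {"DAPI": 0.6, "CDX2": 2.0, "SOX2": 3.4, "PANCK": 4.8, "BCAT": 6.2}
    cols = []
    for name in FLUOROPHORES:
        if name == "AF":
            sig = np.exp(-bands / (0.55 * n_bands))  # broad, decaying
        else:
            sig = np.exp(-0.5 * ((bands - peaks[name]) / 0.9) ** 2)
        cols.append(sig)
    return SpectralLibrary(FLUOROPHORES, np.column_stack(cols))


def _rng(config: CohortConfig, stream: int, case: int | None = None) -> np.random.Generator:
    key = [config.seed, stream] if case is None else [config.seed, stream, case]
    return np.random.default_rng(key)


def _latent_r(rho_spearman: float) -> float:
    """Gaussian-copula latent correlation for a target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def simulate_cohort_table(config: CohortConfig) -> pd.DataFrame:
    """Draw case-level truth, covariates and survival for a whole cohort.

    Returns a table with one row per case: true expression means, CDX2-low
    membership, MSI status, clinicopathological covariates, survival
    time/event, technical-artifact flags and the target epithelial cell
    count per core. No images are rendered; this is the fast path used for
    cohort-scale statistical calibration.
    """
    rng = _rng(config, 0)
    n = config.n_cases

    msi = rng.random(n) < config.frac_msi
    f, m, s = config.frac_cdx2_low, config.frac_msi, config.msi_share_of_low
    if f <= 0:
        p_low = np.zeros(n)
    elif m <= 0:
        p_low = np.full(n, f)
    else:
        p_low_msi = min(s * f / m, 1.0)
        p_low_mss = min((1 - s) * f / (1 - m), 1.0) if m < 1 else 0.0
        p_low = np.where(msi, p_low_msi, p_low_mss)
    low = rng.random(n) < p_low

    # case-level CDX2: two-component lognormal mixture
    z1 = rng.standard_normal(n)
    mu = np.where(low, math.log(config.cdx2_low_median), math.log(config.cdx2_high_median))
    sig = np.where(low, config.cdx2_low_sigma, config.cdx2_high_sigma)
    cdx2 = np.exp(mu + sig * z1)

    # SOX2 via Gaussian copula on CDX2 normal scores
    r = _latent_r(config.rho_cdx2_sox2)
    q = ndtri((rankdata(cdx2) - 0.5) / n)
    z2 = r * q + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    sox2 = np.exp(math.log(config.sox2_median) + config.sox2_sigma * z2)

    bcat = np.exp(
        math.log(config.bcat_median) + config.bcat_sigma * rng.standard_normal(n)
    )
    panck = np.exp(0.15 * rng.standard_normal(n))

    # covariates (directions guided by typical CRC cohort structure)
    gender = rng.choice(["female", "male"], size=n)
    age = np.clip(np.round(rng.normal(71, 11, size=n)), 30, 96).astype(int)
    grade_levels = ["high", "moderate", "low", "mucinous"]
    grade_p_high = [0.10, 0.80, 0.09, 0.01]
    grade_p_low = [0.08, 0.40, 0.47, 0.05]
    grade = np.where(
        low,
        rng.choice(grade_levels, size=n, p=grade_p_low),
        rng.choice(grade_levels, size=n, p=grade_p_high),
    )
    stage = np.where(
        low,
        rng.choice([1, 2, 3, 4], size=n, p=[0.08, 0.41, 0.26, 0.25]),
        rng.choice([1, 2, 3, 4], size=n, p=[0.16, 0.42, 0.26, 0.16]),
    )
    loc_levels = ["right", "left", "rectum", "synchronous"]
    location = np.where(
        msi,
        rng.choice(loc_levels, size=n, p=[0.80, 0.08, 0.09, 0.03]),
        rng.choice(loc_levels, size=n, p=[0.33, 0.36, 0.28, 0.03]),
    )

    # proportional-hazards survival, exponential baseline, administrative
    # censoring at the follow-up horizon (complete follow-up otherwise)
    lam0 = -math.log(config.baseline_survival) / config.followup_months
    lam = lam0 * np.where(low, config.hr_cdx2_low, 1.0)
    t_death = rng.exponential(1.0 / lam)
    event = t_death <= config.followup_months
    time_months = np.minimum(t_death, config.followup_months)

    fold = rng.random(n) < config.frac_fold
    necrosis = rng.random(n) < config.frac_necrosis
    n_cells = rng.poisson(config.cells_per_core, size=n).astype(int)

    return pd.DataFrame(
        {
            "case_id": np.arange(n, dtype=int),
            "cdx2_truth": cdx2,
            "sox2_truth": sox2,
            "bcat_truth": bcat,
            "panck_truth": panck,
            "cdx2_low_truth": low,
            "msi_status": np.where(msi, "MSI", "MSS"),
            "differentiation_grade": grade,
            "stage": stage.astype(int),
            "tumor_location": location,
            "age": age,
            "gender": gender,
            "time_months": time_months,
            "event": event.astype(int),
            "tissue_fold": fold,
            "necrosis": necrosis,
            "n_cells": n_cells,
        }
    )


def simulate_case_cells(case: pd.Series, config: CohortConfig) -> pd.DataFrame:
    """Per-cell true expressions for one case (no geometry).

    Cell values are the case mean times mean-one lognormal noise; the CDX2
    and SOX2 log-noise terms share the cohort's latent correlation so the
    single-cell rank correlation matches the case-level target.
    """
    rng = _rng(config, 1, int(case["case_id"]))
    n = int(case["n_cells"])
    s = config.cell_sigma
    r = _latent_r(config.rho_cdx2_sox2)
    z = rng.standard_normal((n, 2))
    z2 = r * z[:, 0] + math.sqrt(1.0 - r * r) * z[:, 1]
    noise = lambda zz, sd: np.exp(sd * zz - 0.5 * sd * sd)  # noqa: E731
    return pd.DataFrame(
        {
            "case_id": int(case["case_id"]),
            "cell_id": np.arange(1, n + 1, dtype=int),
            "E_CDX2": case["cdx2_truth"] * noise(z[:, 0], s),
            "E_SOX2": case["sox2_truth"] * noise(z2, s),
            "E_BCAT": case["bcat_truth"] * noise(rng.standard_normal(n), s),
            "E_PANCK": case["panck_truth"] * noise(rng.standard_normal(n), 0.2),
            "E_DAPI": 2.0 * noise(rng.standard_normal(n), 0.15),
        }
    )


def _dart_throw(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target: int,
    min_dist: float,
) -> np.ndarray:
    """Place up to ``target`` points with pairwise spacing >= min_dist."""
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0 or target <= 0:
        return np.empty((0, 2))
    d2 = min_dist * min_dist
    # background grid with cell side min_dist/sqrt(2): at most one accepted
    # point per grid cell, so neighbor checks scan a fixed 5x5 window
    cell = min_dist / math.sqrt(2.0)
    grid: dict[tuple[int, int], int] = {}
    py: list[float] = []
    px: list[float] = []
    attempts = 40 * target
    order = rng.integers(0, len(ys), size=attempts)
    jitter = rng.random((attempts, 2)) - 0.5
    cand_y = (ys[order] + jitter[:, 0]).tolist()
    cand_x = (xs[order] + jitter[:, 1]).tolist()
    grid_get = grid.get
    offsets = [(dy, dx) for dy in (-2, -1, 0, 1, 2) for dx in (-2, -1, 0, 1, 2)]
    for k in range(attempts):
        if len(py) >= target:
            break
        y, x = cand_y[k], cand_x[k]
        gy, gx = int(y / cell), int(x / cell)
        ok = True
        for dy, dx in offsets:
            j = grid_get((gy + dy, gx + dx))
            if j is not None and (py[j] - y) ** 2 + (px[j] - x) ** 2 < d2:
                ok = False
                break
        if ok:
            grid[(gy, gx)] = len(py)
            py.append(y)
            px.append(x)
    return np.column_stack([py, px]) if py else np.empty((0, 2))


def _paint(labels: np.ndarray, cell_ids, values) -> np.ndarray:
    """Expand per-cell values into a label image (label 0 -> 0)."""
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=float)
    lut[np.asarray(cell_ids, dtype=int)] = np.asarray(values, dtype=float)
    return lut[labels]


def compartmentalize(
    territory_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    band_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell territories into membrane-band and cytoplasm label images.

    The membrane band is the set of territory pixels within ``band_px / 2``
    (Euclidean) of a differently-labeled or out-of-mask pixel, so two
    adjacent cells jointly form a ribbon of width ``band_px`` centered on
    their shared boundary. Pixels beyond the image edge are treated as
    same-label (no boundary there); out-of-mask pixels inside the image do
    count, so cells at the core edge still receive a band. The nucleus takes
    priority: membrane and cytoplasm exclude nuclear pixels.
    """
    membrane = np.zeros_like(territory_labels)
    cytoplasm = np.zeros_like(territory_labels)
    half = band_px / 2.0
    objects = ndi.find_objects(territory_labels)
    h, w = territory_labels.shape
    for label, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        y0, y1 = max(sl[0].start - 1, 0), min(sl[0].stop + 1, h)
        x0, x1 = max(sl[1].start - 1, 0), min(sl[1].stop + 1, w)
        crop = territory_labels[y0:y1, x0:x1]
        inside = crop == label
        # pad with "inside" at true image borders only
        pad_y = (1 if y0 == 0 else 0, 1 if y1 == h else 0)
        pad_x = (1 if x0 == 0 else 0, 1 if x1 == w else 0)
        if any(pad_y) or any(pad_x):
            padded = np.pad(inside, (pad_y, pad_x), constant_values=True)
            dist = ndi.distance_transform_edt(padded)
            dist = dist[
                pad_y[0] : dist.shape[0] - pad_y[1],
                pad_x[0] : dist.shape[1] - pad_x[1],
            ]
        else:
            dist = ndi.distance_transform_edt(inside)
        band = inside & (dist <= half)
        nuc = nucleus_labels[y0:y1, x0:x1] == label
        membrane[y0:y1, x0:x1][band & ~nuc] = label
        cytoplasm[y0:y1, x0:x1][inside & ~band & ~nuc] = label
    return membrane, cytoplasm


def build_core(case: pd.Series, config: CohortConfig) -> GroundTruth:
    """Construct the geometric ground truth for one case's core.

    The actual cell count is what dart-throwing achieves under the spacing
    constraint, so it can fall slightly short of the target count for dense
    or small cores; the cells table always reflects the placed cells.
    """
    size = config.image_size_px
    rng = _rng(config, 2, int(case["case_id"]))

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    r_core = config.core_radius_frac * size
    dy, dx = yy - cy, xx - cx
    rad = np.hypot(dy, dx)
    core_mask = rad <= r_core

    # smooth epithelial blob inside the core
    phase = rng.uniform(0, 2 * math.pi)
    off = rng.uniform(-0.04, 0.04, size=2) * size
    dye, dxe = yy - (cy + off[0]), xx - (cx + off[1])
    theta = np.arctan2(dye, dxe)
    r_epi = config.epi_radius_frac * r_core * (1.0 + config.epi_wobble * np.sin(3 * theta + phase))
    epithelium = (np.hypot(dye, dxe) <= r_epi) & core_mask

    margin = config.nucleus_radius_px + 1.0
    interior = epithelium & (ndi.distance_transform_edt(epithelium) > margin)
    centers = _dart_throw(
        rng, interior, int(case["n_cells"]), config.min_nucleus_spacing_px
    )
    n_placed = len(centers)

    territory = np.zeros((size, size), dtype=np.int32)
    nucleus = np.zeros_like(territory)
    if n_placed:
        ey, ex = np.nonzero(epithelium)
        tree = cKDTree(centers)
        _, idx = tree.query(np.column_stack([ey, ex]).astype(float))
        territory[ey, ex] = idx.astype(np.int32) + 1
        dist_to_center, idx_all = tree.query(
            np.column_stack([ey, ex]).astype(float), k=1
        )
        nuc_sel = dist_to_center <= config.nucleus_radius_px
        nucleus[ey[nuc_sel], ex[nuc_sel]] = idx_all[nuc_sel].astype(np.int32) + 1

    membrane, cytoplasm = compartmentalize(
        territory, nucleus, config.membrane_band_px
    )

    cells = simulate_case_cells(case, config)
    cells = cells.iloc[:n_placed].copy()
    cells["cell_id"] = np.arange(1, n_placed + 1, dtype=int)
    if n_placed:
        cells["y"] = centers[:, 0]
        cells["x"] = centers[:, 1]
    else:
        cells["y"] = np.empty(0)
        cells["x"] = np.empty(0)

    return GroundTruth(
        case_id=int(case["case_id"]),
        cells=cells,
        core_mask=core_mask,
        epithelium_mask=epithelium,
        territory_labels=territory,
        nucleus_labels=nucleus,
        membrane_labels=membrane,
        cytoplasm_labels=cytoplasm,
    )


def _abundance_maps(
    truth: GroundTruth, config: CohortConfig, model: DetectionModel
) -> dict[str, np.ndarray]:
    """Per-fluorophore abundance (count-scale) maps for one core."""
    cells = truth.cells
    maps: dict[str, np.ndarray] = {}
    g = model.gain
    for marker in MARKER_COMPARTMENT:
        maps[marker] = g * truth.expression_map(marker)
    # pan-cytokeratin: strongest on the membrane, present through the cell body
    panck = g * (
        2.0 * _paint(truth.membrane_labels, cells["cell_id"], cells["E_PANCK"])
        + 1.0 * _paint(truth.cytoplasm_labels, cells["cell_id"], cells["E_PANCK"])
        + 0.6 * _paint(truth.nucleus_labels, cells["cell_id"], cells["E_PANCK"])
    )
    maps["PANCK"] = panck
    maps["DAPI"] = g * _paint(truth.nucleus_labels, cells["cell_id"], cells["E_DAPI"])
    maps["AF"] = np.where(truth.core_mask, 0.5, 0.0)
    return maps


def render_fluorescence(
    truth: GroundTruth,
    library: SpectralLibrary,
    model: DetectionModel,
    config: CohortConfig,
    noise: bool = True,
) -> CoreImage:
    """Forward-render the multichannel fluorescence image of one core.

    Each pixel's spectrum is the abundance-weighted sum of the library
    signatures plus the autofluorescence term and additive Gaussian read
    noise. Counts are linear in expression (abundance = gain * E) and are
    not clipped unless the detection model sets an acquisition ceiling.
    """
    maps = _abundance_maps(truth, config, model)
    missing = [f for f in library.names if f not in maps]
    if missing:
        raise ConfigurationError(
            f"library fluorophore(s) without an assigned abundance map: {missing}"
        )
    size = config.image_size_px
    A = np.stack([maps[name] for name in library.names])
    pixels = np.einsum(
        "bf,fhw->bhw", library.signatures, A, optimize=True
    )
    if noise and model.noise_sd > 0:
        rng = _rng(config, 3, truth.case_id)
        pixels = pixels + rng.normal(0.0, model.noise_sd, size=pixels.shape)
    if model.clip_counts is not None:
        pixels = np.clip(pixels, 0.0, model.clip_counts)
    names = tuple(f"band_{i}" for i in range(library.n_bands))
    return CoreImage(
        pixels=pixels.astype(np.float32),
        channel_names=names,
        um_per_px=config.um_per_px,
        case_id=truth.case_id,
        truth=truth,
    )


def render_chromogenic(
    truth: GroundTruth,
    model: DetectionModel,
    config: CohortConfig,
    marker: str = "CDX2",
    noise: bool = True,
) -> np.ndarray:
    """Render the chromogenic (DAB optical density) image for one marker.

    OD follows the saturating Hill response ``od_max * E / (E + k_half)``:
    strictly increasing and concave in expression, bounded by ``od_max``.
    """
    e_map = truth.expression_map(marker)
    od = model.od(e_map)
    if noise and model.chrom_noise_sd > 0:
        rng = _rng(config, 4, truth.case_id)
        od = od + rng.normal(0.0, model.chrom_noise_sd, size=od.shape)
    return od.astype(np.float32)


def simulate_cohort(
    config: CohortConfig,
    library: SpectralLibrary | None = None,
    model: DetectionModel | None = None,
    markers: tuple[str, ...] = ("CDX2",),
):
    """Simulate a cohort: case table plus a lazy stream of rendered cores.

    Returns
    -------
    cases : DataFrame
        Output of :func:`simulate_cohort_table`.
    cores : generator of SimulatedCore
        One entry per case, rendered on demand (fluorescence multichannel
        image plus chromogenic OD images for ``markers``).
    """
    library = library or default_spectral_library()
    model = model or DetectionModel()
    cases = simulate_cohort_table(config)

    def _iter():
        for _, case in cases.iterrows():
            truth = build_core(case, config)
            fluor = render_fluorescence(truth, library, model, config)
            chrom = {
                mk: render_chromogenic(truth, model, config, marker=mk)
                for mk in markers
            }
            yield SimulatedCore(int(case["case_id"]), fluor, chrom, truth)

    return cases, _iter()
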