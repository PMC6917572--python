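"""End-to-end orchestration: images -> per-cell records -> case scores ->
cohort analysis.

`run_cohort` drives the full chain on a synthetic cohort (render, unmix,
segment, score, exclude); `analyze_cohort` reproduces the statistical
comparison layer on the resulting case table (correlations, covariate
associations, percentile cutoff, Kaplan-Meier / Cox survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import score as sc
from . import stats as st
from .segment import SegmentationParams, SegmentationResult, apply_exclusions, segment_core
from .synthdata import (
    MARKER_COMPARTMENT,
    CohortConfig,
    CoreImage,
    DetectionModel,
    SimulatedCore,
    default_spectral_library,
    simulate_cohort,
)
from .unmix import SpectralLibrary, unmix_pixels

__all__ = ["CoreResult", "CohortResult", "process_core", "run_cohort", "analyze_cohort", "AnalysisReport"]

#: marker/compartment pairs scored by default (DIA)
DEFAULT_DIA_TARGETS = (
    ("CDX2", "nucleus"),
    ("SOX2", "nucleus"),
    ("BCAT", "cytoplasm"),
    ("BCAT", "membrane"),
)


@dataclass
class CoreResult:
    case_id: int
    included: bool
    reason: str
    n_cells: int
    case_scores: dict[str, float | int | None]
    cells: pd.DataFrame
    segmentation: SegmentationResult | None = None


@dataclass
class CohortResult:
    cases: pd.DataFrame  # cohort table joined with scores and inclusion
    cells: pd.DataFrame  # per-cell records of included cases
    config: CohortConfig
    model: DetectionModel


def process_core(
    fluorescence: CoreImage,
    chromogenic: dict[str, np.ndarray],
    library: SpectralLibrary,
    model: DetectionModel,
    seg_params: SegmentationParams = SegmentationParams(),
    min_cells: int = 50,
    artifact_flags: dict[str, bool] | None = None,
    dia_targets=DEFAULT_DIA_TARGETS,
    keep_segmentation: bool = False,
    build_cells: bool = True,
) -> CoreResult:
    """Unmix, segment and score one core.

    Returns per-cell compartment means for every measured marker and the
    case-level DIA and Allred scores, plus the inclusion decision.
    """
    abundances, _ = unmix_pixels(fluorescence.pixels, library)
    amaps = {name: abundances[i] for i, name in enumerate(library.names)}
    seg = segment_core(amaps, seg_params)
    include, reason = apply_exclusions(seg, min_cells=min_cells, artifact_flags=artifact_flags)

    case_id = fluorescence.case_id if fluorescence.case_id is not None else 0
    markers = sorted({m for m, _ in dia_targets})
    per_marker = {m: sc.cell_compartment_means(amaps[m], seg) for m in markers}

    if build_cells and markers:
        cells = pd.DataFrame(
            {
                f"{m}_{comp}": per_marker[m][comp]
                for m in markers
                for comp in sc.COMPARTMENTS
            }
        )
        cells.insert(0, "case_id", case_id)
        cells = cells.reset_index()
    else:
        cells = pd.DataFrame()

    scores: dict[str, float | int | None] = {}
    for m, comp in dia_targets:
        scores[f"dia_{m.lower()}_{comp}"] = sc.dia_case_score(per_marker[m][comp])
    if include:
        for m, od in chromogenic.items():
            comp = MARKER_COMPARTMENT.get(m, "nucleus")
            try:
                cs = sc.allred_case_score(od, seg, model, case_id=case_id, marker=m, compartment=comp)
            except ValueError:
                continue
            scores[f"allred_{m.lower()}_ps"] = cs.proportion_score
            scores[f"allred_{m.lower()}_is"] = cs.intensity_score
            scores[f"allred_{m.lower()}_total"] = cs.allred_total

    return CoreResult(
        case_id=case_id,
        included=include,
        reason=reason,
        n_cells=seg.n_epithelial_cells,
        case_scores=scores,
        cells=cells,
        segmentation=seg if keep_segmentation else None,
    )


def run_cohort(
    config: CohortConfig,
    library: SpectralLibrary | None = None,
    model: DetectionModel | None = None,
    seg_params: SegmentationParams = SegmentationParams(),
    chrom_markers: tuple[str, ...] = ("CDX2",),
    min_cells: int = 50,
    keep_cells: bool = True,
    dia_targets=DEFAULT_DIA_TARGETS,
) -> CohortResult:
    """Run the full image pipeline over a simulated cohort.

    Every core is rendered, unmixed, segmented and scored; cases failing the
    exclusion filters (too few epithelial cells, simulated tissue fold or
    necrosis) keep their covariates but have missing scores.
    """
    library = library or default_spectral_library()
    model = model or DetectionModel()
    cases, cores = simulate_cohort(config, library, model, markers=chrom_markers)

    rows = []
    cell_frames = []
    for core in cores:
        case = cases.loc[cases["case_id"] == core.case_id].iloc[0]
        artifact = {
            "tissue fold": bool(case["tissue_fold"]),
            "necrosis": bool(case["necrosis"]),
        }
        res = process_core(
            core.fluorescence,
            core.chromogenic,
            library,
            model,
            seg_params,
            min_cells=min_cells,
            artifact_flags=artifact,
            dia_targets=dia_targets,
            build_cells=keep_cells,
        )
        row = {
            "case_id": res.case_id,
            "included": res.included,
            "exclusion_reason": res.reason,
            "n_cells_detected": res.n_cells,
        }
        if res.included:
            row.update(res.case_scores)
            if keep_cells:
                cell_frames.append(res.cells)
        rows.append(row)

    scores = pd.DataFrame(rows)
    joined = cases.merge(scores, on="case_id", how="left")
    cells = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else pd.DataFrame()
    )
    return CohortResult(cases=joined, cells=cells, config=config, model=model)


@dataclass
class AnalysisReport:
    """Cohort-level statistical comparison of DIA and Allred scoring."""

    correlations: pd.DataFrame
    associations: pd.DataFrame
    survival: dict[str, st.SurvivalFit]
    labels: pd.DataFrame  # case_id + percentile labels per score column
    thresholds: dict[str, float]
    colocalization: dict[str, float] = field(default_factory=dict)


def analyze_cohort(
    cases: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    dia_col: str = "dia_cdx2_nucleus",
    allred_col: str = "allred_cdx2_total",
    percentile: float = 11.0,
    horizon_months: float = 60.0,
    covariates: list[str] | None = None,
    coloc_markers: tuple[str, str] = ("CDX2_nucleus", "SOX2_nucleus"),
    coloc_sample_n: int = 10_000,
    seed: int = 0,
) -> AnalysisReport:
    """Statistical comparison layer on a scored cohort table.

    Computes score correlations (between methods and, when ground-truth
    columns are present, against truth), covariate association tests
    (MSI, grade, stage, location), the predetermined percentile cutoff on
    each score column, and 5-year overall survival comparisons (KM,
    log-rank, univariable and optional multivariable Cox) for the resulting
    labels. The hazard ratio is oriented low-vs-high (negative vs positive).
    """
    included = cases[cases["included"]] if "included" in cases else cases

    corr_rows = []
    pairs = [(dia_col, allred_col, "dia_vs_allred")]
    if "cdx2_truth" in included.columns:
        pairs += [
            (dia_col, "cdx2_truth", "dia_vs_truth"),
            (allred_col, "cdx2_truth", "allred_vs_truth"),
        ]
    if "dia_sox2_nucleus" in included.columns:
        pairs.append((dia_col, "dia_sox2_nucleus", "cdx2_vs_sox2_dia"))
    for a, b, name in pairs:
        if a in included.columns and b in included.columns:
            sub = included[[a, b]].dropna()
            if len(sub) >= 3:
                rho, p = st.spearman(sub[a], sub[b])
                corr_rows.append({"comparison": name, "x": a, "y": b, "rho": rho, "p": p, "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    assoc_rows = []
    for cov in ("msi_status", "differentiation_grade", "stage", "tumor_location"):
        if cov not in included.columns:
            continue
        for col in (dia_col, allred_col):
            if col not in included.columns:
                continue
            sub = included[[col, cov]].dropna()
            if sub[cov].nunique() < 2:
                continue
            stat, p, test = st.covariate_association(sub[col], sub[cov])
            assoc_rows.append({"score": col, "covariate": cov, "statistic": stat, "p": p, "test": test})
    associations = pd.DataFrame(assoc_rows)

    labels = pd.DataFrame({"case_id": cases["case_id"]})
    thresholds: dict[str, float] = {}
    survival: dict[str, st.SurvivalFit] = {}
    for col in (dia_col, allred_col):
        if col not in cases.columns:
            continue
        lab, thr = sc.classify_by_percentile(cases[col], percentile=percentile)
        name = f"{col}_label"
        labels[name] = lab
        thresholds[col] = thr
        surv_df = cases.assign(**{name: lab})
        surv_df = surv_df[surv_df[name] != ""]
        # orient HR as negative (CDX2-low) vs positive: relabel so that the
        # second sorted level is "negative"
        surv_df = surv_df.assign(
            _grp=np.where(surv_df[name] == "negative", "b_negative", "a_positive")
        )
        if surv_df["_grp"].nunique() == 2:
            survival[col] = st.survival_compare(
                surv_df,
                "_grp",
                horizon_months=horizon_months,
                covariates=covariates,
            )

    coloc: dict[str, float] = {}
    if cells is not None and len(cells) and all(m in cells.columns for m in coloc_markers):
        rho, p, _ = st.single_cell_colocalization(
            cells, coloc_markers[0], coloc_markers[1], sample_n=coloc_sample_n, seed=seed
        )
        coloc = {"rho": rho, "p": p, "n": int(min(len(cells.dropna(subset=list(coloc_markers))), coloc_sample_n))}

    return AnalysisReport(
        correlations=correlations,
        associations=associations,
        survival=survival,
        labels=labels,
        thresholds=thresholds,
        colocalization=coloc,
    )
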