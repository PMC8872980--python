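"""End-to-end study orchestration.

``run_study`` mirrors the paired experimental design: n in vivo animals
(one coronal section each) and n slice replicates per drug, one spotted
control section for the on-tissue calibration, and bulk plasma/buffer
tables.  It quantifies every section, assembles the regional transport
map, and runs the region-vs-whole-section comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CalibrationLayout, PixelGrid, RegionAtlas, analysis_mask
from .errors import DegenerateStatisticsError, InsufficientDataError
from .neuropk import build_kpuu_map, correction_factor
from .quantitation import (
    CalibrationCurve,
    RegionQuantResult,
    calibration_from_section,
    normalize_to_is,
    quantify_region,
)
from .stats import dunnett_vs_reference, normality_gate
from .synthetic import (
    DrugProfile,
    NoiseModel,
    default_atlas,
    default_grid,
    default_layout,
    default_tissue_mask,
    generate_bulk,
    generate_calibration,
    generate_section,
)

WHOLE_SECTION = "whole_section"


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2³¹) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def quantify_section(section, analyte_id: str, atlas: RegionAtlas,
                     curve: CalibrationCurve,
                     layout: CalibrationLayout | None = None
                     ) -> dict[str, RegionQuantResult]:
    """Quantify the whole section plus every atlas region.

    The whole-section entry uses the tissue mask minus any calibration
    spots; regional entries use the atlas masks.
    """
    norm = normalize_to_is(section, analyte_id)
    out: dict[str, RegionQuantResult] = {}
    whole = analysis_mask(section, layout)
    out[WHOLE_SECTION] = quantify_region(norm, whole, curve,
                                         region_label=WHOLE_SECTION)
    for label, mask in atlas.regions.items():
        out[label] = quantify_region(norm, mask, curve, region_label=label)
    return out


def region_table(results: dict[str, RegionQuantResult], *,
                 condition: str = "", section_id: str = "") -> pd.DataFrame:
    rows = []
    for r in results.values():
        d = r.to_dict()
        d["condition"] = condition
        d["section"] = section_id
        rows.append(d)
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Everything one simulated (or measured) study produces."""

    drug: str
    curve: CalibrationCurve
    invivo_tables: list[dict[str, RegionQuantResult]]
    slice_tables: list[dict[str, RegionQuantResult]]
    kpuu_table: pd.DataFrame
    heatmap: dict
    cf: float
    bulk: pd.DataFrame
    truth: dict = field(default_factory=dict)
    comparisons: pd.DataFrame | None = None
    normality: dict = field(default_factory=dict)

    def kpuu(self, region: str = WHOLE_SECTION) -> float:
        row = self.kpuu_table[self.kpuu_table["region"] == region]
        if row.empty:
            raise KeyError(region)
        return float(row["K_p_uu"].iloc[0])

    def concentration(self, region: str, condition: str = "in_vivo") -> float:
        col = ("C_tot_invivo_ng_per_g" if condition == "in_vivo"
               else "C_tot_slice_ng_per_g")
        row = self.kpuu_table[self.kpuu_table["region"] == region]
        if row.empty:
            raise KeyError(region)
        return float(row[col].iloc[0])


def run_study(profile: DrugProfile,
              noise: NoiseModel | None = None,
              seed: int = 0,
              n_invivo: int = 6,
              n_slice: int = 3,
              atlas: RegionAtlas | None = None,
              layout: CalibrationLayout | None = None,
              grid: PixelGrid | None = None,
              apply_cf: bool = False,
              bulk_cv: float = 0.10,
              n_bulk: int = 3,
              weighting: str = "none") -> StudyResult:
    """Simulate and analyse one drug's paired study.

    The correction factor defaults to 1 (study designs match the buffer to
    the unbound plasma level); ``apply_cf=True`` estimates it from the
    generated bulk tables instead.
    """
    noise = noise if noise is not None else NoiseModel()
    grid = grid or default_grid()
    tissue = default_tissue_mask(grid)
    atlas = atlas or default_atlas(grid)
    layout = layout or default_layout(profile.name)

    seeds = child_seeds(seed, n_invivo + n_slice + 2 + 2)
    it = iter(seeds)

    control = generate_section(profile, "control", atlas, noise, next(it),
                               grid=grid, tissue_mask=tissue,
                               subject_id="control")
    spotted = generate_calibration(control, profile, layout, noise, next(it),
                                   atlas=atlas)
    curve = calibration_from_section(spotted, layout, profile.name,
                                     weighting=weighting)

    invivo_sections = [
        generate_section(profile, "in_vivo", atlas, noise, next(it),
                         grid=grid, tissue_mask=tissue,
                         subject_id=f"animal{i + 1}")
        for i in range(n_invivo)]
    slice_sections = [
        generate_section(profile, "brain_slice", atlas, noise, next(it),
                         grid=grid, tissue_mask=tissue,
                         replicate_id=f"slice{i + 1}")
        for i in range(n_slice)]

    invivo_tables = [quantify_section(s, profile.name, atlas, curve)
                     for s in invivo_sections]
    slice_tables = [quantify_section(s, profile.name, atlas, curve)
                    for s in slice_sections]

    bulk_seeds = child_seeds(seed + 1, 2)
    plasma = generate_bulk(profile, "plasma_total", n_bulk, bulk_cv,
                           bulk_seeds[0])
    buffer = generate_bulk(profile, "buffer_unbound", n_bulk, bulk_cv,
                           bulk_seeds[1])
    from .dataset import bulk_to_frame

    bulk = bulk_to_frame(plasma + buffer)
    plasma_mean = float(np.mean([s.value for s in plasma]))
    buffer_mean = float(np.mean([s.value for s in buffer]))
    if apply_cf:
        cf = correction_factor(buffer_mean,
                               profile.f_u_plasma * plasma_mean)
    else:
        cf = 1.0

    kpuu_table, heatmap = build_kpuu_map(
        invivo_tables, slice_tables, cf=cf,
        c_u_buffer=buffer_mean, c_tot_plasma=plasma_mean)

    comparisons, normality = _region_statistics(invivo_tables)

    truth = {
        "kpuu_brain": profile.whole_section_kpuu(atlas, tissue),
        "kpuu_roi": {r: profile.kpuu_roi[r] for r in atlas.labels},
        "c_tot_invivo": {r: profile.true_concentration(r, "in_vivo")
                         for r in atlas.labels},
        "c_tot_invivo_whole": profile.whole_section_concentration(
            atlas, tissue, "in_vivo"),
        "c_tot_slice_whole": profile.whole_section_concentration(
            atlas, tissue, "brain_slice"),
    }
    return StudyResult(drug=profile.name, curve=curve,
                       invivo_tables=invivo_tables,
                       slice_tables=slice_tables,
                       kpuu_table=kpuu_table, heatmap=heatmap, cf=cf,
                       bulk=bulk, truth=truth, comparisons=comparisons,
                       normality=normality)


def _region_statistics(invivo_tables):
    """Dunnett comparison of per-animal regional concentrations against the
    whole-section reference, gated on Shapiro–Wilk normality."""
    regions = [r for r in invivo_tables[0] if r != WHOLE_SECTION]
    groups = [[t[r].concentration for t in invivo_tables] for r in regions]
    reference = [t[WHOLE_SECTION].concentration for t in invivo_tables]

    normality = {}
    try:
        w, p, ok = normality_gate(reference)
        normality[WHOLE_SECTION] = {"W": w, "p": p, "passed": ok}
    except InsufficientDataError:
        normality[WHOLE_SECTION] = None

    try:
        comps = dunnett_vs_reference(groups, reference, labels=regions)
        comparisons = pd.DataFrame([c.to_dict() for c in comps])
    except (DegenerateStatisticsError, InsufficientDataError):
        comparisons = None
    return comparisons, normality
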