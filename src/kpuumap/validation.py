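"""Synthetic method-validation study.

Emulates the bioanalytical validation workflow: the calibration series is
re-spotted and re-measured on consecutive days, quality-control spots at a
low and a high tissue-equivalent level are quantified through each day's
curve, and the internal-standard response stability is tracked across
sections.  The result feeds :func:`kpuumap.stats.validation_report`.
"""

from __future__ import annotations

from .dataset import CalibrationLayout, CalibrationSpot
from .pipeline import child_seeds
from .quantitation import (
    calibration_from_section,
    normalize_to_is,
    quantify_region,
    spot_tissue_equivalent,
)
from .stats import ValidationReport, validation_report
from .synthetic import (
    DrugProfile,
    NoiseModel,
    default_atlas,
    default_grid,
    default_layout,
    default_tissue_mask,
    generate_calibration,
    generate_section,
)

#: Low / high QC tissue-equivalent levels (ng g⁻¹) per packaged drug,
#: spanning each drug's expected total-concentration range.
QC_LEVELS = {
    "risperidone": (103.0, 411.0),
    "clozapine": (115.0, 1147.0),
    "olanzapine": (1144.0, 4579.0),
}

_QC_COLS = (32, 50, 68)
_QC_ROW = 62


def _qc_layout(level_ng_per_g: float, grid) -> CalibrationLayout:
    """Three replicate QC spots whose tissue-equivalent concentration is
    the requested level."""
    conv = spot_tissue_equivalent(1.0, 40.0, 0.785, grid)
    conc = level_ng_per_g / conv
    return CalibrationLayout(spots=[
        CalibrationSpot(center=(_QC_ROW, c), standard_concentration=conc)
        for c in _QC_COLS])


def run_validation_study(profile: DrugProfile,
                         noise: NoiseModel | None = None,
                         seed: int = 0,
                         n_days: int = 3) -> ValidationReport:
    """Replicate-day calibration + QC study on synthetic control tissue."""
    noise = noise if noise is not None else NoiseModel()
    grid = default_grid()
    tissue = default_tissue_mask(grid)
    atlas = default_atlas(grid)
    cal_layout = default_layout(profile.name)
    levels = QC_LEVELS.get(profile.name)
    if levels is None:
        conv = spot_tissue_equivalent(1.0, 40.0, 0.785, grid)
        levels = (25.0 * conv, 500.0 * conv)

    curves = []
    qc_days: dict[float, list[list[float]]] = {lv: [] for lv in levels}
    is_responses = []
    seeds = child_seeds(seed, n_days * (2 + 2 * len(levels)))
    it = iter(seeds)
    for _day in range(n_days):
        control = generate_section(profile, "control", atlas, noise,
                                   next(it), grid=grid, tissue_mask=tissue)
        spotted = generate_calibration(control, profile, cal_layout, noise,
                                       next(it))
        # 1/x² weighting keeps the low end of the wide dilution series
        # from being dominated by absolute residuals at the top standards
        curves.append(calibration_from_section(spotted, cal_layout,
                                               profile.name,
                                               weighting="inverse_x2"))
        is_img = spotted.internal_standard_for(profile.name).intensities
        is_responses.append(float(is_img[tissue].mean()))

        for level in levels:
            qc_layout = _qc_layout(level, grid)
            qc_control = generate_section(profile, "control", atlas, noise,
                                          next(it), grid=grid,
                                          tissue_mask=tissue)
            qc_section = generate_calibration(qc_control, profile,
                                              qc_layout, noise, next(it))
            norm = normalize_to_is(qc_section, profile.name)
            measured = [
                quantify_region(norm, spot.mask(grid), curves[-1],
                                region_label=f"qc_{level:g}").concentration
                for spot in qc_layout.spots]
            qc_days[level].append(measured)

    qc_runs = {lv: qc_days[lv][0] for lv in levels}  # within-run = day 1
    return validation_report(curves, qc_runs, replicate_days=qc_days,
                             is_responses=is_responses)
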