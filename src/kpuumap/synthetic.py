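"""Synthetic paired in vivo / brain-slice sections with known ground truth.

The generator is the oracle for the whole chain: it forward-models regional
total concentrations from a drug's ground-truth unbound parameters and
renders them into noisy two-channel (analyte + deuterated internal
standard) ion images.

Forward model
-------------
Per region r with unbound transport ratio ``Kpuu_r`` and unbound volume of
distribution ``Vu_r`` (mL g⁻¹):

* in vivo section:      ``C_tot,r = Kpuu_r · Vu_r · C_u,plasma,ss``
* brain-slice section:  ``C_tot,r = Vu_r · C_u,buffer,ss``
* control section:      ``C_tot,r = 0``

Pixel analyte intensity is ``R · m(p) · gain(x,y) · ε(p) + background`` with
``m(p)`` the analyte mass under the pixel (concentration × pixel tissue
mass), ``gain`` a smooth multiplicative field shared between channels
(matrix deposition / spray heterogeneity) and ``ε`` mean-one lognormal
detection noise.  The internal standard is sprayed uniformly
(``m_IS`` per pixel) and sees the same gain field plus its own noise, so
the analyte/IS ratio cancels the gain — the property IS normalization
exploits on real data.

The packaged drug profiles (risperidone, clozapine, olanzapine) encode
whole-section Kpuu,brain values of 0.10, 0.31 and 0.82, risperidone motor /
piriform cortex Kpuu,ROI of 0.08 / 0.12, insular-cortex total-concentration
excesses of 1.3- / 1.2- / 1.5-fold over the whole-section mean, and reduced
white-matter exposure.  The unannotated-parenchyma entries are solved
against the default atlas geometry so that the pixel-weighted whole-section
truths match those targets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import (
    BulkSample,
    CalibrationLayout,
    CalibrationSpot,
    ChannelImage,
    PixelGrid,
    RegionAtlas,
    SectionDataset,
)
from .errors import ConfigurationError, DataValidationError
from .quantitation import spot_tissue_equivalent

#: Label for tissue outside every annotated region.
PARENCHYMA = "parenchyma"

#: Calibration standard series (ng mL⁻¹) spotted at 40 nL each.
STANDARD_SERIES = (25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


# --------------------------------------------------------------- profiles

@dataclass
class DrugProfile:
    """Ground-truth generator parameters for one drug.

    ``kpuu_roi`` / ``v_u_roi`` map region labels (plus the special
    ``parenchyma`` key for unannotated tissue) to the regional unbound
    transport ratio (dimensionless) and unbound volume of distribution
    (mL g⁻¹).  ``response_factor`` converts analyte mass to detected
    intensity (counts per ng); ``is_amount_per_pixel`` is the sprayed
    internal-standard load (ng per pixel).
    """

    name: str
    c_u_plasma_ss: float        # ng mL-1
    c_u_buffer_ss: float        # ng mL-1
    f_u_plasma: float
    kpuu_roi: dict[str, float] = field(default_factory=dict)
    v_u_roi: dict[str, float] = field(default_factory=dict)
    response_factor: float = 1.0e7       # counts per ng analyte
    is_response_factor: float = 1.0e7    # counts per ng IS
    is_amount_per_pixel: float = 2.0e-4  # ng IS deposited per pixel

    def __post_init__(self) -> None:
        if not (0.0 < self.f_u_plasma <= 1.0):
            raise DataValidationError("f_u_plasma must be in (0, 1]")
        for nm in ("c_u_plasma_ss", "c_u_buffer_ss", "response_factor",
                   "is_response_factor", "is_amount_per_pixel"):
            if getattr(self, nm) <= 0:
                raise DataValidationError(f"{nm} must be > 0")
        for d in (self.kpuu_roi, self.v_u_roi):
            for k, v in d.items():
                if not np.isfinite(v) or v <= 0:
                    raise DataValidationError(
                        f"ground-truth value for {k!r} must be positive")
        if set(self.kpuu_roi) != set(self.v_u_roi):
            raise DataValidationError(
                "kpuu_roi and v_u_roi must cover the same regions")

    @property
    def c_tot_plasma_ss(self) -> float:
        """Total plasma concentration implied by f_u,plasma (ng mL⁻¹)."""
        return self.c_u_plasma_ss / self.f_u_plasma

    def regions(self) -> list[str]:
        return [r for r in self.kpuu_roi if r != PARENCHYMA]

    def true_concentration(self, region: str, condition: str) -> float:
        """Ground-truth total tissue concentration (ng g⁻¹)."""
        if region not in self.kpuu_roi:
            raise ConfigurationError(
                f"region {region!r} not in profile {self.name!r}")
        if condition == "control":
            return 0.0
        v = self.v_u_roi[region]
        if condition == "in_vivo":
            return self.kpuu_roi[region] * v * self.c_u_plasma_ss
        if condition == "brain_slice":
            return v * self.c_u_buffer_ss
        raise ConfigurationError(f"unknown condition {condition!r}")

    def concentration_image(self, atlas: RegionAtlas,
                            tissue_mask: np.ndarray,
                            condition: str) -> np.ndarray:
        """Per-pixel ground-truth concentration map for one condition."""
        atlas.check_within(tissue_mask)
        img = np.zeros(tissue_mask.shape)
        img[tissue_mask] = self.true_concentration(PARENCHYMA, condition)
        for label, mask in atlas.regions.items():
            img[mask] = self.true_concentration(label, condition)
        return img

    def whole_section_concentration(self, atlas: RegionAtlas,
                                    tissue_mask: np.ndarray,
                                    condition: str) -> float:
        img = self.concentration_image(atlas, tissue_mask, condition)
        return float(img[tissue_mask].mean())

    def whole_section_kpuu(self, atlas: RegionAtlas,
                           tissue_mask: np.ndarray) -> float:
        """Area-weighted whole-section Kpuu truth (CF-corrected ratio of the
        mean in vivo to mean slice concentration)."""
        c_iv = self.whole_section_concentration(atlas, tissue_mask, "in_vivo")
        c_sl = self.whole_section_concentration(atlas, tissue_mask,
                                                "brain_slice")
        cf = self.c_u_buffer_ss / self.c_u_plasma_ss
        return cf * c_iv / c_sl

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "c_u_plasma_ss": self.c_u_plasma_ss,
            "c_u_buffer_ss": self.c_u_buffer_ss,
            "f_u_plasma": self.f_u_plasma,
            "kpuu_roi": dict(self.kpuu_roi),
            "v_u_roi": dict(self.v_u_roi),
            "response_factor": self.response_factor,
            "is_response_factor": self.is_response_factor,
            "is_amount_per_pixel": self.is_amount_per_pixel,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DrugProfile":
        return cls(**d)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative detection-noise model.

    pixel_cv
        Coefficient of variation of the mean-one lognormal per-pixel
        detection noise (per channel, independent).
    gain_amplitude
        Peak deviation of the smooth multiplicative spatial gain field
        shared across channels (matrix/spray heterogeneity).
    is_spray_cv
        Extra heterogeneity of the internal-standard spray, combined with
        pixel_cv on the IS channel.
    background
        Additive mean background intensity (counts) on analyte channels
        over tissue.
    """

    pixel_cv: float = 0.15
    gain_amplitude: float = 0.2
    is_spray_cv: float = 0.05
    background: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("pixel_cv", "gain_amplitude", "is_spray_cv", "background"):
            if getattr(self, nm) < 0:
                raise DataValidationError(f"{nm} must be >= 0")
        if self.gain_amplitude >= 1:
            raise DataValidationError("gain_amplitude must be < 1")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(pixel_cv=0.0, gain_amplitude=0.0, is_spray_cv=0.0,
                   background=0.0)


# ------------------------------------------------- default geometry / atlas

def default_grid() -> PixelGrid:
    """80 × 100 pixels at a 100-µm raster: an 8 × 10 mm coronal section."""
    return PixelGrid(n_rows=80, n_cols=100, raster_step=100.0)


def default_tissue_mask(grid: PixelGrid | None = None) -> np.ndarray:
    """Elliptical section footprint centred on the grid."""
    grid = grid or default_grid()
    rr, cc = np.ogrid[:grid.n_rows, :grid.n_cols]
    r0, c0 = grid.n_rows / 2.0, grid.n_cols / 2.0
    a, b = 0.45 * grid.n_rows, 0.46 * grid.n_cols
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


# Region rectangles (row0, row1, col0, col1), intersected with the tissue
# ellipse.  Layout sketches one hemisphere of a coronal section at the level
# of the striatum: dorsal cortical ribbon, corpus callosum arc beneath it,
# striatum and septal nuclei in the centre, ventral cortex laterally.
_REGION_RECTS = {
    "MCx": (10, 19, 24, 39),
    "CgCx": (10, 17, 42, 59),
    "SCx": (12, 20, 62, 81),
    "cc": (20, 25, 30, 71),
    "ec": (24, 29, 10, 19),
    "InCx": (30, 41, 6, 15),
    "CPu": (28, 41, 24, 43),
    "LS": (30, 41, 48, 57),
    "aca": (44, 49, 46, 55),
    "Pir": (44, 53, 10, 21),
    "NAc": (44, 53, 28, 41),
}


def default_atlas(grid: PixelGrid | None = None) -> RegionAtlas:
    """Synthetic coronal-section atlas with the 11-region vocabulary."""
    grid = grid or default_grid()
    tissue = default_tissue_mask(grid)
    regions = {}
    for label, (r0, r1, c0, c1) in _REGION_RECTS.items():
        m = np.zeros(grid.shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        m &= tissue
        regions[label] = m
    return RegionAtlas(regions)


def default_layout(analyte_id: str = "",
                   standards: tuple[float, ...] = STANDARD_SERIES,
                   volume_nl: float = 40.0) -> CalibrationLayout:
    """Six-point dilution-series layout in the ventral, region-free band."""
    cols = (22, 33, 44, 56, 67, 78)
    if len(standards) > len(cols):
        raise ConfigurationError("too many standards for the default layout")
    spots = [CalibrationSpot(center=(62, c), standard_concentration=conc,
                             spotted_volume=volume_nl, analyte_id=analyte_id)
             for c, conc in zip(cols, standards)]
    return CalibrationLayout(spots=spots)


# ------------------------------------------------------- packaged profiles

# Whole-section Kpuu,brain targets, mean unbound volume of distribution,
# steady-state unbound plasma (= buffer) concentration and plasma free
# fraction per drug.  Bulk levels are chosen so the whole-section in vivo
# concentration falls inside each drug's QC range.
_DRUG_PARAMS = {
    "risperidone": dict(kpuu=0.10, vbar=12.5, cu=240.0, fu=0.10,
                        rf=1.2e7, rf_is=1.0e7),
    "clozapine": dict(kpuu=0.31, vbar=15.0, cu=130.0, fu=0.05,
                      rf=0.9e7, rf_is=0.8e7),
    "olanzapine": dict(kpuu=0.82, vbar=20.0, cu=150.0, fu=0.23,
                       rf=1.5e7, rf_is=1.3e7),
}

# Per-region multipliers: sigma = slice concentration (and Vu) relative to
# the drug mean, kappa = Kpuu,ROI relative to Kpuu,brain.  White matter
# (cc, ec, aca) carries less tissue in both conditions; the insular cortex
# in vivo excess (sigma·kappa) is pinned at 1.3 / 1.2 / 1.5.
_SIGMA = {
    "risperidone": {"cc": 0.55, "ec": 0.65, "aca": 0.70, "CgCx": 1.05,
                    "MCx": 1.00, "SCx": 1.05, "InCx": 1.3 / 1.10,
                    "Pir": 1.10, "CPu": 1.00, "NAc": 1.00, "LS": 0.90},
    "clozapine": {"cc": 0.55, "ec": 0.65, "aca": 0.70, "CgCx": 1.05,
                  "MCx": 1.00, "SCx": 1.05, "InCx": 1.2 / 1.05,
                  "Pir": 1.05, "CPu": 1.05, "NAc": 1.00, "LS": 0.90},
    "olanzapine": {"cc": 0.55, "ec": 0.65, "aca": 0.70, "CgCx": 1.00,
                   "MCx": 1.00, "SCx": 1.05, "InCx": 1.5 / 1.10,
                   "Pir": 1.05, "CPu": 1.05, "NAc": 1.00, "LS": 0.95},
}
_KAPPA = {
    # motor cortex 0.08 and piriform 0.12 → 0.8 / 1.2 relative to 0.10
    "risperidone": {"cc": 0.75, "ec": 0.90, "aca": 1.15, "CgCx": 1.00,
                    "MCx": 0.80, "SCx": 0.95, "InCx": 1.10, "Pir": 1.20,
                    "CPu": 1.00, "NAc": 0.95, "LS": 0.90},
    # uniform moderate efflux, most efficient in the piriform cortex
    "clozapine": {"cc": 0.95, "ec": 0.95, "aca": 1.20, "CgCx": 1.00,
                  "MCx": 1.00, "SCx": 1.05, "InCx": 1.05, "Pir": 0.75,
                  "CPu": 1.00, "NAc": 0.95, "LS": 0.85},
    # heterogeneous: uptake-leaning aca/SCx, strong efflux in LS and cc
    "olanzapine": {"cc": 0.80, "ec": 0.95, "aca": 1.30, "CgCx": 1.05,
                   "MCx": 1.00, "SCx": 1.25, "InCx": 1.10, "Pir": 1.00,
                   "CPu": 1.00, "NAc": 0.95, "LS": 0.55},
}


def default_profiles(atlas: RegionAtlas | None = None,
                     tissue_mask: np.ndarray | None = None
                     ) -> dict[str, DrugProfile]:
    """The three packaged antipsychotic profiles.

    The unannotated-parenchyma multipliers are solved against the atlas
    geometry so that the pixel-weighted whole-section slice concentration
    equals ``vbar · C_u,buffer`` and the whole-section Kpuu equals the
    drug's target exactly.
    """
    if atlas is None:
        atlas = default_atlas()
    if tissue_mask is None:
        tissue_mask = default_tissue_mask()
    atlas.check_within(tissue_mask)
    w_total = float(tissue_mask.sum())
    w_region = {label: float(mask.sum())
                for label, mask in atlas.regions.items()}
    w_bg = w_total - sum(w_region.values())
    if w_bg <= 0:
        raise ConfigurationError(
            "atlas leaves no unannotated parenchyma to balance against")

    profiles = {}
    for name, p in _DRUG_PARAMS.items():
        sigma = dict(_SIGMA[name])
        kappa = dict(_KAPPA[name])
        rho = {r: sigma[r] * kappa[r] for r in sigma}
        sigma_bg = (w_total - sum(w_region[r] * sigma[r] for r in sigma)) / w_bg
        rho_bg = (w_total - sum(w_region[r] * rho[r] for r in rho)) / w_bg
        if sigma_bg <= 0 or rho_bg <= 0:
            raise ConfigurationError(
                f"profile {name!r} cannot be balanced on this atlas")
        sigma[PARENCHYMA] = sigma_bg
        kappa[PARENCHYMA] = rho_bg / sigma_bg
        profiles[name] = DrugProfile(
            name=name,
            c_u_plasma_ss=p["cu"], c_u_buffer_ss=p["cu"],
            f_u_plasma=p["fu"],
            kpuu_roi={r: p["kpuu"] * kappa[r] for r in sigma},
            v_u_roi={r: p["vbar"] * sigma[r] for r in sigma},
            response_factor=p["rf"], is_response_factor=p["rf_is"],
        )
    return profiles


# ----------------------------------------------------------- noise fields

def _gain_field(grid: PixelGrid, noise: NoiseModel,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative gain: 1 + amplitude · P(u, v), P a random
    quadratic on [-1, 1]² normalised to unit maximum deviation."""
    if noise.gain_amplitude == 0:
        return np.ones(grid.shape)
    u = np.linspace(-1.0, 1.0, grid.n_cols)[None, :]
    v = np.linspace(-1.0, 1.0, grid.n_rows)[:, None]
    coeffs = rng.uniform(-1.0, 1.0, size=5)
    p = (coeffs[0] * u + coeffs[1] * v + coeffs[2] * u * v
         + coeffs[3] * u ** 2 + coeffs[4] * v ** 2)
    peak = np.abs(p).max()
    if peak > 0:
        p = p / peak
    return 1.0 + noise.gain_amplitude * p


def _lognormal_noise(shape: tuple[int, int], cv: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Mean-one lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    s = float(np.sqrt(np.log1p(cv * cv)))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=shape)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(n)]


# -------------------------------------------------------------- generators

def generate_section(profile: DrugProfile, condition: str,
                     atlas: RegionAtlas, noise: NoiseModel, seed: int,
                     grid: PixelGrid | None = None,
                     tissue_mask: np.ndarray | None = None,
                     subject_id: str = "", replicate_id: str = ""
                     ) -> SectionDataset:
    """Render one section for a drug and condition.

    The same seed always produces a bit-identical section.  The gain field
    is attached to the returned dataset (``_gain`` attribute) so that
    calibration spots added afterwards can share it.
    """
    grid = grid or default_grid()
    if tissue_mask is None:
        tissue_mask = default_tissue_mask(grid)
    for label in atlas.labels:
        if label not in profile.kpuu_roi:
            raise ConfigurationError(
                f"atlas region {label!r} unknown to profile {profile.name!r}")

    conc = profile.concentration_image(atlas, tissue_mask, condition)
    mass = grid.pixel_tissue_mass()  # g per pixel
    analyte_mass = conc * mass       # ng per pixel

    rng_gain, rng_a, rng_is = _streams(seed, 3)
    gain = _gain_field(grid, noise, rng_gain)
    eps_a = _lognormal_noise(grid.shape, noise.pixel_cv, rng_a)
    is_cv = float(np.sqrt(noise.pixel_cv ** 2 + noise.is_spray_cv ** 2))
    eps_is = _lognormal_noise(grid.shape, is_cv, rng_is)

    analyte = (profile.response_factor * analyte_mass * gain * eps_a
               + noise.background)
    is_img = (profile.is_response_factor * profile.is_amount_per_pixel
              * gain * eps_is)
    analyte[~tissue_mask] = 0.0
    is_img[~tissue_mask] = 0.0

    ds = SectionDataset(
        grid=grid,
        channels=[
            ChannelImage(analyte_id=profile.name, role="analyte",
                         intensities=analyte, group=profile.name),
            ChannelImage(analyte_id=f"{profile.name}-d4",
                         role="internal_standard", intensities=is_img,
                         group=profile.name),
        ],
        tissue_mask=tissue_mask, condition=condition,
        subject_id=subject_id, replicate_id=replicate_id,
        metadata={"drug": profile.name, "seed": int(seed)})
    ds._gain = gain  # shared with generate_calibration when in memory
    return ds


def generate_calibration(control: SectionDataset, profile: DrugProfile,
                         layout: CalibrationLayout, noise: NoiseModel,
                         seed: int,
                         atlas: RegionAtlas | None = None) -> SectionDataset:
    """Add calibration-spot signal onto a control section (returns a copy).

    Spot pixels carry the analyte intensity implied by the spot's
    tissue-equivalent concentration through the same response model as
    tissue pixels.  If the control section still carries its generation
    gain field in memory, the spots share it (as a real co-sprayed section
    would); otherwise the field is rebuilt from ``seed``.
    """
    layout.check_on_tissue(control)
    if atlas is not None:
        layout.check_disjoint_from(atlas, control.grid)

    grid = control.grid
    gain = getattr(control, "_gain", None)
    rng_gain, rng_spot = _streams(seed, 2)
    if gain is None:
        gain = _gain_field(grid, noise, rng_gain)
    eps = _lognormal_noise(grid.shape, noise.pixel_cv, rng_spot)
    mass = grid.pixel_tissue_mass()

    analyte = control.channel(profile.name).intensities.copy()
    for spot in layout.spots:
        c_eq = spot_tissue_equivalent(
            spot.standard_concentration, spot.spotted_volume, spot.area, grid)
        m = spot.mask(grid)
        analyte[m] += (profile.response_factor * c_eq * mass
                       * gain[m] * eps[m])

    channels = []
    for ch in control.channels:
        if ch.analyte_id == profile.name:
            channels.append(ChannelImage(analyte_id=ch.analyte_id,
                                         role=ch.role, intensities=analyte,
                                         group=ch.group))
        else:
            channels.append(ChannelImage(analyte_id=ch.analyte_id,
                                         role=ch.role,
                                         intensities=ch.intensities.copy(),
                                         group=ch.group))
    ds = SectionDataset(
        grid=grid, channels=channels,
        tissue_mask=control.tissue_mask.copy(), condition="control",
        subject_id=control.subject_id, replicate_id=control.replicate_id,
        metadata={**control.metadata, "calibration": True})
    ds._gain = gain
    return ds


def generate_bulk(profile: DrugProfile, matrix: str, n: int,
                  noise_cv: float, seed: int) -> list[BulkSample]:
    """Lognormal bulk replicates around the profile's steady-state truth."""
    if n < 1:
        raise DataValidationError("n must be >= 1")
    if matrix == "plasma_total":
        truth = profile.c_tot_plasma_ss
    elif matrix == "buffer_unbound":
        truth = profile.c_u_buffer_ss
    else:
        raise ConfigurationError(
            f"bulk matrix {matrix!r} not generated synthetically")
    (rng,) = _streams(seed, 1)
    eps = _lognormal_noise((n, 1), noise_cv, rng).ravel()
    return [BulkSample(matrix=matrix, value=float(truth * e),
                       replicate_id=f"rep{i + 1}", analyte_id=profile.name)
            for i, e in enumerate(eps)]
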