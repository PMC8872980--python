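"""Data model and I/O for MSI sections, region atlases, calibration layouts
and bulk samples.

A section is a rectangular pixel grid with one intensity image per ion
channel (analyte, deuterated internal standard, optionally metabolites),
a tissue mask, and acquisition metadata.  Pixel geometry (raster step,
section thickness) together with tissue density converts per-pixel analyte
amounts into tissue concentrations (ng per g tissue).

On-disk format: a directory holding one ``.npy`` array per image plus a
JSON manifest (``manifest.json``) describing the grid, channels, masks and
metadata.  The round trip is bit-exact.  imzML is supported as read-only
ingestion (:func:`read_imzml`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.morphology import dilation, disk

from .errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateInputError,
    StructuralError,
)

#: Anatomical vocabulary of the coronal-section atlas: white matter
#: (corpus callosum, external capsule, anterior commissure), cortical
#: subregions (cingulate, motor, somatosensory, insular, piriform) and
#: subcortical gray matter (caudate putamen, nucleus accumbens, lateral
#: septum).
REGION_VOCABULARY = (
    "cc", "ec", "aca",
    "CgCx", "MCx", "SCx", "InCx", "Pir",
    "CPu", "NAc", "LS",
)

CHANNEL_ROLES = ("analyte", "internal_standard", "metabolite")
CONDITIONS = ("in_vivo", "brain_slice", "control")

#: Rat brain tissue density used for intensity-to-concentration conversion.
DEFAULT_TISSUE_DENSITY = 1.027  # g cm^-3
DEFAULT_SECTION_THICKNESS = 12.0  # µm


@dataclass(frozen=True)
class PixelGrid:
    """Pixel geometry of one section.

    Parameters
    ----------
    n_rows, n_cols
        Image dimensions in pixels.
    raster_step
        Lateral raster step in µm (pixel pitch; pixels are square).
    section_thickness
        Cryosection thickness in µm.
    tissue_density
        Tissue density in g cm^-3.
    """

    n_rows: int
    n_cols: int
    raster_step: float = 100.0
    section_thickness: float = DEFAULT_SECTION_THICKNESS
    tissue_density: float = DEFAULT_TISSUE_DENSITY

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "raster_step",
                     "section_thickness", "tissue_density"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"PixelGrid.{name} must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_mm2(self) -> float:
        return (self.raster_step / 1000.0) ** 2

    def pixel_tissue_mass(self) -> float:
        """Tissue mass under one pixel, in grams.

        raster_step² × thickness × density, with µm converted to cm.
        """
        step_cm = self.raster_step * 1e-4
        thick_cm = self.section_thickness * 1e-4
        return step_cm * step_cm * thick_cm * self.tissue_density

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "raster_step": self.raster_step,
            "section_thickness": self.section_thickness,
            "tissue_density": self.tissue_density,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PixelGrid":
        return cls(**{k: d[k] for k in (
            "n_rows", "n_cols", "raster_step",
            "section_thickness", "tissue_density")})


def pixel_tissue_mass(grid: PixelGrid) -> float:
    """Tissue mass per pixel in grams (module-level convenience)."""
    return grid.pixel_tissue_mass()


@dataclass
class ChannelImage:
    """One ion image: m/z-window-summed intensities on the section grid.

    ``group`` ties an analyte to its deuterated internal standard: the
    channels of one drug share the group label and exactly one of them has
    the ``internal_standard`` role.
    """

    analyte_id: str
    role: str
    intensities: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise DataValidationError(f"unknown channel role {self.role!r}")
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise DataValidationError("channel image must be 2-D")
        if np.any(self.intensities < 0):
            raise DataValidationError(
                f"channel {self.analyte_id!r} has negative intensities")
        if not self.group:
            self.group = self.analyte_id


@dataclass
class SectionDataset:
    """One measured (or simulated) section: grid, channels, tissue mask,
    experimental condition and identifiers."""

    grid: PixelGrid
    channels: list[ChannelImage]
    tissue_mask: np.ndarray
    condition: str
    subject_id: str = ""
    replicate_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataValidationError(f"unknown condition {self.condition!r}")
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.tissue_mask.shape != self.grid.shape:
            raise StructuralError(
                f"tissue mask shape {self.tissue_mask.shape} != grid {self.grid.shape}")
        for ch in self.channels:
            if ch.intensities.shape != self.grid.shape:
                raise StructuralError(
                    f"channel {ch.analyte_id!r} shape {ch.intensities.shape} "
                    f"!= grid {self.grid.shape}")
        for group in {ch.group for ch in self.channels}:
            n_is = sum(1 for ch in self.channels
                       if ch.group == group and ch.role == "internal_standard")
            if n_is > 1:
                raise DataValidationError(
                    f"group {group!r} has {n_is} internal-standard channels")

    def channel(self, analyte_id: str) -> ChannelImage:
        for ch in self.channels:
            if ch.analyte_id == analyte_id:
                return ch
        raise ConfigurationError(f"no channel {analyte_id!r} in dataset")

    def internal_standard_for(self, analyte_id: str) -> ChannelImage:
        group = self.channel(analyte_id).group
        for ch in self.channels:
            if ch.group == group and ch.role == "internal_standard":
                return ch
        raise ConfigurationError(
            f"no internal-standard channel for analyte {analyte_id!r}")

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "kpuumap-section/1",
            "grid": self.grid.to_dict(),
            "condition": self.condition,
            "subject_id": self.subject_id,
            "replicate_id": self.replicate_id,
            "metadata": self.metadata,
            "tissue_mask": "tissue_mask.npy",
            "channels": [],
        }
        np.save(path / "tissue_mask.npy", self.tissue_mask)
        for i, ch in enumerate(self.channels):
            fname = f"channel_{i:02d}.npy"
            np.save(path / fname, ch.intensities)
            manifest["channels"].append({
                "analyte_id": ch.analyte_id,
                "role": ch.role,
                "group": ch.group,
                "file": fname,
            })
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return path


def load_dataset(path: str | Path) -> SectionDataset:
    """Load a section dataset from its manifest directory.

    Validates array shapes against the declared grid and intensity
    non-negativity; unknown manifest keys and extra channels are preserved.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise StructuralError(f"no manifest.json under {path}")
    manifest = json.loads(mpath.read_text())
    grid = PixelGrid.from_dict(manifest["grid"])
    tissue_mask = np.load(path / manifest["tissue_mask"])
    if tissue_mask.shape != grid.shape:
        raise StructuralError(
            f"tissue mask shape {tissue_mask.shape} does not match "
            f"declared grid {grid.shape}")
    channels = []
    for spec in manifest["channels"]:
        arr = np.load(path / spec["file"])
        if arr.shape != grid.shape:
            raise StructuralError(
                f"channel {spec['analyte_id']!r} shape {arr.shape} does not "
                f"match declared grid {grid.shape}")
        channels.append(ChannelImage(
            analyte_id=spec["analyte_id"], role=spec["role"],
            intensities=arr, group=spec.get("group", "")))
    return SectionDataset(
        grid=grid, channels=channels, tissue_mask=tissue_mask,
        condition=manifest["condition"],
        subject_id=manifest.get("subject_id", ""),
        replicate_id=manifest.get("replicate_id", ""),
        metadata=manifest.get("metadata", {}))


class RegionAtlas:
    """Named boolean masks for brain regions on one section grid.

    Masks must be mutually disjoint; their union must lie within the tissue
    mask of any section they annotate (checked at use time).
    """

    def __init__(self, regions: Mapping[str, np.ndarray],
                 vocabulary: Sequence[str] | None = REGION_VOCABULARY):
        self.regions: dict[str, np.ndarray] = {}
        occupied: np.ndarray | None = None
        for label, mask in regions.items():
            if vocabulary is not None and label not in vocabulary:
                raise ConfigurationError(
                    f"region label {label!r} not in atlas vocabulary")
            mask = np.asarray(mask, dtype=bool)
            if occupied is None:
                occupied = np.zeros_like(mask)
            if mask.shape != occupied.shape:
                raise StructuralError("atlas masks have inconsistent shapes")
            if np.any(mask & occupied):
                raise DataValidationError(
                    f"region {label!r} overlaps another atlas region")
            occupied |= mask
            self.regions[label] = mask
        if occupied is None:
            raise DegenerateInputError("atlas has no regions")
        self._union = occupied

    @property
    def labels(self) -> list[str]:
        return list(self.regions)

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.regions[label]
        except KeyError:
            raise ConfigurationError(f"unknown region {label!r}") from None

    def union(self) -> np.ndarray:
        return self._union.copy()

    def check_within(self, tissue_mask: np.ndarray) -> None:
        if np.any(self._union & ~np.asarray(tissue_mask, dtype=bool)):
            raise DataValidationError("atlas regions extend outside tissue")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {"format": "kpuumap-atlas/1", "regions": {}}
        for i, (label, mask) in enumerate(self.regions.items()):
            fname = f"region_{i:02d}.npy"
            np.save(path / fname, mask)
            manifest["regions"][label] = fname
        (path / "atlas.json").write_text(json.dumps(manifest, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path,
             vocabulary: Sequence[str] | None = REGION_VOCABULARY) -> "RegionAtlas":
        path = Path(path)
        manifest = json.loads((path / "atlas.json").read_text())
        regions = {label: np.load(path / fname)
                   for label, fname in manifest["regions"].items()}
        # disjointness re-checked by the constructor
        return cls(regions, vocabulary=vocabulary)


@dataclass(frozen=True)
class CalibrationSpot:
    """One spotted calibration standard on control tissue.

    ``standard_concentration`` is the concentration of the spotted solution
    (ng mL⁻¹); ``spotted_volume`` the dispensed volume (nL); ``area`` the
    dried-spot footprint (mm²; default 0.785 mm² — a 1.0-mm disc).
    """

    center: tuple[int, int]
    standard_concentration: float
    spotted_volume: float = 40.0
    area: float = 0.785
    analyte_id: str = ""

    def __post_init__(self) -> None:
        if self.standard_concentration < 0 or self.spotted_volume <= 0 \
                or self.area <= 0:
            raise DataValidationError("calibration spot parameters must be > 0")

    def mask(self, grid: PixelGrid) -> np.ndarray:
        """Boolean disc of the recorded area centred on the spot."""
        radius_mm = float(np.sqrt(self.area / np.pi))
        radius_px = radius_mm / (grid.raster_step / 1000.0)
        rr, cc = np.ogrid[:grid.n_rows, :grid.n_cols]
        r0, c0 = self.center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px ** 2


@dataclass
class CalibrationLayout:
    """The set of calibration spots applied to one control section."""

    spots: list[CalibrationSpot]

    def masks(self, grid: PixelGrid) -> list[np.ndarray]:
        return [s.mask(grid) for s in self.spots]

    def combined_mask(self, grid: PixelGrid) -> np.ndarray:
        out = np.zeros(grid.shape, dtype=bool)
        for m in self.masks(grid):
            out |= m
        return out

    def check_on_tissue(self, section: SectionDataset) -> None:
        for spot in self.spots:
            if not np.all(section.tissue_mask[spot.mask(section.grid)]):
                raise DataValidationError(
                    f"calibration spot at {spot.center} extends off tissue")

    def check_disjoint_from(self, atlas: RegionAtlas, grid: PixelGrid) -> None:
        if np.any(self.combined_mask(grid) & atlas.union()):
            raise ConfigurationError(
                "calibration spots overlap atlas analysis regions")


def analysis_mask(section: SectionDataset,
                  layout: CalibrationLayout | None = None,
                  dilation_px: int = 2) -> np.ndarray:
    """Whole-section analysis mask: tissue minus (dilated) calibration spots.

    Whole-section ("entire coronal section") statistics must exclude the
    spotted standards; spots are dilated by ``dilation_px`` to keep spreading
    edges out of the tissue statistics.
    """
    mask = section.tissue_mask.copy()
    if layout is not None and layout.spots:
        spot = layout.combined_mask(section.grid)
        if dilation_px > 0:
            spot = dilation(spot, disk(dilation_px))
        mask &= ~spot
    if not mask.any():
        raise DegenerateInputError(
            "analysis mask is empty (spots cover all tissue)")
    return mask


# ------------------------------------------------------------- bulk samples

BULK_MATRICES = ("plasma_total", "buffer_unbound", "brain_homogenate_total")
_BULK_UNITS = {
    "plasma_total": "ng mL-1",
    "buffer_unbound": "ng mL-1",
    "brain_homogenate_total": "ng g-1",
}


@dataclass(frozen=True)
class BulkSample:
    """One bulk (non-imaging) measurement: total plasma, unbound buffer or
    brain-homogenate concentration, as produced by LC-MS/MS or dried-spot
    MSI and supplied to the pipeline as a table."""

    matrix: str
    value: float
    replicate_id: str = ""
    analyte_id: str = ""

    def __post_init__(self) -> None:
        if self.matrix not in BULK_MATRICES:
            raise DataValidationError(f"unknown bulk matrix {self.matrix!r}")
        if self.value < 0:
            raise DataValidationError("bulk concentration must be >= 0")

    @property
    def units(self) -> str:
        return _BULK_UNITS[self.matrix]


def bulk_to_frame(samples: Iterable[BulkSample]):
    """Tabulate bulk samples (columns: matrix, value, units, replicate_id,
    analyte_id)."""
    import pandas as pd

    return pd.DataFrame(
        [{"matrix": s.matrix, "value": s.value, "units": s.units,
          "replicate_id": s.replicate_id, "analyte_id": s.analyte_id}
         for s in samples])


def bulk_from_frame(df) -> list[BulkSample]:
    return [BulkSample(matrix=r.matrix, value=float(r.value),
                       replicate_id=str(getattr(r, "replicate_id", "")),
                       analyte_id=str(getattr(r, "analyte_id", "")))
            for r in df.itertuples(index=False)]
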