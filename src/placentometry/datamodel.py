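"""Shared domain types for placental morphometry.

The mouse placenta is organised into three zones (decidua, junctional zone,
labyrinth) built from a small set of trophoblast cell types.  Everything the
package measures is expressed through the small value types below: labelled
section fields, fluorescence images, per-nucleus measurement records, ordered
section stacks for volume estimation, point-grid overlays, and per-conceptus
biometry rows.

Conventions
-----------
* Coordinates are 0-based, row-major; a pixel's centre sits at its integer
  index.  Areas are always reported in μm² via ``pixel_size**2``.
* Ploidy is expressed in C units (haploid genome equivalents; diploid = 2C)
  and is kept continuous — trophoblast giant cells under-/over-replicate
  parts of their genome, so non-power-of-two means are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Cell types recognised in nucleus records.
CELL_TYPES = frozenset(
    {
        "P-TGC",
        "S-TGC",
        "SpT",
        "GlyT",
        "SynT",
        "chorion",
        "amnion",
        "endothelium",
        "pericyte",
        "other",
    }
)

#: Immunofluorescence markers carried on nucleus records.
MARKERS = frozenset({"K18", "Ki67", "pHH3", "PECAM", "aSMA"})

#: Stable integer codes for the six labyrinth compartments scored on the
#: point grid (maternal/fetal blood space, sinusoidal TGC, syncytiotrophoblast,
#: fetal endothelium+pericytes, unknown).
LABYRINTH_LEGEND: dict[int, str] = {
    0: "unknown",
    1: "MBS",
    2: "S-TGC",
    3: "SynT",
    4: "FBS",
    5: "endothelium/pericyte",
}

#: Nuclear-area gate (μm²) used to identify spongiotrophoblast nuclei and
#: separate them from glycogen trophoblast cells.
SPT_AREA_GATE = (80.0, 200.0)


@dataclass
class LabelMap:
    """Integer compartment mask for one section field.

    Parameters
    ----------
    pixels
        2-D integer array of compartment codes.
    pixel_size
        Side length of a pixel in μm.
    legend
        Mapping from code to compartment name; every code present in
        ``pixels`` must appear here.
    """

    pixels: np.ndarray
    pixel_size: float
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("LabelMap.pixels must be a 2-D array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("LabelMap.pixels must be integer-valued")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        present = set(np.unique(self.pixels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(
                f"label codes missing from legend: {sorted(missing)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_of(self, code: int) -> float:
        """Area (μm²) covered by one compartment code."""
        return float(np.count_nonzero(self.pixels == code)) * self.pixel_size**2

    def area_fractions(self) -> dict[str, float]:
        """Exact pixel-census area fraction per compartment name."""
        total = self.pixels.size
        out: dict[str, float] = {}
        for code, name in self.legend.items():
            out[name] = float(np.count_nonzero(self.pixels == code)) / total
        return out


@dataclass
class IntensityImage:
    """Grayscale fluorescence image (e.g. the DAPI channel) for one field."""

    pixels: np.ndarray
    pixel_size: float
    channel: str = "DAPI"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("IntensityImage.pixels must be a 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(self.pixels < 0):
            raise ValueError("intensity values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NucleusRecord:
    """One measured nucleus.

    ``integrated_density`` is the raw summed intensity over the traced
    nuclear outline; ``ctnf`` is the background-corrected total nuclear
    fluorescence ``integrated_density - area_px * mean_background`` where
    ``area_px`` is the nuclear area in pixels.  ``ploidy`` (C units) is
    assigned by normalising CTNF against diploid amniotic epithelium from
    the same slide.
    """

    nucleus_id: str
    slide_id: str
    cell_type: str
    area: float  # μm²
    integrated_density: float
    mean_background: Optional[float] = None  # intensity / pixel
    ctnf: Optional[float] = None
    ploidy: Optional[float] = None  # C units
    markers: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if not self.area > 0:
            raise ValueError("nuclear area must be > 0")
        bad = set(self.markers) - MARKERS
        if bad:
            raise ValueError(f"unknown markers: {sorted(bad)}")
        self.markers = frozenset(self.markers)
        if self.ploidy is not None and self.ploidy < 0:
            raise ValueError("ploidy must be >= 0")

    def has(self, marker: str) -> bool:
        return marker in self.markers


@dataclass
class SectionSet:
    """Ordered sections of one placenta, for Cavalieri volume estimation.

    ``sampling_period`` is k when every k-th cut section was kept, and
    ``offset`` the index of the first kept section within [0, k).
    """

    placenta_id: str
    sections: list  # list[tuple[LabelMap, Optional[IntensityImage]]]
    section_thickness: float  # μm
    sampling_period: int = 1
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.section_thickness > 0:
            raise ValueError("section_thickness must be > 0")
        if self.sampling_period < 1:
            raise ValueError("sampling_period must be >= 1")
        if not 0 <= self.offset < self.sampling_period:
            raise ValueError("offset must lie in [0, sampling_period)")

    def __len__(self) -> int:
        return len(self.sections)

    def label_maps(self) -> list[LabelMap]:
        return [lm for lm, _ in self.sections]


@dataclass
class GridSample:
    """Result of one point-grid overlay: classified lattice points."""

    field_id: str
    grid_shape: tuple[int, int]
    points: list  # list[tuple[int, int, int]] = (row, col, code)

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if len(self.points) != rows * cols:
            raise ValueError(
                f"expected {rows * cols} points, got {len(self.points)}"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    def codes(self) -> np.ndarray:
        return np.array([code for _, _, code in self.points], dtype=int)


@dataclass
class BiometryRecord:
    """One conceptus in a diet cohort."""

    conceptus_id: str
    litter_id: str
    embryonic_day: float  # 13.5, 16.5 or 18.5
    sex: str  # "M" / "F"
    diet: str  # "Con" / "LP"
    fetal_weight: float  # g
    placental_weight: float  # g
    maternal_weight: float  # g
    litter_size: int

    def __post_init__(self) -> None:
        if self.sex not in {"M", "F"}:
            raise ValueError("sex must be 'M' or 'F'")
        if self.diet not in {"Con", "LP"}:
            raise ValueError("diet must be 'Con' or 'LP'")
        for name in ("fetal_weight", "placental_weight", "maternal_weight"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.litter_size < 1:
            raise ValueError("litter_size must be >= 1")


@dataclass
class CtRecord:
    """One qPCR measurement: target and reference (Hprt1) cycle thresholds."""

    sample_id: str
    group: str  # "Con" / "LP"
    sex: str
    embryonic_day: float
    gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not 0 < v < 45:
                raise ValueError(f"{name} must lie in (0, 45), got {v}")
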