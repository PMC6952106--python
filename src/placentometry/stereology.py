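"""Point-grid composition, Cavalieri volume and nuclei-number estimation.

Composition follows the Delesse principle: the fraction of systematically
placed grid points landing on a compartment estimates its volume (area)
fraction.  Volumes follow the Cavalieri principle: the sum of
cross-sectional areas of systematically sampled parallel sections times the
section spacing.  Total nuclei numbers use 2-D profile counts with the
Abercrombie correction T/(T+D) for nuclei split between adjacent sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .datamodel import GridSample, LabelMap, SectionSet


@dataclass
class CompositionEstimate:
    """Pooled point-fraction composition with binomial standard errors."""

    fractions: dict  # compartment name -> proportion
    n_points: int
    se: dict  # compartment name -> sqrt(p(1-p)/n)

    def as_percent(self) -> dict:
        return {k: 100.0 * v for k, v in self.fractions.items()}


@dataclass
class VolumeEstimate:
    volume_mm3: float
    n_sections_used: int
    method: str = "cavalieri"


@dataclass
class CountingParams:
    """Parameters for Abercrombie-corrected nuclei-number estimation.

    ``mean_diameter`` is the mean nuclear diameter D (μm) along the cutting
    axis; a nucleus of diameter D appears as a profile in any section whose
    slab of thickness T it intersects, so raw profile counts overcount by
    (T+D)/T and are corrected by T/(T+D).
    """

    mean_diameter: float  # μm
    profile_counts: Optional[Sequence[int]] = None  # per kept section
    section_areas_um2: Optional[Sequence[float]] = None
    reference_volume_mm3: Optional[float] = None


def systematic_sample(
    section_set: SectionSet, period_k: int, seed: Optional[int] = None
) -> SectionSet:
    """Keep every *period_k*-th section starting at a random offset.

    The offset is drawn uniformly on [0, k) — systematic uniform random
    sampling, which keeps the Cavalieri estimator unbiased.
    """
    if period_k < 1:
        raise ValueError("period_k must be >= 1")
    if len(section_set.sections) == 0:
        raise ValueError("empty section list")
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, period_k))
    kept = section_set.sections[offset::period_k]
    return SectionSet(
        placenta_id=section_set.placenta_id,
        sections=kept,
        section_thickness=section_set.section_thickness,
        sampling_period=section_set.sampling_period * period_k,
        offset=offset,
    )


def overlay_grid(
    label_map: LabelMap,
    rows: int = 10,
    cols: int = 10,
    seed: Optional[int] = None,
    field_id: str = "field",
) -> GridSample:
    """Superimpose a rows×cols point grid with one random translation.

    Grid spacing is ``floor(dim / rows)`` per axis; the whole lattice gets a
    single uniform-random integer translation in [0, spacing) per axis, then
    each point takes the compartment code of its containing pixel
    (pixel-centre convention, so boundary points are deterministic).
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one point")
    h, w = label_map.shape
    dy, dx = h // rows, w // cols
    if dy < 1 or dx < 1:
        raise ValueError(
            f"{rows}x{cols} grid does not fit in a {h}x{w} field"
        )
    rng = np.random.default_rng(seed)
    oy = int(rng.integers(0, dy))
    ox = int(rng.integers(0, dx))
    points = []
    for i in range(rows):
        for j in range(cols):
            y = oy + i * dy
            x = ox + j * dx
            points.append((y, x, int(label_map.pixels[y, x])))
    return GridSample(field_id=field_id, grid_shape=(rows, cols), points=points)


def estimate_composition(
    grid_samples: Sequence[GridSample],
    legend: Optional[dict] = None,
) -> CompositionEstimate:
    """Pool classified grid points into per-compartment fractions.

    Points from all samples are pooled (the study design: several fields per
    section, several sections per conceptus) and each compartment's fraction
    gets a binomial standard error sqrt(p(1-p)/n).
    """
    if not grid_samples:
        raise ValueError("need at least one grid sample")
    codes = np.concatenate([gs.codes() for gs in grid_samples])
    n = codes.size
    if n == 0:
        raise ValueError("zero grid points")
    uniq, counts = np.unique(codes, return_counts=True)
    fractions: dict = {}
    se: dict = {}
    keys = legend.items() if legend else [(c, c) for c in uniq]
    count_of = dict(zip(uniq.tolist(), counts.tolist()))
    for code, name in keys:
        p = count_of.get(code, 0) / n
        fractions[name] = p
        se[name] = float(np.sqrt(p * (1 - p) / n))
    return CompositionEstimate(fractions=fractions, n_points=int(n), se=se)


def tissue_area_um2(label_map: LabelMap) -> float:
    """Default section area: everything not labelled 0 (background)."""
    return float(np.count_nonzero(label_map.pixels)) * label_map.pixel_size**2


def cavalieri_volume(
    section_set: SectionSet,
    area_of: Callable[[LabelMap], float] = tissue_area_um2,
) -> VolumeEstimate:
    """Cavalieri volume: Σ section areas × thickness × sampling period.

    ``area_of`` maps a section's LabelMap to an area in μm² (default: all
    non-background pixels); the result is reported in mm³.
    """
    t = section_set.section_thickness
    if not t > 0:
        raise ValueError("missing section thickness")
    areas = [area_of(lm) for lm in section_set.label_maps()]
    if not areas:
        raise ValueError("empty section set")
    vol_um3 = float(np.sum(areas)) * t * section_set.sampling_period
    return VolumeEstimate(
        volume_mm3=vol_um3 / 1e9, n_sections_used=len(areas)
    )


def estimate_nuclei_number(
    section_set: SectionSet, params: CountingParams
) -> float:
    """Total nuclei from Abercrombie-corrected profile densities.

    N = (Σ profiles) × V_ref / (Σ section areas × (T + D)), i.e. the profile
    count per section volume, corrected by T/(T+D) for split nuclei, scaled
    to the reference volume.  Profile counts and section areas come from
    ``params`` when given, otherwise areas from the section label maps; the
    reference volume defaults to the Cavalieri estimate over the stack.
    """
    t = section_set.section_thickness
    d = params.mean_diameter
    if d < 0:
        raise ValueError("mean_diameter must be >= 0")
    if params.profile_counts is None:
        raise ValueError("profile_counts are required")
    counts = np.asarray(params.profile_counts, dtype=float)
    if params.section_areas_um2 is not None:
        areas = np.asarray(params.section_areas_um2, dtype=float)
    else:
        areas = np.array([tissue_area_um2(lm) for lm in section_set.label_maps()])
    if counts.shape != areas.shape:
        raise ValueError("profile_counts and section areas must align")
    if params.reference_volume_mm3 is not None:
        v_ref_um3 = params.reference_volume_mm3 * 1e9
    else:
        v_ref_um3 = cavalieri_volume(section_set).volume_mm3 * 1e9
    if v_ref_um3 <= 0:
        raise ValueError("reference volume must be > 0")
    total_area = areas.sum()
    if total_area <= 0:
        if counts.sum() == 0:
            return 0.0
        raise ValueError("zero section area with nonzero profile counts")
    return float(counts.sum() * v_ref_um3 / (total_area * (t + d)))
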