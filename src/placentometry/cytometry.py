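"""Cell-cycle kinetics and DAPI-based DNA-content (ploidy) estimation.

Two marker fractions drive the kinetics: Ki67 (expressed through G1/S, so
it flags all cycling cells) and phospho-histone H3 (late G2/M only,
~0.8 h).  Their ratio times the G2/M duration gives the total cell-cycle
length; population doubling times come directly from cell counts over
time.

DNA content is estimated from DAPI fluorescence as corrected total nuclear
fluorescence, CTNF = integrated density − nuclear area (px) × mean
background, normalised per slide against amniotic epithelial nuclei whose
DNA content is diploid by construction (2C), giving a continuous ploidy in
C units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import IntensityImage, NucleusRecord


@dataclass
class LabelingIndex:
    """Marker-positive fraction of K18+ trophoblast, with binomial SE."""

    marker: str
    fraction: float
    n_cells: int
    se: float
    zone: Optional[str] = None
    embryonic_day: Optional[float] = None


@dataclass
class CycleEstimate:
    t_total_hours: Optional[float]  # None when undefined (pHH3 fraction 0)
    t_g2m_hours: float = 0.8
    method: str = "marker_ratio"


@dataclass
class PloidyEstimate:
    nucleus_id: str
    ctnf: float
    reference_ctnf_mean: float
    ploidy: float  # C units
    cell_type: Optional[str] = None


def labeling_index(
    nuclei: Sequence[NucleusRecord],
    marker: str,
    zone: Optional[str] = None,
    embryonic_day: Optional[float] = None,
) -> LabelingIndex:
    """Fraction of K18-positive (trophoblast) nuclei positive for *marker*.

    Marker-positive cells that are not K18-positive are not trophoblast and
    are excluded from both numerator and denominator.  Raises if no K18+
    cells are present.
    """
    k18 = [n for n in nuclei if n.has("K18")]
    if not k18:
        raise ValueError("no K18-positive cells to index")
    n = len(k18)
    pos = sum(1 for r in k18 if r.has(marker))
    p = pos / n
    return LabelingIndex(
        marker=marker,
        fraction=p,
        n_cells=n,
        se=math.sqrt(p * (1 - p) / n),
        zone=zone,
        embryonic_day=embryonic_day,
    )


def cycle_length(
    ki67_fraction: float, phh3_fraction: float, t_g2m: float = 0.8
) -> CycleEstimate:
    """Total cell-cycle length from the Ki67 : pHH3 marker ratio.

    t_total = ki67_fraction × t_g2m / phh3_fraction.  Both fractions are
    proportions in [0, 1] (the CLI accepts percentages and divides by 100).
    A zero pHH3 fraction leaves the estimate undefined rather than raising.
    """
    for name, f in (("ki67_fraction", ki67_fraction), ("phh3_fraction", phh3_fraction)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    if phh3_fraction == 0:
        return CycleEstimate(t_total_hours=None, t_g2m_hours=t_g2m)
    return CycleEstimate(
        t_total_hours=ki67_fraction * t_g2m / phh3_fraction,
        t_g2m_hours=t_g2m,
    )


def doubling_time(n0: float, n1: float, dt_hours: float) -> float:
    """Population doubling time Td = dt / log2(n1/n0).

    Negative when the population shrinks; infinite (math.inf) when the
    count is unchanged.
    """
    if n0 <= 0 or n1 <= 0:
        raise ValueError("cell counts must be > 0")
    if dt_hours <= 0:
        raise ValueError("dt_hours must be > 0")
    if n1 == n0:
        return math.inf
    return dt_hours / math.log2(n1 / n0)


def ctnf(nucleus: NucleusRecord, background: float, pixel_size: float = 1.0) -> float:
    """Corrected total nuclear fluorescence.

    CTNF = integrated density − area_px × mean background, with area_px the
    nuclear area in pixels (area in μm² over pixel_size²).  Negative values
    (background over-subtraction) are clipped to 0 with a warning.
    """
    if background is None:
        raise ValueError("background estimate is required")
    area_px = nucleus.area / pixel_size**2
    value = nucleus.integrated_density - area_px * background
    if value < 0:
        warnings.warn(
            f"negative CTNF for nucleus {nucleus.nucleus_id}; clipping to 0",
            stacklevel=2,
        )
        value = 0.0
    return float(value)


def estimate_background(
    image: IntensityImage, nuclei_mask: np.ndarray
) -> float:
    """Mean background fluorescence per pixel: median outside all nuclei.

    The median is robust to stray bright pixels; ``nuclei_mask`` is any
    array that is nonzero inside nuclei.
    """
    outside = np.asarray(nuclei_mask) == 0
    if not outside.any():
        raise ValueError("no background pixels outside nuclei")
    return float(np.median(image.pixels[outside]))


def ploidy(
    nuclei: Sequence[NucleusRecord],
    reference_nuclei: Sequence[NucleusRecord],
    background: Optional[float] = None,
    pixel_size: float = 1.0,
    min_reference: int = 10,
) -> list[PloidyEstimate]:
    """Assign ploidy by normalising CTNF to same-slide diploid references.

    ploidy = 2 × CTNF / mean(reference CTNF), the references being amniotic
    epithelial nuclei (diploid, 2C) from the same slide — per-slide
    normalisation is the contract and a reference from another slide
    raises.  The reference population's own mean assigned ploidy is exactly
    2C by construction.
    """
    if len(reference_nuclei) < min_reference:
        raise ValueError(
            f"need >= {min_reference} reference nuclei, got {len(reference_nuclei)}"
        )
    slides = {n.slide_id for n in nuclei} | {n.slide_id for n in reference_nuclei}
    if len(slides) > 1:
        raise ValueError(
            f"ploidy normalisation is per-slide; got slides {sorted(slides)}"
        )

    def _ctnf(rec: NucleusRecord) -> float:
        if rec.ctnf is not None:
            return rec.ctnf
        bg = background if background is not None else rec.mean_background
        return ctnf(rec, bg, pixel_size=pixel_size)

    ref_mean = float(np.mean([_ctnf(r) for r in reference_nuclei]))
    if ref_mean <= 0:
        raise ValueError("reference CTNF mean must be > 0")
    out = []
    for rec in nuclei:
        c = _ctnf(rec)
        out.append(
            PloidyEstimate(
                nucleus_id=rec.nucleus_id,
                ctnf=c,
                reference_ctnf_mean=ref_mean,
                ploidy=2.0 * c / ref_mean,
                cell_type=rec.cell_type,
            )
        )
    return out


def default_ploidy_bins(max_c: float = 16.0) -> np.ndarray:
    """log2-spaced bin edges centred on 2, 4, 8, ... C."""
    n = int(np.ceil(np.log2(max_c))) + 1
    centers = 2.0 ** np.arange(1, n + 1)
    return 2.0 ** (np.arange(0, n + 1) + 0.5)


def ploidy_histogram(
    estimates: Sequence[PloidyEstimate],
    bin_edges: Optional[np.ndarray] = None,
):
    """Relative frequency of cells per C-value bin.

    Default bins are log2-spaced and centred on 2, 4, 8, 16...C, extended to
    cover the data; frequencies sum to 1.  Returns a DataFrame with bin
    edges, counts and frequencies.
    """
    import pandas as pd

    if not estimates:
        raise ValueError("no ploidy estimates to bin")
    values = np.array([e.ploidy for e in estimates])
    if bin_edges is None:
        bin_edges = default_ploidy_bins(max(values.max(), 16.0))
        bin_edges = np.concatenate(([0.0], bin_edges[:-1], [np.inf]))
    counts, edges = np.histogram(values, bins=bin_edges)
    freq = counts / counts.sum()
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "frequency": freq,
        }
    )
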