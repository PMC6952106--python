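"""Synthetic placental data with known ground truth.

Every downstream estimator in this package is exercised against data from
this module: labelled labyrinth fields with exact compartment area
fractions, DAPI-like intensity images with nuclei of known true ploidy,
ordered section stacks of known volume, and diet cohorts drawn from a
linear model with known coefficients.

Defaults reproduce the measured structure of the study system: the E13.5
control labyrinth composition (MBS 17.4%, S-TGC 4.0%, SynT 18.4%, FBS
14.7%, endothelium/pericytes 43.6%), E8.5 chorion marker fractions (Ki67
87.3%, pHH3 7.0% of K18+ cells), and trophoblast ploidy distributions such
as sinusoidal TGCs at 8.20C ± 2.9 (E16.5).  Ploidy is generated continuous
(truncated normal with a 2C floor), not snapped to powers of two, because
endoreduplicating trophoblast only partially reduplicates its genome.
Intensity noise is multiplicative lognormal (default CV 5%), the dominant
noise source in fluorescence integrals.

Fixing the seed makes every generator byte-identical between runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .datamodel import (
    BiometryRecord,
    IntensityImage,
    LabelMap,
    LABYRINTH_LEGEND,
    NucleusRecord,
    SectionSet,
    SPT_AREA_GATE,
)

#: E13.5 control labyrinth composition used as the default field mixture.
DEFAULT_FRACTIONS = {
    "MBS": 0.174,
    "S-TGC": 0.040,
    "SynT": 0.184,
    "FBS": 0.147,
    "endothelium/pericyte": 0.436,
    "unknown": 0.019,
}

#: Per-cell-type ploidy distributions (mean C, sd C, floor C).  Amnion is the
#: diploid reference and is generated at exactly 2C.  The S-TGC default is
#: the E16.5 distribution; the P-TGC default is a nominal high-ploidy value
#: (parietal TGCs reach hundreds of genome copies; only relative recovery
#: matters here).
DEFAULT_PLOIDY = {
    "amnion": (2.0, 0.0, 2.0),
    "chorion": (2.0, 0.0, 2.0),
    "SpT": (6.43, 3.0, 2.0),
    "S-TGC": (8.20, 2.9, 2.0),
    "P-TGC": (64.0, 16.0, 2.0),
}

#: Nuclear area ranges (μm²) per cell type.  SpT nuclei occupy the 80–200 μm²
#: gate that separates them from glycogen trophoblast.
DEFAULT_AREAS = {
    "amnion": (50.0, 80.0),
    "chorion": (40.0, 80.0),
    "SpT": SPT_AREA_GATE,
    "S-TGC": (250.0, 450.0),
    "P-TGC": (500.0, 900.0),
}

#: Marker-positive probabilities per cell type (E8.5 chorion / ectoplacental
#: cone labelling indices among K18+ trophoblast).
DEFAULT_MARKER_PROBS = {
    "chorion": {"K18": 1.0, "Ki67": 0.873, "pHH3": 0.070},
    "SpT": {"K18": 1.0, "Ki67": 0.731, "pHH3": 0.030},
    "S-TGC": {"K18": 1.0, "Ki67": 0.15, "pHH3": 0.01},
    "P-TGC": {"K18": 1.0, "Ki67": 0.9, "pHH3": 0.0},
    "amnion": {},
}

#: The sampling protocol: nuclei drawn per section field.
DEFAULT_NUCLEI_PER_FIELD = {"P-TGC": 10, "S-TGC": 10, "SpT": 20, "amnion": 50}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    ``intensity_per_C`` is the expected integrated fluorescence contributed
    by one haploid genome equivalent; ``intensity_noise_cv`` the coefficient
    of variation of the multiplicative lognormal noise on each nucleus's
    integral; ``background_level``/``background_noise_sd`` the additive
    per-pixel background and its Gaussian noise.
    """

    seed: int = 0
    field_shape: tuple = (200, 200)
    pixel_size: float = 1.0  # μm / px
    compartment_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    nuclei_per_field: dict = field(default_factory=lambda: dict(DEFAULT_NUCLEI_PER_FIELD))
    ploidy_spec: dict = field(default_factory=lambda: dict(DEFAULT_PLOIDY))
    nuclear_areas: dict = field(default_factory=lambda: dict(DEFAULT_AREAS))
    intensity_per_C: float = 100.0
    intensity_noise_cv: float = 0.05
    background_level: float = 5.0
    background_noise_sd: float = 0.5
    marker_probs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKER_PROBS.items()})
    n_sections: int = 40
    section_thickness: float = 20.0  # μm
    sampling_period: int = 4

    def __post_init__(self) -> None:
        fr = self.compartment_fractions
        if any(f < 0 for f in fr.values()):
            raise ValueError("compartment fractions must be >= 0")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("compartment fractions must sum to 1")
        for ct, spec in self.ploidy_spec.items():
            if spec[1] < 0:
                raise ValueError(f"ploidy sd must be >= 0 (cell type {ct})")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Ground truth stored alongside every generated dataset."""

    area_fractions: Optional[dict] = None
    volume_mm3: Optional[float] = None
    realized_volume_mm3: Optional[float] = None
    true_ploidy: Optional[dict] = None  # nucleus_id -> C
    true_signal: Optional[dict] = None  # nucleus_id -> photon sum
    background_level: Optional[float] = None
    nuclei_mask: Optional[np.ndarray] = None  # labelled per-nucleus mask
    marker_probs: Optional[dict] = None
    effects: Optional[dict] = None

    def to_json(self, path) -> None:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if v is not None and k != "nuclei_mask"
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=float)


def _quota(fractions: dict[str, float], n_pixels: int) -> dict[str, int]:
    """Largest-remainder apportionment of pixels to compartments."""
    raw = {k: f * n_pixels for k, f in fractions.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_pixels - sum(base.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:short]:
        base[k] += 1
    return base


def make_label_field(
    config: SynthConfig, seed: Optional[int] = None
) -> tuple[LabelMap, GroundTruth]:
    """Generate a labelled labyrinth field with exact compartment quotas.

    Each compartment's pixel count is fixed by largest-remainder
    apportionment of the target fractions, so realized fractions match the
    targets to within one pixel in the field (well inside ±0.5 percentage
    points for fields of 100×100 and up).  Spatial coherence comes from
    ranking Gaussian-smoothed noise per compartment and claiming quota
    pixels in score order.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = tuple(config.field_shape)
    n_pixels = shape[0] * shape[1]
    fractions = config.compartment_fractions
    for name, f in fractions.items():
        if 0 < f * n_pixels < 1:
            raise ValueError(
                f"fraction {f} for {name!r} is infeasible: less than one pixel"
            )
    quota = _quota(fractions, n_pixels)

    name_to_code = {name: code for code, name in LABYRINTH_LEGEND.items()}
    for name in fractions:
        if name not in name_to_code:
            name_to_code[name] = max(name_to_code.values()) + 1
    legend = {code: name for name, code in name_to_code.items()}

    sigma = max(2.0, min(shape) / 10.0)
    scores = {
        name: ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        for name in fractions
    }
    out = np.full(shape, -1, dtype=np.int32)
    flat_out = out.ravel()
    # claim pixels largest-quota first so small compartments stay contiguous
    for name in sorted(quota, key=lambda k: (-quota[k], k)):
        need = quota[name]
        if need == 0:
            continue
        score = scores[name].ravel().copy()
        score[flat_out != -1] = -np.inf
        idx = np.argpartition(score, -need)[-need:]
        flat_out[idx] = name_to_code[name]

    label_map = LabelMap(pixels=out, pixel_size=config.pixel_size, legend=legend)
    realized = {
        name: quota[name] / n_pixels for name in fractions
    }
    return label_map, GroundTruth(area_fractions=realized)


def _disk_mask(shape, center, n_px):
    """Exact-count pseudo-disk: the n_px pixels closest to *center*.

    Distances are evaluated only on a local window around the centre, big
    enough to always contain the n_px nearest pixels.
    """
    r = int(np.ceil(np.sqrt(n_px / np.pi))) + 2
    y0, y1 = max(0, center[0] - r), min(shape[0], center[0] + r + 1)
    x0, x1 = max(0, center[1] - r), min(shape[1], center[1] + r + 1)
    rr, cc = np.ogrid[y0:y1, x0:x1]
    d2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2).ravel()
    if n_px > d2.size:
        raise ValueError("disk does not fit in the field")
    idx = np.argpartition(d2, n_px - 1)[:n_px]
    win = np.zeros((y1 - y0) * (x1 - x0), dtype=bool)
    win[idx] = True
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = win.reshape(y1 - y0, x1 - x0)
    return mask


def _draw_ploidy(rng, spec, size):
    mean_c, sd_c, min_c = spec
    if sd_c == 0:
        return np.full(size, float(mean_c))
    a = (min_c - mean_c) / sd_c
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean_c, scale=sd_c, size=size, random_state=rng
    )


def make_nuclei(
    config: SynthConfig, seed: Optional[int] = None
) -> tuple[IntensityImage, list[NucleusRecord], GroundTruth]:
    """Generate one DAPI-like field of nuclei with known true ploidy.

    Each nucleus is an exact-pixel-count disk on a regular (shuffled) cell
    grid, so nuclei never overlap.  Its total signal is
    ``ploidy × intensity_per_C × lognormal(CV)`` spread uniformly over its
    pixels, on top of a noisy uniform background.  Amnion reference nuclei
    carry exactly 2C of DNA.  Marker flags are Bernoulli draws from the
    per-type probabilities; every trophoblast nucleus is K18+.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    px = config.pixel_size
    counts = {ct: n for ct, n in config.nuclei_per_field.items() if n > 0}
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("no nuclei requested")

    max_area_px = max(
        int(np.ceil(config.nuclear_areas[ct][1] / px**2)) for ct in counts
    )
    cell = int(np.ceil(2 * np.sqrt(max_area_px / np.pi))) + 6
    grid = int(np.ceil(np.sqrt(n_total)))
    shape = (grid * cell, grid * cell)

    slots = [(i, j) for i in range(grid) for j in range(grid)]
    rng.shuffle(slots)

    background = np.clip(
        config.background_level
        + rng.normal(0.0, config.background_noise_sd, size=shape),
        0.0,
        None,
    )
    image = background.copy()
    labels = np.zeros(shape, dtype=np.int32)

    sigma_ln = np.sqrt(np.log(1 + config.intensity_noise_cv**2))

    records: list[NucleusRecord] = []
    true_ploidy: dict[str, float] = {}
    true_signal: dict[str, float] = {}
    k = 0
    for ct in sorted(counts):
        n = counts[ct]
        ploidies = _draw_ploidy(rng, config.ploidy_spec[ct], n)
        lo, hi = config.nuclear_areas[ct]
        areas = rng.uniform(lo, hi, size=n)
        probs = config.marker_probs.get(ct, {})
        for i in range(n):
            r, c = slots[k]
            center = (r * cell + cell // 2, c * cell + cell // 2)
            n_px = max(1, int(round(areas[i] / px**2)))
            mask = _disk_mask(shape, center, n_px)
            noise = (
                np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
                if sigma_ln > 0
                else 1.0
            )
            signal = ploidies[i] * config.intensity_per_C * noise
            image[mask] += signal / n_px
            labels[mask] = k + 1
            nid = f"n{k:04d}"
            markers = frozenset(
                m for m, p in probs.items() if rng.random() < p
            )
            records.append(
                NucleusRecord(
                    nucleus_id=nid,
                    slide_id="synthetic-slide",
                    cell_type=ct,
                    area=n_px * px**2,
                    integrated_density=float(image[mask].sum()),
                    markers=markers,
                )
            )
            true_ploidy[nid] = float(ploidies[i])
            true_signal[nid] = float(signal)
            k += 1

    img = IntensityImage(pixels=image, pixel_size=px, channel="DAPI")
    truth = GroundTruth(
        true_ploidy=true_ploidy,
        true_signal=true_signal,
        background_level=config.background_level,
        nuclei_mask=labels,
        marker_probs={ct: dict(config.marker_probs.get(ct, {})) for ct in counts},
    )
    return img, records, truth


def make_section_stack(
    config: SynthConfig, true_volume_mm3: float, seed: Optional[int] = None
) -> tuple[SectionSet, GroundTruth]:
    """Generate an ordered stack of sections integrating to a known volume.

    The cross-sectional area follows a parabolic profile along the stack
    (zero at both poles), scaled so the discrete sum of section areas times
    thickness equals ``true_volume_mm3``.  Each section is rendered as an
    exact-pixel-count disk, so the realized volume differs from the target
    only by per-section rounding (well under 1%).
    """
    if not true_volume_mm3 > 0:
        raise ValueError("true_volume must be > 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_sections
    t = config.section_thickness
    vol_um3 = true_volume_mm3 * 1e9

    z = (np.arange(n) + 0.5) / n
    profile = z * (1 - z)  # parabolic, zero at the poles
    areas_um2 = vol_um3 * profile / (profile.sum() * t)

    shape = tuple(config.field_shape)
    # pick a pixel size so the largest section fills at most ~half the field
    px = max(config.pixel_size, float(np.sqrt(2 * areas_um2.max() / (shape[0] * shape[1]))))

    legend = {0: "background", 1: "tissue"}
    center = (shape[0] // 2, shape[1] // 2)
    sections = []
    realized_um3 = 0.0
    for a in areas_um2:
        n_px = max(1, int(round(a / px**2)))
        mask = _disk_mask(shape, center, n_px)
        lm = LabelMap(
            pixels=mask.astype(np.int32), pixel_size=px, legend=dict(legend)
        )
        sections.append((lm, None))
        realized_um3 += n_px * px**2 * t

    stack = SectionSet(
        placenta_id=f"synthetic-{true_volume_mm3:g}mm3",
        sections=sections,
        section_thickness=t,
        sampling_period=1,
        offset=0,
    )
    truth = GroundTruth(
        volume_mm3=true_volume_mm3, realized_volume_mm3=realized_um3 / 1e9
    )
    return stack, truth


@dataclass
class CohortEffects:
    """Coefficients of the biometry linear model (grams).

    Fetal weight = ``mu_fetal + beta_diet·I(LP) + beta_sex·I(F)
    + beta_fp·(placental − mean placental) + litter intercept + noise``;
    placental weight has its own smaller diet/sex effects (males heavier).
    Maternal weight shrinks by ``maternal_lp_loss`` (fractional) under the
    low-protein diet.
    """

    mu_fetal: float = 1.10
    beta_diet: float = -0.10  # LP fetuses lighter
    beta_sex: float = -0.05  # female fetuses lighter
    beta_fp: float = 0.6  # g fetal per g placental (0.06 g per 0.1 g)
    mu_placental: float = 0.095
    beta_diet_placental: float = -0.008
    beta_sex_placental: float = -0.007  # female placentas lighter
    mu_maternal: float = 25.0
    maternal_lp_loss: float = 0.30
    litter_sd: float = 0.05  # litter random intercept, g
    noise_sd: float = 0.08  # residual fetal noise, g
    placental_noise_sd: float = 0.010

    def to_dict(self) -> dict:
        return asdict(self)


def make_cohort(
    n_litters: int,
    pups_per_litter: int,
    effects: Optional[CohortEffects] = None,
    seed: int = 0,
    embryonic_day: float = 18.5,
) -> tuple[list[BiometryRecord], GroundTruth]:
    """Generate a two-diet cohort from the biometry linear model.

    Litters alternate diet assignment (balanced design); sexes are Bernoulli
    within litter; litter sizes vary by ±2 pups around ``pups_per_litter``
    (litter size is a covariate downstream, so it must not be constant).
    All generating coefficients are returned in the ground truth so the
    ANCOVA / bootstrap machinery can be checked for recovery.
    """
    if n_litters < 2:
        raise ValueError("need at least 2 litters")
    eff = effects or CohortEffects()
    rng = np.random.default_rng(seed)
    records: list[BiometryRecord] = []
    for li in range(n_litters):
        diet = "Con" if li % 2 == 0 else "LP"
        litter_id = f"L{li:03d}"
        n_pups = max(2, pups_per_litter + int(rng.integers(-2, 3)))
        litter_intercept = rng.normal(0.0, eff.litter_sd) if eff.litter_sd > 0 else 0.0
        maternal = eff.mu_maternal * (
            1 - (eff.maternal_lp_loss if diet == "LP" else 0.0)
        ) + rng.normal(0.0, 1.0)
        for pi in range(n_pups):
            sex = "F" if rng.random() < 0.5 else "M"
            placental = (
                eff.mu_placental
                + eff.beta_diet_placental * (diet == "LP")
                + eff.beta_sex_placental * (sex == "F")
                + (rng.normal(0.0, eff.placental_noise_sd) if eff.placental_noise_sd > 0 else 0.0)
            )
            placental = max(placental, 1e-3)
            fetal = (
                eff.mu_fetal
                + eff.beta_diet * (diet == "LP")
                + eff.beta_sex * (sex == "F")
                + eff.beta_fp * (placental - eff.mu_placental)
                + litter_intercept
                + (rng.normal(0.0, eff.noise_sd) if eff.noise_sd > 0 else 0.0)
            )
            fetal = max(fetal, 1e-3)
            records.append(
                BiometryRecord(
                    conceptus_id=f"{litter_id}-p{pi:02d}",
                    litter_id=litter_id,
                    embryonic_day=embryonic_day,
                    sex=sex,
                    diet=diet,
                    fetal_weight=fetal,
                    placental_weight=placental,
                    maternal_weight=max(maternal, 1.0),
                    litter_size=n_pups,
                )
            )
    return records, GroundTruth(effects=eff.to_dict())
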