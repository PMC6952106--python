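"""Readers and writers for section images and measurement tables.

Masks and intensity images travel as TIFF or PNG; nuclei, biometry and Ct
tables travel as comma-separated UTF-8 CSV with "." decimals.  The
documented header names are the contract.  Every table written by the
pipeline carries a single provenance comment line (``# placentometry ...``)
recording the seed and a hash of the configuration, which readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .datamodel import (
    BiometryRecord,
    CtRecord,
    IntensityImage,
    LabelMap,
    NucleusRecord,
)

NUCLEI_COLUMNS = [
    "nucleus_id",
    "slide_id",
    "cell_type",
    "area_um2",
    "integrated_density",
    "mean_background",
    "ctnf",
    "ploidy",
    "markers",
]

BIOMETRY_COLUMNS = [
    "conceptus_id",
    "litter_id",
    "embryonic_day",
    "sex",
    "diet",
    "fetal_weight",
    "placental_weight",
    "maternal_weight",
    "litter_size",
]

CT_COLUMNS = [
    "sample_id",
    "group",
    "sex",
    "embryonic_day",
    "gene",
    "ct_target",
    "ct_reference",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(seed: Optional[int] = None, config: Optional[dict] = None) -> str:
    parts = ["# placentometry"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    return " ".join(parts)


def _write_csv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# images


def _read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def read_label_map(path, legend: dict[int, str], pixel_size: float) -> LabelMap:
    """Read an integer compartment mask and validate it against *legend*.

    Raises ``ValueError`` naming any pixel code absent from the legend, or
    if the image is not integer-valued.
    """
    arr = _read_image(path)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = np.round(arr).astype(np.int32)
        else:
            raise ValueError(f"{path}: label image is not integer-valued")
    return LabelMap(pixels=arr.astype(np.int32), pixel_size=pixel_size, legend=dict(legend))


def write_label_map(label_map: LabelMap, path) -> None:
    path = Path(path)
    arr = label_map.pixels.astype(np.uint8 if label_map.pixels.max() < 256 else np.int32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr.astype(np.uint8))


def read_intensity_image(path, pixel_size: float, channel: str = "DAPI") -> IntensityImage:
    arr = _read_image(path).astype(float)
    return IntensityImage(pixels=arr, pixel_size=pixel_size, channel=channel)


def write_intensity_image(image: IntensityImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        arr = image.pixels
        scaled = np.clip(arr / max(arr.max(), 1e-12) * 65535, 0, 65535)
        iio.imwrite(path, scaled.astype(np.uint16))


# ---------------------------------------------------------------------------
# nuclei tables


def write_nuclei_table(records: Iterable[NucleusRecord], path, seed=None, config=None) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "nucleus_id": r.nucleus_id,
                "slide_id": r.slide_id,
                "cell_type": r.cell_type,
                "area_um2": r.area,
                "integrated_density": r.integrated_density,
                "mean_background": r.mean_background,
                "ctnf": r.ctnf,
                "ploidy": r.ploidy,
                "markers": ";".join(sorted(r.markers)),
            }
        )
    df = pd.DataFrame(rows, columns=NUCLEI_COLUMNS)
    _write_csv(df, path, seed=seed, config=config)


def read_nuclei_table(path) -> list[NucleusRecord]:
    """Read a per-nucleus measurement CSV.

    Raises ``ValueError`` naming any missing column, or on a non-positive
    nuclear area.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in NUCLEI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        markers = frozenset(
            m for m in str(row["markers"]).split(";") if m and m != "nan"
        )

        def opt(name):
            v = row[name]
            return None if pd.isna(v) else float(v)

        records.append(
            NucleusRecord(
                nucleus_id=str(row["nucleus_id"]),
                slide_id=str(row["slide_id"]),
                cell_type=str(row["cell_type"]),
                area=float(row["area_um2"]),
                integrated_density=float(row["integrated_density"]),
                mean_background=opt("mean_background"),
                ctnf=opt("ctnf"),
                ploidy=opt("ploidy"),
                markers=markers,
            )
        )
    return records


# ---------------------------------------------------------------------------
# biometry tables


def write_biometry_table(records: Iterable[BiometryRecord], path, seed=None, config=None) -> None:
    df = pd.DataFrame(
        [
            {
                "conceptus_id": r.conceptus_id,
                "litter_id": r.litter_id,
                "embryonic_day": r.embryonic_day,
                "sex": r.sex,
                "diet": r.diet,
                "fetal_weight": r.fetal_weight,
                "placental_weight": r.placental_weight,
                "maternal_weight": r.maternal_weight,
                "litter_size": r.litter_size,
            }
            for r in records
        ],
        columns=BIOMETRY_COLUMNS,
    )
    _write_csv(df, path, seed=seed, config=config)


def read_biometry_table(path) -> list[BiometryRecord]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in BIOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        BiometryRecord(
            conceptus_id=str(row["conceptus_id"]),
            litter_id=str(row["litter_id"]),
            embryonic_day=float(row["embryonic_day"]),
            sex=str(row["sex"]),
            diet=str(row["diet"]),
            fetal_weight=float(row["fetal_weight"]),
            placental_weight=float(row["placental_weight"]),
            maternal_weight=float(row["maternal_weight"]),
            litter_size=int(row["litter_size"]),
        )
        for _, row in df.iterrows()
    ]


def biometry_frame(records: Iterable[BiometryRecord]) -> pd.DataFrame:
    """Biometry records as a DataFrame (the stats module's working format)."""
    return pd.DataFrame(
        [
            {
                "conceptus_id": r.conceptus_id,
                "litter_id": r.litter_id,
                "embryonic_day": r.embryonic_day,
                "sex": r.sex,
                "diet": r.diet,
                "fetal_weight": r.fetal_weight,
                "placental_weight": r.placental_weight,
                "maternal_weight": r.maternal_weight,
                "litter_size": r.litter_size,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables


def write_ct_table(records: Iterable[CtRecord], path, seed=None, config=None) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "sex": r.sex,
                "embryonic_day": r.embryonic_day,
                "gene": r.gene,
                "ct_target": r.ct_target,
                "ct_reference": r.ct_reference,
            }
            for r in records
        ],
        columns=CT_COLUMNS,
    )
    _write_csv(df, path, seed=seed, config=config)


def read_ct_table(path) -> list[CtRecord]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CtRecord(
            sample_id=str(row["sample_id"]),
            group=str(row["group"]),
            sex=str(row["sex"]),
            embryonic_day=float(row["embryonic_day"]),
            gene=str(row["gene"]),
            ct_target=float(row["ct_target"]),
            ct_reference=float(row["ct_reference"]),
        )
        for _, row in df.iterrows()
    ]
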