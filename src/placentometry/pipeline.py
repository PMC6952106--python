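"""End-to-end orchestration: synthesis → estimation → cohort statistics.

``run_pipeline`` regenerates a complete synthetic study and produces the
study-shaped output tables: ``composition.csv`` (labyrinth composition),
``labeling.csv`` (labelling indices and cycle lengths), ``ploidy.csv``
(per-nucleus ploidy), ``morpho.csv`` (expression area / cell number /
size) and ``stats.csv`` (volumes, efficiency and cohort model results).
Identical config + seed gives byte-identical outputs, captured in a run
manifest hashing every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import SPT_AREA_GATE
from .io import config_hash, provenance_line, write_nuclei_table, write_biometry_table
from .synthgen import (
    CohortEffects,
    GroundTruth,
    SynthConfig,
    make_cohort,
    make_label_field,
    make_nuclei,
    make_section_stack,
)
from . import cytometry, morphometry, stats, stereology

log = logging.getLogger("placentometry")

REQUIRED_STAGES = ("synth", "stereology", "cytometry", "morphometry", "stats")


def demo_config(seed: int = 42) -> dict:
    """The default demo study configuration."""
    return {
        "seed": seed,
        "synth": {
            "n_fields": 12,
            "field_shape": [200, 200],
            "pixel_size": 1.0,
            "volume_ratio": 55.0,
            "small_volume_mm3": 0.002,
            "n_litters": 12,
            "pups_per_litter": 8,
        },
        "stereology": {"grid_rows": 10, "grid_cols": 10, "period_k": 4},
        "cytometry": {"t_g2m_hours": 0.8},
        "morphometry": {"gate_um2": list(SPT_AREA_GATE)},
        "stats": {"n_resamples": 2000, "alpha": 0.05},
    }


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict  # relative path -> sha256
    outputs_hash: str
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, seed: int, cfg: dict) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed, cfg) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Run the full synthetic study and write all output tables.

    Raises ``KeyError`` naming any missing stage block.  Any stage failure
    propagates with the stage name in the log.
    """
    for stage in REQUIRED_STAGES:
        if stage not in config:
            raise KeyError(f"config is missing the {stage!r} stage block")
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    syn = config["synth"]
    files: dict[str, str] = {}

    # --- synth + stereology: labyrinth composition -------------------------
    log.info("stage synth/stereology: composition fields")
    scfg = SynthConfig(
        seed=seeds[0],
        field_shape=tuple(syn["field_shape"]),
        pixel_size=syn["pixel_size"],
    )
    field_lm, field_truth = make_label_field(scfg)
    rows_g = config["stereology"]["grid_rows"]
    cols_g = config["stereology"]["grid_cols"]
    grid_rng = np.random.default_rng(seeds[1])
    grids = [
        stereology.overlay_grid(
            field_lm, rows_g, cols_g,
            seed=int(grid_rng.integers(2**31)), field_id=f"grid{i:02d}",
        )
        for i in range(syn["n_fields"])
    ]
    comp = stereology.estimate_composition(grids, legend=field_lm.legend)
    comp_df = pd.DataFrame(
        {
            "compartment": list(comp.fractions),
            "fraction": list(comp.fractions.values()),
            "percent": [100 * v for v in comp.fractions.values()],
            "se": [comp.se[k] for k in comp.fractions],
            "true_fraction": [
                field_truth.area_fractions.get(k, 0.0) for k in comp.fractions
            ],
            "n_points": comp.n_points,
        }
    )
    _write(comp_df, out / "composition.csv", seed, config)

    # --- synth + stereology: Cavalieri volumes -----------------------------
    log.info("stage stereology: Cavalieri volumes")
    k = config["stereology"]["period_k"]
    v_small = syn["small_volume_mm3"]
    v_large = v_small * syn["volume_ratio"]
    vols = {}
    for name, v, sd_seed in (("early", v_small, seeds[2]), ("late", v_large, seeds[3])):
        stack, truth = make_section_stack(scfg, v, seed=sd_seed)
        sampled = stereology.systematic_sample(stack, k, seed=sd_seed + 1)
        est = stereology.cavalieri_volume(sampled)
        vols[name] = (est.volume_mm3, truth.volume_mm3)

    # --- cytometry: nuclei, labelling, ploidy ------------------------------
    log.info("stage cytometry: nuclei and ploidy")
    ncfg = SynthConfig(
        seed=seeds[4],
        nuclei_per_field={"chorion": 500, "S-TGC": 200, "SpT": 200, "amnion": 50},
    )
    img, nuclei, truth_n = make_nuclei(ncfg)
    bg = cytometry.estimate_background(img, truth_n.nuclei_mask)
    for rec in nuclei:
        rec.mean_background = bg
        rec.ctnf = cytometry.ctnf(rec, bg, pixel_size=img.pixel_size)
    refs = [n for n in nuclei if n.cell_type == "amnion"]
    lab_rows = []
    t_g2m = config["cytometry"]["t_g2m_hours"]
    for ct in ("chorion", "SpT"):
        sub = [n for n in nuclei if n.cell_type == ct]
        li_ki = cytometry.labeling_index(sub, "Ki67", zone=ct)
        li_ph = cytometry.labeling_index(sub, "pHH3", zone=ct)
        cyc = cytometry.cycle_length(li_ki.fraction, li_ph.fraction, t_g2m)
        lab_rows.append(
            {
                "zone": ct,
                "ki67_percent": 100 * li_ki.fraction,
                "phh3_percent": 100 * li_ph.fraction,
                "n_cells": li_ki.n_cells,
                "cycle_hours": cyc.t_total_hours,
            }
        )
    _write(pd.DataFrame(lab_rows), out / "labeling.csv", seed, config)

    ploidy_rows = []
    for ct in ("S-TGC", "SpT"):
        sub = [n for n in nuclei if n.cell_type == ct]
        for est in cytometry.ploidy(sub, refs):
            ploidy_rows.append(
                {
                    "nucleus_id": est.nucleus_id,
                    "cell_type": est.cell_type,
                    "ctnf": est.ctnf,
                    "ploidy_c": est.ploidy,
                    "true_ploidy_c": truth_n.true_ploidy[est.nucleus_id],
                }
            )
    _write(pd.DataFrame(ploidy_rows), out / "ploidy.csv", seed, config)
    write_nuclei_table(nuclei, out / "nuclei.csv", seed=seed, config=config)

    # --- morphometry: junctional-zone expression area ----------------------
    log.info("stage morphometry: particle analysis")
    mcfg = SynthConfig(
        seed=seeds[5],
        nuclei_per_field={"SpT": 150},
        background_level=2.0,
    )
    mimg, mnuclei, mtruth = make_nuclei(mcfg)
    mask = (mtruth.nuclei_mask > 0).astype(np.uint8)
    # dilate the traced region a little, as a manual trace would
    from scipy import ndimage as ndi

    mask = ndi.binary_dilation(mask, iterations=3).astype(np.uint8)
    gate = config["morphometry"]["gate_um2"]
    params = morphometry.ParticleParams(min_area=gate[0], max_area=gate[1])
    ans = morphometry.area_number_size(mask, mimg, params)
    morpho_df = pd.DataFrame(
        [
            {
                "total_area_mm2": ans.total_area_mm2,
                "n_cells": ans.n_cells,
                "mean_cell_size_um2": ans.mean_cell_size_um2,
                "true_n_cells": len(mnuclei),
            }
        ]
    )
    _write(morpho_df, out / "morpho.csv", seed, config)

    # --- stats: cohort biometry --------------------------------------------
    log.info("stage stats: cohort models")
    cohort, truth_c = make_cohort(
        n_litters=syn["n_litters"],
        pups_per_litter=syn["pups_per_litter"],
        seed=seeds[6],
    )
    write_biometry_table(cohort, out / "biometry.csv", seed=seed, config=config)
    from .io import biometry_frame

    bio = biometry_frame(cohort)
    anc = stats.ancova_backward(bio, "fetal_weight")
    boot = stats.bootstrap_coefficients(
        bio,
        "fetal_weight",
        n_resamples=config["stats"]["n_resamples"],
        seed=seeds[7],
    )
    eff = stats.fp_ratio(cohort)
    ratios = pd.Series([e.fp_ratio for e in eff])
    stat_rows = [
        {"quantity": "volume_ratio_late_early", "value": vols["late"][0] / vols["early"][0]},
        {"quantity": "true_volume_ratio", "value": vols["late"][1] / vols["early"][1]},
        {"quantity": "fp_ratio_mean", "value": ratios.mean()},
    ]
    for term, p in anc.p_values.items():
        stat_rows.append({"quantity": f"ancova_p[{term}]", "value": p})
    for term, b in boot.items():
        stat_rows.append({"quantity": f"bootstrap_coef[{term}]", "value": b.coefficient})
        stat_rows.append({"quantity": f"bootstrap_p[{term}]", "value": b.p_value})
    _write(pd.DataFrame(stat_rows), out / "stats.csv", seed, config)

    truth = GroundTruth(
        area_fractions=field_truth.area_fractions,
        true_ploidy=truth_n.true_ploidy,
        background_level=truth_n.background_level,
        marker_probs=truth_n.marker_probs,
        effects=truth_c.effects,
    )
    truth.to_json(out / "ground_truth.json")

    for p in sorted(out.glob("*.csv")) + [out / "ground_truth.json"]:
        files[p.name] = _sha256(p)
    outputs_hash = hashlib.sha256(
        "".join(f"{k}:{v}" for k, v in sorted(files.items())).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=seed,
        version=__version__,
        files=files,
        outputs_hash=outputs_hash,
        started=started,
        finished=time.time(),
    )
    manifest.to_json(out / "manifest.json")
    log.info("pipeline complete: %d files, outputs %s", len(files), outputs_hash[:12])
    return manifest
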