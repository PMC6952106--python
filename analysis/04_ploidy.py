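#!/usr/bin/env python
"""Endoreduplication: CTNF ploidy recovery across the measured distributions.

For each published trophoblast ploidy distribution — S-TGCs at E13.5
(6.12C), E16.5 (8.20C), E18.5 control (7.96C) and E18.5 low-protein
(11.24C); SpT at E18.5 control (6.43C) and low-protein (9.03C) — 200 nuclei
are generated (truncated normal, 2C floor) alongside 50 diploid amniotic
reference nuclei on the same synthetic slide.  The pipeline estimates the
background, corrects each nucleus's integrated density (CTNF), normalises
to the amnion mean (2C), and the recovered population mean is compared to
the generator's realized truth.  A log2-binned frequency table reproduces
the ploidy-histogram view.
"""

import numpy as np
import pandas as pd

from placentometry.cytometry import (
    ctnf,
    estimate_background,
    ploidy,
    ploidy_histogram,
)
from placentometry.synthgen import SynthConfig, make_nuclei

SEED = 42

SPECS = [
    ("S-TGC", "E13.5", "Con", 6.12, 2.6),
    ("S-TGC", "E16.5", "Con", 8.20, 2.9),
    ("S-TGC", "E18.5", "Con", 7.96, 3.4),
    ("S-TGC", "E18.5", "LP", 11.24, 3.19),
    ("SpT", "E18.5", "Con", 6.43, 3.0),
    ("SpT", "E18.5", "LP", 9.03, 3.0),
]

rows = []
histo = None
for i, (ct, day, diet, mean_c, sd_c) in enumerate(SPECS):
    cfg = SynthConfig(
        seed=SEED + i,
        nuclei_per_field={ct: 200, "amnion": 50},
        ploidy_spec={ct: (mean_c, sd_c, 2.0), "amnion": (2.0, 0.0, 2.0)},
    )
    img, nuclei, truth = make_nuclei(cfg)
    bg = estimate_background(img, truth.nuclei_mask)
    for rec in nuclei:
        rec.ctnf = ctnf(rec, bg, pixel_size=img.pixel_size)
    refs = [r for r in nuclei if r.cell_type == "amnion"]
    cells = [r for r in nuclei if r.cell_type == ct]
    ests = ploidy(cells, refs)
    est_mean = float(np.mean([e.ploidy for e in ests]))
    true_mean = float(np.mean([truth.true_ploidy[c.nucleus_id] for c in cells]))
    rows.append(
        {
            "cell_type": ct,
            "embryonic_day": day,
            "diet": diet,
            "nominal_mean_c": mean_c,
            "generated_mean_c": true_mean,
            "recovered_mean_c": est_mean,
            "relative_error": (est_mean - true_mean) / true_mean,
        }
    )
    if (ct, day, diet) == ("S-TGC", "E18.5", "LP"):
        histo = ploidy_histogram(ests)

df = pd.DataFrame(rows)
df.to_csv("results/ploidy_recovery.csv", index=False)
histo.to_csv("results/ploidy_histogram_stgc_e185_lp.csv", index=False)

print("CTNF ploidy recovery (n = 200 nuclei + 50 amnion references each):")
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nAll recovered means are within 5% of the generated truth."
      if (df.relative_error.abs() < 0.05).all()
      else "\nWARNING: a recovered mean deviates by more than 5%.")
print("\nS-TGC E18.5 low-protein ploidy histogram (log2 bins):")
print(histo.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
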