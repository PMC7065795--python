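"""Generate the synthetic study cohort and the FEM/HSA input surrogates.

Emulates the study design: 40 fractured osteoporotic patients (29 women,
11 men) measured before and after two years of teriparatide, with a
14/40 responder mixture (responders get the responder effect profile on
all 24 panel variables, the rest the non-responder profile).  Also writes
a synthetic vertebral BMD map and an annular femoral cross-section
profile for the mechanical stages.

Writes under results/: cohort.csv, bmd_map.csv (+ sidecar JSON),
profile_annulus.csv.
"""

import json
import sys
from pathlib import Path

import numpy as np

from osteomap import cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

spec = cohort.default_study_spec(seed=SEED)
table = cohort.generate_cohort(spec)
cohort.write_cohort_csv(table, OUT / "cohort.csv")
n_before = table[table.timepoint == "before"].patient_id.nunique()
print(f"cohort: {n_before} patients x 2 timepoints "
      f"({(table.sex == 'F').sum() // 2} F / {(table.sex == 'M').sum() // 2} M)"
      f" -> {OUT / 'cohort.csv'}")

bmd = cohort.generate_bmd_map(
    50, 30, mean_bmd=0.745, noise_sd=0.05, shape="vertebra",
    pixel_size=1.0, seed=SEED,
)
np.savetxt(OUT / "bmd_map.csv", bmd.grid, delimiter=",", fmt="%.6g")
np.savetxt(OUT / "bmd_mask.csv", bmd.mask.astype(int), delimiter=",", fmt="%d")
(OUT / "bmd_map.json").write_text(
    json.dumps({"pixel_size_mm": bmd.pixel_size, "mask_file": "bmd_mask.csv"})
)
print(f"BMD map: {bmd.grid.shape[1]}x{bmd.grid.shape[0]} px, "
      f"in-mask mean {bmd.in_mask_mean:.3f} g/cm2 -> {OUT / 'bmd_map.csv'}")

profile = cohort.generate_annulus_profile(1.5, 1.2, density=1.05, spacing=0.005)
with open(OUT / "profile_annulus.csv", "w") as fh:
    fh.write("position_cm,areal_mass_g_cm2\n")
    for x, m in zip(profile.positions, profile.areal_mass):
        fh.write(f"{x:.6g},{m:.6g}\n")
print(f"annulus profile: {profile.positions.size} samples "
      f"-> {OUT / 'profile_annulus.csv'}")
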