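# osteomap

Analysis pipeline for studying how a bone-forming osteoporosis therapy
(teriparatide, daily 20 µg for two years) changes DXA-derived bone
*quantity* and *quality* measures in fractured osteoporotic patients —
and for mapping how the relationships *between* those measures reorganize
under therapy.

The original clinical cohort (40 patients, 29 women / 11 men) is not
publicly available, so the package ships a first-class synthetic-cohort
generator that reproduces the study's design and published summary
statistics; every downstream stage is exercised and tested on that
synthetic data.

## What it computes

**Paired cohort statistics.** For each of 24 panel variables (hip
structural analysis indices at the narrow neck / intertrochanteric /
femoral shaft regions, shaft–neck angle, spine deformity index SDI, hip
axis length HAL, lumbar BMD, trabecular bone score TBS, bone strain index
BSI): a Shapiro–Wilk gate chooses mean/SD + paired *t* or median/IQR +
Wilcoxon signed-rank; percent variation is reported from the summary
centers. Patients are stratified as responders (> 10 % lumbar-BMD gain)
vs non-responders.

**Auto-Contractive Map connectivity.** An unsupervised three-layer ANN
trained on the min–max-scaled panel yields a square weight matrix W; the
distance transform d = 1 − W_sym/C is filtered by a minimum spanning tree
and extended to a Maximally Regular Graph by re-adding skipped links
while a hubness function H = (#3- or 4-cycles)/(1 + E − (N−1)) increases.
Hub and edge counts are compared across strata/timepoints.

**Bone Strain Index (FEM).** A 2D areal-BMD map is meshed into
constant-strain triangles (plane stress), each element's modulus follows
the trabecular power law E = 4730·ρ_app^1.56 MPa, a patient-specific
compressive load F = 0.6·g·weight·(height/1.70 m) is applied to the upper
surface, and BSI = s × (area-weighted mean equivalent strain). Higher
BSI ⇒ more strained, weaker bone.

**Hip structural analysis.** From a projected areal-mass profile m(x):
CSA = Σm·Δx/ρ_m, CSMI = Σm·(x−x̄)²·Δx/ρ_m, section modulus CSMI/d_max,
and buckling ratio d_max/t with the cortical thickness t recovered from
an annulus model.

## Worked example

```
python analysis/01_simulate_cohort.py 1
python analysis/02_cohort_statistics.py
python analysis/03_connectivity_maps.py
python analysis/04_bone_strength.py
```

prints (seed 1):

```
cohort: 40 patients x 2 timepoints (29 F / 11 M) -> results/cohort.csv
responders: 14  non-responders: 26 (threshold > 10% lumbar BMD gain)
headline variations (whole cohort): BMD +8.05%  TBS +3.69%  BSI -13.35%
...
responders before->after: edges -6%  hubs +10%
BSI before 1.820, after +8.36% BMD 1.605 (-11.77%) at load 412.0 N
HSA: CSA 2.5446 cm2  CSMI 2.3470 cm4  SECT_MOD 1.5699 cm3  width 2.99 cm  BR 4.96
```

The synthetic cohort's 14/26 responder split matches the study design by
construction; the headline variations recover the injected treatment
effects (lumbar BMD up, trabecular texture up, vertebral strain down —
i.e. stronger bone); the FEM run shows that an 8.36 % mineral gain lowers
the strain index by ~12 %; and the annulus cross-section reproduces its
analytic section properties (CSA π(r_o²−r_i²) = 2.5447 cm², BR
r_o/t = 5.0) to better than 1 %.

The same stages are available as a CLI
(`osteomap simulate | stats | map | compare-maps | bsi | hsa | full`).

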