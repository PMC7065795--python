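# Methods

This note documents the models, conventions and deliberately fixed
choices behind each stage of the pipeline, and what the synthetic data
do and do not establish.

## Synthetic cohort generator

The generator emulates a two-timepoint (before/after two years of
teriparatide) observational cohort of fractured osteoporotic patients.

**Latent model.** Baseline values of the 24-variable panel are drawn
from a multivariate normal on z-scores and back-transformed per variable
by an affine map `center + scale·z`. Strictly positive quantities are
floored at 1e-6; the spine deformity index is snapped to its
half-integer scoring grid and floored at 0. The default correlation is
block-structured — 0.6 within an anatomical block (narrow neck,
intertrochanteric, femoral shaft, lumbar spine, other), 0.3 across —
which decomposes as 0.4·I + 0.3·J + 0.3·blockdiag(J) and is therefore
positive semidefinite with unit diagonal by construction.

**Defaults.** Centers and dispersions default to the study's published
pre-treatment summaries. Rows summarized as median/IQR are converted to
a latent SD by IQR/1.349 (the IQR of a normal in SD units), so both
kinds of published dispersion are usable on the Gaussian latent scale.
Anthropometrics: age ~ N(70, 10.6²) clipped to the enrolment range
43–91; height by sex; weight derived from a BMI draw ~ N(25.9, 4.09²) so
body-mass index matches the published cohort.

**Treatment effects.** The post-treatment visit multiplies each baseline
value by `(1 + effect/100)·exp(N(0, noise_sd²))`. The multiplicative
lognormal noise preserves positivity; its mean bias `exp(noise_sd²/2)`
is ≈ 1.0002 at the default noise_sd = 0.02 and is ignored. With
noise_sd = 0 the after/before ratio is exact, which is the contract the
effect-recovery tests rely on. Sex (29 F / 11 M by default) and the
responder flags are assigned deterministically *before* any random draw,
so composition is exact: the study-emulation spec gives 14/40 patients
(8 F, 6 M) the published responder effect profile and the remainder the
non-responder profile.

**What it does not emulate.** Per-variable non-normal shapes (which real
variables were skewed is only partly recoverable from the published
footnotes), drop-out, more than two visits, and any real-image content
of DXA scans. Passing tests therefore demonstrate correctness of the
*machinery* under a plausible generative model, not properties of the
clinical population.

The BMD-map generator produces rectangular or waisted
("vertebra"-shaped, strictly interior, 4-connected) pixel masks with
i.i.d. Gaussian pixel noise around a target mean, clipped at zero. The
annulus profile generator evaluates the closed-form line integral
through an annulus and is the analytic oracle input for the geometry
stage.

## Paired statistics

* **Gate direction.** Parametric treatment iff Shapiro–Wilk p ≥ α
  (α = 0.05). The gate for *test choice* is applied to the paired
  differences; the gate for *presentation* (mean/SD vs median/IQR) to
  the raw per-timepoint values, requiring both visits to pass.
* **Quantiles.** IQR = Q3 − Q1 with linear interpolation between order
  statistics (quantile type 7, numpy's default). Sample SD uses the
  n − 1 denominator.
* **Tests.** Paired two-sided Student's t, or Wilcoxon signed-rank with
  zero differences dropped, exact null for n ≤ 25 and the
  continuity-corrected normal approximation otherwise.
* **Degenerate input.** All-zero differences yield p = 1 with a
  degenerate flag (not an exception); constant non-zero differences are
  flagged and reported with p = 0 (every patient moved identically).
* **Percent variation** is computed from the unrounded summary centers,
  not from per-patient ratios, and reported rounded half-away-from-zero
  to two decimals. This reproduces the published variation column
  exactly for the self-consistent rows; a few published rows (e.g.
  lumbar BMD 8.36 % vs 8.32 % recomputed) differ by ≤ 0.05 points, the
  footprint of the source rounding its own summaries.
* **Responder rule.** Strict `> 10 %` lumbar-BMD gain, with a 1e-9
  guard so an exact +10.00 % change computed in floating point is not
  promoted to responder.

No multiple-testing correction or confidence intervals are computed
(none were reported in the analysis being reproduced).

## Auto-Contractive Map

The three-layer contractive network is trained on the per-column
min–max-scaled panel. The update equations (per pattern, patterns in
fixed row order) are

    h_j   = x_j (1 − v_j/C)
    Δv_j  = (x_j − h_j)(1 − v_j/C)
    Net_i = Σ_j h_j (1 − W_ij/C)
    o_i   = h_i (1 − Net_i/C)
    ΔW_ij = (h_i − o_i)(1 − W_ij/C) h_j

with every weight initialized to 1e-5 (zero is a fixed point) and the
contraction ceiling C defaulting to the number of variables. Training
is deterministic and stops when the largest per-epoch weight change
drops below `tol` (1e-6) or at `max_epochs` (1000); on the default
40-patient panel it converges in ≈ 50–150 epochs. Per-pattern (rather
than batch) updating and this stopping rule are deliberate fixed
choices; both are exposed as parameters. The input-weight vector v is
provably non-decreasing for inputs in [0,1], and the third-order energy
E = Σ_q Σ_i u_iq (A u_q)_i², A = 1 − W/C, is observed (and tested) to be
non-increasing across epochs after the first on ≥ 18/20 random datasets
— an empirical property, not a guarantee. The second-order
("traditional") energy is provided as a diagnostic only and takes its
σ matrix explicitly.

Distances are d = clamp(1 − W_sym/C, 0, 1) with W symmetrized by
arithmetic mean and a forced zero diagonal; the raw asymmetric W is kept
on the model for inspection.

## Connectivity maps

* **MST.** Kruskal with a deterministic (distance, lexicographic pair)
  tie-break, validated against exhaustive Prüfer-sequence enumeration of
  all 7⁵ spanning trees on 7 nodes.
* **Hubness.** H(g) = (#distinct simple cycles of length 3 or 4) /
  (1 + E − (N−1)). The original software's hubness function is not
  public; this cycle-density form is a *reconstruction* satisfying the
  published criteria (rewards quantitatively relevant links that create
  regular cyclic microstructures) and is brute-force testable. H of any
  tree is 0; H(K4) = 7/4.
* **MRG.** Non-tree candidate edges sorted by increasing distance are
  added cumulatively (cap: N extras); the cumulative prefix maximizing H
  is returned, ties resolved toward fewer edges.
* **Hubs.** Degree ≥ 3 (configurable). Published maps with ~9–10 hubs
  among 24 nodes are consistent with a low absolute threshold, not with
  "maximum degree only".
* **Deltas.** Percent changes 100·(c₂−c₁)/c₁ rounded half-away-from-zero
  to integers for reporting (exact values retained); a zero baseline
  reports an undefined marker instead of raising.

Because the hubness function is a reconstruction and the clinical
patient-level data are unavailable, the *published* hub/edge counts of
the real maps are reproduced only at the arithmetic level (percent
deltas from printed counts), never asserted for maps trained on
synthetic cohorts.

## Bone Strain Index (FEM)

Plane-stress, small-strain, linear elastic model on constant-strain
triangles: two per in-mask pixel, node coordinates in mm, unit
out-of-plane thickness (projection convention), ν = 0.3.

* **Material.** E = a·ρ_app^b with a = 4730 MPa, b = 1.56 — the
  vertebral trabecular density–modulus power law — where
  ρ_app = areal BMD / t_eff and t_eff = 3.0 cm is the effective
  anteroposterior thickness. A floor E_min = 1 MPa keeps empty pixels
  from making the system singular. All coefficients are configurable
  surrogates: the proprietary product's exact relations are not public.
* **Load.** F = c_w·g·weight·(height/h_ref), c_w = 0.6, h_ref = 1.70 m:
  a two-parameter weight-proportional surrogate with a height lever
  factor (the cited lumbar-force relation is not reproduced in the
  source). 70 kg / 1.70 m gives 412.02 N. Applied as consistent nodal
  loads distributed uniformly along the up-facing boundary edges.
* **Supports.** Down-facing boundary nodes clamped in both components by
  default; a roller variant (vertical fixity + one lateral pin) is used
  for closed-form comparisons because it leaves Poisson expansion free.
* **Strain scalar.** Von-Mises-type equivalent strain of the implied 3D
  state (ε_zz = −ν/(1−ν)(εxx+εyy)); maximum absolute principal strain is
  selectable. Which scalar the commercial product averages is unstated.
* **Index and calibration.** BSI = s × area-weighted mean equivalent
  strain. s = 193 is frozen from a one-time computation so the reference
  synthetic vertebra (uniform 0.745 g/cm², 50 × 30 mm, 412 N, clamped
  base) scores ≈ 2.5, matching the magnitude of baseline clinical
  values. Only scale-invariant properties (linearity in load, strict
  monotone decrease in uniform BMD, mesh-refinement stability < 0.1 %,
  patch-test exactness) are asserted in tests.

## HSA geometry

CSA, center, CSMI, width (span above an edge threshold defaulting to
1 % of the profile maximum), d_max, section modulus = CSMI/d_max.
Areal mass is converted to solid-bone area with ρ_m = 1.05 g/cm³.
Cortical thickness inverts the annulus model
cortex_fraction·CSA = π(r_o² − r_i²) with r_o = width/2 and
cortex_fraction = 1 by default (all projected mass cortical); the
vendor's estimator is proprietary and this inversion is a documented
surrogate. Buckling ratio = d_max/t. Profiles are in cm; width is
reported in mm in CSV exports to mirror the published table units.

## Problem sizes and numerical tolerances

Test and acceptance runs use: effect recovery at n = 500 patients
(recovers every injected effect within ±1.5 points at noise_sd = 0.02),
responder-fraction recovery at n = 200 (±10 points), moment convergence
at n = 5000 (3 standard errors), MST oracle on 100 random 7-node
matrices, MRG oracle on 50 random 6-node instances, FEM closed-form
column at 10 × 20 px (0.5 % tolerance; patch test at machine precision),
annulus geometry at 0.005 cm spacing (1 %). Cost-function equivalences
are asserted at 1e-12 absolute; the scalar training oracle at 12
significant digits.

## Known limitations

* The hubness function, the density–modulus variant, the load relation,
  the areal→apparent density conversion and the cortical-thickness
  estimator are all documented surrogates for proprietary or uncited
  components; conclusions that depend on their exact forms should be
  drawn with care, and all are configurable.
* The FEM is 2D plane stress on a projection — it ranks bone states and
  scales correctly, but its absolute strains are not those of a 3D
  vertebra.
* The synthetic generator matches first and second moments and the
  responder mixture, not higher-order shape, so non-parametric branches
  are exercised by construction rather than by faithfully skewed data.
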