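"""Synthetic DXA cohort, BMD-map and cross-section generators.

The real study population (40 fractured osteoporotic patients measured
before and after two years of teriparatide) is not publicly deposited, so
every downstream stage of the pipeline — paired statistics, connectivity
mapping, the finite-element strain index and hip structural analysis — is
exercised on synthetic data whose structure matches the study design: a
fixed 29 F / 11 M composition, a 24-variable densitometric panel measured
at two timepoints, configurable per-variable treatment effects with
multiplicative noise, and an optional responder / non-responder mixture.

Baseline centers and dispersions default to the published pre-treatment
summaries; treatment effects default to the published percent variations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PANEL_VARIABLES",
    "NONPARAMETRIC_VARIABLES",
    "BASELINE_SUMMARY",
    "EFFECT_ALL_PCT",
    "EFFECT_RESPONDERS_PCT",
    "EFFECT_NONRESPONDERS_PCT",
    "CohortSpec",
    "BMDMap",
    "CrossSectionProfile",
    "default_study_spec",
    "generate_cohort",
    "apply_effect_profile",
    "generate_bmd_map",
    "generate_annulus_profile",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: The densitometric / clinical variable panel, in report order.
#: NN / IT / FS are the narrow-neck, intertrochanteric and femoral-shaft
#: HSA regions; the final block is lumbar-spine and whole-skeleton scalars.
PANEL_VARIABLES: tuple[str, ...] = (
    "NN_BMD", "NN_CSA", "NN_CSMI", "NN_WIDTH", "NN_SECT_MOD", "NN_BR",
    "IT_BMD", "IT_CSA", "IT_CSMI", "IT_WIDTH", "IT_SECT_MOD", "IT_BR",
    "FS_BMD", "FS_CSA", "FS_CSMI", "FS_WIDTH", "FS_SECT_MOD", "FS_BR",
    "SHAFT_NECK_ANGLE", "SDI", "HAL", "BMD", "TBS", "BSI",
)

#: Variables whose published summaries are median/IQR (skewed in the study).
NONPARAMETRIC_VARIABLES: frozenset[str] = frozenset(
    {"NN_CSMI", "NN_BR", "IT_CSMI", "IT_SECT_MOD", "FS_BR", "SDI", "TBS"}
)

#: Published whole-population baseline (center, dispersion).  Center is a
#: mean (SD) for parametric rows, a median (IQR) for the rows above.
BASELINE_SUMMARY: dict[str, tuple[float, float]] = {
    "NN_BMD": (0.740, 0.112),
    "NN_CSA": (2.347, 0.401),
    "NN_CSMI": (2.197, 1.112),
    "NN_WIDTH": (3.345, 0.352),
    "NN_SECT_MOD": (1.213, 0.302),
    "NN_BR": (13.480, 3.930),
    "IT_BMD": (0.742, 0.147),
    "IT_CSA": (4.125, 0.943),
    "IT_CSMI": (11.548, 6.546),
    "IT_WIDTH": (5.847, 0.716),
    "IT_SECT_MOD": (3.626, 1.580),
    "IT_BR": (11.439, 3.549),
    "FS_BMD": (1.262, 0.349),
    "FS_CSA": (3.624, 1.239),
    "FS_CSMI": (3.568, 1.514),
    "FS_WIDTH": (3.076, 0.269),
    "FS_SECT_MOD": (2.256, 0.840),
    "FS_BR": (3.558, 1.285),
    "SHAFT_NECK_ANGLE": (128.895, 5.141),
    "SDI": (8.000, 6.000),
    "HAL": (107.750, 10.473),
    "BMD": (0.745, 0.143),
    "TBS": (1.123, 0.159),
    "BSI": (2.472, 0.691),
}

#: Published percent variation after two years of teriparatide, whole cohort.
EFFECT_ALL_PCT: dict[str, float] = {
    "NN_BMD": 2.92, "NN_CSA": 1.62, "NN_CSMI": 1.87, "NN_WIDTH": 0.27,
    "NN_SECT_MOD": 1.33, "NN_BR": -4.67,
    "IT_BMD": 1.57, "IT_CSA": 1.65, "IT_CSMI": 0.84, "IT_WIDTH": 0.02,
    "IT_SECT_MOD": -2.32, "IT_BR": -3.25,
    "FS_BMD": 0.23, "FS_CSA": -0.98, "FS_CSMI": -1.27, "FS_WIDTH": 0.26,
    "FS_SECT_MOD": -2.33, "FS_BR": 1.62,
    "SHAFT_NECK_ANGLE": 0.25, "SDI": 12.50, "HAL": 0.32,
    "BMD": 8.36, "TBS": 5.08, "BSI": -13.90,
}

#: Published percent variation in the responder subgroup (>10% lumbar BMD gain).
EFFECT_RESPONDERS_PCT: dict[str, float] = {
    "NN_BMD": 3.56, "NN_CSA": 5.32, "NN_CSMI": 5.97, "NN_WIDTH": 2.28,
    "NN_SECT_MOD": 5.39, "NN_BR": 2.69,
    "IT_BMD": 6.02, "IT_CSA": 6.49, "IT_CSMI": -6.00, "IT_WIDTH": 0.21,
    "IT_SECT_MOD": 3.28, "IT_BR": -4.55,
    "FS_BMD": 0.29, "FS_CSA": 0.59, "FS_CSMI": 0.33, "FS_WIDTH": 0.28,
    "FS_SECT_MOD": -0.98, "FS_BR": 2.91,
    "SHAFT_NECK_ANGLE": -0.23, "SDI": 12.50, "HAL": 0.45,
    "BMD": 20.04, "TBS": 11.87, "BSI": -25.46,
}

#: Published percent variation in the non-responder subgroup.
EFFECT_NONRESPONDERS_PCT: dict[str, float] = {
    "NN_BMD": 0.67, "NN_CSA": -0.38, "NN_CSMI": -3.21, "NN_WIDTH": -0.89,
    "NN_SECT_MOD": -0.95, "NN_BR": -3.77,
    "IT_BMD": -0.59, "IT_CSA": -0.94, "IT_CSMI": -4.43, "IT_WIDTH": -0.10,
    "IT_SECT_MOD": -4.99, "IT_BR": 2.04,
    "FS_BMD": -3.74, "FS_CSA": -3.49, "FS_CSMI": -9.02, "FS_WIDTH": 0.26,
    "FS_SECT_MOD": -9.94, "FS_BR": -0.36,
    "SHAFT_NECK_ANGLE": 0.52, "SDI": 13.33, "HAL": 0.25,
    "BMD": 2.19, "TBS": -0.04, "BSI": -6.57,
}

# Variables that are physically strictly positive (floored at EPS_POSITIVE).
_POSITIVE_VARIABLES = frozenset(PANEL_VARIABLES) - {"SHAFT_NECK_ANGLE", "SDI"}
EPS_POSITIVE = 1e-6

#: Normal-distribution IQR in units of SD; converts published IQRs to latent SDs.
_IQR_TO_SD = 1.0 / 1.3489795003921634

META_COLUMNS = ("patient_id", "timepoint", "sex", "age", "weight", "height")


class CohortSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


def _default_correlation(variables: Sequence[str]) -> np.ndarray:
    """Block-structured PSD correlation: 0.6 within an anatomical block,
    0.3 across blocks.  Decomposes as 0.4·I + 0.3·J + 0.3·blockdiag(J),
    a sum of PSD matrices, hence PSD with unit diagonal by construction."""
    blocks = {
        "NN": [v for v in variables if v.startswith("NN_")],
        "IT": [v for v in variables if v.startswith("IT_")],
        "FS": [v for v in variables if v.startswith("FS_")],
        "SPINE": [v for v in variables if v in ("BMD", "TBS", "BSI")],
        "OTHER": [v for v in variables if v in ("SHAFT_NECK_ANGLE", "SDI", "HAL")],
    }
    idx = {v: i for i, v in enumerate(variables)}
    n = len(variables)
    corr = np.full((n, n), 0.3)
    for members in blocks.values():
        for a in members:
            for b in members:
                corr[idx[a], idx[b]] = 0.6
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CohortSpec:
    """Generative specification for a two-timepoint DXA cohort.

    ``baseline`` maps each panel variable to its (center, scale) on the
    observation scale: the latent model is multivariate normal on z-scores,
    back-transformed per variable by ``center + scale·z``.  ``effect`` is a
    mean percent shift applied multiplicatively to form the post-treatment
    visit; treatment noise is lognormal, ``exp(N(0, noise_sd²))``, so
    positivity is preserved.  If ``responder_fraction`` is set, that
    fraction of patients receives ``responder_effect`` instead of
    ``effect``, emulating the study's responder / non-responder mixture.
    """

    n_patients: int = 40
    n_female: int = 29
    n_male: int = 11
    variables: tuple[str, ...] = PANEL_VARIABLES
    baseline: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    correlation: np.ndarray | None = None
    effect: Mapping[str, float] = field(default_factory=dict)
    effect_noise_sd: float | Mapping[str, float] = 0.02
    responder_fraction: float | None = None
    responder_effect: Mapping[str, float] | None = None
    responder_sex_counts: tuple[int, int] | None = None  # (n_female, n_male)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline:
            self.baseline = {
                v: (
                    BASELINE_SUMMARY[v][0],
                    BASELINE_SUMMARY[v][1]
                    * (_IQR_TO_SD if v in NONPARAMETRIC_VARIABLES else 1.0),
                )
                for v in self.variables
            }
        if not self.effect:
            self.effect = {v: EFFECT_ALL_PCT.get(v, 0.0) for v in self.variables}

    def validate(self) -> None:
        if self.n_patients < 0:
            raise CohortSpecError("n_patients must be non-negative")
        if self.n_female + self.n_male != self.n_patients:
            raise CohortSpecError(
                f"sex counts {self.n_female}+{self.n_male} != n_patients {self.n_patients}"
            )
        for v in self.variables:
            if v not in self.baseline:
                raise CohortSpecError(f"baseline missing variable {v!r}")
            center, scale = self.baseline[v]
            if scale <= 0:
                raise CohortSpecError(f"non-positive dispersion for {v!r}: {scale}")
        corr = self.correlation_matrix()
        if corr.shape != (len(self.variables),) * 2:
            raise CohortSpecError("correlation matrix shape mismatch")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise CohortSpecError("correlation matrix not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise CohortSpecError("correlation matrix diagonal must be 1")
        eigmin = np.linalg.eigvalsh(corr)[0]
        if eigmin < -1e-10:
            raise CohortSpecError(
                f"correlation matrix not positive semidefinite (min eig {eigmin:.3g})"
            )
        if self.responder_fraction is not None and not (
            0.0 <= self.responder_fraction <= 1.0
        ):
            raise CohortSpecError("responder_fraction must lie in [0, 1]")

    def correlation_matrix(self) -> np.ndarray:
        if self.correlation is None:
            return _default_correlation(self.variables)
        return np.asarray(self.correlation, dtype=float)

    def noise_sd(self, variable: str) -> float:
        if isinstance(self.effect_noise_sd, Mapping):
            return float(self.effect_noise_sd.get(variable, 0.0))
        return float(self.effect_noise_sd)


def default_study_spec(seed: int = 0) -> CohortSpec:
    """The study-emulation spec: 40 patients (29 F / 11 M), a 14/40
    responder mixture (8 F / 6 M) receiving the responder effect profile,
    the remainder the non-responder profile."""
    return CohortSpec(
        effect=dict(EFFECT_NONRESPONDERS_PCT),
        responder_fraction=14 / 40,
        responder_effect=dict(EFFECT_RESPONDERS_PCT),
        responder_sex_counts=(8, 6),
        seed=seed,
    )


def _responder_flags(spec: CohortSpec, sexes: np.ndarray) -> np.ndarray:
    """Deterministic responder assignment before any random draw."""
    n = spec.n_patients
    flags = np.zeros(n, dtype=bool)
    if spec.responder_fraction is None or n == 0:
        return flags
    k = int(round(spec.responder_fraction * n))
    if spec.responder_sex_counts is not None:
        k_f, k_m = spec.responder_sex_counts
        if k_f + k_m != k:
            raise CohortSpecError(
                "responder_sex_counts must sum to round(responder_fraction * n)"
            )
    else:
        k_f = int(round(k * spec.n_female / n)) if n else 0
        k_m = k - k_f
    f_idx = np.flatnonzero(sexes == "F")
    m_idx = np.flatnonzero(sexes == "M")
    if k_f > f_idx.size or k_m > m_idx.size:
        raise CohortSpecError("responder sex counts exceed available patients")
    flags[f_idx[:k_f]] = True
    flags[m_idx[:k_m]] = True
    return flags


def _round_half_grid(values: np.ndarray) -> np.ndarray:
    """Snap to the 0.5 grid used by semi-quantitative deformity scores."""
    return np.round(values * 2.0) / 2.0


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a two-timepoint cohort table.

    Returns a DataFrame with one row per patient per timepoint
    (``timepoint`` ∈ {before, after}), metadata columns
    ``patient_id, timepoint, sex, age, weight, height`` and one column per
    panel variable.  Deterministic given ``spec`` (including its seed).
    """
    spec.validate()
    n = spec.n_patients
    variables = list(spec.variables)
    if n == 0:
        return pd.DataFrame(columns=list(META_COLUMNS) + variables)

    rng = np.random.default_rng(spec.seed)
    ids = np.array([f"P{i + 1:03d}" for i in range(n)])
    # Sex fixed before any draw so composition is exact.
    sexes = np.array(["F"] * spec.n_female + ["M"] * spec.n_male)
    responder = _responder_flags(spec, sexes)

    # Anthropometrics: age ~ N(70, 10.6²) clipped to the study range;
    # height by sex; weight derived from a BMI draw so BMI matches the
    # published 25.9 ± 4.09 kg/m².
    age = np.clip(rng.normal(70.0, 10.6, size=n), 43.0, 91.0)
    height = np.where(
        sexes == "F", rng.normal(1.60, 0.06, size=n), rng.normal(1.72, 0.07, size=n)
    )
    height = np.clip(height, 1.40, 2.00)
    bmi = np.clip(rng.normal(25.9, 4.09, size=n), 16.0, 45.0)
    weight = bmi * height**2

    # Correlated latent z-scores → per-variable affine back-transform.
    corr = spec.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(variables)))
    z = rng.standard_normal(size=(n, len(variables))) @ chol.T
    centers = np.array([spec.baseline[v][0] for v in variables])
    scales = np.array([spec.baseline[v][1] for v in variables])
    values = centers + scales * z
    for j, v in enumerate(variables):
        if v in _POSITIVE_VARIABLES:
            values[:, j] = np.maximum(values[:, j], EPS_POSITIVE)
        if v == "SDI":
            values[:, j] = np.maximum(_round_half_grid(values[:, j]), 0.0)

    before = pd.DataFrame(values, columns=variables)
    before.insert(0, "height", height)
    before.insert(0, "weight", weight)
    before.insert(0, "age", age)
    before.insert(0, "sex", sexes)
    before.insert(0, "timepoint", "before")
    before.insert(0, "patient_id", ids)

    effect_rows = []
    for i in range(n):
        profile = (
            spec.responder_effect
            if responder[i] and spec.responder_effect is not None
            else spec.effect
        )
        effect_rows.append([profile.get(v, 0.0) for v in variables])
    effect_matrix = np.asarray(effect_rows, dtype=float)
    noise_sd = np.array([spec.noise_sd(v) for v in variables])

    after = _apply_effects(before, variables, effect_matrix, noise_sd, rng)
    table = pd.concat([before, after], ignore_index=True)
    return table


def _apply_effects(
    before: pd.DataFrame,
    variables: Sequence[str],
    effect_matrix: np.ndarray,
    noise_sd: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    after = before.copy()
    after["timepoint"] = "after"
    base = before[list(variables)].to_numpy(dtype=float)
    noise = np.where(
        noise_sd > 0,
        np.exp(rng.standard_normal(size=base.shape) * noise_sd),
        1.0,
    )
    values = base * (1.0 + effect_matrix / 100.0) * noise
    for j, v in enumerate(variables):
        if v == "SDI":
            values[:, j] = np.maximum(_round_half_grid(values[:, j]), 0.0)
    after[list(variables)] = values
    return after


def apply_effect_profile(
    cohort: pd.DataFrame,
    effect: Mapping[str, float],
    noise_sd: float | Mapping[str, float] = 0.0,
    seed: int = 0,
    variables: Sequence[str] | None = None,
    snap_sdi: bool = False,
) -> pd.DataFrame:
    """Add (or replace) the post-treatment rows of a cohort.

    With ``noise_sd == 0`` the per-patient ratio after/before equals
    ``1 + effect/100`` exactly.  ``effect`` must name every panel variable.

    ``snap_sdi`` re-snaps the deformity score to its half-integer grid;
    it is off by default so that the exact-ratio contract holds for SDI too.
    """
    before = cohort[cohort["timepoint"] == "before"]
    if before.empty:
        raise ValueError("cohort has no 'before' rows")
    if variables is None:
        variables = [c for c in cohort.columns if c not in META_COLUMNS]
    missing = [v for v in variables if v not in effect]
    if missing:
        raise KeyError(f"effect profile missing variables: {missing}")

    rng = np.random.default_rng(seed)
    if isinstance(noise_sd, Mapping):
        sd = np.array([float(noise_sd.get(v, 0.0)) for v in variables])
    else:
        sd = np.full(len(variables), float(noise_sd))
    effect_matrix = np.tile(
        np.array([effect[v] for v in variables], dtype=float), (len(before), 1)
    )
    after = before.copy()
    after["timepoint"] = "after"
    base = before[list(variables)].to_numpy(dtype=float)
    noise = np.where(sd > 0, np.exp(rng.standard_normal(size=base.shape) * sd), 1.0)
    values = base * (1.0 + effect_matrix / 100.0) * noise
    if snap_sdi and "SDI" in variables:
        j = list(variables).index("SDI")
        values[:, j] = np.maximum(_round_half_grid(values[:, j]), 0.0)
    after[list(variables)] = values
    return pd.concat([before, after], ignore_index=True)


# ---------------------------------------------------------------------------
# BMD pixel maps and cross-section profiles
# ---------------------------------------------------------------------------


@dataclass
class BMDMap:
    """2D areal-BMD pixel grid (g/cm²) with an in-bone mask.

    Row 0 of ``grid`` is the *bottom* row of the image (y increases with
    row index); ``pixel_size`` is the square pixel edge in mm.
    """

    grid: np.ndarray
    pixel_size: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.shape != self.mask.shape:
            raise ValueError("grid and mask shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if (self.grid < 0).any():
            raise ValueError("BMD values must be non-negative")

    @property
    def in_mask_mean(self) -> float:
        return float(self.grid[self.mask].mean())


@dataclass
class CrossSectionProfile:
    """Projected areal-mass profile across a bone section.

    ``positions`` are uniformly spaced (cm); ``areal_mass`` is g/cm².
    """

    positions: np.ndarray
    areal_mass: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areal_mass = np.asarray(self.areal_mass, dtype=float)
        if self.positions.ndim != 1 or self.positions.size < 2:
            raise ValueError("profile needs at least 2 positions")
        dx = np.diff(self.positions)
        if not np.allclose(dx, dx[0], rtol=1e-9, atol=1e-12) or dx[0] <= 0:
            raise ValueError("positions must be uniformly spaced and increasing")
        if self.areal_mass.shape != self.positions.shape:
            raise ValueError("areal_mass and positions shapes differ")
        if (self.areal_mass < 0).any():
            raise ValueError("areal mass must be non-negative")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


def _vertebra_mask(ny: int, nx: int) -> np.ndarray:
    """Waisted, vertebral-body-like mask strictly inside the grid bounds."""
    mask = np.zeros((ny, nx), dtype=bool)
    if ny < 3 or nx < 3:
        mask[ny // 2, nx // 2] = True
        return mask
    half_max = (nx - 2) / 2.0
    waist = 0.18 * half_max
    cx = (nx - 1) / 2.0
    for i in range(1, ny - 1):
        t = (i - 1) / max(ny - 3, 1)
        half = half_max - waist * np.sin(np.pi * t)
        j0 = int(np.ceil(cx - half))
        j1 = int(np.floor(cx + half))
        mask[i, max(j0, 1) : min(j1, nx - 2) + 1] = True
    return mask


def generate_bmd_map(
    nx: int,
    ny: int,
    mean_bmd: float,
    noise_sd: float = 0.0,
    shape: str = "rect",
    pixel_size: float = 1.0,
    seed: int = 0,
) -> BMDMap:
    """Synthetic areal-BMD map: ``shape='rect'`` fills the whole grid,
    ``'vertebra'`` a waisted mask strictly inside the bounds.  Pixel
    values are ``mean_bmd + N(0, noise_sd²)`` clipped at zero."""
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if mean_bmd < 0:
        raise ValueError("mean_bmd must be non-negative")
    if shape == "rect":
        mask = np.ones((ny, nx), dtype=bool)
    elif shape == "vertebra":
        mask = _vertebra_mask(ny, nx)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    rng = np.random.default_rng(seed)
    grid = np.full((ny, nx), float(mean_bmd))
    if noise_sd > 0:
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
    grid = np.clip(grid, 0.0, None)
    grid[~mask] = 0.0
    return BMDMap(grid=grid, pixel_size=pixel_size, mask=mask)


def generate_annulus_profile(
    r_outer: float,
    r_inner: float = 0.0,
    density: float = 1.05,
    spacing: float = 0.01,
) -> CrossSectionProfile:
    """Projected areal mass of an annular (tube-like) cross section.

    The closed form ``m(x) = ρ·2·(√(r_o²−x²) − [|x|<r_i]·√(r_i²−x²))`` is
    the line integral through an annulus of volumetric density ρ; it
    serves as the analytic oracle input for the HSA geometry stage.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not 0 <= r_inner < r_outer:
        raise ValueError("need 0 <= r_inner < r_outer")
    half = int(np.ceil(r_outer / spacing)) + 1
    x = np.arange(-half, half + 1) * spacing
    outer = np.sqrt(np.clip(r_outer**2 - x**2, 0.0, None))
    inner = np.where(
        np.abs(x) < r_inner, np.sqrt(np.clip(r_inner**2 - x**2, 0.0, None)), 0.0
    )
    m = 2.0 * density * (outer - inner)
    m[np.abs(x) >= r_outer] = 0.0
    return CrossSectionProfile(positions=x, areal_mass=m)


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return table
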