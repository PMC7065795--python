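"""Hip structural analysis geometry from projected areal-mass profiles.

A DXA scanner projects the mineral mass of a femoral cross section onto a
line; dividing the areal-mass profile m(x) (g/cm²) by the effective density
of fully mineralized bone ρ_m converts it to a linear thickness, from which
the classic structural indices follow:

    CSA      = Σ m_i Δx / ρ_m                  bone cross-sectional area, cm²
    x̄        = Σ m_i x_i / Σ m_i               mass center of the profile
    CSMI     = Σ m_i (x_i − x̄)² Δx / ρ_m       moment of inertia, cm⁴
    SECT_MOD = CSMI / d_max                    section modulus, cm³
    BR       = d_max / t                       buckling ratio

where d_max is the larger distance from the center to either profile edge
and t the mean cortical thickness, here recovered from an annulus model:
cortex_fraction·CSA = π(r_o² − r_i²) with r_o = width/2, t = r_o − r_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import CrossSectionProfile

__all__ = [
    "HsaResult",
    "hsa_from_profile",
    "estimate_cortical_thickness",
    "buckling_ratio",
]

#: Effective density of fully mineralized bone tissue, g/cm³ (standard
#: HSA convention for converting areal mass to solid bone area).
RHO_M = 1.05


@dataclass
class HsaResult:
    csa: float  # cm²
    csmi: float  # cm⁴
    sect_mod: float  # cm³
    width: float  # cm
    d_max: float  # cm
    cortical_thickness_est: float  # cm
    br: float  # dimensionless
    center: float  # cm, mass center position


def estimate_cortical_thickness(
    csa: float, width: float, cortex_fraction: float = 1.0
) -> float:
    """Mean cortical thickness from the annulus model.

    Solves cortex_fraction·csa = π(r_o² − r_i²) with r_o = width/2 and
    returns t = r_o − r_i.  Fails if the cortical area exceeds the disc
    of diameter ``width`` (no real annulus exists).
    """
    if csa <= 0 or width <= 0:
        raise ValueError("csa and width must be positive")
    if not 0 < cortex_fraction <= 1:
        raise ValueError("cortex_fraction must lie in (0, 1]")
    r_o = width / 2.0
    ri_sq = r_o**2 - cortex_fraction * csa / math.pi
    if ri_sq < -1e-12:
        raise ValueError("cortical area exceeds the enclosing disc: no annulus fits")
    return r_o - math.sqrt(max(ri_sq, 0.0))


def buckling_ratio(d_max: float, t: float) -> float:
    """BR = outer radius / mean cortical thickness."""
    if t <= 0:
        raise ValueError("cortical thickness must be positive")
    if d_max < 0:
        raise ValueError("d_max must be non-negative")
    return d_max / t


def hsa_from_profile(
    profile: CrossSectionProfile,
    rho_m: float = RHO_M,
    edge_threshold: float | None = None,
    cortex_fraction: float = 1.0,
) -> HsaResult:
    """Structural indices of a projected cross-section profile.

    ``edge_threshold`` (default 1% of the profile maximum) defines the
    in-bone span used for the width measurement.
    """
    x = profile.positions
    m = profile.areal_mass
    dx = profile.spacing
    if not m.any():
        raise ValueError("all-zero profile")
    if edge_threshold is None:
        edge_threshold = 0.01 * float(m.max())
    above = np.flatnonzero(m > edge_threshold)
    if above.size < 3:
        raise ValueError("fewer than 3 samples above the edge threshold")

    total_mass = float((m * dx).sum())
    csa = total_mass / rho_m
    center = float((m * x).sum() / m.sum())
    csmi = float((m * (x - center) ** 2 * dx).sum() / rho_m)
    left, right = x[above[0]], x[above[-1]]
    width = float(right - left)
    d_max = float(max(center - left, right - center))
    if d_max <= 0:
        raise ValueError("degenerate profile: zero d_max")
    sect_mod = csmi / d_max
    t = estimate_cortical_thickness(csa, width, cortex_fraction)
    return HsaResult(
        csa=csa, csmi=csmi, sect_mod=sect_mod, width=width, d_max=d_max,
        cortical_thickness_est=t, br=buckling_ratio(d_max, t), center=center,
    )
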