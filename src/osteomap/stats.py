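"""Normality-gated paired before/after statistics and responder stratification.

Implements the classical analysis layer of the pipeline: Shapiro–Wilk
normality gating, mean/SD vs median/IQR summaries, percent variation of
the summary centers, paired Student's t vs Wilcoxon signed-rank
comparison, the >10% lumbar-BMD responder rule, and the assembly of a
full per-variable summary table.

Conventions (fixed here, stated in docs/methods.md):

* parametric iff Shapiro–Wilk p ≥ alpha (default 0.05);
* the gate for *test choice* is applied to the paired differences, the
  gate for *presentation mode* (mean/SD vs median/IQR) to the raw
  per-timepoint values (both visits must pass);
* IQR uses linear interpolation between order statistics (quantile
  "type 7", numpy's default);
* Wilcoxon signed-rank: two-sided, zero differences dropped, exact null
  distribution for n ≤ 25, else normal approximation with continuity
  correction;
* percent variation is computed from the unrounded summary centers and
  reported rounded half-away-from-zero to two decimals;
* responder rule: strictly greater than the threshold percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import META_COLUMNS, PANEL_VARIABLES

__all__ = [
    "StatRow",
    "ResponderSplit",
    "normality_gate",
    "summarize",
    "percent_variation",
    "paired_compare",
    "split_responders",
    "build_summary_table",
    "summary_table_to_frame",
]

Mode = Literal["parametric", "nonparametric"]

PARAMETRIC: Mode = "parametric"
NONPARAMETRIC: Mode = "nonparametric"


@dataclass
class StatRow:
    """One line of a per-variable before/after summary report."""

    variable: str
    mode: Mode
    center_before: float
    center_after: float
    disp_before: float
    disp_after: float
    variation_pct: float
    p_value: float
    test: str
    significant: bool = False
    degenerate: bool = False


@dataclass
class ResponderSplit:
    responders: set = field(default_factory=set)
    non_responders: set = field(default_factory=set)
    threshold_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.responders & self.non_responders:
            raise ValueError("responder sets must be disjoint")


def _as_clean_array(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValueError("values contain non-finite entries")
    return arr


def normality_gate(values: Iterable[float], alpha: float = 0.05) -> Mode:
    """Shapiro–Wilk gate: parametric iff p ≥ alpha."""
    arr = _as_clean_array(values)
    if arr.size < 3:
        raise ValueError("normality gate needs at least 3 values")
    if np.ptp(arr) == 0:
        raise ValueError("normality gate undefined for constant input")
    p = sps.shapiro(arr).pvalue
    return PARAMETRIC if p >= alpha else NONPARAMETRIC


def summarize(values: Iterable[float], mode: Mode) -> tuple[float, float]:
    """(center, dispersion): mean/sample-SD or median/IQR per mode."""
    arr = _as_clean_array(values)
    if arr.size < 1:
        raise ValueError("summarize needs at least one value")
    if mode == PARAMETRIC:
        if arr.size < 2:
            raise ValueError("sample SD undefined for a single value")
        return float(arr.mean()), float(arr.std(ddof=1))
    if mode == NONPARAMETRIC:
        q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation (type 7)
        return float(np.median(arr)), float(q3 - q1)
    raise ValueError(f"unknown mode {mode!r}")


def _round_half_away(x: float, ndigits: int) -> float:
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def percent_variation(
    center_before: float, center_after: float, ndigits: int | None = 2
) -> float:
    """100·(after − before)/before, rounded half-away-from-zero for reporting.

    Pass ``ndigits=None`` for the unrounded value.
    """
    if center_before == 0:
        raise ZeroDivisionError("percent variation undefined for zero baseline")
    pct = 100.0 * (center_after - center_before) / center_before
    if ndigits is None:
        return pct
    return _round_half_away(pct, ndigits)


def paired_compare(
    before: Iterable[float],
    after: Iterable[float],
    alpha: float = 0.05,
    variable: str = "",
    presentation_mode: Mode | None = None,
) -> StatRow:
    """Paired two-sided comparison with a Shapiro–Wilk gate on the differences.

    Normally-distributed differences → paired t; otherwise Wilcoxon
    signed-rank (zeros dropped; exact for n ≤ 25 else corrected normal
    approximation).  All-zero differences yield p = 1 with the degenerate
    flag set rather than an exception; constant non-zero differences are
    also flagged degenerate (the gate is undefined) and reported with
    p = 0 under the t label, since every patient moved identically.
    """
    b = _as_clean_array(before)
    a = _as_clean_array(after)
    if b.size != a.size:
        raise ValueError("before/after must be equal length")
    if b.size < 3:
        raise ValueError("paired comparison needs n >= 3")
    diffs = a - b

    degenerate = False
    if np.ptp(diffs) == 0:
        degenerate = True
        if np.all(diffs == 0):
            p, test = 1.0, "paired_t"
        else:
            p, test = 0.0, "paired_t"
        gate = PARAMETRIC
    else:
        gate = normality_gate(diffs, alpha=alpha)
        if gate == PARAMETRIC:
            p = float(sps.ttest_rel(a, b).pvalue)
            test = "paired_t"
        else:
            nz = diffs[diffs != 0]
            method = "exact" if nz.size <= 25 else "approx"
            res = sps.wilcoxon(
                a, b, zero_method="wilcox", alternative="two-sided",
                correction=True, method=method,
            )
            p = float(res.pvalue)
            test = "wilcoxon_signed_rank"

    mode = presentation_mode
    if mode is None:
        # Presentation gate on raw values: both visits must look normal.
        try:
            mode = (
                PARAMETRIC
                if normality_gate(b, alpha) == PARAMETRIC
                and normality_gate(a, alpha) == PARAMETRIC
                else NONPARAMETRIC
            )
        except ValueError:  # constant raw values
            mode = PARAMETRIC
    cb, db = summarize(b, mode)
    ca, da = summarize(a, mode)
    variation = percent_variation(cb, ca) if cb != 0 else float("nan")
    return StatRow(
        variable=variable,
        mode=mode,
        center_before=cb,
        center_after=ca,
        disp_before=db,
        disp_after=da,
        variation_pct=variation,
        p_value=p,
        test=test,
        significant=p < 0.05,
        degenerate=degenerate,
    )


def _paired_pivot(cohort: pd.DataFrame, variable: str) -> pd.DataFrame:
    wide = cohort.pivot_table(
        index="patient_id", columns="timepoint", values=variable, aggfunc="first"
    )
    missing = [c for c in ("before", "after") if c not in wide.columns]
    if missing:
        raise ValueError(f"cohort lacks timepoint(s) {missing} for {variable!r}")
    incomplete = wide.index[wide[["before", "after"]].isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(f"patients missing a timepoint: {incomplete}")
    return wide


def split_responders(
    cohort: pd.DataFrame, threshold_pct: float = 10.0, variable: str = "BMD"
) -> ResponderSplit:
    """Partition patients by the lumbar-BMD response rule (> threshold %)."""
    wide = _paired_pivot(cohort, variable)
    change = 100.0 * (wide["after"] - wide["before"]) / wide["before"]
    # strict inequality, with a tiny guard so an exact +threshold change
    # is not promoted to responder by floating-point round-off
    responders = set(wide.index[change - threshold_pct > 1e-9])
    non_responders = set(wide.index) - responders
    return ResponderSplit(
        responders=responders,
        non_responders=non_responders,
        threshold_pct=threshold_pct,
    )


def build_summary_table(
    cohort: pd.DataFrame,
    subset: str = "all",
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
    threshold_pct: float = 10.0,
) -> list[StatRow]:
    """One StatRow per panel variable, in report order.

    ``subset`` ∈ {all, responders, non_responders}; the responder split is
    recomputed from the cohort's lumbar BMD when a subgroup is requested.
    """
    if variables is None:
        variables = [c for c in PANEL_VARIABLES if c in cohort.columns]
        if not variables:
            variables = [c for c in cohort.columns if c not in META_COLUMNS]
    if subset not in ("all", "responders", "non_responders"):
        raise ValueError(f"unknown subset {subset!r}")
    table = cohort
    if subset != "all":
        split = split_responders(table, threshold_pct=threshold_pct)
        keep = split.responders if subset == "responders" else split.non_responders
        table = table[table["patient_id"].isin(keep)]
        if table.empty:
            raise ValueError(f"subset {subset!r} selects no patients")
    rows = []
    for v in variables:
        wide = _paired_pivot(table, v)
        rows.append(
            paired_compare(
                wide["before"].to_numpy(), wide["after"].to_numpy(),
                alpha=alpha, variable=v,
            )
        )
    return rows


def summary_table_to_frame(rows: Sequence[StatRow]) -> pd.DataFrame:
    """Tabular (CSV-ready) form of a summary table, mirroring the report
    layout: center, dispersion, variation % and p per variable, with a
    significance marker column."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "mode": [r.mode for r in rows],
            "center_before": [r.center_before for r in rows],
            "disp_before": [r.disp_before for r in rows],
            "center_after": [r.center_after for r in rows],
            "disp_after": [r.disp_after for r in rows],
            "variation_pct": [r.variation_pct for r in rows],
            "p_value": [r.p_value for r in rows],
            "test": [r.test for r in rows],
            "significant": ["*" if r.significant else "" for r in rows],
        }
    )
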