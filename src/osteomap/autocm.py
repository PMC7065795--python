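"""Auto-Contractive Map: an unsupervised ANN yielding variable-to-variable
connection weights.

The Auto-CM is a three-layer network (input, hidden, output; all of width
N = number of variables) trained on M patterns scaled to [0, 1].  Its
learning rule contracts each weight toward the ceiling C at a rate driven
by the co-activation of the variables it links, so after training the
hidden→output matrix W encodes association strength: strongly coupled
variables end up with weights near C, weakly coupled ones near their
initial value.  The distance transform d = 1 − W_sym/C then feeds the
minimum-spanning-tree / maximally-regular-graph mapping stage.

Per-epoch, per-pattern update (patterns in fixed row order):

    h_j   = x_j · (1 − v_j/C)                 (input → hidden)
    Δv_j  = (x_j − h_j) · (1 − v_j/C)         (input weights)
    Net_i = Σ_j h_j · (1 − W_ij/C)            (hidden → output)
    o_i   = h_i · (1 − Net_i/C)
    ΔW_ij = (h_i − o_i) · (1 − W_ij/C) · h_j  (connection matrix)

Training is fully deterministic: no randomness enters here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "AutoCMModel",
    "normalize",
    "train",
    "autocm_cost",
    "traditional_cost",
    "to_distance",
]


@dataclass
class NormalizedMatrix:
    """M×N matrix min-max scaled to [0,1] per column, with the original
    column ranges retained so the transform is exactly invertible."""

    values: np.ndarray
    variables: tuple[str, ...]
    col_min: np.ndarray
    col_max: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (patterns × variables)")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("normalized values must lie in [0, 1]")

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def inverse(self) -> np.ndarray:
        return self.col_min + self.values * (self.col_max - self.col_min)


@dataclass
class AutoCMModel:
    """Trained Auto-CM: input→hidden vector v, hidden→output matrix W,
    contraction ceiling C."""

    v: np.ndarray
    W: np.ndarray
    C: float
    epochs_run: int
    converged: bool
    variables: tuple[str, ...] = ()


def normalize(table, variables: Sequence[str] | None = None) -> NormalizedMatrix:
    """Per-column min-max scaling to [0, 1].

    Accepts a numeric DataFrame (column names become variable names) or a
    2D array.  Constant and non-finite columns are rejected by name.
    """
    if isinstance(table, pd.DataFrame):
        frame = table if variables is None else table[list(variables)]
        names = tuple(frame.columns)
        values = frame.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        names = tuple(
            variables
            if variables is not None
            else (f"x{i}" for i in range(values.shape[1]))
        )
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 patterns")
    bad = [names[j] for j in range(values.shape[1]) if not np.isfinite(values[:, j]).all()]
    if bad:
        raise ValueError(f"non-finite values in column(s): {bad}")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    constant = [names[j] for j in range(values.shape[1]) if hi[j] == lo[j]]
    if constant:
        raise ValueError(f"constant column(s) cannot be normalized: {constant}")
    scaled = (values - lo) / (hi - lo)
    return NormalizedMatrix(values=scaled, variables=names, col_min=lo, col_max=hi)


def train(
    X: NormalizedMatrix,
    C: float | None = None,
    tol: float = 1e-6,
    max_epochs: int = 1000,
    init: float = 1e-5,
) -> AutoCMModel:
    """Train the Auto-CM on a normalized matrix.

    ``C`` defaults to the number of variables.  One epoch presents every
    pattern once, in row order, applying the contractive updates after
    each pattern.  Training stops when the largest absolute weight change
    over an epoch falls below ``tol`` (converged) or at ``max_epochs``.
    All weights start at ``init`` (not zero: x = 0 is a fixed point of the
    update) and remain in [0, C].
    """
    n = X.n_variables
    if n < 2:
        raise ValueError("need at least 2 variables")
    C_val = float(C) if C is not None else float(n)
    if C_val <= 0:
        raise ValueError("C must be positive")

    v = np.full(n, float(init))
    W = np.full((n, n), float(init))
    patterns = X.values
    epochs = 0
    converged = False
    for epoch in range(max_epochs):
        max_delta = 0.0
        for q in range(patterns.shape[0]):
            x = patterns[q]
            hv = 1.0 - v / C_val
            h = x * hv
            dv = (x - h) * hv
            hw = 1.0 - W / C_val
            net = hw @ h
            o = h * (1.0 - net / C_val)
            # (h_i − o_i)·(1 − W_ij/C)·h_j with i indexing rows
            dW = ((h - o)[:, None] * h[None, :]) * hw
            v = v + dv
            W = W + dW
            if not (np.isfinite(v).all() and np.isfinite(W).all()):
                raise FloatingPointError(
                    "non-finite weight during training (divergent configuration)"
                )
            step = max(np.abs(dv).max(initial=0.0), np.abs(dW).max(initial=0.0))
            if step > max_delta:
                max_delta = step
        epochs = epoch + 1
        if max_delta < tol:
            # A non-finite tol means "run one epoch and stop": the loop
            # exits but the model is not certified converged.
            converged = bool(np.isfinite(tol))
            break
    v = np.clip(v, 0.0, C_val)
    W = np.clip(W, 0.0, C_val)
    return AutoCMModel(
        v=v, W=W, C=C_val, epochs_run=epochs, converged=converged,
        variables=X.variables,
    )


def autocm_cost(X: NormalizedMatrix, model: AutoCMModel) -> float:
    """Third-order Auto-CM energy
    E = Σ_q Σ_i Σ_j Σ_k u_iq·u_jq·u_kq·A_ij·A_ik with A = 1 − W/C.

    Evaluated as Σ_q Σ_i u_iq·(A u_q)_i², which is algebraically the same
    quadruple sum.
    """
    if model.W.shape != (X.n_variables,) * 2:
        raise ValueError("model/matrix dimension mismatch")
    A = 1.0 - model.W / model.C
    U = X.values  # M × N
    Au = U @ A.T  # (A u_q)_i for each pattern
    return float(np.sum(U * Au**2))


def traditional_cost(X: NormalizedMatrix, sigma: np.ndarray) -> float:
    """Second-order energy E = Σ_q Σ_i Σ_j u_iq·u_jq·σ_ij (diagnostic)."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (X.n_variables,) * 2:
        raise ValueError("sigma must be N×N")
    U = X.values
    return float(np.einsum("qi,ij,qj->", U, sigma, U))


def to_distance(model: AutoCMModel) -> pd.DataFrame:
    """Distance transform of the trained connection matrix.

    W is symmetrized by arithmetic mean, then d = clamp(1 − W_sym/C, 0, 1)
    with a forced zero diagonal.  Returned as a labeled DataFrame so the
    graph stage keeps variable names.
    """
    W_sym = (model.W + model.W.T) / 2.0
    d = np.clip(1.0 - W_sym / model.C, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    names = list(model.variables) if model.variables else None
    return pd.DataFrame(d, index=names, columns=names)
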