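"""Auto-Contractive-Map association learning.

The Auto-CM is a three-layer network (input, hidden, output — one unit per
node) trained on the [0,1] node matrix.  Both layers contract their signal by
a factor (1 − weight/C), where C is the contraction constant:

    hidden   h_s(i) = m_s(i) · (1 − v(i)/C)
    net      Net_s(j) = Σ_i (w(i,j)/C) · h_s(i) / N
    output   o_s(j) = h_s(j) · (1 − Net_s(j)/C)

with batch (epoch) updates averaged over the S records:

    Δv(i)   = Σ_s (m_s(i) − h_s(i)) · (1 − v(i)/C) / S
    Δw(i,j) = Σ_s (h_s(j) − o_s(j)) · (1 − w(i,j)/C) · h_s(i) / S

The input weights v grow monotonically toward C, squeezing the hidden signal
to zero; learning therefore halts by itself, and the frozen association
matrix w records how strongly each node pair co-activated while signal still
flowed.  Strongly associated pairs end with larger w.  Weights are then read
as proximities: d = (C − w), min–max rescaled over the off-diagonal to [0,1],
gives the symmetric distance matrix the spanning-tree filters operate on.

The exact contraction constant and stopping rule of the original software
are not published; this formulation is a faithful reconstruction of the
standard Auto-CM dynamics, and the min–max rescale of the distances makes
the downstream maps invariant to the overall weight scale.

Training is fully deterministic: constant (non-random) weight
initialisation, batch updates, no sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scaling import ScaledMatrix


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class AutoCMConfig:
    """Training hyperparameters.

    contraction: the constant C; 1.0 suits inputs already in [0,1].
    tolerance: convergence when mean |Δw| per epoch drops below it.
    init_scale: constant initial value of every weight (deterministic init).
    record_order_seed: kept for interface compatibility; updates are batch,
        so record order cannot influence the result and the seed is inert.
    """

    contraction: float = 1.0
    max_epochs: int = 5000
    tolerance: float = 1e-8
    init_scale: float = 1e-4
    record_order_seed: int = 0

    def __post_init__(self) -> None:
        if self.contraction <= 0:
            raise ValueError("contraction constant C must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.init_scale < self.contraction:
            raise ValueError("init_scale must be in (0, C)")


@dataclass
class WeightMatrix:
    labels: list[str]
    v: np.ndarray          # input-layer weights, one per node
    w: np.ndarray          # symmetrized node × node association weights
    epochs_run: int
    converged: bool
    contraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path)


@dataclass
class DistanceMatrix:
    """Symmetric node × node distances rescaled to [0,1], zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if d.min() < 0 or d.max() > 1:
            raise ValueError("distances must lie in [0,1]")
        self.d = d

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path)


def train_autocm(scaled: ScaledMatrix, config: AutoCMConfig | None = None) -> WeightMatrix:
    """Train the Auto-CM on a scaled node matrix.

    Runs the contractive batch dynamics until the mean absolute weight change
    per epoch falls below the tolerance or the epoch cap is reached; returns
    the symmetrized association matrix with a convergence flag.
    """
    config = config or AutoCMConfig()
    M = np.asarray(scaled.values, dtype=float)
    S, N = M.shape
    if N < 2:
        raise ValueError("need at least 2 nodes")
    if S < 1:
        raise ValueError("need at least 1 record")
    C = config.contraction
    v = np.full(N, config.init_scale)
    W = np.full((N, N), config.init_scale)

    epochs = 0
    converged = False
    for epoch in range(1, config.max_epochs + 1):
        H = M * (1.0 - v / C)                  # S × N hidden activations
        Net = (H @ (W / C)) / N                # S × N
        O = H * (1.0 - Net / C)
        dv = ((M - H) * (1.0 - v / C)).mean(axis=0)
        dW = (H.T @ (H - O)) / S * (1.0 - W / C)
        v = v + dv
        W = W + dW
        epochs = epoch
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(v))):
            bad = np.argwhere(~np.isfinite(W))
            node = scaled.node_labels[bad[0][0]] if bad.size else "?"
            raise TrainingError(
                f"non-finite weights at epoch {epoch} (node {node!r})"
            )
        if float(np.abs(dW).mean()) < config.tolerance:
            converged = True
            break

    W = np.clip((W + W.T) / 2.0, 0.0, C)  # symmetrize; contraction bounds by C
    return WeightMatrix(
        labels=list(scaled.node_labels),
        v=v,
        w=W,
        epochs_run=epochs,
        converged=converged,
        contraction=C,
    )


def weights_to_distances(wm: WeightMatrix) -> DistanceMatrix:
    """Turn learned weights into map distances.

    d = (C − w) min–max rescaled over the off-diagonal entries to [0,1]; the
    transform is strictly decreasing in w, so stronger associations sit
    closer.  Errors when all off-diagonal weights are equal (no geometry to
    resolve).
    """
    W = wm.w
    n = W.shape[0]
    raw = wm.contraction - W
    off = ~np.eye(n, dtype=bool)
    lo, hi = float(raw[off].min()), float(raw[off].max())
    if hi == lo:
        raise ValueError(
            "all off-diagonal weights are equal; distance geometry unresolvable"
        )
    d = (raw - lo) / (hi - lo)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(labels=list(wm.labels), d=d)
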