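"""Redundancy pruning of the feature space by Kendall rank correlation.

Feature pairs correlated above tau = 0.90 are visited in descending-tau
order (ties broken by name) and one member of each still-intact pair is
removed uniformly at random, so no surviving pair exceeds the threshold.
The threshold applies to the signed tau by default; absolute-value mode is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from ._rng import substream

__all__ = ["CorrelationMatrix", "kendall_matrix", "prune_correlated"]


@dataclass
class CorrelationMatrix:
    feature_names: list[str]
    tau: np.ndarray  # symmetric, diagonal 1, tau-b

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        n = len(self.feature_names)
        if self.tau.shape != (n, n):
            raise ValueError("tau matrix shape does not match feature names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tau, index=self.feature_names,
                            columns=self.feature_names)


def kendall_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Kendall tau-b over the columns of a feature table.

    Constant features have undefined tau; it is recorded as 0 with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 samples")
    names = list(table.columns)
    X = table.to_numpy(dtype=float)
    n = len(names)
    constant = [names[j] for j in range(n) if np.ptp(X[:, j]) == 0]
    if constant:
        warnings.warn(f"constant features, tau recorded as 0: {constant}")
    tau = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            t = kendalltau(X[:, a], X[:, b]).statistic
            tau[a, b] = tau[b, a] = 0.0 if np.isnan(t) else t
    return CorrelationMatrix(names, tau)


def prune_correlated(cm: CorrelationMatrix, threshold: float = 0.90,
                     seed: int = 0, absolute: bool = False) -> list[str]:
    """Remove one random member of every over-correlated pair.

    Pairs with tau (or |tau| in absolute mode) above ``threshold`` are
    processed in descending correlation order, ties broken by name pair; if
    both members are still present one is dropped uniformly at random.
    Returns the kept features in their original order.
    """
    rng = substream(seed, "prune")
    names = cm.feature_names
    score = np.abs(cm.tau) if absolute else cm.tau
    pairs = [(score[a, b], names[a], names[b])
             for a in range(len(names)) for b in range(a + 1, len(names))
             if score[a, b] > threshold]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    alive = set(names)
    for _, fa, fb in pairs:
        if fa in alive and fb in alive:
            alive.discard(fa if rng.random() < 0.5 else fb)
    return [f for f in names if f in alive]
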