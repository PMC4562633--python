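"""Correlation-distance baseline for neighbor calling.

A predictor p ∈ Π is a neighbor of pathway χ when its correlation
distance d(p, a) = 1 - r(p, a) to at least one pathway gene a falls at
or below a threshold μ. The shared set (Θ1∩2) is the intersection of
the two pathways' neighbor sets, mirroring the elastic-net result shape
so both methods can be compared downstream.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from scipy.stats import rankdata

from .preprocessing import ExpressionMatrix
from .sparse_neighbors import Edge, NeighborResult, PathwayPair

__all__ = ["CorrConfig", "correlation_neighbors"]


@dataclass(frozen=True)
class CorrConfig:
    """Threshold μ on d = 1 - r; ``absolute`` uses d = 1 - |r| instead."""

    mu: float = 0.1
    method: str = "pearson"
    absolute: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 2.0:
            raise ValueError("mu must be in [0, 2]")
        if self.method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")


def _standardized_rows(values: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        values = rankdata(values, axis=1)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene profile in correlation baseline")
    return (values - values.mean(axis=1, keepdims=True)) / sd


def correlation_neighbors(
    matrix: ExpressionMatrix, pair: PathwayPair, config: CorrConfig = CorrConfig()
) -> NeighborResult:
    """Call neighbors of both pathways by thresholded correlation distance.

    Edges carry the correlation coefficient in the coefficient slot;
    penalty and variance-explained fields are NaN (not applicable).
    """
    index = matrix.values.index
    pool = list(pair.pool)
    missing = [g for g in pool if g not in index]
    if missing:
        raise ValueError(f"{len(missing)} pool genes missing from matrix")
    P = _standardized_rows(matrix.values.loc[pool].to_numpy(dtype=float),
                           config.method)
    T = P.shape[1]
    edges: list[Edge] = []
    for which in (1, 2):
        chi = sorted(pair.chi(which) & set(index))
        if not chi:
            raise ValueError(f"no genes of pathway {which} found in the matrix")
        C = _standardized_rows(matrix.values.loc[chi].to_numpy(dtype=float),
                               config.method)
        r = P @ C.T / T  # (|Π|, |χ|) correlation matrix
        if config.absolute:
            r = np.abs(r)
        dist = 1.0 - r
        hit_p, hit_a = np.nonzero(dist <= config.mu)
        for i, j in zip(hit_p, hit_a):
            edges.append(
                Edge(chi[j], pool[i], float(r[i, j]), which,
                     float("nan"), float("nan"), True)
            )
    return NeighborResult(matrix.condition, pair, edges, method="correlation")
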