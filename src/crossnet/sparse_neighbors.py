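"""Elastic-net neighbor calling between two pathways.

Each gene ``a_i`` of a pathway χ is modeled from the predictor pool
Π = (Ω\\χ1) ∩ (Ω\\χ2) — all genes outside both pathways — with an
elastic-net regression over a descending penalty-strength path

    minimize over (ω, b):  ||y - Xω - b||² / (2T)
                           + s·( λ·||ω||₁ + (1-λ)/2·||ω||₂² )

where T is the number of samples, λ ∈ (0, 1] mixes the ℓ1 (sparsity) and
ℓ2 (grouping) penalties and s sweeps a geometric grid from ``s_max`` (the
smallest strength at which every coefficient is exactly zero) downward.
The model actually used for a gene is the sparsest path point whose
training variance explained (1 - RSS/TSS) reaches ``variance_target``;
its non-zero-coefficient predictors are the gene's *neighbors*.  The
pathway's neighbor set Γ is the union over its genes, and the *shared
neighbors* of two pathways are Γ1 ∩ Γ2 — predictors connected to at
least one gene in each pathway, candidates for intermediaries that link
the pathways.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path as _sk_enet_path

from .preprocessing import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayPair",
    "EnetConfig",
    "RegressionPath",
    "Edge",
    "NeighborResult",
    "build_predictor_pool",
    "fit_enet_path",
    "select_coefficients",
    "neighbors_of_gene",
    "neighbors_of_pathway",
    "shared_neighbors",
]


@dataclass(frozen=True)
class PathwayPair:
    """Two disjoint pathway gene sets χ1, χ2 and the predictor pool Π."""

    name1: str
    name2: str
    chi1: frozenset[str]
    chi2: frozenset[str]
    pool: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.chi1 & self.chi2:
            raise ValueError(f"pathways overlap: {sorted(self.chi1 & self.chi2)}")
        pool = set(self.pool)
        if pool & self.chi1 or pool & self.chi2:
            raise ValueError("predictor pool overlaps a pathway")
        if len(self.pool) != len(pool):
            raise ValueError("predictor pool has duplicate genes")

    def chi(self, which: int) -> frozenset[str]:
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        return self.chi1 if which == 1 else self.chi2


@dataclass(frozen=True)
class EnetConfig:
    """Elastic-net settings.

    ``mixing`` is the ℓ1/ℓ2 mixing λ (1 = lasso); ``variance_target`` the
    fraction of training variance the selected model must explain;
    ``n_penalties``/``penalty_ratio`` define the geometric strength grid;
    ``zero_tol`` separates solver-exact zeros from numerically tiny
    coefficients when calling neighbors.
    """

    mixing: float = 0.5
    variance_target: float = 0.75
    n_penalties: int = 100
    penalty_ratio: float = 1e-3
    zero_tol: float = 1e-10
    tol: float = 1e-9  # coordinate-descent tolerance; keeps stationarity and
    # identical-predictor coefficient agreement well under 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.mixing <= 1.0:
            raise ValueError("mixing must be in (0, 1]")
        if not 0.0 <= self.variance_target < 1.0:
            raise ValueError("variance_target must be in [0, 1)")
        if self.n_penalties < 1 or not 0.0 < self.penalty_ratio < 1.0:
            raise ValueError("invalid penalty grid")


@dataclass
class RegressionPath:
    """Solution path for one modeled gene over a descending penalty grid."""

    target_gene: str
    penalties: np.ndarray  # strictly decreasing, shape (n_penalties,)
    coefficients: np.ndarray  # shape (n_penalties, P)
    variance_explained: np.ndarray  # shape (n_penalties,)
    intercepts: np.ndarray  # shape (n_penalties,)

    def __len__(self) -> int:
        return len(self.penalties)


class Edge(NamedTuple):
    pathway_gene: str
    predictor_gene: str
    coefficient: float
    which_pathway: int
    penalty: float
    variance_explained: float
    met_target: bool


@dataclass
class NeighborResult:
    """Neighbor sets Γ1, Γ2 and shared set Γ1∩2 for one condition."""

    condition: str
    pathway_pair: PathwayPair
    edges: list[Edge]
    method: str = "enet"
    gamma1: frozenset[str] = field(init=False)
    gamma2: frozenset[str] = field(init=False)
    shared: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.gamma1 = frozenset(
            e.predictor_gene for e in self.edges if e.which_pathway == 1
        )
        self.gamma2 = frozenset(
            e.predictor_gene for e in self.edges if e.which_pathway == 2
        )
        self.shared = self.gamma1 & self.gamma2
        pool = set(self.pathway_pair.pool)
        if not (self.gamma1 <= pool and self.gamma2 <= pool):
            raise ValueError("neighbor outside the predictor pool")


def build_predictor_pool(
    universe: Iterable[str],
    chi1: Iterable[str],
    chi2: Iterable[str],
    name1: str = "pathway1",
    name2: str = "pathway2",
) -> PathwayPair:
    """Intersect pathways with the gene universe and derive Π.

    Overlapping pathways are an error (the method assumes disjoint gene
    sets); pathway genes absent from the universe are dropped with a
    logged count.
    """
    universe = set(universe)
    chi1, chi2 = set(chi1), set(chi2)
    if chi1 & chi2:
        raise ValueError(f"pathways overlap: {sorted(chi1 & chi2)}")
    absent1, absent2 = chi1 - universe, chi2 - universe
    if absent1 or absent2:
        logger.warning(
            "%d genes of %s and %d genes of %s absent from the matrix",
            len(absent1), name1, len(absent2), name2,
        )
    chi1 &= universe
    chi2 &= universe
    if not chi1 or not chi2:
        raise ValueError("a pathway has no genes left after matching the matrix")
    pool = tuple(sorted(universe - chi1 - chi2))
    if not pool:
        raise ValueError("empty predictor pool: pathways cover the whole universe")
    return PathwayPair(name1, name2, frozenset(chi1), frozenset(chi2), pool)


def fit_enet_path(
    y: np.ndarray, X: np.ndarray, config: EnetConfig, target_gene: str = ""
) -> RegressionPath:
    """Solve the elastic net over a geometric penalty-strength grid.

    The grid starts at ``s_max = max_j |x_j'(y - mean y)| / (T·λ)``, the
    smallest strength whose solution is identically zero, and descends to
    ``s_max · penalty_ratio``. An intercept is always fitted; predictors
    are used as given (they are expected to be z-scored upstream and are
    not re-standardized here).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("y must be (T,), X must be (T, P)")
    T, P = X.shape
    if T < 3:
        raise ValueError(f"need at least 3 samples, got {T}")
    if P < 1:
        raise ValueError("need at least one predictor")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("non-finite values in y or X")

    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    s_max = float(np.max(np.abs(Xc.T @ yc)) / (T * config.mixing))
    if s_max <= 0.0:  # y constant: the zero model is exact everywhere
        penalties = np.ones(1)
        coefs = np.zeros((1, P))
        return RegressionPath(target_gene, penalties, coefs, np.zeros(1),
                              np.full(1, y_mean))
    penalties = np.geomspace(s_max, s_max * config.penalty_ratio, config.n_penalties)

    # tol is far below the 1e-6 stationarity contract; the coordinate-descent
    # convergence warning at this tolerance is noise, stationarity is what counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coef_path, _ = _sk_enet_path(
            Xc,
            yc,
            l1_ratio=config.mixing,
            alphas=penalties,
            eps=config.penalty_ratio,
            tol=config.tol,
            max_iter=100_000,
        )
    coefs = coef_path.T  # (n_penalties, P)
    residuals = yc[None, :] - coefs @ Xc.T
    tss = float(yc @ yc)
    rss = np.einsum("ij,ij->i", residuals, residuals)
    variance_explained = 1.0 - rss / tss
    variance_explained[~coefs.any(axis=1)] = 0.0  # zero model explains nothing, exactly
    intercepts = y_mean - coefs @ x_mean
    return RegressionPath(target_gene, penalties, coefs, variance_explained, intercepts)


def _fit_until_target(
    y: np.ndarray, X: np.ndarray, config: EnetConfig, target_gene: str = "",
    chunk: int = 20,
) -> RegressionPath:
    """Path solved in warm-started chunks, stopping once the variance
    target is reached.

    Identical grid and solutions as :func:`fit_enet_path` (continuation
    along the same penalties), but path points past the first target
    crossing — which model selection never looks at — are not computed.
    Used internally by :func:`neighbors_of_pathway` for speed.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    T, P = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = np.ascontiguousarray(X - x_mean)
    yc = y - y_mean

    s_max = float(np.max(np.abs(Xc.T @ yc)) / (T * config.mixing))
    if s_max <= 0.0:
        return RegressionPath(target_gene, np.ones(1), np.zeros((1, P)),
                              np.zeros(1), np.full(1, y_mean))
    penalties = np.geomspace(s_max, s_max * config.penalty_ratio, config.n_penalties)
    tss = float(yc @ yc)

    coef_blocks: list[np.ndarray] = []
    ve_blocks: list[np.ndarray] = []
    coef_init = np.zeros(P)
    done = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        while done < len(penalties):
            block = penalties[done:done + chunk]
            _, coef_path, _ = _sk_enet_path(
                Xc, yc,
                l1_ratio=config.mixing,
                alphas=block,
                tol=config.tol,
                max_iter=100_000,
                coef_init=coef_init,
            )
            coefs = coef_path.T
            residuals = yc[None, :] - coefs @ Xc.T
            ve = 1.0 - np.einsum("ij,ij->i", residuals, residuals) / tss
            ve[~coefs.any(axis=1)] = 0.0
            coef_blocks.append(coefs)
            ve_blocks.append(ve)
            done += len(block)
            coef_init = coefs[-1].copy()
            if np.any(ve >= config.variance_target):
                cut = done - len(block) + int(np.argmax(ve >= config.variance_target)) + 1
                all_coefs = np.vstack(coef_blocks)[:cut]
                all_ve = np.concatenate(ve_blocks)[:cut]
                return RegressionPath(
                    target_gene, penalties[:cut], all_coefs, all_ve,
                    y_mean - all_coefs @ x_mean,
                )
    all_coefs = np.vstack(coef_blocks)
    all_ve = np.concatenate(ve_blocks)
    return RegressionPath(target_gene, penalties, all_coefs, all_ve,
                          y_mean - all_coefs @ x_mean)


def select_coefficients(
    path: RegressionPath, variance_target: float
) -> tuple[np.ndarray, float, bool, int]:
    """Sparsest path point reaching the variance target.

    Returns ``(coefficients, achieved_variance, met_target, index)`` at
    the largest penalty whose variance explained is at least the target;
    if no point reaches it, the smallest-penalty (densest) model is
    returned with ``met_target=False``.
    """
    if len(path) == 0:
        raise ValueError("empty regression path")
    reached = np.flatnonzero(path.variance_explained >= variance_target)
    if reached.size:
        i = int(reached[0])
        return path.coefficients[i], float(path.variance_explained[i]), True, i
    i = len(path) - 1
    logger.debug(
        "gene %s: variance target %.2f not reached (best %.3f); using densest model",
        path.target_gene, variance_target, path.variance_explained[i],
    )
    return path.coefficients[i], float(path.variance_explained[i]), False, i


def neighbors_of_gene(
    coefficients: np.ndarray, pool: Sequence[str], zero_tol: float = 1e-10
) -> set[str]:
    """Predictor genes with coefficient magnitude above ``zero_tol``."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (len(pool),):
        raise ValueError("coefficient vector length must equal |pool|")
    idx = np.flatnonzero(np.abs(coefficients) > zero_tol)
    return {pool[i] for i in idx}


def _pool_design(matrix: ExpressionMatrix, pair: PathwayPair) -> np.ndarray:
    missing = [g for g in pair.pool if g not in matrix.values.index]
    if missing:
        raise ValueError(f"{len(missing)} pool genes missing from matrix")
    return np.ascontiguousarray(matrix.values.loc[list(pair.pool)].to_numpy().T)


def neighbors_of_pathway(
    matrix: ExpressionMatrix,
    pair: PathwayPair,
    which: int,
    config: EnetConfig = EnetConfig(),
    X: np.ndarray | None = None,
) -> tuple[set[str], list[Edge]]:
    """Neighbor set Γ of one pathway: union of per-gene neighbor calls.

    Each present pathway gene is modeled on the pool; edges record every
    (pathway gene, predictor, coefficient) with the penalty and variance
    explained of the selected path point.
    """
    chi = sorted(pair.chi(which) & set(matrix.values.index))
    if not chi:
        raise ValueError(f"no genes of pathway {which} found in the matrix")
    if X is None:
        X = _pool_design(matrix, pair)
    edges: list[Edge] = []
    for gene in chi:
        y = matrix.profile(gene)
        path = _fit_until_target(y, X, config, target_gene=gene)
        coef, achieved, met, i = select_coefficients(path, config.variance_target)
        nz = np.flatnonzero(np.abs(coef) > config.zero_tol)
        logger.debug(
            "%s: penalty=%.4g variance=%.3f neighbors=%d met_target=%s",
            gene, path.penalties[i], achieved, nz.size, met,
        )
        for j in nz:
            edges.append(
                Edge(gene, pair.pool[j], float(coef[j]), which,
                     float(path.penalties[i]), achieved, met)
            )
    gamma = {e.predictor_gene for e in edges}
    return gamma, edges


def shared_neighbors(
    matrix: ExpressionMatrix, pair: PathwayPair, config: EnetConfig = EnetConfig()
) -> NeighborResult:
    """Run neighbor discovery for both pathways and intersect.

    The shared set Γ1∩2 contains the predictors with a non-zero
    coefficient for at least one gene in each pathway, with full edge
    provenance retained in the result.
    """
    X = _pool_design(matrix, pair)
    _, edges1 = neighbors_of_pathway(matrix, pair, 1, config, X=X)
    _, edges2 = neighbors_of_pathway(matrix, pair, 2, config, X=X)
    result = NeighborResult(matrix.condition, pair, edges1 + edges2, method="enet")
    logger.info(
        "%s: |Γ1|=%d |Γ2|=%d |Γ1∩2|=%d",
        matrix.condition, len(result.gamma1), len(result.gamma2), len(result.shared),
    )
    return result


def write_edges(result: NeighborResult, path, header: str | None = None) -> None:
    """Write edges as TSV (condition, pathway, genes, coefficient, fit info)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "condition\tmethod\tpathway_id\tpathway_gene\tneighbor_gene"
            "\tcoefficient\tpenalty\tvariance_explained\tmet_target\n"
        )
        pair = result.pathway_pair
        for e in sorted(result.edges):
            pathway = pair.name1 if e.which_pathway == 1 else pair.name2
            fh.write(
                f"{result.condition}\t{result.method}\t{pathway}\t{e.pathway_gene}"
                f"\t{e.predictor_gene}\t{e.coefficient:.10g}\t{e.penalty:.10g}"
                f"\t{e.variance_explained:.10g}\t{e.met_target}\n"
            )
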