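"""Synthetic expression data with planted pathway/intermediary structure.

The generator emulates the statistical structure that co-expression
neighbor calling assumes: two latent pathway-activity signals z1 and z2
(a smooth time-course curve or an AR(1) population profile) drive two
disjoint pathway gene sets; *intermediary* genes load on one or both
signals; a large pool of independent noise genes provides the null
background. Knockout conditions abolish one signal: every gene that
loaded on it receives an independent per-gene standard-normal profile in
its place, so the coordinated activity — and with it the correlations
that make the gene discoverable — collapses, while loadings on the
surviving signal are untouched.

Gene construction (before per-gene observation noise of sd
``noise_sd`` and final per-row z-scoring):

* pathway-k gene:        loading · z_k
* shared intermediary:   loading · (z1 + z2) / √2
* one-signal intermediary: loading · z_k
* noise gene:            independent N(0, 1)

Everything is reproducible from the config seed via one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .preprocessing import ExpressionMatrix

__all__ = ["SimConfig", "SyntheticTruth", "simulate", "evaluate_recovery"]

CONDITIONS = ("WT", "KO1", "KO2")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults state the standard benchmark world: a 30-sample experiment,
    two 10-gene pathways, 15 intermediaries shared between both signals,
    5 per-signal intermediaries, 300 independent noise genes, unit
    signal loading and observation noise sd 0.25 on unit-variance
    signals.
    """

    n_samples: int = 30
    n_pathway1: int = 10
    n_pathway2: int = 10
    n_shared: int = 15
    n_p1_only: int = 5
    n_p2_only: int = 5
    n_noise: int = 300
    loading: float = 1.0
    noise_sd: float = 0.25
    signal_model: str = "smooth_curve"
    seed: int = 1

    def __post_init__(self) -> None:
        counts = (self.n_samples, self.n_pathway1, self.n_pathway2, self.n_shared,
                  self.n_p1_only, self.n_p2_only, self.n_noise)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if self.n_pathway1 == 0 or self.n_pathway2 == 0:
            raise ValueError("both pathways need at least one gene")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.signal_model not in ("smooth_curve", "ar1"):
            raise ValueError("signal_model must be 'smooth_curve' or 'ar1'")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")


@dataclass
class SyntheticTruth:
    """Planted gene memberships and the generating config."""

    pathway1_genes: frozenset[str]
    pathway2_genes: frozenset[str]
    planted_shared: frozenset[str]
    planted_p1_only: frozenset[str]
    planted_p2_only: frozenset[str]
    noise_genes: frozenset[str]
    config: SimConfig

    def to_dict(self) -> dict:
        d = {
            name: sorted(getattr(self, name))
            for name in ("pathway1_genes", "pathway2_genes", "planted_shared",
                         "planted_p1_only", "planted_p2_only", "noise_genes")
        }
        d["config"] = asdict(self.config)
        return d

    @property
    def universe(self) -> frozenset[str]:
        return (self.pathway1_genes | self.pathway2_genes | self.planted_shared
                | self.planted_p1_only | self.planted_p2_only | self.noise_genes)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _draw_signal(rng: np.random.Generator, T: int, model: str) -> np.ndarray:
    """One unit-variance latent activity profile of length T."""
    if model == "smooth_curve":
        # random smooth curve over ordered samples: cubic spline through
        # a few random control points (a time-course-like trajectory)
        n_knots = min(6, T)
        knots = np.linspace(0.0, float(T - 1), n_knots)
        values = rng.normal(size=n_knots)
        curve = CubicSpline(knots, values)(np.arange(T, dtype=float))
        if np.ptp(curve) == 0:  # vanishing chance; keep standardization safe
            curve = curve + rng.normal(size=T) * 1e-6
        return _standardize(curve)
    # AR(1) with persistence 0.8 (correlated population samples)
    eps = rng.normal(size=T)
    x = np.empty(T)
    x[0] = eps[0]
    for t in range(1, T):
        x[t] = 0.8 * x[t - 1] + eps[t]
    return _standardize(x)


def _gene_names(config: SimConfig) -> dict[str, list[str]]:
    return {
        "pathway1": [f"path1_{i:03d}" for i in range(config.n_pathway1)],
        "pathway2": [f"path2_{i:03d}" for i in range(config.n_pathway2)],
        "shared": [f"shared_{i:03d}" for i in range(config.n_shared)],
        "p1_only": [f"p1only_{i:03d}" for i in range(config.n_p1_only)],
        "p2_only": [f"p2only_{i:03d}" for i in range(config.n_p2_only)],
        "noise": [f"noise_{i:03d}" for i in range(config.n_noise)],
    }


def simulate(config: SimConfig) -> tuple[dict[str, ExpressionMatrix], SyntheticTruth]:
    """Generate WT / KO1 / KO2 expression matrices plus the planted truth.

    Each condition is an independent sample set: fresh latent signals
    and noise are drawn per condition. In KO1 (KO2) the z1 (z2) signal
    is abolished — replaced per gene by an independent standard-normal
    profile — for every gene that loads on it. All rows are z-scored on
    output.
    """
    rng = np.random.default_rng(config.seed)
    names = _gene_names(config)
    T = config.n_samples
    matrices: dict[str, ExpressionMatrix] = {}
    for condition in CONDITIONS:
        z1 = _draw_signal(rng, T, config.signal_model)
        z2 = _draw_signal(rng, T, config.signal_model)

        def signal(which: int) -> np.ndarray:
            # the abolished signal decoheres into per-gene noise
            if (condition == "KO1" and which == 1) or (
                condition == "KO2" and which == 2
            ):
                return rng.normal(size=T)
            return z1 if which == 1 else z2

        rows: list[np.ndarray] = []
        index: list[str] = []

        def noisy(base: np.ndarray) -> np.ndarray:
            if config.noise_sd > 0:
                return base + rng.normal(scale=config.noise_sd, size=T)
            return base.copy()

        for g in names["pathway1"]:
            rows.append(noisy(config.loading * signal(1)))
            index.append(g)
        for g in names["pathway2"]:
            rows.append(noisy(config.loading * signal(2)))
            index.append(g)
        for g in names["shared"]:
            rows.append(noisy(config.loading * (signal(1) + signal(2)) / np.sqrt(2)))
            index.append(g)
        for g in names["p1_only"]:
            rows.append(noisy(config.loading * signal(1)))
            index.append(g)
        for g in names["p2_only"]:
            rows.append(noisy(config.loading * signal(2)))
            index.append(g)
        for g in names["noise"]:
            rows.append(rng.normal(size=T))
            index.append(g)

        data = np.vstack(rows)
        data = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, ddof=1,
                                                                    keepdims=True)
        frame = pd.DataFrame(data, index=index,
                             columns=[f"t{j:02d}" for j in range(T)])
        matrices[condition] = ExpressionMatrix(frame, condition, stage="zscore")

    truth = SyntheticTruth(
        pathway1_genes=frozenset(names["pathway1"]),
        pathway2_genes=frozenset(names["pathway2"]),
        planted_shared=frozenset(names["shared"]),
        planted_p1_only=frozenset(names["p1_only"]),
        planted_p2_only=frozenset(names["p2_only"]),
        noise_genes=frozenset(names["noise"]),
        config=config,
    )
    return matrices, truth


def evaluate_recovery(
    predicted: set[str], truth_positive: set[str], universe: set[str]
) -> tuple[float, float, float]:
    """Precision, recall and F1 of a predicted gene set against the truth.

    Empty-set conventions: with nothing predicted, precision is 1 when
    there was nothing to find and 0 otherwise; recall of an empty truth
    set is 1.
    """
    predicted, truth_positive, universe = set(predicted), set(truth_positive), set(universe)
    if not predicted <= universe or not truth_positive <= universe:
        raise ValueError("predicted and truth sets must lie inside the universe")
    tp = len(predicted & truth_positive)
    if predicted:
        precision = tp / len(predicted)
    else:
        precision = 1.0 if not truth_positive else 0.0
    recall = tp / len(truth_positive) if truth_positive else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1
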