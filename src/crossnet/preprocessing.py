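"""Expression-matrix I/O, filtering and normalization.

An :class:`ExpressionMatrix` is a genes-by-samples table of continuous
expression values (FPKM-like, normalized counts, or z-scores) for one
biological condition.  The filtering rules implemented here are the ones
commonly applied before co-expression modeling of bulk RNA-Seq:

* ``filter_dynamic_genes`` keeps genes whose expression is both detectable
  (max over samples above an absolute floor) and dynamic (max exceeds a
  fold multiple of the min) in at least one condition.
* ``znormalize`` brings every gene profile to mean 0 / sd 1, the scale on
  which correlation- and regression-based neighbor calling operates.
* ``normalize_counts_q75`` is upper-quartile normalization for raw counts:
  each sample's counts are divided by the 75th percentile of that sample's
  non-zero counts.
* ``filter_min_reads`` keeps genes detected in every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ExpressionLoadError",
    "read_expression",
    "write_expression",
    "filter_dynamic_genes",
    "znormalize",
    "normalize_counts_q75",
    "filter_min_reads",
    "read_gene_sets",
]


class ExpressionLoadError(ValueError):
    """Raised when an expression file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression values for one condition.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns. No
        missing values are allowed; gene ids must be unique.
    condition
        Label of the biological condition (e.g. ``"WT"``, ``"MyD88KO"``).
    stage
        Unit tag: ``"raw"`` (FPKM-like or counts), ``"normalized"``
        (scaled counts) or ``"zscore"``.
    """

    values: pd.DataFrame
    condition: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {', '.join(map(str, dups))}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset preserving this matrix's gene order."""
        keep = set(genes)
        idx = [g for g in self.values.index if g in keep]
        return ExpressionMatrix(self.values.loc[idx].copy(), self.condition, self.stage)

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (pathways or annotation terms)."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_desc, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def items(self):
        return self.sets.items()


def read_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column holds gene ids, the header row holds sample ids.
    Duplicate gene ids, missing cells and non-numeric cells are load
    failures that name the offending gene/sample.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ExpressionLoadError(f"{path}: malformed file: {exc}") from exc
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique()
        raise ExpressionLoadError(
            f"{path}: duplicate gene ids: {', '.join(map(str, dups))}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        gene = numeric.index[bad.any(axis=1)][0]
        sample = numeric.columns[bad.loc[gene]][0]
        raise ExpressionLoadError(
            f"{path}: non-numeric or missing value at gene {gene!r}, sample {sample!r}"
        )
    return ExpressionMatrix(numeric, condition=condition)


def write_expression(matrix: ExpressionMatrix, path: str | Path, header: str | None = None) -> None:
    """Write a matrix as TSV; ``header`` lines (if any) are '#'-prefixed."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene", float_format="%.10g")


def _check_same_universe(matrices: Iterable[ExpressionMatrix]) -> list[ExpressionMatrix]:
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices given")
    universe = mats[0].gene_ids
    for m in mats[1:]:
        if m.gene_ids != universe:
            raise ValueError(
                f"gene universes differ between conditions "
                f"{mats[0].condition!r} and {m.condition!r}"
            )
    return mats


def filter_dynamic_genes(
    matrices: Iterable[ExpressionMatrix], fold: float = 2.0, floor: float = 5.0
) -> set[str]:
    """Genes expressed and dynamic in at least one condition.

    A gene is kept iff in some condition its per-sample maximum exceeds
    ``floor`` and also exceeds ``fold`` times its per-sample minimum.
    The ``max > fold * min`` form is well defined at min = 0, where any
    positive maximum passes the fold test.
    """
    mats = _check_same_universe(matrices)
    kept: set[str] = set()
    for m in mats:
        vmax = m.values.max(axis=1)
        vmin = m.values.min(axis=1)
        ok = (vmax > floor) & (vmax > fold * vmin)
        kept.update(m.values.index[ok])
    return kept


def znormalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every gene profile to mean 0, sample sd 1 (denominator T-1).

    Zero-variance genes cannot be z-scored and must be removed first;
    their presence is an error listing the offending genes.
    """
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    flat = sd[sd == 0].index
    if len(flat):
        raise ValueError(
            f"zero-variance genes cannot be z-normalized: {', '.join(map(str, flat))}"
        )
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, matrix.condition, stage="zscore")


def drop_zero_variance(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove zero-variance genes (with a warning) ahead of z-scoring."""
    sd = matrix.values.std(axis=1, ddof=1)
    flat = sd[sd == 0].index
    if len(flat):
        logger.warning(
            "dropping %d zero-variance genes before z-normalization", len(flat)
        )
        return ExpressionMatrix(
            matrix.values.drop(index=flat), matrix.condition, matrix.stage
        )
    return matrix


def normalize_counts_q75(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Upper-quartile normalization of raw counts.

    Each sample's column is divided by the 75th percentile (linear
    interpolation between order statistics) of that column's non-zero
    counts. Zero counts stay zero.
    """
    values = matrix.values
    if (values < 0).any().any():
        raise ValueError("counts must be nonnegative")
    divisors = {}
    for sample in values.columns:
        col = values[sample].to_numpy()
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts")
        divisors[sample] = float(np.percentile(nonzero, 75))
    out = values.div(pd.Series(divisors), axis=1)
    return ExpressionMatrix(out, matrix.condition, stage="normalized")


def filter_min_reads(matrix: ExpressionMatrix, min_count: int = 1) -> set[str]:
    """Genes with at least ``min_count`` reads in every sample."""
    ok = (matrix.values >= min_count).all(axis=1)
    return set(matrix.values.index[ok])


def read_gene_sets(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read gene sets from a GMT file or a plain one-gene-per-line list.

    A line with three or more tab-separated fields is treated as a GMT
    record (term, description, genes...); a file of single-field lines is
    one unnamed set. Empty sets and duplicate term ids are errors.
    """
    path = Path(path)
    name = name or path.stem
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no gene sets found")
    if any("\t" in ln for ln in lines):
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        for i, ln in enumerate(lines, start=1):
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: GMT line has no genes")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in sets:
                raise ValueError(f"{path}:{i}: duplicate term id {term!r}")
            if not genes:
                raise ValueError(f"{path}:{i}: empty gene set for term {term!r}")
            sets[term] = (desc, frozenset(genes))
        return GeneSetCollection(name, sets)
    genes = [ln.strip() for ln in lines]
    return GeneSetCollection(name, {name: ("", frozenset(genes))})


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain one-gene-per-line list; an empty list is allowed
    (e.g. a knockout condition whose shared-neighbor set is empty)."""
    return {
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    }


def write_gene_list(genes: Iterable[str], path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")


def load_condition_matrices(
    paths: Mapping[str, str | Path]
) -> dict[str, ExpressionMatrix]:
    """Read one matrix per condition from a {condition: path} mapping."""
    return {cond: read_expression(p, cond) for cond, p in paths.items()}
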