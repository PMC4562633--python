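"""Set algebra of neighbor sets across biological conditions.

Comparing the shared-neighbor sets found in wild-type and knockout
samples localizes intermediary genes to the ablated branch: a gene found
in the wild type and one knockout but not the other (e.g. the region
W∩T\\M for MyD88/TRIF knockouts) depends on the branch that was removed.
``venn_regions`` partitions the union of per-condition gene sets into
membership-signature regions for 2 or 3 (or more) conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["ConditionComparison", "venn_regions"]


def region_label(include: Iterable[str], exclude: Iterable[str]) -> str:
    """Canonical label, e.g. ``"W∩T\\M"``: members sorted, then non-members."""
    inc = "∩".join(sorted(include))
    exc = "".join(f"\\{c}" for c in sorted(exclude))
    return inc + exc


@dataclass
class ConditionComparison:
    """Disjoint membership regions over per-condition gene sets."""

    condition_sets: dict[str, frozenset[str]]
    regions: dict[str, frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        conditions = sorted(self.condition_sets)
        union: set[str] = set().union(*self.condition_sets.values())
        regions: dict[str, frozenset[str]] = {}
        for gene in union:
            inc = [c for c in conditions if gene in self.condition_sets[c]]
            exc = [c for c in conditions if gene not in self.condition_sets[c]]
            label = region_label(inc, exc)
            regions.setdefault(label, set()).add(gene)  # type: ignore[arg-type]
        self.regions = {k: frozenset(v) for k, v in regions.items()}
        self._assert_partition(union)

    def _assert_partition(self, union: set[str]) -> None:
        seen: set[str] = set()
        for genes in self.regions.values():
            if genes & seen:
                raise AssertionError("venn regions are not disjoint")
            seen |= genes
        if seen != union:
            raise AssertionError("venn regions do not cover the union")

    def region(self, include: Iterable[str], exclude: Iterable[str] = ()) -> frozenset[str]:
        """Genes in every ``include`` condition and no ``exclude`` condition.

        Unlike raw region lookup this aggregates: conditions named in
        neither argument may or may not contain the gene.
        """
        include, exclude = set(include), set(exclude)
        unknown = (include | exclude) - set(self.condition_sets)
        if unknown:
            raise KeyError(f"unknown conditions: {sorted(unknown)}")
        out = set.intersection(*(set(self.condition_sets[c]) for c in include))
        for c in exclude:
            out -= self.condition_sets[c]
        return frozenset(out)

    def only(self, condition: str) -> frozenset[str]:
        """Genes found in exactly this condition."""
        others = set(self.condition_sets) - {condition}
        return self.region({condition}, others)

    def summary(self) -> list[tuple[str, int]]:
        return sorted((label, len(g)) for label, g in self.regions.items())


def venn_regions(sets: Mapping[str, Iterable[str]]) -> ConditionComparison:
    """Partition per-condition gene sets into membership regions.

    Every gene in the union belongs to exactly one region keyed by its
    canonical membership signature; with k conditions at most 2^k - 1
    regions are non-empty.
    """
    if not sets:
        raise ValueError("no condition sets given")
    return ConditionComparison({c: frozenset(g) for c, g in sets.items()})
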