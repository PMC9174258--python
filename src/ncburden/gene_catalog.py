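"""Merging multiple gene lists into one non-redundant catalog.

Two genes from *different* source catalogs are "the same gene" when either
their names match case-insensitively, or they lie on the same chromosome with
reciprocal overlap at or above a threshold (default 0.5). On a match the
record from the higher-priority catalog (earlier in the input order) wins:
its coordinates and metadata are retained. Genes are never merged within a
single catalog — each input list is taken as internally non-redundant — which
makes the merge idempotent.

Name-only matches across chromosomes are merged but flagged in the report,
since coordinate agreement cannot confirm them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from intervaltree import IntervalTree

from .genome_io import GeneFeature


@dataclass
class GeneCatalog:
    """An ordered, non-redundant gene list with priority-ordered source labels."""

    genes: list[GeneFeature]
    source_priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate gene_id in catalog: {i!r}")
                seen.add(i)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def by_chrom(self) -> dict[str, list[GeneFeature]]:
        out: dict[str, list[GeneFeature]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


@dataclass(frozen=True)
class MergeConflict:
    """A dropped gene and the retained gene it matched."""

    kept_id: str
    kept_source: str
    dropped_id: str
    dropped_source: str
    reason: str  # "id" | "name" | "coords" | "name-only-cross-chrom" | "name-only-low-overlap"


def reciprocal_overlap(a: GeneFeature, b: GeneFeature) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def merge_catalogs(
    catalogs: Sequence[GeneCatalog], reciprocal: float = 0.5
) -> tuple[GeneCatalog, list[MergeConflict]]:
    """Merge catalogs ordered by priority (index 0 wins conflicts).

    Returns the merged catalog and a report listing every resolved conflict.
    Output size equals the sum of input sizes exactly when the report is empty.
    """
    if not catalogs:
        raise ValueError("merge_catalogs needs at least one catalog")

    kept: list[GeneFeature] = []
    kept_origin: list[int] = []  # catalog index each kept gene came from
    by_id: dict[str, int] = {}
    by_name: dict[str, list[int]] = {}
    trees: dict[str, IntervalTree] = {}
    conflicts: list[MergeConflict] = []

    def find_match(g: GeneFeature, cat_idx: int) -> tuple[int, str] | None:
        # id match
        j = by_id.get(g.gene_id)
        if j is not None and kept_origin[j] != cat_idx:
            return j, "id"
        # name match (case-insensitive)
        for j in by_name.get(g.gene_name.lower(), []):
            if kept_origin[j] == cat_idx:
                continue
            other = kept[j]
            if other.chrom != g.chrom:
                return j, "name-only-cross-chrom"
            if reciprocal_overlap(g, other) >= reciprocal:
                return j, "name"
            return j, "name-only-low-overlap"
        # coordinate match
        tree = trees.get(g.chrom)
        if tree is not None:
            best: tuple[float, int] | None = None
            for iv in tree.overlap(g.start, g.end):
                j = iv.data
                if kept_origin[j] == cat_idx:
                    continue
                ro = reciprocal_overlap(g, kept[j])
                if ro >= reciprocal and (best is None or ro > best[0]):
                    best = (ro, j)
            if best is not None:
                return best[1], "coords"
        return None

    for cat_idx, catalog in enumerate(catalogs):
        for g in catalog.genes:
            match = find_match(g, cat_idx)
            if match is not None:
                j, reason = match
                winner = kept[j]
                conflicts.append(
                    MergeConflict(winner.gene_id, winner.source, g.gene_id, g.source, reason)
                )
                continue
            idx = len(kept)
            kept.append(g)
            kept_origin.append(cat_idx)
            by_id[g.gene_id] = idx
            by_name.setdefault(g.gene_name.lower(), []).append(idx)
            trees.setdefault(g.chrom, IntervalTree())[g.start:g.end] = idx

    priority: list[str] = []
    for c in catalogs:
        for label in c.source_priority:
            if label not in priority:
                priority.append(label)
    return GeneCatalog(genes=kept, source_priority=priority), conflicts


def conflicts_frame(conflicts: Sequence[MergeConflict]):
    import pandas as pd

    return pd.DataFrame(
        [
            (c.kept_id, c.kept_source, c.dropped_id, c.dropped_source, c.reason)
            for c in conflicts
        ],
        columns=["kept_id", "kept_source", "dropped_id", "dropped_source", "reason"],
    )
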