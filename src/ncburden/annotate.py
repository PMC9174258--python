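"""Per-gene overlap and aggregation profiles against annotation tracks.

Five aggregation rules are supported, one per annotation shape:

* binary      — does the gene intersect the track at all (>= 1 bp)?
* counted     — how many items (GWAS SNPs; distinct eQTL variant||gene keys)
                fall inside the gene?
* segmented   — per chromatin state, the fraction of the gene covered by
                that state's ranges (union within state).
* scored      — union coverage of the gene by scored peaks, plus a score
                averaged over overlapping peaks weighted by each peak's
                per-peak overlap fraction.
* id_aggregated — for tracks whose ranges carry several (id, score) pairs
                (DNase cell types, TF names): per id, overlap fractions are
                summed across that id's ranges and scores are overlap-weighted
                averaged.

All overlap fractions are relative to gene length, never to peak length.
A gene with no overlapping scored peak reports a *missing* weighted score
(None), not 0 — zero is a legal signal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .gene_catalog import GeneCatalog
from .genome_io import (
    EqtlAssociation,
    GeneFeature,
    GwasSnp,
    MultiIdInterval,
    TrackInterval,
)


@dataclass(frozen=True)
class BinaryEntry:
    overlaps: bool


@dataclass(frozen=True)
class CountedEntry:
    n_items: int
    item_keys: frozenset[str]


@dataclass(frozen=True)
class SegmentedEntry:
    fractions: Mapping[str, float]  # state -> coverage fraction of the gene


@dataclass(frozen=True)
class ScoredEntry:
    coverage_fraction: float
    weighted_score: float | None  # None when no peak overlaps
    max_score: float | None
    n_peaks: int


@dataclass(frozen=True)
class IdEntry:
    summed_overlap_fraction: float
    weighted_score: float
    max_score: float


@dataclass
class OverlapProfile:
    gene_id: str
    entries: dict[str, object] = field(default_factory=dict)


class TrackIndex:
    """Interval index over one track; query results match a naive scan."""

    def __init__(self, intervals: Iterable[TrackInterval | MultiIdInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = iv

    def query(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda x: (x.start, x.end))
        return hits


def _as_index(track) -> TrackIndex:
    return track if isinstance(track, TrackIndex) else TrackIndex(track)


def _union_bp(gene: GeneFeature, intervals: Sequence) -> int:
    """bp of the gene covered by the union of the given intervals."""
    clipped = sorted(
        (max(iv.start, gene.start), min(iv.end, gene.end)) for iv in intervals
    )
    total, cur_s, cur_e = 0, None, None
    for s, e in clipped:
        if e <= s:
            continue
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def binary_overlap(gene: GeneFeature, track) -> bool:
    """True iff the gene shares >= 1 bp with any track interval (half-open)."""
    return bool(_as_index(track).query(gene.chrom, gene.start, gene.end))


def count_items(
    gene: GeneFeature, items: Sequence[GwasSnp | EqtlAssociation]
) -> CountedEntry:
    """Count point items inside the gene; eQTL entries dedup on variation_id||gene_id."""
    keys: set[str] = set()
    n_gwas = 0
    for item in items:
        if not (gene.start <= item.pos0 < gene.end) or item.chrom != gene.chrom:
            continue
        if isinstance(item, EqtlAssociation):
            keys.add(item.key)
        else:
            key = f"{item.chrom}:{item.pos}:{item.trait}"
            if key not in keys:
                keys.add(key)
                n_gwas += 1
    return CountedEntry(n_items=len(keys), item_keys=frozenset(keys))


def segmentation_profile(gene: GeneFeature, segmentation) -> SegmentedEntry:
    """Per-state fraction of the gene covered by that state's ranges (union)."""
    hits = _as_index(segmentation).query(gene.chrom, gene.start, gene.end)
    by_state: dict[str, list] = {}
    for iv in hits:
        by_state.setdefault(iv.label, []).append(iv)
    fractions = {
        state: _union_bp(gene, ivs) / gene.length for state, ivs in by_state.items()
    }
    return SegmentedEntry(fractions=fractions)


def scored_coverage(
    gene: GeneFeature, peaks, min_score: float | None = None
) -> ScoredEntry:
    """Union coverage plus overlap-weighted mean peak score.

    w_i = |gene ∩ peak_i| / gene_length; weighted_score = Σ s_i w_i / Σ w_i.
    Coverage uses the union of overlapping peaks so it cannot exceed 1, while
    score weights are per-peak, so stacked peaks contribute independently.
    ``min_score`` filters peaks by signal value before aggregation.
    """
    hits = _as_index(peaks).query(gene.chrom, gene.start, gene.end)
    if min_score is not None:
        hits = [iv for iv in hits if iv.score is not None and iv.score >= min_score]
    if not hits:
        return ScoredEntry(0.0, None, None, 0)
    weights, scores = [], []
    for iv in hits:
        ov = min(iv.end, gene.end) - max(iv.start, gene.start)
        weights.append(ov / gene.length)
        scores.append(iv.score if iv.score is not None else 0.0)
    wsum = sum(weights)
    weighted = sum(s * w for s, w in zip(scores, weights)) / wsum
    coverage = _union_bp(gene, hits) / gene.length
    return ScoredEntry(coverage, weighted, max(scores), len(hits))


def id_aggregate(gene: GeneFeature, track) -> dict[str, IdEntry]:
    """Aggregate multi-id ranges per identifier.

    Each id's overlap fractions are *summed* over its ranges (a duplicate id
    appearing in several aggregated sets collapses to one measure; the sum may
    exceed 1 for self-overlapping inputs) and its scores are averaged with
    those overlap fractions as weights.
    """
    hits = _as_index(track).query(gene.chrom, gene.start, gene.end)
    acc: dict[str, list[tuple[float, float]]] = {}
    for iv in hits:
        ov = (min(iv.end, gene.end) - max(iv.start, gene.start)) / gene.length
        for id_, score in zip(iv.ids, iv.scores):
            acc.setdefault(id_, []).append((ov, score))
    out: dict[str, IdEntry] = {}
    for id_, pairs in acc.items():
        wsum = sum(w for w, _ in pairs)
        weighted = sum(w * s for w, s in pairs) / wsum
        out[id_] = IdEntry(wsum, weighted, max(s for _, s in pairs))
    return out


@dataclass(frozen=True)
class TrackSpec:
    """A named track plus the aggregation rule to apply to it."""

    name: str
    kind: str  # binary | counted | segmented | scored | id_aggregated
    data: object  # list of intervals / items as appropriate


def profile_gene(gene: GeneFeature, tracks: Sequence[TrackSpec]) -> OverlapProfile:
    profile = OverlapProfile(gene_id=gene.gene_id)
    for spec in tracks:
        if spec.kind == "binary":
            profile.entries[spec.name] = BinaryEntry(binary_overlap(gene, spec.data))
        elif spec.kind == "counted":
            profile.entries[spec.name] = count_items(gene, spec.data)
        elif spec.kind == "segmented":
            profile.entries[spec.name] = segmentation_profile(gene, spec.data)
        elif spec.kind == "scored":
            profile.entries[spec.name] = scored_coverage(gene, spec.data)
        elif spec.kind == "id_aggregated":
            profile.entries[spec.name] = id_aggregate(gene, spec.data)
        else:
            raise ValueError(f"unknown track kind {spec.kind!r}")
    return profile


def profile_catalog(
    catalog: GeneCatalog, tracks: Sequence[TrackSpec]
) -> dict[str, OverlapProfile]:
    """One profile per catalog gene; tracks are indexed once and reused."""
    indexed = [
        TrackSpec(t.name, t.kind, _as_index(t.data) if t.kind != "counted" else t.data)
        for t in tracks
    ]
    return {g.gene_id: profile_gene(g, indexed) for g in catalog.genes}


def profiles_frame(profiles: Mapping[str, OverlapProfile]) -> pd.DataFrame:
    """Wide per-gene table with deterministic (sorted) column order.

    Columns are ``<track>__<field>`` (and ``<track>__<state-or-id>__<field>``
    for segmented / id-aggregated tracks). Missing weighted scores stay NaN.
    """
    rows: list[dict[str, object]] = []
    for gene_id in sorted(profiles):
        profile = profiles[gene_id]
        row: dict[str, object] = {"gene_id": gene_id}
        for name, entry in profile.entries.items():
            if isinstance(entry, BinaryEntry):
                row[f"{name}__overlaps"] = entry.overlaps
            elif isinstance(entry, CountedEntry):
                row[f"{name}__n_items"] = entry.n_items
            elif isinstance(entry, SegmentedEntry):
                for state, frac in entry.fractions.items():
                    row[f"{name}__{state}__coverage"] = frac
            elif isinstance(entry, ScoredEntry):
                row[f"{name}__coverage"] = entry.coverage_fraction
                row[f"{name}__score"] = entry.weighted_score
                row[f"{name}__max_score"] = entry.max_score
            elif isinstance(entry, dict):  # id_aggregated
                for id_, ie in entry.items():
                    row[f"{name}__{id_}__coverage"] = ie.summed_overlap_fraction
                    row[f"{name}__{id_}__score"] = ie.weighted_score
                    row[f"{name}__{id_}__max_score"] = ie.max_score
        rows.append(row)
    df = pd.DataFrame(rows)
    ordered = ["gene_id"] + sorted(c for c in df.columns if c != "gene_id")
    df = df.reindex(columns=ordered)
    for col in df.columns:
        if col.endswith(("__coverage", "__n_items")):
            df[col] = df[col].fillna(0)
        if col.endswith("__overlaps"):
            df[col] = df[col].fillna(False)
    return df
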