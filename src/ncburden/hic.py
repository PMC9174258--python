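"""Hi-C interaction filtering, gene annotation, and ncRNA-to-promoter linkage.

Significance-annotated interaction lists (fixed-size fragment pairs with a
read count and a background-model p-value) are filtered to cis interactions
with p < 0.01, read count >= 10 and fragment-start distance strictly between
5 kb and 20 Mb. Fragment ends are annotated with genes at >= 10% overlap of
the *gene's* length (genes are typically smaller than the fragments). Links
between candidate non-coding genes and protein-coding genes are formed when
the two ends of one interaction carry, respectively, a candidate ncRNA and a
coding gene — either via the coding gene body (the same 10% rule) or via its
promoter window (TSS +/- 2 kb by default, 10% of the window length); both
modes are emitted and labelled. Two libraries are intersected by exact
unordered fragment-pair identity, and per-gene support fractions are
compared against an all-genes background via the binomial enrichment model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .enrich import EnrichmentResult, enrichment
from .gene_catalog import GeneCatalog
from .genome_io import GeneFeature, HiCInteractionRecord


@dataclass
class FilteredInteraction:
    record: HiCInteractionRecord
    distance: int
    cis: bool = True
    genes_end1: list[str] = field(default_factory=list)
    genes_end2: list[str] = field(default_factory=list)

    @property
    def pair_key(self) -> frozenset[tuple[str, int, int]]:
        """Unordered fragment-pair identity used for library intersection."""
        return frozenset([self.record.end_a, self.record.end_b])


@dataclass(frozen=True)
class GeneLink:
    ncrna_id: str
    coding_gene_id: str
    via_promoter: bool
    library_support: frozenset[str]
    n_interactions: int  # supporting interactions across claimed libraries


def filter_interactions(
    records: Iterable[HiCInteractionRecord],
    p_max: float = 0.01,
    min_reads: int = 10,
    min_dist: int = 5_000,
    max_dist: int = 20_000_000,
) -> list[FilteredInteraction]:
    """Keep cis interactions with p < p_max, reads >= min_reads and
    min_dist < |start2 - start1| < max_dist (both distance bounds strict)."""
    out = []
    for r in records:
        if r.chrom1 != r.chrom2:
            continue
        dist = abs(r.start2 - r.start1)
        if r.p_value < p_max and r.read_count >= min_reads and min_dist < dist < max_dist:
            out.append(FilteredInteraction(record=r, distance=dist))
    return out


def _gene_tree(catalog: GeneCatalog) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in catalog.genes:
        trees.setdefault(g.chrom, IntervalTree())[g.start:g.end] = g
    return trees


def _genes_at(
    trees: Mapping[str, IntervalTree],
    frag: tuple[str, int, int],
    min_overlap: float,
) -> list[str]:
    chrom, start, end = frag
    tree = trees.get(chrom)
    if tree is None:
        return []
    out = []
    for iv in tree.overlap(start, end):
        g: GeneFeature = iv.data
        inter = min(g.end, end) - max(g.start, start)
        if inter / g.length >= min_overlap:
            out.append(g.gene_id)
    return sorted(out)


def annotate_ends(
    interactions: Sequence[FilteredInteraction],
    catalog: GeneCatalog,
    min_gene_overlap: float = 0.10,
) -> list[FilteredInteraction]:
    """Attach gene lists to both fragment ends.

    Gene g annotates fragment f iff |g ∩ f| / length(g) >= min_gene_overlap.
    """
    trees = _gene_tree(catalog)
    out = []
    for fi in interactions:
        out.append(
            replace(
                fi,
                genes_end1=_genes_at(trees, fi.record.end_a, min_gene_overlap),
                genes_end2=_genes_at(trees, fi.record.end_b, min_gene_overlap),
            )
        )
    return out


def _promoter_interval(g: GeneFeature, window: int) -> tuple[str, int, int]:
    if g.strand == ".":
        warnings.warn(f"coding gene {g.gene_id} has no strand; taking TSS = start")
    tss = g.tss()
    return (g.chrom, max(0, tss - window), tss + window)


def link_ncrna_coding(
    interactions: Sequence[FilteredInteraction],
    ncrna_ids: set[str],
    coding_catalog: GeneCatalog,
    promoter_window: int = 2_000,
    min_overlap: float = 0.10,
    library: str = "lib1",
) -> list[GeneLink]:
    """Link ncRNAs to coding genes that share a filtered interaction.

    One end must carry an ncRNA from ``ncrna_ids`` (gene-body annotation);
    the other end must carry a coding gene — by gene body (>= 10% of the gene)
    or by its promoter window (>= 10% of the window length). Both linkage
    modes are reported, distinguished by ``via_promoter``.
    """
    body_trees = _gene_tree(coding_catalog)
    promoter_genes = []
    for g in coding_catalog.genes:
        chrom, p_start, p_end = _promoter_interval(g, promoter_window)
        promoter_genes.append(
            GeneFeature(g.gene_id, g.gene_name, chrom, p_start, p_end,
                        g.strand, g.biotype, g.source)
        )
    prom_trees = _gene_tree(
        GeneCatalog(genes=promoter_genes,
                    source_priority=list(coding_catalog.source_priority))
    )

    hits: dict[tuple[str, str, bool], int] = {}
    for fi in interactions:
        ends = [
            (fi.genes_end1, fi.record.end_a, fi.genes_end2, fi.record.end_b),
            (fi.genes_end2, fi.record.end_b, fi.genes_end1, fi.record.end_a),
        ]
        seen_here: set[tuple[str, str, bool]] = set()
        for nc_genes, _nc_frag, _other_genes, other_frag in ends:
            ncs = [g for g in nc_genes if g in ncrna_ids]
            if not ncs:
                continue
            body = _genes_at(body_trees, other_frag, min_overlap)
            prom = _genes_at(prom_trees, other_frag, min_overlap)
            for nc in ncs:
                for cg in body:
                    seen_here.add((nc, cg, False))
                for cg in prom:
                    seen_here.add((nc, cg, True))
        for key in seen_here:
            hits[key] = hits.get(key, 0) + 1

    return [
        GeneLink(nc, cg, via_prom, frozenset([library]), n)
        for (nc, cg, via_prom), n in sorted(hits.items())
    ]


def intersect_libraries(
    interactions1: Sequence[FilteredInteraction],
    links1: Sequence[GeneLink],
    interactions2: Sequence[FilteredInteraction],
    links2: Sequence[GeneLink],
) -> tuple[list[FilteredInteraction], list[GeneLink]]:
    """Common interactions (exact unordered fragment-pair equality) and
    merged links with per-library support recorded."""
    keys2 = {fi.pair_key for fi in interactions2}
    common = [fi for fi in interactions1 if fi.pair_key in keys2]

    merged: dict[tuple[str, str, bool], GeneLink] = {}
    for links in (links1, links2):
        for ln in links:
            key = (ln.ncrna_id, ln.coding_gene_id, ln.via_promoter)
            if key in merged:
                prev = merged[key]
                merged[key] = GeneLink(
                    ln.ncrna_id, ln.coding_gene_id, ln.via_promoter,
                    prev.library_support | ln.library_support,
                    prev.n_interactions + ln.n_interactions,
                )
            else:
                merged[key] = ln
    return common, [merged[k] for k in sorted(merged)]


@dataclass(frozen=True)
class SupportSummary:
    n_supported_candidates: int
    n_candidates: int
    fraction: float
    n_supported_all: int
    n_all: int
    fraction_all: float
    enrichment: EnrichmentResult | None


def support_fraction(
    links: Sequence[GeneLink],
    candidate_ids: set[str],
    all_gene_ids: Sequence[str],
    require_dual: bool = True,
) -> SupportSummary:
    """Fraction of candidates with >= 1 qualifying link, vs all genes.

    ``require_dual`` demands support in both libraries. The candidate-vs-all
    comparison is scored with the binomial enrichment model (Y = supported
    candidates, S = |candidates|, A = supported genes overall, N = all genes).
    """
    def qualifies(ln: GeneLink) -> bool:
        return len(ln.library_support) >= 2 if require_dual else True

    supported = {ln.ncrna_id for ln in links if qualifies(ln)}
    y = len(supported & candidate_ids)
    s = len(candidate_ids)
    a = len(supported & set(all_gene_ids))
    n = len(all_gene_ids)
    enr = enrichment(y, s, a, n, trait_name="hic_support") if a > 0 and s > 0 else None
    return SupportSummary(
        y, s, y / s if s else 0.0, a, n, a / n if n else 0.0, enr
    )


def links_frame(links: Sequence[GeneLink]):
    import pandas as pd

    return pd.DataFrame(
        [
            (ln.ncrna_id, ln.coding_gene_id, ln.via_promoter,
             ",".join(sorted(ln.library_support)), ln.n_interactions)
            for ln in links
        ],
        columns=["ncrna_id", "coding_gene_id", "via_promoter", "library_support",
                 "n_interactions"],
    )
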