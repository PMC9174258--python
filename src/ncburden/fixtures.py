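"""Deterministic synthetic inputs with known planted structure.

The generator emulates the study design the pipeline is built for at desk
scale: a case cohort and pooled control cohorts of somatic SNV calls over a
small synthetic genome (two 10 Mb chromosomes), a non-coding gene catalog
with a handful of *spiked* genes mutated far above background in cases only,
regulatory annotation tracks in every supported shape, and two Hi-C
interaction libraries with planted ncRNA-to-coding-promoter contacts.

Default study conditions: 150 case and 600 control samples (three control
cohorts of 200), 205 genes of 1-10 kb, per-sample background mutation
probability 0.02 per gene, and 5 spiked genes with case mutation probability
0.5. A planted GWAS trait marks exactly the spiked genes so downstream
enrichment of the candidate set is known to be real.

Everything derives from a single seed; the same seed yields byte-identical
files. Planted truth is written alongside the data as a JSON manifest so
tests can assert recovery without re-deriving it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import genome_io
from .gene_catalog import GeneCatalog
from .genome_io import (
    GeneFeature,
    GwasSnp,
    EqtlAssociation,
    HiCInteractionRecord,
    MultiIdInterval,
    MutationRecord,
    TrackInterval,
)

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    """All knobs of the generator; defaults are the standard study conditions."""

    seed: int = 17
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 10_000_000, "chrS2": 10_000_000}
    )
    case_label: str = "breast"
    ctrl_labels: tuple[str, ...] = ("ovary", "lung", "skin")
    n_case: int = 150
    n_ctrl: int = 600
    n_genes: int = 205
    gene_length_range: tuple[int, int] = (1_000, 10_000)
    background_rate: float = 0.02
    spike_genes: tuple[tuple[int, float], ...] = (
        (0, 0.5), (1, 0.5), (2, 0.5), (3, 0.5), (4, 0.5)
    )
    # tracks
    n_peaks: int = 300
    peak_length_range: tuple[int, int] = (500, 3_000)
    score_range: tuple[float, float] = (1.0, 20.0)
    states: tuple[str, ...] = ("Promoter", "Enhancer", "Transcribed", "Repressed", "Quiescent")
    n_gwas_background: int = 60
    n_eqtl: int = 80
    dnase_ids: tuple[str, ...] = ("MCF-7", "T-47D", "HMEC")
    # coding genes / Hi-C
    n_coding: int = 40
    coding_length: int = 20_000
    hic_bin_size: int = 5_000
    n_hic_noise: int = 60
    n_planted_links: int = 4


def spike_demo(seed: int = 17) -> FixtureSpec:
    """The standard spiked-cohort preset."""
    return FixtureSpec(seed=seed)


def make_genes(spec: FixtureSpec) -> GeneCatalog:
    """Non-overlapping ncRNA genes laid out along the synthetic chromosomes."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    chroms = list(spec.chrom_sizes)
    genes = []
    per_chrom = -(-spec.n_genes // len(chroms))  # ceil
    i = 0
    biotypes = ("lncRNA_intergenic", "pseudogene", "lncRNA_divergent", "antisense")
    for chrom in chroms:
        pos = 50_000
        for _ in range(per_chrom):
            if i >= spec.n_genes:
                break
            length = int(rng.integers(*spec.gene_length_range))
            gap = int(rng.integers(20_000, 60_000))
            start = pos + gap
            end = start + length
            if end > spec.chrom_sizes[chrom] - 50_000:
                break
            genes.append(
                GeneFeature(
                    f"NC{i:04d}", f"NC{i:04d}", chrom, start, end,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=str(rng.choice(biotypes)), source="synthetic",
                )
            )
            pos = end
            i += 1
    if i < spec.n_genes:
        raise ValueError("chromosomes too small for requested gene count")
    return GeneCatalog(genes=genes, source_priority=["synthetic"])


def make_coding(spec: FixtureSpec) -> GeneCatalog:
    """Stranded protein-coding genes for promoter linkage, clear of bin edges."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    chroms = list(spec.chrom_sizes)
    genes = []
    for i in range(spec.n_coding):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(100_000, spec.chrom_sizes[chrom] - 200_000))
        genes.append(
            GeneFeature(
                f"PC{i:03d}", f"PC{i:03d}", chrom, start, start + spec.coding_length,
                strand="+" if rng.random() < 0.5 else "-",
                biotype="protein_coding", source="synthetic",
            )
        )
    return GeneCatalog(genes=genes, source_priority=["synthetic"])


def make_cohort(
    spec: FixtureSpec, catalog: GeneCatalog
) -> tuple[list[MutationRecord], dict[str, str], dict]:
    """Simulate per-sample mutation incidence and SNV placement.

    Every (gene, sample) pair is mutated independently with the background
    probability, except spiked genes in case samples which use their spike
    rate; a mutated sample receives >= 1 SNV uniformly inside the gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    design: dict[str, str] = {}
    samples = []
    for i in range(spec.n_case):
        sid = f"CASE{i:04d}"
        design[sid] = spec.case_label
        samples.append(sid)
    for i in range(spec.n_ctrl):
        sid = f"CTRL{i:04d}"
        design[sid] = spec.ctrl_labels[i % len(spec.ctrl_labels)]
        samples.append(sid)

    spike_rate = dict(spec.spike_genes)
    muts: list[MutationRecord] = []
    for gi, gene in enumerate(catalog.genes):
        for sid in samples:
            is_case = design[sid] == spec.case_label
            rate = spike_rate[gi] if (gi in spike_rate and is_case) else spec.background_rate
            if rng.random() >= rate:
                continue
            n_snv = 1 + int(rng.poisson(0.3))
            for _ in range(n_snv):
                pos0 = int(rng.integers(gene.start, gene.end))
                ref, alt = rng.choice(list(_BASES), size=2, replace=False)
                muts.append(
                    MutationRecord(sid, design[sid], gene.chrom, pos0 + 1, str(ref), str(alt))
                )
    truth = {
        "spiked_gene_ids": [catalog.genes[gi].gene_id for gi, _ in spec.spike_genes],
        "background_rate": spec.background_rate,
        "spike_rates": {catalog.genes[gi].gene_id: r for gi, r in spec.spike_genes},
        "n_case": spec.n_case,
        "n_ctrl": spec.n_ctrl,
    }
    return muts, design, truth


def make_tracks(spec: FixtureSpec, catalog: GeneCatalog) -> tuple[dict, dict]:
    """Annotation tracks of every shape, with the GWAS trait planted in the
    spiked genes. Returns ({track name: data}, truth manifest)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    chroms = list(spec.chrom_sizes)
    spiked = [catalog.genes[gi] for gi, _ in spec.spike_genes]

    def random_interval(length_range):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*length_range))
        start = int(rng.integers(0, spec.chrom_sizes[chrom] - length))
        return chrom, start, start + length

    peaks = []
    for _ in range(spec.n_peaks):
        chrom, s, e = random_interval(spec.peak_length_range)
        peaks.append(TrackInterval(chrom, s, e, score=float(rng.uniform(*spec.score_range))))
    # guarantee every spiked gene carries a high-signal peak
    for g in spiked:
        peaks.append(TrackInterval(g.chrom, g.start, g.end, score=float(rng.uniform(15, 20))))

    segmentation = []
    for chrom, size in spec.chrom_sizes.items():
        pos = 0
        while pos < size:
            seg_len = int(rng.integers(50_000, 200_000))
            end = min(pos + seg_len, size)
            segmentation.append(
                TrackInterval(chrom, pos, end, label=str(rng.choice(spec.states)))
            )
            pos = end

    gwas = []
    for g in spiked:  # planted trait: >= 2 genome-wide-significant SNPs per spiked gene
        for _ in range(2 + int(rng.integers(0, 3))):
            pos0 = int(rng.integers(g.start, g.end))
            gwas.append(GwasSnp(g.chrom, pos0 + 1, "trait_bc", 10.0 ** -rng.uniform(9, 15), "catA"))
    for _ in range(spec.n_gwas_background):
        chrom, s, _ = random_interval((1, 2))
        # half pass the genome-wide threshold, half do not
        p = 10.0 ** -rng.uniform(9, 12) if rng.random() < 0.5 else 10.0 ** -rng.uniform(3, 7)
        gwas.append(GwasSnp(chrom, s + 1, "trait_other", p, "catB"))

    eqtl = []
    for i in range(spec.n_eqtl):
        gene = catalog.genes[int(rng.integers(len(catalog.genes)))]
        pos0 = int(rng.integers(gene.start, gene.end))
        eqtl.append(
            EqtlAssociation(gene.chrom, pos0 + 1, f"var{i:04d}", f"EG{int(rng.integers(30)):03d}")
        )

    dnase = []
    for _ in range(spec.n_peaks // 2):
        chrom, s, e = random_interval(spec.peak_length_range)
        n_ids = 1 + int(rng.integers(0, len(spec.dnase_ids)))
        idx = rng.choice(len(spec.dnase_ids), size=n_ids, replace=False)
        ids = tuple(spec.dnase_ids[j] for j in sorted(idx))
        scores = tuple(float(rng.uniform(*spec.score_range)) for _ in ids)
        dnase.append(MultiIdInterval(chrom, s, e, ids, scores))

    tracks = {
        "h3k27ac": peaks,
        "chromhmm": segmentation,
        "gwas": gwas,
        "eqtl": eqtl,
        "dnase": dnase,
    }
    truth = {
        "gwas_trait_gene_ids": [g.gene_id for g in spiked],
        "high_peak_gene_ids": [g.gene_id for g in spiked],
    }
    return tracks, truth


def make_interactions(
    spec: FixtureSpec, catalog: GeneCatalog, coding: GeneCatalog
) -> tuple[list[HiCInteractionRecord], list[HiCInteractionRecord], dict]:
    """Two Hi-C libraries with planted dual-library ncRNA-promoter links
    plus noise interactions that fail the significance filters."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5]))
    b = spec.hic_bin_size

    def bin_of(chrom: str, pos: int) -> tuple[str, int, int]:
        start = (pos // b) * b
        return chrom, start, start + b

    planted = []
    lib1: list[HiCInteractionRecord] = []
    lib2: list[HiCInteractionRecord] = []
    spiked = [catalog.genes[gi] for gi, _ in spec.spike_genes]
    coding_by_chrom: dict[str, list[GeneFeature]] = {}
    for g in coding.genes:
        coding_by_chrom.setdefault(g.chrom, []).append(g)
    for g in spiked[: spec.n_planted_links]:
        partners = [
            c for c in coding_by_chrom.get(g.chrom, [])
            if 10 * b < abs(c.tss() - g.start) < 15_000_000
        ]
        if not partners:
            continue
        partner = partners[int(rng.integers(len(partners)))]
        frag1 = bin_of(g.chrom, (g.start + g.end) // 2)
        frag2 = bin_of(partner.chrom, partner.tss())
        rec = HiCInteractionRecord(
            frag1[0], frag1[1], frag1[2], frag2[0], frag2[1], frag2[2],
            read_count=int(rng.integers(15, 60)), p_value=float(rng.uniform(1e-6, 5e-3)),
        )
        lib1.append(rec)
        lib2.append(
            HiCInteractionRecord(
                rec.chrom1, rec.start1, rec.end1, rec.chrom2, rec.start2, rec.end2,
                read_count=int(rng.integers(15, 60)), p_value=float(rng.uniform(1e-6, 5e-3)),
            )
        )
        planted.append({"ncrna_id": g.gene_id, "coding_gene_id": partner.gene_id})

    chroms = list(spec.chrom_sizes)
    for lib in (lib1, lib2):
        for _ in range(spec.n_hic_noise):
            chrom = chroms[int(rng.integers(len(chroms)))]
            s1 = (int(rng.integers(0, spec.chrom_sizes[chrom] - b)) // b) * b
            offset = int(rng.integers(2, 1000)) * b
            s2 = min(s1 + offset, ((spec.chrom_sizes[chrom] - b) // b) * b)
            fail = rng.random()
            if fail < 0.4:  # fails on p-value
                p, reads = float(rng.uniform(0.02, 0.9)), int(rng.integers(10, 40))
            elif fail < 0.7:  # fails on read count
                p, reads = float(rng.uniform(1e-5, 5e-3)), int(rng.integers(0, 10))
            else:  # passes filters but links nothing in particular
                p, reads = float(rng.uniform(1e-5, 5e-3)), int(rng.integers(10, 40))
            lib.append(HiCInteractionRecord(chrom, s1, s1 + b, chrom, s2, s2 + b, reads, p))
    truth = {"planted_links": planted, "bin_size": b}
    return lib1, lib2, truth


def generate(spec: FixtureSpec, outdir: str | os.PathLike) -> dict:
    """Write the full fixture set to ``outdir``; returns the truth manifest.

    Files: genes.bed, coding.bed, mutations.tsv, design.tsv, h3k27ac.narrowPeak,
    chromhmm.bed, gwas.tsv, eqtl.tsv, dnase.bed, hic_lib1.tsv, hic_lib2.tsv,
    manifest.json. Every file round-trips through its genome_io reader.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = make_genes(spec)
    coding = make_coding(spec)
    muts, design, cohort_truth = make_cohort(spec, catalog)
    tracks, track_truth = make_tracks(spec, catalog)
    lib1, lib2, hic_truth = make_interactions(spec, catalog, coding)

    genome_io.write_genes(catalog, outdir / "genes.bed")
    genome_io.write_genes(coding, outdir / "coding.bed")
    genome_io.write_mutations(muts, outdir / "mutations.tsv")
    genome_io.write_design(design, outdir / "design.tsv")
    _write_narrowpeak(tracks["h3k27ac"], outdir / "h3k27ac.narrowPeak")
    _write_bed4(tracks["chromhmm"], outdir / "chromhmm.bed")
    genome_io.write_gwas(tracks["gwas"], outdir / "gwas.tsv")
    genome_io.write_eqtl(tracks["eqtl"], outdir / "eqtl.tsv")
    _write_multi_id(tracks["dnase"], outdir / "dnase.bed")
    genome_io.write_interactions(lib1, outdir / "hic_lib1.tsv")
    genome_io.write_interactions(lib2, outdir / "hic_lib2.tsv")

    manifest = {
        "spec": {**asdict(spec), "chrom_sizes": dict(spec.chrom_sizes)},
        "cohort": cohort_truth,
        "tracks": track_truth,
        "hic": hic_truth,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
    return manifest


def _write_narrowpeak(peaks, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t0\t.\t{p.score:.6g}\t-1\t-1\t-1\n"
            )


def _write_bed4(intervals, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def _write_multi_id(intervals, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            ids = ",".join(iv.ids)
            scores = ",".join(f"{s:.6g}" for s in iv.scores)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ids}\t{scores}\n")
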