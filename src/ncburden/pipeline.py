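"""End-to-end orchestration: significance calls -> profiles -> enrichment -> Hi-C links.

The resolved configuration and seed are written next to the outputs so a
rerun with the same config and inputs reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import annotate, enrich, genome_io, hic, mutsig

log = logging.getLogger("ncburden")


@dataclass
class RunConfig:
    """All thresholds of the pipeline with their standard defaults."""

    mutations: str = "mutations.tsv"
    design: str = "design.tsv"
    genes: str = "genes.bed"
    coding: str = "coding.bed"
    case_label: str = "breast"
    # significance
    null_mode: str = "exact"          # "exact" | "mc"
    n_perm: int = 1_000_000
    alpha: float = 0.01
    seed: int = 17
    # annotation / enrichment
    h3k27ac: str = "h3k27ac.narrowPeak"
    chromhmm: str = "chromhmm.bed"
    gwas: str = "gwas.tsv"
    eqtl: str = "eqtl.tsv"
    dnase: str = "dnase.bed"
    gwas_p: float = 1e-8
    atleast_sweep: tuple[int, ...] = (1, 2, 3, 4, 5)
    minscore_sweep: tuple[float, ...] = (0.0, 5.0, 10.0)
    # Hi-C
    hic_lib1: str = "hic_lib1.tsv"
    hic_lib2: str = "hic_lib2.tsv"
    hic_p: float = 0.01
    hic_min_reads: int = 10
    hic_min_dist: int = 5_000
    hic_max_dist: int = 20_000_000
    gene_overlap: float = 0.10
    promoter_window: int = 2_000

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("atleast_sweep", "minscore_sweep"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolve_paths(self, indir: str | Path) -> "RunConfig":
        indir = Path(indir)
        updates = {}
        for key in ("mutations", "design", "genes", "coding", "h3k27ac", "chromhmm",
                    "gwas", "eqtl", "dnase", "hic_lib1", "hic_lib2"):
            updates[key] = str(indir / getattr(self, key))
        return dataclasses.replace(self, **updates)


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in dependency order; returns a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in (cfg.mutations, cfg.design, cfg.genes):
        if not Path(path).exists():
            raise FileNotFoundError(path)

    # --- stage: inputs
    muts, rej = genome_io.read_mutations(cfg.mutations)
    design = mutsig.CohortDesign(cfg.case_label, genome_io.read_design(cfg.design))
    catalog = genome_io.read_genes(cfg.genes, dialect="bed")
    log.info("inputs: %d SNVs (%d rejected), %d samples (%d case), %d genes",
             len(muts), rej.n_rejected, design.n_total, design.n_case, len(catalog))

    # --- stage: significance
    incidence = mutsig.build_incidence(muts, catalog, design)
    fishers = mutsig.fisher_results(incidence, design)
    nulls = mutsig.compute_nulls(incidence, design, mode=cfg.null_mode,
                                 n_perm=cfg.n_perm, seed=cfg.seed)
    calls = mutsig.call_significant(fishers, nulls, alpha=cfg.alpha)
    n_sig = sum(c.is_significant for c in calls)
    log.info("significance: %d of %d genes significant at alpha=%g",
             n_sig, len(calls), cfg.alpha)
    sets = mutsig.rank_sets(calls) if 0 < n_sig <= len(calls) // 4 else None
    genome_io.write_table(mutsig.calls_frame(fishers, calls, sets), outdir / "calls.tsv")

    # --- stage: annotation profiles
    gwas_snps = genome_io.pool_gwas([genome_io.read_gwas(cfg.gwas)], cfg.gwas_p)
    tracks = [
        annotate.TrackSpec("h3k27ac", "scored", genome_io.read_track(cfg.h3k27ac, "narrowPeak")),
        annotate.TrackSpec("chromhmm", "segmented", genome_io.read_segmentation(cfg.chromhmm)),
        annotate.TrackSpec("gwas", "counted", gwas_snps),
        annotate.TrackSpec("eqtl", "counted", genome_io.read_eqtl(cfg.eqtl)),
        annotate.TrackSpec("dnase", "id_aggregated", genome_io.read_multi_id_track(cfg.dnase)),
    ]
    profiles = annotate.profile_catalog(catalog, tracks)
    genome_io.write_table(annotate.profiles_frame(profiles), outdir / "profiles.tsv")
    log.info("annotation: %d profiles x %d tracks (%d GWAS SNPs retained)",
             len(profiles), len(tracks), len(gwas_snps))

    # --- stage: enrichment sweeps
    enrichment_table = None
    if sets is not None:
        sweeps = [
            enrich.TraitSweep("gwas", "atleast", tuple(cfg.atleast_sweep)),
            enrich.TraitSweep("eqtl", "atleast", (1,)),
            enrich.TraitSweep("h3k27ac", "minscore", tuple(cfg.minscore_sweep)),
            enrich.TraitSweep("dnase", "minscore", tuple(cfg.minscore_sweep)),
            enrich.TraitSweep("h3k27ac", "overlap"),
        ]
        enrichment_table = enrich.compare_sets(sets, profiles, sweeps)
        genome_io.write_table(enrichment_table, outdir / "enrichment.tsv")
        for _, row in enrichment_table[enrichment_table["set"] == "candidate"].iterrows():
            log.info("enrichment: candidate %s(%s=%s): Y=%d S=%d A=%d N=%d ratio=%.3f",
                     row["trait"], row["sweep_kind"], row["sweep_value"],
                     row["Y"], row["S"], row["A"], row["N"], row["ratio"])

    # --- stage: Hi-C linkage
    summary_hic = None
    lib1_path, lib2_path = Path(cfg.hic_lib1), Path(cfg.hic_lib2)
    if lib1_path.exists() and lib2_path.exists() and sets is not None:
        coding = genome_io.read_genes(cfg.coding, dialect="bed")
        candidate_ids = set(sets.candidate_set)
        all_ids = catalog.gene_ids()
        libs = {}
        for label, path in (("lib1", lib1_path), ("lib2", lib2_path)):
            recs, _rej = genome_io.read_interactions(path)
            kept = hic.filter_interactions(
                recs, cfg.hic_p, cfg.hic_min_reads, cfg.hic_min_dist, cfg.hic_max_dist)
            kept = hic.annotate_ends(kept, catalog, cfg.gene_overlap)
            links = hic.link_ncrna_coding(
                kept, set(all_ids), coding, cfg.promoter_window, cfg.gene_overlap, label)
            libs[label] = (kept, links)
            log.info("hic %s: %d of %d interactions kept, %d links", label,
                     len(kept), len(recs), len(links))
        common, merged_links = hic.intersect_libraries(*libs["lib1"], *libs["lib2"])
        support = hic.support_fraction(merged_links, candidate_ids, all_ids, require_dual=True)
        genome_io.write_table(hic.links_frame(merged_links), outdir / "links.tsv")
        log.info("hic: %d common interactions; %d/%d candidates supported (%.1f%%)",
                 len(common), support.n_supported_candidates, support.n_candidates,
                 100 * support.fraction)
        summary_hic = {
            "n_common_interactions": len(common),
            "n_links": len(merged_links),
            "support_fraction": support.fraction,
            "support_fraction_all": support.fraction_all,
            "support_ratio": support.enrichment.ratio if support.enrichment else None,
        }

    summary = {
        "n_mutations": len(muts),
        "n_rejected": rej.n_rejected,
        "n_genes": len(catalog),
        "n_significant": n_sig,
        "candidate_set": list(sets.candidate_set) if sets else [],
        "hic": summary_hic,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    resolved = {k: list(v) if isinstance(v, tuple) else v
                for k, v in dataclasses.asdict(cfg).items()}
    with open(outdir / "run_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    return summary
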