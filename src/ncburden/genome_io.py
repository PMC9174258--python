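"""Readers and writers for the external file formats of the pipeline.

Internal coordinate convention is uniformly 0-based half-open ``[start, end)``.
One-based inputs (GTF gene rows, mutation positions, SNP positions) are
converted at the parse boundary and converted back on write, so a single
convention holds everywhere downstream.

Chromosome names are compared as exact strings; no ``chr``-prefix
harmonization is attempted (callers must supply consistently named inputs).

Parsers never silently drop records: every record either becomes an object
or is counted in a :class:`RejectionReport`, so
``records_in == records_out + rejections`` always holds.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

_BASES = frozenset("ACGT")

MUTATION_COLUMNS = ["sample_id", "cancer_type", "chrom", "pos", "ref", "alt"]
INTERACTION_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "read_count", "p_value",
]


class ParseError(ValueError):
    """A malformed line that cannot be interpreted at all (with line number)."""


@dataclass
class RejectionReport:
    """Per-file account of records that parsed but were excluded by policy."""

    rejections: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line_no: int, reason: str) -> None:
        self.rejections.append((line_no, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.rejections:
            out[reason] = out.get(reason, 0) + 1
        return out


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant attributed to a sample.

    ``pos`` is 1-based as in VCF; ``pos0`` gives the internal 0-based index.
    """

    sample_id: str
    cancer_type: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("MutationRecord is SNV-only: ref/alt must be single bases")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class GeneFeature:
    """A genomic interval used as the unit of testing (gene-level)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."
    biotype: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def tss(self) -> int:
        """Strand-aware transcription start (0-based position)."""
        if self.strand == "-":
            return self.end - 1
        return self.start


@dataclass(frozen=True)
class TrackInterval:
    """An annotation interval with optional score and label."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end ({self.end}) must exceed start ({self.start})")
        if self.score is not None and self.score < 0:
            raise ValueError(f"interval score must be non-negative, got {self.score}")


@dataclass(frozen=True)
class MultiIdInterval:
    """An interval annotated with one or more (id, score) pairs.

    Used for tracks where each range is attributed to several identifiers,
    e.g. DNase accessibility cell types or transcription-factor names.
    """

    chrom: str
    start: int
    end: int
    ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")
        if len(self.ids) != len(self.scores) or not self.ids:
            raise ValueError("ids and scores must be non-empty and of equal length")


@dataclass(frozen=True)
class GwasSnp:
    chrom: str
    pos: int  # 1-based
    trait: str
    p_value: float
    source_catalog: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"GWAS p_value must be in (0,1], got {self.p_value}")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class EqtlAssociation:
    chrom: str
    pos: int  # 1-based
    variation_id: str
    gene_id: str

    @property
    def key(self) -> str:
        return self.variation_id + self.gene_id

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class HiCInteractionRecord:
    """A pair of fixed-size genomic fragments with contact support.

    Fragment coordinates are 0-based half-open; ``p_value`` comes from an
    upstream background model and is consumed as given.
    """

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    read_count: int
    p_value: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError(f"read_count must be non-negative, got {self.read_count}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")

    @property
    def end_a(self) -> tuple[str, int, int]:
        return (self.chrom1, self.start1, self.end1)

    @property
    def end_b(self) -> tuple[str, int, int]:
        return (self.chrom2, self.start2, self.end2)


# ---------------------------------------------------------------------------
# mutation input

def read_mutations(
    path: str | os.PathLike, format: str = "tsv"
) -> tuple[list[MutationRecord], RejectionReport]:
    """Read somatic mutation calls, keeping SNVs only.

    Insertions, deletions and multi-nucleotide variants are counted in the
    rejection report and not returned. Malformed lines raise
    :class:`ParseError` with the offending line number.
    """
    if format == "tsv":
        return _read_mutations_tsv(path)
    if format == "vcf-lite":
        return _read_mutations_vcf_lite(path)
    raise ValueError(f"unknown mutation format {format!r}")


def _classify_alleles(ref: str, alt: str) -> str | None:
    """Return a rejection reason, or None if (ref, alt) is a valid SNV."""
    if len(ref) > 1 and len(alt) == 1:
        return "deletion"
    if len(ref) == 1 and len(alt) > 1:
        return "insertion"
    if len(ref) > 1 and len(alt) > 1:
        return "mnv"
    if ref not in _BASES or alt not in _BASES:
        return "non-acgt-allele"
    if ref == alt:
        return "ref-equals-alt"
    return None


def _read_mutations_tsv(path) -> tuple[list[MutationRecord], RejectionReport]:
    records: list[MutationRecord] = []
    report = RejectionReport()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MUTATION_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header {MUTATION_COLUMNS}, got {header}"
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}: line {line_no}: expected 6 fields, got {len(fields)}")
            sample_id, cancer_type, chrom, pos_s, ref, alt = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}: line {line_no}: non-integer pos {pos_s!r}") from None
            reason = _classify_alleles(ref.upper(), alt.upper())
            if reason is not None:
                report.add(line_no, reason)
                continue
            records.append(
                MutationRecord(sample_id, cancer_type, chrom, pos, ref.upper(), alt.upper())
            )
    return records, report


def _read_mutations_vcf_lite(path) -> tuple[list[MutationRecord], RejectionReport]:
    """Minimal VCF dialect: CHROM POS ID REF ALT [...] INFO with SAMPLE=/CANCER= keys."""
    records: list[MutationRecord] = []
    report = RejectionReport()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {line_no}: expected >= 6 fields")
            chrom, pos_s, _id, ref, alt = fields[:5]
            info = fields[7] if len(fields) >= 8 else fields[5]
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            if "SAMPLE" not in kv or "CANCER" not in kv:
                raise ParseError(
                    f"{path}: line {line_no}: INFO must carry SAMPLE= and CANCER= keys"
                )
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}: line {line_no}: non-integer POS {pos_s!r}") from None
            reason = _classify_alleles(ref.upper(), alt.upper())
            if reason is not None:
                report.add(line_no, reason)
                continue
            records.append(
                MutationRecord(kv["SAMPLE"], kv["CANCER"], chrom, pos, ref.upper(), alt.upper())
            )
    return records, report


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    rows = [
        (r.sample_id, r.cancer_type, r.chrom, r.pos, r.ref, r.alt) for r in records
    ]
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    write_table(df, path)


# ---------------------------------------------------------------------------
# gene catalogs

def read_genes(path, dialect: str = "bed", source: str = ""):
    """Read a gene list (BED6+ or GTF ``gene`` rows) into a GeneCatalog.

    BED is consumed as 0-based half-open; GTF 1-based inclusive rows are
    converted (start-1, end). Records with end <= start are rejected with a
    warning; duplicated gene_ids raise.
    """
    from .gene_catalog import GeneCatalog  # deferred: avoids a module cycle

    if dialect == "bed":
        genes = list(_read_genes_bed(path, source))
    elif dialect == "gtf":
        genes = list(_read_genes_gtf(path, source))
    else:
        raise ValueError(f"unknown gene dialect {dialect!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    label = source or str(path)
    return GeneCatalog(genes=genes, source_priority=[label])


def _read_genes_bed(path, source: str):
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}: line {line_no}: BED needs >= 4 columns")
            chrom, start_s, end_s, name = f[:4]
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-", ".") else "."
            biotype = f[6] if len(f) > 6 else ""
            src = f[7] if len(f) > 7 else source
            start, end = int(start_s), int(end_s)
            if end <= start:
                warnings.warn(f"{path}: line {line_no}: dropping gene {name} with end <= start")
                continue
            yield GeneFeature(name, name, chrom, start, end, strand, biotype, src or source)


def _read_genes_gtf(path, source: str):
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}: line {line_no}: GTF needs 9 columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = f
            if feature != "gene":
                continue
            attr = _parse_gtf_attrs(attrs)
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}: line {line_no}: gene row lacks gene_id")
            gene_name = attr.get("gene_name", gene_id)
            biotype = attr.get("gene_biotype", attr.get("gene_type", ""))
            start, end = int(start_s) - 1, int(end_s)  # 1-based inclusive -> half-open
            if end <= start:
                warnings.warn(f"{path}: line {line_no}: dropping gene {gene_id} with end <= start")
                continue
            yield GeneFeature(
                gene_id, gene_name, chrom, start, end,
                strand if strand in ("+", "-") else ".", biotype, source,
            )


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def write_genes(catalog, path) -> None:
    """Write a catalog as BED6 + biotype + source (round-trips through read_genes)."""
    rows = [
        (g.chrom, g.start, g.end, g.gene_id, ".", g.strand, g.biotype, g.source)
        for g in catalog.genes
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "biotype", "source"],
    )
    _atomic_to_csv(df, path, header=False)


# ---------------------------------------------------------------------------
# annotation tracks

def read_track(path, kind: str = "bed") -> list[TrackInterval]:
    """Read BED4 (label), BED5 (score) or ENCODE narrowPeak (signalValue) intervals."""
    intervals: list[TrackInterval] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}: line {line_no}: need >= 3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if kind == "narrowPeak":
                if len(f) < 7:
                    raise ParseError(f"{path}: line {line_no}: narrowPeak needs >= 7 columns")
                intervals.append(
                    TrackInterval(chrom, start, end, score=float(f[6]), label=f[3] or None)
                )
            elif kind == "bed":
                label = f[3] if len(f) > 3 and f[3] != "." else None
                score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                intervals.append(TrackInterval(chrom, start, end, score=score, label=label))
            else:
                raise ValueError(f"unknown track kind {kind!r}")
    return intervals


def read_segmentation(path) -> list[TrackInterval]:
    """Chromatin-state segmentation: BED4 whose name column is the state label."""
    intervals = read_track(path, kind="bed")
    for iv in intervals:
        if iv.label is None:
            raise ParseError(f"{path}: segmentation interval at {iv.chrom}:{iv.start} lacks a state label")
    return intervals


def read_multi_id_track(path) -> list[MultiIdInterval]:
    """BED-like track where col4 is comma-separated ids and col5 matching scores."""
    out: list[MultiIdInterval] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ParseError(f"{path}: line {line_no}: need 5 columns (ids, scores)")
            ids = tuple(f[3].split(","))
            scores = tuple(float(s) for s in f[4].split(","))
            out.append(MultiIdInterval(f[0], int(f[1]), int(f[2]), ids, scores))
    return out


# ---------------------------------------------------------------------------
# GWAS / eQTL

def read_gwas(path) -> list[GwasSnp]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "trait": str})
    required = {"chrom", "pos", "trait", "p_value"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: GWAS table needs columns {sorted(required)}")
    source = df["source_catalog"] if "source_catalog" in df.columns else [""] * len(df)
    return [
        GwasSnp(str(c), int(p), str(t), float(pv), str(s))
        for c, p, t, pv, s in zip(df["chrom"], df["pos"], df["trait"], df["p_value"], source)
    ]


def pool_gwas(catalogs: Sequence[Sequence[GwasSnp]], p_threshold: float = 1e-8) -> list[GwasSnp]:
    """Union multiple GWAS catalogs, dedup on (chrom, pos, trait), keep p < threshold.

    The threshold is strict: a SNP at exactly the threshold is excluded.
    """
    seen: set[tuple[str, int, str]] = set()
    out: list[GwasSnp] = []
    for catalog in catalogs:
        for snp in catalog:
            if snp.p_value >= p_threshold:
                continue
            key = (snp.chrom, snp.pos, snp.trait)
            if key in seen:
                continue
            seen.add(key)
            out.append(snp)
    return out


def write_gwas(snps: Iterable[GwasSnp], path) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.pos, s.trait, s.p_value, s.source_catalog) for s in snps],
        columns=["chrom", "pos", "trait", "p_value", "source_catalog"],
    )
    write_table(df, path)


def read_eqtl(path) -> list[EqtlAssociation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variation_id": str, "gene_id": str})
    required = {"chrom", "pos", "variation_id", "gene_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: eQTL table needs columns {sorted(required)}")
    return [
        EqtlAssociation(str(c), int(p), str(v), str(g))
        for c, p, v, g in zip(df["chrom"], df["pos"], df["variation_id"], df["gene_id"])
    ]


def write_eqtl(assocs: Iterable[EqtlAssociation], path) -> None:
    df = pd.DataFrame(
        [(a.chrom, a.pos, a.variation_id, a.gene_id) for a in assocs],
        columns=["chrom", "pos", "variation_id", "gene_id"],
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# cohort design

def read_design(path) -> dict[str, str]:
    """TSV sample_id, cancer_type -> mapping; each sample in exactly one cohort."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "cancer_type"}.issubset(df.columns):
        raise ParseError(f"{path}: design table needs columns sample_id, cancer_type")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated sample_ids: {sorted(set(dup))[:5]}")
    return dict(zip(df["sample_id"], df["cancer_type"]))


def write_design(mapping: dict[str, str], path) -> None:
    df = pd.DataFrame(sorted(mapping.items()), columns=["sample_id", "cancer_type"])
    write_table(df, path)


# ---------------------------------------------------------------------------
# Hi-C interactions

def read_interactions(path) -> tuple[list[HiCInteractionRecord], RejectionReport]:
    """BEDPE-like TSV with header; negative read counts are rejected, not fatal."""
    records: list[HiCInteractionRecord] = []
    report = RejectionReport()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != INTERACTION_COLUMNS:
            raise ParseError(f"{path}: expected header {INTERACTION_COLUMNS}, got {header}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ParseError(f"{path}: line {line_no}: expected 8 fields")
            read_count = int(f[6])
            if read_count < 0:
                report.add(line_no, f"negative read_count ({read_count})")
                continue
            records.append(
                HiCInteractionRecord(
                    f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]),
                    read_count, float(f[7]),
                )
            )
    return records, report


def write_interactions(records: Iterable[HiCInteractionRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.chrom1, r.start1, r.end1, r.chrom2, r.start2, r.end2, r.read_count, r.p_value)
            for r in records
        ],
        columns=INTERACTION_COLUMNS,
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# generic table output

def _atomic_to_csv(df: pd.DataFrame, path, header: bool = True) -> None:
    tmp = f"{path}.tmp.{os.getpid()}"
    df.to_csv(tmp, sep="\t", index=False, header=header, encoding="utf-8")
    os.replace(tmp, path)


def write_table(df: pd.DataFrame, path) -> None:
    """Tab-separated, UTF-8, header, deterministic column order, atomic rename."""
    _atomic_to_csv(df, path, header=True)
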