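"""Per-gene case-vs-control mutation burden testing.

The unit of evidence is the *mutated sample*: a sample contributes at most
once to a gene however many of its SNVs fall inside. For each gene the 2x2
table (case mutated, case unmutated, control mutated, control unmutated) is
scored with a one-sided Fisher exact test in the case-enrichment direction.

Significance is then calibrated per gene against a permutation null: holding
the gene's total number of mutated samples ``m`` fixed, case/control labels
are permuted and the Fisher p recomputed. Permuting labels with ``m`` fixed
makes the number of mutated case samples hypergeometric, so the null can be
sampled by drawing ``k ~ Hypergeometric(n_total, m, n_case)`` directly — an
exact shortcut, not an approximation; a literal label-shuffle implementation
is kept alongside as a slow reference. A gene is significant when its
permutation empirical p is at or below ``alpha`` (default 0.01, the "99%
confidence" threshold). No further multiple-testing layer is applied: the
per-gene permutation threshold is the calibration.

Each gene draws its Monte-Carlo permutations from an RNG stream derived from
(master seed, gene_id), so results do not depend on gene order and are
reproducible gene-by-gene.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .gene_catalog import GeneCatalog
from .genome_io import MutationRecord


@dataclass(frozen=True)
class CohortDesign:
    """Case label plus the full sample -> cancer-type assignment.

    Cohort sizes come from the design, not from the mutation file: samples
    with zero SNVs in every tested gene still count in ``n_case``/``n_total``.
    """

    case_label: str
    sample_cohort: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.n_case == 0:
            raise ValueError(f"no samples labelled {self.case_label!r} in design")

    @property
    def n_total(self) -> int:
        return len(self.sample_cohort)

    @property
    def n_case(self) -> int:
        return sum(1 for v in self.sample_cohort.values() if v == self.case_label)

    @property
    def n_ctrl(self) -> int:
        return self.n_total - self.n_case

    def is_case(self, sample_id: str) -> bool:
        return self.sample_cohort[sample_id] == self.case_label

    def with_case(self, case_label: str) -> "CohortDesign":
        return CohortDesign(case_label, self.sample_cohort)


@dataclass(frozen=True)
class FisherResult:
    gene_id: str
    a: int  # case samples mutated in the gene
    b: int  # case samples not mutated
    c: int  # control samples mutated
    d: int  # control samples not mutated
    p_value: float


@dataclass
class PermutationNull:
    """Empirical null of per-gene Fisher p-values under label permutation.

    ``support_p`` holds the distinct null p-values (ascending) with either
    Monte-Carlo ``counts`` (mode "monte_carlo"/"shuffle") or exact ``probs``
    (mode "exact"). ``threshold_p`` is the null distribution's 1% quantile,
    the per-gene significance cutoff.
    """

    gene_id: str
    m: int
    n_perm: int
    seed: int | None
    mode: str
    support_p: np.ndarray
    counts: np.ndarray | None = None
    probs: np.ndarray | None = None
    threshold_p: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.support_p)
        self.support_p = np.asarray(self.support_p, dtype=float)[order]
        if self.counts is not None:
            self.counts = np.asarray(self.counts)[order]
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)[order]
        self.threshold_p = self.quantile(0.01)

    def _cdf_weights(self) -> np.ndarray:
        if self.probs is not None:
            return self.probs
        return self.counts / self.counts.sum()

    def quantile(self, q: float) -> float:
        """inf{v in support : P(null <= v) >= q}."""
        cdf = np.cumsum(self._cdf_weights())
        idx = int(np.searchsorted(cdf, q - 1e-12))
        idx = min(idx, len(self.support_p) - 1)
        return float(self.support_p[idx])

    def empirical_p(self, observed_p: float) -> float:
        """P(null p <= observed p); MC modes apply the (1+count)/(n+1) correction."""
        mask = self.support_p <= observed_p + 1e-12
        if self.probs is not None:
            return float(self.probs[mask].sum())
        hits = int(self.counts[mask].sum())
        return (1 + hits) / (self.n_perm + 1)


@dataclass(frozen=True)
class SignificanceCall:
    gene_id: str
    fisher_p: float
    threshold_p: float
    empirical_p: float
    is_significant: bool


@dataclass(frozen=True)
class RankedSets:
    """Equal-size disjoint gene sets from the Fisher-p-sorted list."""

    candidate_set: tuple[str, ...]
    second_set: tuple[str, ...]
    third_set: tuple[str, ...]
    last_set: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.candidate_set)

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {
            "candidate": self.candidate_set,
            "second": self.second_set,
            "third": self.third_set,
            "last": self.last_set,
        }


# ---------------------------------------------------------------------------
# incidence

def build_incidence(
    mutations: Iterable[MutationRecord],
    catalog: GeneCatalog,
    design: CohortDesign,
) -> pd.DataFrame:
    """Count distinct mutated case/control samples per gene.

    A 1-based mutation position P falls in gene [s, e) iff s <= P-1 < e.
    Returns a frame indexed by gene_id with columns mutated_case,
    mutated_ctrl, m — one row per catalog gene, zeros included.
    """
    trees: dict[str, IntervalTree] = {}
    for g in catalog.genes:
        trees.setdefault(g.chrom, IntervalTree())[g.start:g.end] = g.gene_id

    case_samples: dict[str, set[str]] = {g.gene_id: set() for g in catalog.genes}
    ctrl_samples: dict[str, set[str]] = {g.gene_id: set() for g in catalog.genes}
    unknown: set[str] = set()
    for mut in mutations:
        if mut.sample_id not in design.sample_cohort:
            unknown.add(mut.sample_id)
            continue
        tree = trees.get(mut.chrom)
        if tree is None:
            continue
        bucket = case_samples if design.is_case(mut.sample_id) else ctrl_samples
        for iv in tree.at(mut.pos0):
            bucket[iv.data].add(mut.sample_id)
    if unknown:
        raise ValueError(
            f"samples present in mutations but absent from design: {sorted(unknown)[:10]}"
        )

    ids = catalog.gene_ids()
    mc = np.array([len(case_samples[i]) for i in ids])
    mt = np.array([len(ctrl_samples[i]) for i in ids])
    return pd.DataFrame(
        {"mutated_case": mc, "mutated_ctrl": mt, "m": mc + mt},
        index=pd.Index(ids, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# Fisher exact test (one-sided, case enrichment)

def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c mutated, n=a+b case draws)."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    n_total = a + b + c + d
    return float(min(1.0, hypergeom.sf(a - 1, n_total, a + c, a + b)))


def _fisher_p_for_k(ks: np.ndarray, m: int, design: CohortDesign) -> np.ndarray:
    """Vectorized one-sided Fisher p for tables with k mutated case samples."""
    return np.minimum(1.0, hypergeom.sf(ks - 1, design.n_total, m, design.n_case))


# ---------------------------------------------------------------------------
# permutation nulls

def gene_rng(master_seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene RNG stream from (master seed, stable hash of gene_id)."""
    digest = hashlib.sha256(gene_id.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed)] + words))


def permutation_null_mc(
    gene_id: str,
    m: int,
    design: CohortDesign,
    n_perm: int = 1_000_000,
    seed: int = 0,
) -> PermutationNull:
    """Monte-Carlo permutation null via the hypergeometric shortcut.

    Equivalent to shuffling sample labels with the gene's mutated-sample set
    fixed, but draws only the count of mutated case samples per permutation.
    """
    if not 0 <= m <= design.n_total:
        raise ValueError(f"m={m} outside [0, n_total={design.n_total}]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn("n_perm < 100: null quantile estimates are unstable")
    rng = gene_rng(seed, gene_id)
    ks = rng.hypergeometric(m, design.n_total - m, design.n_case, size=n_perm)
    uniq, counts = np.unique(ks, return_counts=True)
    ps = _fisher_p_for_k(uniq, m, design)
    return PermutationNull(gene_id, m, n_perm, seed, "monte_carlo", ps, counts=counts)


def permutation_null_exact(gene_id: str, m: int, design: CohortDesign) -> PermutationNull:
    """Closed-form permutation null: enumerate every reachable table.

    Under label permutation with the gene's mutated-sample set fixed, the
    mutated-case count K is Hypergeometric(n_total, m, n_case); the null is
    the induced distribution of Fisher p over the reachable K values.
    """
    if not 0 <= m <= design.n_total:
        raise ValueError(f"m={m} outside [0, n_total={design.n_total}]")
    k_lo = max(0, m - design.n_ctrl)
    k_hi = min(m, design.n_case)
    ks = np.arange(k_lo, k_hi + 1)
    probs = hypergeom.pmf(ks, design.n_total, m, design.n_case)
    probs = probs / probs.sum()
    ps = _fisher_p_for_k(ks, m, design)
    # distinct p atoms: sum probabilities of k values mapping to the same p
    uniq, inverse = np.unique(ps, return_inverse=True)
    agg = np.zeros(len(uniq))
    np.add.at(agg, inverse, probs)
    return PermutationNull(gene_id, m, 0, None, "exact", uniq, probs=agg)


def permutation_null_shuffle(
    gene_id: str,
    m: int,
    design: CohortDesign,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationNull:
    """Literal label-shuffle null: slow reference for the hypergeometric shortcut.

    Explicitly permutes the sample -> cohort label vector each iteration,
    recounts the mutated case samples, and records the Fisher p.
    """
    rng = gene_rng(seed, gene_id)
    labels = np.zeros(design.n_total, dtype=bool)
    labels[: design.n_case] = True  # which permuted slots are case samples
    ks = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        ks[i] = int(perm[:m].sum())  # the gene's m mutated samples are slots 0..m-1
    uniq, counts = np.unique(ks, return_counts=True)
    ps = _fisher_p_for_k(uniq, m, design)
    return PermutationNull(gene_id, m, n_perm, seed, "shuffle", ps, counts=counts)


# ---------------------------------------------------------------------------
# calls, ranking, cross-cancer

def fisher_results(incidence: pd.DataFrame, design: CohortDesign) -> list[FisherResult]:
    out = []
    for gene_id, row in incidence.iterrows():
        a = int(row["mutated_case"])
        c = int(row["mutated_ctrl"])
        b = design.n_case - a
        d = design.n_ctrl - c
        out.append(FisherResult(str(gene_id), a, b, c, d, fisher_one_sided(a, b, c, d)))
    return out


def compute_nulls(
    incidence: pd.DataFrame,
    design: CohortDesign,
    mode: str = "exact",
    n_perm: int = 1_000_000,
    seed: int = 0,
) -> dict[str, PermutationNull]:
    """One permutation null per gene; exact nulls are cached by m."""
    nulls: dict[str, PermutationNull] = {}
    exact_cache: dict[int, PermutationNull] = {}
    for gene_id, row in incidence.iterrows():
        m = int(row["m"])
        if mode == "exact":
            if m not in exact_cache:
                exact_cache[m] = permutation_null_exact(str(gene_id), m, design)
            base = exact_cache[m]
            nulls[str(gene_id)] = PermutationNull(
                str(gene_id), m, 0, None, "exact", base.support_p.copy(),
                probs=base.probs.copy(),
            )
        elif mode == "mc":
            nulls[str(gene_id)] = permutation_null_mc(str(gene_id), m, design, n_perm, seed)
        else:
            raise ValueError(f"unknown null mode {mode!r}")
    return nulls


def call_significant(
    fishers: Sequence[FisherResult],
    nulls: Mapping[str, PermutationNull],
    alpha: float = 0.01,
) -> list[SignificanceCall]:
    """Per-gene significance: empirical permutation p <= alpha.

    Output sorted by (fisher_p ascending, gene_id ascending).
    """
    missing = [f.gene_id for f in fishers if f.gene_id not in nulls]
    if missing:
        raise ValueError(f"missing permutation null for genes: {missing[:10]}")
    calls = []
    for f in fishers:
        null = nulls[f.gene_id]
        emp = null.empirical_p(f.p_value)
        calls.append(
            SignificanceCall(f.gene_id, f.p_value, null.threshold_p, emp, emp <= alpha)
        )
    calls.sort(key=lambda c: (c.fisher_p, c.gene_id))
    return calls


def rank_sets(calls: Sequence[SignificanceCall], k: int | None = None) -> RankedSets:
    """Candidate / 2nd / 3rd / last sets of equal size k from the sorted list.

    Candidate = significant genes; second and third = the next two blocks of
    k non-candidate genes in (fisher_p, gene_id) order; last = the final k
    genes of the sorted list (excluding candidates).
    """
    ordered = sorted(calls, key=lambda c: (c.fisher_p, c.gene_id))
    candidate = [c.gene_id for c in ordered if c.is_significant]
    if k is None:
        k = len(candidate)
    if k == 0:
        raise ValueError("no significant genes: ranked sets are undefined for k=0")
    if len(ordered) < 4 * k:
        raise ValueError(
            f"ranked sets need >= 4k = {4 * k} tested genes, got {len(ordered)}"
        )
    candidate = candidate[:k]
    cand_set = set(candidate)
    rest = [c.gene_id for c in ordered if c.gene_id not in cand_set]
    return RankedSets(
        candidate_set=tuple(candidate),
        second_set=tuple(rest[:k]),
        third_set=tuple(rest[k : 2 * k]),
        last_set=tuple(rest[-k:]),
    )


def cross_cancer_overlap(
    per_cancer_calls: Mapping[str, Sequence[SignificanceCall]],
    reference: str,
) -> tuple[dict[str, int], dict[str, int]]:
    """Specificity counts of the reference cancer's candidate set.

    Vector 1: per cancer, how many reference candidates are also significant
    there. Vector 2: per cancer, how many reference candidates are among its
    top-k genes by Fisher p (k = reference candidate-set size).
    """
    ref_calls = per_cancer_calls[reference]
    cand = {c.gene_id for c in ref_calls if c.is_significant}
    k = len(cand)
    v_significant: dict[str, int] = {}
    v_topk: dict[str, int] = {}
    for cancer, calls in per_cancer_calls.items():
        ordered = sorted(calls, key=lambda c: (c.fisher_p, c.gene_id))
        sig = {c.gene_id for c in ordered if c.is_significant}
        topk = {c.gene_id for c in ordered[:k]}
        v_significant[cancer] = len(cand & sig)
        v_topk[cancer] = len(cand & topk)
    return v_significant, v_topk


def calls_frame(
    fishers: Sequence[FisherResult],
    calls: Sequence[SignificanceCall],
    sets: RankedSets | None = None,
) -> pd.DataFrame:
    """Result table: gene_id, a, b, c, d, fisher_p, threshold_p, empirical_p, ..."""
    fmap = {f.gene_id: f for f in fishers}
    set_of: dict[str, str] = {}
    if sets is not None:
        for name, ids in sets.as_dict().items():
            for gid in ids:
                set_of[gid] = name
    rows = []
    for c in calls:
        f = fmap[c.gene_id]
        rows.append(
            (c.gene_id, f.a, f.b, f.c, f.d, c.fisher_p, c.threshold_p,
             c.empirical_p, c.is_significant, set_of.get(c.gene_id, ""))
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "a", "b", "c", "d", "fisher_p", "threshold_p",
                 "empirical_p", "is_significant", "rank_set"],
    )
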