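"""Set-level annotation enrichment with a binomial null.

With N genes in the catalog, A carrying a trait, and a gene set of size S in
which Y carry it, the enrichment ratio is (Y/S)/(A/N): trait prevalence in
the set over genome-wide prevalence. Under random sampling of S genes the
trait count is modelled as X ~ Binomial(S, A/N) — a with-replacement
approximation of the hypergeometric draw, adequate when S << N; the
hypergeometric alternative is available behind ``model="hypergeom"``.
The p-value is the upper tail P(X >= Y).

Traits are derived from overlap profiles three ways: plain overlap, "at
least k items" sweeps (e.g. k GWAS SNPs inside the gene), and "minimum
signal score" sweeps (>= 1 overlapping peak at or above a signal threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import binom, hypergeom

from .annotate import CountedEntry, OverlapProfile, ScoredEntry
from .mutsig import RankedSets


@dataclass(frozen=True)
class EnrichmentResult:
    trait_name: str
    N: int
    S: int
    A: int
    Y: int
    expected: float   # S * A / N
    ratio: float      # (Y/S) / (A/N)
    binom_p: float    # P(X >= Y), X ~ Binom(S, A/N)


def enrichment(
    Y: int, S: int, A: int, N: int, trait_name: str = "", model: str = "binomial"
) -> EnrichmentResult:
    """Enrichment ratio and upper-tail p for Y of S set genes vs A of N overall."""
    if not (0 <= Y <= S <= N):
        raise ValueError(f"need 0 <= Y <= S <= N, got Y={Y} S={S} N={N}")
    if not (0 <= A <= N):
        raise ValueError(f"need 0 <= A <= N, got A={A} N={N}")
    if S == 0:
        raise ValueError("S must be positive")
    if A == 0:
        if Y > 0:
            raise ValueError("trait absent genome-wide (A=0) but present in set (Y>0)")
        raise ValueError("A must be positive (trait absent genome-wide)")
    rate = A / N
    ratio = (Y / S) / rate
    if Y == 0:
        p = 1.0
    elif model == "binomial":
        p = float(min(1.0, binom.sf(Y - 1, S, rate)))
    elif model == "hypergeom":
        p = float(min(1.0, hypergeom.sf(Y - 1, N, A, S)))
    else:
        raise ValueError(f"unknown enrichment model {model!r}")
    return EnrichmentResult(trait_name, N, S, A, Y, S * rate, ratio, p)


# ---------------------------------------------------------------------------
# trait indicators over profiles

def _entry(profile: OverlapProfile, trait: str):
    if trait not in profile.entries:
        raise KeyError(f"profile for {profile.gene_id} lacks trait {trait!r}")
    return profile.entries[trait]


def trait_overlap(profiles: Mapping[str, OverlapProfile], trait: str) -> dict[str, bool]:
    """Binary trait: the gene overlaps the annotation at all."""
    out = {}
    for gid, profile in profiles.items():
        e = _entry(profile, trait)
        if hasattr(e, "overlaps"):
            out[gid] = bool(e.overlaps)
        elif isinstance(e, CountedEntry):
            out[gid] = e.n_items > 0
        elif isinstance(e, ScoredEntry):
            out[gid] = e.n_peaks > 0
        elif isinstance(e, dict):
            out[gid] = len(e) > 0
        else:  # segmented
            out[gid] = any(f > 0 for f in e.fractions.values())
    return out


def trait_at_least_k(
    profiles: Mapping[str, OverlapProfile], trait: str, k: int
) -> dict[str, bool]:
    """Indicator: the gene contains at least k counted items (SNPs, eQTL keys)."""
    out = {}
    for gid, profile in profiles.items():
        e = _entry(profile, trait)
        if not isinstance(e, CountedEntry):
            raise TypeError(f"trait {trait!r} is not a counted annotation")
        out[gid] = e.n_items >= k
    return out


def trait_min_score(
    profiles: Mapping[str, OverlapProfile], trait: str, score_threshold: float
) -> dict[str, bool]:
    """Indicator: the gene overlaps >= 1 peak with signal >= threshold."""
    out = {}
    for gid, profile in profiles.items():
        e = _entry(profile, trait)
        if isinstance(e, ScoredEntry):
            out[gid] = e.max_score is not None and e.max_score >= score_threshold
        elif isinstance(e, dict):  # id_aggregated: any id with a qualifying peak
            out[gid] = any(ie.max_score >= score_threshold for ie in e.values())
        else:
            raise TypeError(f"trait {trait!r} carries no signal scores")
    return out


@dataclass(frozen=True)
class TraitSweep:
    """A trait plus the sweep to run over it.

    kind "overlap" ignores values; "atleast" sweeps minimum item counts;
    "minscore" sweeps minimum signal values.
    """

    trait: str
    kind: str  # overlap | atleast | minscore
    values: tuple[float, ...] = (0,)


def _indicator(profiles, sweep: TraitSweep, value) -> dict[str, bool]:
    if sweep.kind == "overlap":
        return trait_overlap(profiles, sweep.trait)
    if sweep.kind == "atleast":
        return trait_at_least_k(profiles, sweep.trait, int(value))
    if sweep.kind == "minscore":
        return trait_min_score(profiles, sweep.trait, float(value))
    raise ValueError(f"unknown sweep kind {sweep.kind!r}")


def compare_sets(
    ranked: RankedSets,
    profiles: Mapping[str, OverlapProfile],
    sweeps: Sequence[TraitSweep],
    model: str = "binomial",
) -> pd.DataFrame:
    """Enrichment of every (gene set, trait, sweep point) in long format.

    N and A are computed over all profiled genes. When A = 0 (no gene
    genome-wide carries the trait at that sweep point) the ratio and p are
    reported as missing, not 0.
    """
    N = len(profiles)
    rows = []
    for sweep in sweeps:
        for value in sweep.values:
            ind = _indicator(profiles, sweep, value)
            A = sum(ind.values())
            for set_name, ids in ranked.as_dict().items():
                S = len(ids)
                Y = sum(1 for gid in ids if ind[gid])
                if A == 0:
                    rows.append(
                        (set_name, sweep.trait, sweep.kind, value, N, S, A, Y,
                         0.0, math.nan, math.nan)
                    )
                    continue
                r = enrichment(Y, S, A, N, trait_name=sweep.trait, model=model)
                rows.append(
                    (set_name, sweep.trait, sweep.kind, value, N, S, A, Y,
                     r.expected, r.ratio, r.binom_p)
                )
    return pd.DataFrame(
        rows,
        columns=["set", "trait", "sweep_kind", "sweep_value", "N", "S", "A", "Y",
                 "expected", "ratio", "binom_p"],
    )
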