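"""Training/benchmark set construction.

Merges labelled sources, removes duplicate and conflicting records,
filters population-cohort variants in dominant genes (carrier removal),
assigns confidence-tier sample weights, splits high-confidence pathogenic
variants into a held-out benchmark, and balances the benchmark per
molecular consequence with allele-frequency matching.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .variants import ClassifiedVariant, VariantKey

logger = logging.getLogger(__name__)

#: AF bin edges used when matching benchmark allele-frequency histograms.
DEFAULT_AF_BIN_EDGES: tuple[float, ...] = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)

#: sources treated as general-population cohorts (carrier filter applies).
DEFAULT_POPULATION_SOURCES = frozenset({"population", "exac", "gnomad", "gonl"})

_CLINVAR_HIGH_LEVELS = frozenset(
    {
        "criteria provided, multiple submitters, no conflicts",
        "reviewed by expert panel",
        "practice guideline",
    }
)


def _clinvar_is_high(review_level: str | None) -> bool:
    if review_level is None:
        return False
    return review_level.strip().lower() in _CLINVAR_HIGH_LEVELS


def _lab_consortium_is_high(review_level: str | None) -> bool:
    # high iff at least one supporting lab and no conflicting interpretation
    if review_level is None:
        return False
    rl = review_level.strip().lower()
    if "conflict" in rl and "no conflict" not in rl:
        return False
    digits = "".join(ch for ch in rl if ch.isdigit())
    n_labs = int(digits) if digits else (1 if "lab" in rl else 0)
    return n_labs >= 1


def _default_high_criteria() -> dict[str, Callable[[str | None], bool]]:
    return {"clinvar": _clinvar_is_high, "vkgl": _lab_consortium_is_high}


@dataclass
class ConfidencePolicy:
    """Maps source + review level to a confidence tier and sample weight.

    high_weight/low_weight default to 1.0/0.8; setting ``low_weight=0``
    makes training equivalent to excluding low-confidence variants.
    """

    high_weight: float = 1.0
    low_weight: float = 0.8
    high_criteria: dict[str, Callable[[str | None], bool]] = field(
        default_factory=_default_high_criteria
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_weight <= self.high_weight <= 1.0:
            raise ValueError("need 0 <= low_weight <= high_weight <= 1")

    def is_high(self, source: str, review_level: str | None) -> bool:
        pred = self.high_criteria.get(source.strip().lower())
        return bool(pred(review_level)) if pred is not None else False


@dataclass
class CurationAudit:
    duplicates_removed: int = 0
    conflicts_removed: int = 0  # keys with disagreeing labels
    conflict_records_removed: int = 0  # records dropped for those keys
    dominant_gene_removed: int = 0
    unknown_gene_variants: int = 0
    benchmark_overlap_removed: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class CuratedDataset:
    training: list[ClassifiedVariant]
    benchmark: list[ClassifiedVariant]
    audit: CurationAudit


def merge_and_deduplicate(
    sources: Sequence[Sequence[ClassifiedVariant]],
    source_priority: Sequence[str] | None = None,
) -> tuple[list[ClassifiedVariant], CurationAudit]:
    """Merge labelled sources into one record per variant key.

    Keys whose labels disagree across any pair of occurrences are removed
    entirely; for same-label duplicates the occurrence from the
    highest-priority source is kept (priority defaults to source order of
    appearance). Output preserves first-occurrence order of surviving keys.
    """
    audit = CurationAudit()
    flat: list[ClassifiedVariant] = [v for src in sources for v in src]
    if source_priority is None:
        seen_sources: list[str] = []
        for v in flat:
            if v.source not in seen_sources:
                seen_sources.append(v.source)
        source_priority = seen_sources
    prio = {s: i for i, s in enumerate(source_priority)}

    by_key: dict[VariantKey, list[ClassifiedVariant]] = defaultdict(list)
    order: list[VariantKey] = []
    for v in flat:
        if v.key not in by_key:
            order.append(v.key)
        by_key[v.key].append(v)

    merged: list[ClassifiedVariant] = []
    for key in order:
        occ = by_key[key]
        labels = {v.label for v in occ}
        if len(labels) > 1:
            audit.conflicts_removed += 1
            audit.conflict_records_removed += len(occ)
            continue
        if len(occ) > 1:
            audit.duplicates_removed += len(occ) - 1
        best = min(
            range(len(occ)),
            key=lambda i: (prio.get(occ[i].source, len(prio)), i),
        )
        merged.append(occ[best])
    return merged, audit


def filter_dominant_population_variants(
    variants: Sequence[ClassifiedVariant],
    inheritance: Mapping[str, "object"],
    population_sources: frozenset[str] | set[str] = DEFAULT_POPULATION_SOURCES,
    audit: CurationAudit | None = None,
) -> tuple[list[ClassifiedVariant], int]:
    """Drop population-cohort variants located in dominant genes.

    Population cohorts contain healthy carriers of dominant-disease
    variants, which would contaminate the neutral class; curated-source
    variants pass through untouched. Genes absent from the inheritance
    mapping count as non-dominant (tallied as unknown).
    """
    if audit is None:
        audit = CurationAudit()
    kept: list[ClassifiedVariant] = []
    removed = 0
    pop = {s.lower() for s in population_sources}
    for v in variants:
        if v.source.strip().lower() not in pop:
            kept.append(v)
            continue
        dominant = False
        for gene in v.genes:
            entry = inheritance.get(gene.upper())
            if entry is None:
                audit.unknown_gene_variants += 1
            elif getattr(entry, "dominant"):
                dominant = True
        if dominant:
            removed += 1
        else:
            kept.append(v)
    audit.dominant_gene_removed += removed
    return kept, removed


def assign_confidence(
    variant: ClassifiedVariant, policy: ConfidencePolicy
) -> ClassifiedVariant:
    """Stamp the confidence tier and sample weight implied by the policy."""
    high = policy.is_high(variant.source, variant.review_level)
    return replace(
        variant,
        confidence="high" if high else "low",
        sample_weight=policy.high_weight if high else policy.low_weight,
    )


def split_high_confidence_benchmark(
    variants: Sequence[ClassifiedVariant], fraction: float = 0.5, seed: int = 0
) -> tuple[list[ClassifiedVariant], list[ClassifiedVariant]]:
    """Randomly partition variants into (benchmark, remainder).

    Benchmark size is round-half-to-even of ``fraction * n``; the split is
    deterministic given the seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(variants)
    if n == 0:
        return [], []
    n_bench = int(round(fraction * n))  # Python round: half-to-even
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bench = [variants[i] for i in sorted(perm[:n_bench])]
    rest = [variants[i] for i in sorted(perm[n_bench:])]
    return bench, rest


def af_bin_index(af: float, edges: Sequence[float] = DEFAULT_AF_BIN_EDGES) -> int:
    """Index of the half-open AF bin [edges[i], edges[i+1]) containing af;
    af == edges[-1] falls in the last bin."""
    idx = int(np.searchsorted(edges, af, side="right")) - 1
    return min(max(idx, 0), len(edges) - 2)


class BalanceReport(NamedTuple):
    per_consequence: dict[str, dict]
    skipped_consequences: list[str]


def build_balanced_benchmark(
    pathogenic: Sequence[ClassifiedVariant],
    neutral_pool: Sequence[ClassifiedVariant],
    af_bin_edges: Sequence[float] = DEFAULT_AF_BIN_EDGES,
    seed: int = 0,
) -> tuple[list[ClassifiedVariant], BalanceReport]:
    """Build a benchmark with equal pathogenic/neutral counts per molecular
    consequence and matched allele-frequency histograms.

    For each consequence the neutral draw follows the pathogenic AF-bin
    histogram (per-bin quota); bins short of neutral variants are refilled
    from adjacent bins outward. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_bins = len(af_bin_edges) - 1
    path_by_cons: dict[str, list[ClassifiedVariant]] = defaultdict(list)
    neut_by_cons: dict[str, list[ClassifiedVariant]] = defaultdict(list)
    for v in pathogenic:
        path_by_cons[v.consequence or "unknown"].append(v)
    for v in neutral_pool:
        neut_by_cons[v.consequence or "unknown"].append(v)

    out: list[ClassifiedVariant] = []
    per_cons: dict[str, dict] = {}
    skipped: list[str] = []
    for cons in sorted(path_by_cons):
        path_c = sorted(path_by_cons[cons], key=lambda v: v.key)
        neut_c = sorted(neut_by_cons.get(cons, []), key=lambda v: v.key)
        if not neut_c:
            skipped.append(cons)
            logger.warning("no neutral variants for consequence %r; excluded", cons)
            continue
        n_c = min(len(path_c), len(neut_c))
        if n_c < len(path_c):
            idx = rng.choice(len(path_c), size=n_c, replace=False)
            path_sel = [path_c[i] for i in sorted(idx)]
        else:
            path_sel = path_c

        quota = Counter(af_bin_index(v.allele_frequency, af_bin_edges) for v in path_sel)
        pools: dict[int, list[ClassifiedVariant]] = defaultdict(list)
        for v in neut_c:
            pools[af_bin_index(v.allele_frequency, af_bin_edges)].append(v)
        for b in pools:
            pools[b] = [pools[b][i] for i in rng.permutation(len(pools[b]))]

        neut_sel: list[ClassifiedVariant] = []
        shortfall: dict[int, int] = {}
        for b in range(n_bins):
            want = quota.get(b, 0)
            take = min(want, len(pools[b]))
            neut_sel.extend(pools[b][:take])
            pools[b] = pools[b][take:]
            if want - take:
                shortfall[b] = want - take
        refilled: dict[int, int] = {}
        for b, short in sorted(shortfall.items()):
            for dist in range(1, n_bins):
                if short == 0:
                    break
                for nb in (b - dist, b + dist):
                    if short == 0 or not 0 <= nb < n_bins:
                        continue
                    take = min(short, len(pools[nb]))
                    neut_sel.extend(pools[nb][:take])
                    pools[nb] = pools[nb][take:]
                    refilled[nb] = refilled.get(nb, 0) + take
                    short -= take
        assert len(neut_sel) == n_c, "neutral pool accounting failed"

        out.extend(path_sel)
        out.extend(neut_sel)
        per_cons[cons] = {
            "n": n_c,
            "bin_quota": {b: quota.get(b, 0) for b in range(n_bins) if quota.get(b, 0)},
            "shortfall": shortfall,
            "refilled": refilled,
        }
    return out, BalanceReport(per_cons, skipped)


class CohortVariant(NamedTuple):
    key: VariantKey
    passed: bool
    af: float


def build_population_neutral_set(
    cohort_variants: Iterable[CohortVariant],
    training_keys: set[VariantKey],
    af_cutoff: float = 0.01,
    source: str = "population",
) -> list[ClassifiedVariant]:
    """Select quality-passing, rare (within-cohort AF < cutoff) cohort
    variants unseen in training; all labelled neutral."""
    out: list[ClassifiedVariant] = []
    for cv in cohort_variants:
        if cv.passed and cv.af < af_cutoff and cv.key not in training_keys:
            out.append(
                ClassifiedVariant(
                    key=cv.key,
                    label="neutral",
                    source=source,
                    allele_frequency=cv.af,
                )
            )
    return out


def read_cohort_vcf(path: str) -> list[CohortVariant]:
    """Read a population-cohort VCF into (key, PASS flag, within-cohort AF)
    tuples. PASS is taken from the FILTER field per the VCF standard; AF is
    INFO/AF when present, else AC/AN."""
    from cyvcf2 import VCF

    out: list[CohortVariant] = []
    for rec in VCF(str(path)):
        passed = rec.FILTER is None  # cyvcf2 reports PASS as None
        afs = rec.INFO.get("AF")
        if afs is None:
            ac, an = rec.INFO.get("AC"), rec.INFO.get("AN")
            if ac is not None and an:
                afs = (
                    tuple(a / an for a in ac)
                    if isinstance(ac, tuple)
                    else (ac / an,)
                )
        if afs is not None and not isinstance(afs, tuple):
            afs = (afs,)
        for j, alt in enumerate(rec.ALT):
            af = float(afs[j]) if afs is not None and j < len(afs) else 0.0
            try:
                key = VariantKey(rec.CHROM, rec.POS, rec.REF, alt)
            except ValueError:
                continue
            out.append(CohortVariant(key, passed, af))
    return out


def curate(
    sources: Sequence[Sequence[ClassifiedVariant]],
    inheritance: Mapping[str, "object"],
    policy: ConfidencePolicy | None = None,
    benchmark_fraction: float = 0.5,
    af_bin_edges: Sequence[float] = DEFAULT_AF_BIN_EDGES,
    population_sources: frozenset[str] | set[str] = DEFAULT_POPULATION_SOURCES,
    seed: int = 0,
) -> CuratedDataset:
    """Full curation pipeline: merge/dedup → confidence weights → dominant
    carrier filter → benchmark split (half of the high-confidence
    pathogenic variants) → consequence/AF-balanced benchmark → disjoint
    training set."""
    policy = policy or ConfidencePolicy()
    merged, audit = merge_and_deduplicate(sources)
    weighted = [assign_confidence(v, policy) for v in merged]
    filtered, _ = filter_dominant_population_variants(
        weighted, inheritance, population_sources, audit
    )

    high_path = [v for v in filtered if v.label == "pathogenic" and v.confidence == "high"]
    bench_path, _rest = split_high_confidence_benchmark(
        high_path, benchmark_fraction, seed
    )
    neutral_pool = [v for v in filtered if v.label == "neutral"]
    benchmark, _report = build_balanced_benchmark(
        bench_path, neutral_pool, af_bin_edges, seed + 1
    )
    bench_keys = {v.key for v in benchmark}
    training = [v for v in filtered if v.key not in bench_keys]
    audit.benchmark_overlap_removed = len(filtered) - len(training)
    return CuratedDataset(training=training, benchmark=benchmark, audit=audit)
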