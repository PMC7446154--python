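"""Clinical exome ranking protocol.

Per patient: drop variants with population allele frequency above a cutoff
(default 10%), sort the remainder by pathogenicity score descending, and
report the rank of the known disease-causing variant. Ties are resolved
pessimistically (the causal variant takes the worst position within its
tie group), and variants the tool declined to score sort below all scored
variants. Cohort-level utility is the fraction of cases whose causal
variant lands within the top X% (default 1%).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .variants import VariantKey


@dataclass(frozen=True)
class PatientVariant:
    key: VariantKey
    allele_frequency: float
    consequence: str | None = None
    scores: Mapping[str, float | None] = field(default_factory=dict)


@dataclass
class PatientCase:
    patient_id: str
    variants: list[PatientVariant]
    causal_keys: tuple[VariantKey, ...]

    def __post_init__(self) -> None:
        if not self.causal_keys:
            raise ValueError("a case needs at least one causal variant")
        keys = {v.key for v in self.variants}
        missing = [k for k in self.causal_keys if k not in keys]
        if missing:
            raise ValueError(
                f"causal variants not in patient {self.patient_id}'s list: {missing}"
            )


@dataclass(frozen=True)
class RankResult:
    patient_id: str
    tool: str
    causal_key: VariantKey
    rank: int
    total_after_filter: int

    @property
    def percentile(self) -> float:
        return 100.0 * self.rank / self.total_after_filter


def _worst_rank(
    kept: Sequence[PatientVariant], causal: PatientVariant, tool: str
) -> int:
    c_score = causal.scores.get(tool)
    if c_score is None:
        # unscored variants form the bottom tie group
        return len(kept)
    better = ties = 0
    for v in kept:
        s = v.scores.get(tool)
        if s is None:
            continue
        if s > c_score:
            better += 1
        elif s == c_score:
            ties += 1  # includes the causal variant itself
    return better + ties


def rank_causal_variant(
    case: PatientCase, tool: str, af_cutoff: float = 0.10
) -> list[RankResult]:
    """Rank each causal variant among the patient's AF-filtered variants.

    Variants with allele frequency strictly above ``af_cutoff`` are removed
    first; a causal variant removed by the filter is an explicit error.
    """
    kept = [v for v in case.variants if v.allele_frequency <= af_cutoff]
    kept_keys = {v.key: v for v in kept}
    results: list[RankResult] = []
    for ck in case.causal_keys:
        causal = kept_keys.get(ck)
        if causal is None:
            raise ValueError(
                f"causal variant {ck} of patient {case.patient_id} was removed "
                f"by the allele-frequency filter (> {af_cutoff:g})"
            )
        results.append(
            RankResult(
                patient_id=case.patient_id,
                tool=tool,
                causal_key=ck,
                rank=_worst_rank(kept, causal, tool),
                total_after_filter=len(kept),
            )
        )
    return results


def top_percent_yield(
    results: Sequence[RankResult], percent: float = 1.0, per: str = "case"
) -> float:
    """Fraction of cases (or causal variants, ``per='variant'``) ranked
    within the top ``percent`` of the patient's filtered variant list.

    A case with several causal variants counts once, via its best-ranked
    causal variant; the boundary is inclusive (percentile <= percent).
    """
    if not results:
        raise ValueError("no rank results supplied")
    if per == "variant":
        hits = sum(1 for r in results if r.percentile <= percent)
        return hits / len(results)
    if per != "case":
        raise ValueError("per must be 'case' or 'variant'")
    best: dict[str, float] = {}
    for r in results:
        p = r.percentile
        if r.patient_id not in best or p < best[r.patient_id]:
            best[r.patient_id] = p
    hits = sum(1 for p in best.values() if p <= percent)
    return hits / len(best)
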