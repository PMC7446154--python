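"""Score-set evaluation: ROC AUC, bootstrap SD, threshold confusion
matrices with missing-prediction accounting, and AF-bin / consequence
stratified reports.

AUC is the Mann–Whitney statistic (probability a random pathogenic variant
outscores a random neutral one, ties counting one half), computed exactly
via midranks. Two false-positive-rate variants are kept: the conventional
per-predicted-row fp/(fp+tn) inside ConfusionSummary, and
``false_positive_rate`` which divides by ALL true neutral variants
(including those with no prediction) — the definition used when comparing
tools that decline to score some variants.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .variants import ClassifiedVariant

logger = logging.getLogger(__name__)

#: AF bin edges for stratified evaluation: {0} plus four half-open bins.
DEFAULT_EVAL_AF_EDGES: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2, 1.0)

GE = "greater_equal_is_pathogenic"
LE = "less_equal_is_pathogenic"


@dataclass(frozen=True)
class ToolThresholdRule:
    tool_name: str
    threshold: float
    direction: str = GE

    def calls_pathogenic(self, score: float) -> bool:
        if self.direction == GE:
            return score >= self.threshold
        if self.direction == LE:
            return score <= self.threshold
        raise ValueError(f"unknown direction: {self.direction!r}")


#: published decision thresholds for externally supplied score columns.
DEFAULT_RULES: dict[str, ToolThresholdRule] = {
    "boosted_tree": ToolThresholdRule("boosted_tree", 0.02, GE),
    "cadd": ToolThresholdRule("cadd", 20.0, GE),
    "revel": ToolThresholdRule("revel", 0.5, GE),
    "clinpred": ToolThresholdRule("clinpred", 0.5, GE),
    "sift": ToolThresholdRule("sift", 0.5, GE),
    "fathmm-xf": ToolThresholdRule("fathmm-xf", 0.5, GE),
    "provean": ToolThresholdRule("provean", -2.5, LE),
}


@dataclass
class ConfusionSummary:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    no_prediction_pathogenic: int = 0
    no_prediction_neutral: int = 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def fpr(self) -> float:
        """FPR over predicted rows only: fp / (fp + tn)."""
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else math.nan

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "no_prediction_pathogenic": self.no_prediction_pathogenic,
            "no_prediction_neutral": self.no_prediction_neutral,
            "recall": self.recall, "fpr": self.fpr, "precision": self.precision,
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if not (labels == 1).any():
        raise ValueError("no pathogenic (label 1) examples present")
    if not (labels == 0).any():
        raise ValueError("no neutral (label 0) examples present")


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUC: over all (pathogenic, neutral) pairs, the mean of
    1 if the pathogenic score is higher, 0.5 on ties, 0 otherwise."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks handle ties exactly
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_auc_sd(
    scores: Sequence[float],
    labels: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[float, float]:
    """Bootstrap mean and population SD of the AUC: ``n_reps`` resamples
    with replacement at the original sample size. Single-class resamples
    are redrawn up to ``max_retries`` times, then skipped with a warning."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    n = scores.size
    aucs: list[float] = []
    for _ in range(n_reps):
        for _attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            if len(set(labels[idx])) == 2:
                aucs.append(compute_auc(scores[idx], labels[idx]))
                break
        else:
            warnings.warn("bootstrap resample degenerate after retries; skipped")
    if not aucs:
        raise ValueError("all bootstrap resamples were single-class")
    arr = np.asarray(aucs)
    return float(arr.mean()), float(arr.std(ddof=0))


def confusion_at_threshold(
    scores: Sequence[float | None],
    labels: Sequence[int],
    rule: ToolThresholdRule,
) -> ConfusionSummary:
    """Apply a tool's decision rule; rows with an absent score (None/NaN)
    are tallied as no-prediction by their true class, never as errors."""
    summary = ConfusionSummary()
    for score, label in zip(scores, labels, strict=True):
        absent = score is None or (isinstance(score, float) and math.isnan(score))
        if absent:
            if label == 1:
                summary.no_prediction_pathogenic += 1
            else:
                summary.no_prediction_neutral += 1
            continue
        called = rule.calls_pathogenic(float(score))
        if label == 1:
            if called:
                summary.tp += 1
            else:
                summary.fn += 1
        else:
            if called:
                summary.fp += 1
            else:
                summary.tn += 1
    return summary


def false_positive_rate(summary: ConfusionSummary) -> float:
    """Neutral variants called pathogenic divided by ALL true neutral
    variants (missing predictions included in the denominator)."""
    denom = summary.fp + summary.tn + summary.no_prediction_neutral
    if denom == 0:
        raise ValueError("no neutral variants to compute a false-positive rate")
    return summary.fp / denom


@dataclass
class StratumResult:
    n_pathogenic: int
    n_neutral: int
    evaluable: bool
    auc: float | None = None
    auc_sd: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class StratifiedReport:
    overall: StratumResult
    by_af_bin: dict[str, StratumResult] = field(default_factory=dict)
    by_consequence: dict[str, StratumResult] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "by_af_bin": {k: v.as_dict() for k, v in self.by_af_bin.items()},
            "by_consequence": {k: v.as_dict() for k, v in self.by_consequence.items()},
        }


def af_bin_label(af: float, edges: Sequence[float] = DEFAULT_EVAL_AF_EDGES) -> str:
    """Stratification bin: AF exactly 0 gets its own bin, positive AFs fall
    into half-open intervals (edges[i], edges[i+1]]."""
    if af == 0.0:
        return "0"
    i = int(np.searchsorted(edges, af, side="left")) - 1
    i = min(max(i, 0), len(edges) - 2)
    return f"({edges[i]:g},{edges[i + 1]:g}]"


def _stratum_result(
    scores: np.ndarray, labels: np.ndarray, n_boot: int, seed: int
) -> StratumResult:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return StratumResult(n_pos, n_neg, evaluable=False)
    auc = compute_auc(scores, labels)
    _, sd = bootstrap_auc_sd(scores, labels, n_reps=n_boot, seed=seed)
    return StratumResult(n_pos, n_neg, True, auc, sd)


def stratified_evaluation(
    scores: Sequence[float],
    variants: Sequence[ClassifiedVariant],
    af_bin_edges: Sequence[float] = DEFAULT_EVAL_AF_EDGES,
    n_boot: int = 100,
    seed: int = 0,
) -> StratifiedReport:
    """AUC with bootstrap SD overall and per AF bin / molecular consequence;
    strata missing a class are reported as not evaluable with their counts."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([1 if v.label == "pathogenic" else 0 for v in variants])
    if scores.size != labels.size:
        raise ValueError("scores and variants are misaligned")
    report = StratifiedReport(overall=_stratum_result(scores, labels, n_boot, seed))

    groups: dict[str, list[int]] = defaultdict(list)
    for i, v in enumerate(variants):
        groups[af_bin_label(v.allele_frequency, af_bin_edges)].append(i)
    for name in sorted(groups):
        idx = np.asarray(groups[name])
        report.by_af_bin[name] = _stratum_result(scores[idx], labels[idx], n_boot, seed)

    by_cons: dict[str, list[int]] = defaultdict(list)
    for i, v in enumerate(variants):
        by_cons[v.consequence or "unknown"].append(i)
    for name in sorted(by_cons):
        idx = np.asarray(by_cons[name])
        report.by_consequence[name] = _stratum_result(scores[idx], labels[idx], n_boot, seed)
    return report
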