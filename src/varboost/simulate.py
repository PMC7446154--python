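"""Synthetic labelled, annotated variant sets with known statistical
structure.

The generator plants the class signal in a single numerical feature: the
informative feature is drawn from Normal(d, 1) for pathogenic variants and
Normal(0, 1) for neutral ones, while every other numerical and categorical
feature is class-independent noise. With unit variances the optimal
(Bayes) AUC on that feature is the closed form Phi(d / sqrt(2)), which
gives the whole pipeline a parameter-recovery oracle. Allele frequencies
follow the same mixture (a point mass at 0 plus a log-uniform tail) in
both classes by default, so AF carries no class signal unless explicitly
configured to.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ranking import PatientCase, PatientVariant
from .variants import (
    AnnotationRecord,
    ClassifiedVariant,
    FeatureManifest,
    InheritanceEntry,
    VariantKey,
    write_af_lookup,
    write_annotations,
    write_inheritance_table,
    write_labelled_variants,
)

_BASES = ("A", "C", "G", "T")
_CHROMS = tuple(str(i) for i in range(1, 23))

#: review-level strings the default confidence policy maps to high/low.
_CLINVAR_HIGH = "criteria provided, multiple submitters, no conflicts"
_CLINVAR_LOW = "criteria provided, single submitter"
_VKGL_HIGH = "2 labs, no conflicts"


@dataclass(frozen=True)
class AlleleFrequencyModel:
    """Point mass at AF 0 with probability ``p_zero``; otherwise
    log-uniform on [af_min, af_max]."""

    p_zero: float = 0.35
    af_min: float = 1e-6
    af_max: float = 1e-2

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError("p_zero must lie in [0, 1]")
        if not 0.0 < self.af_min <= self.af_max <= 1.0:
            raise ValueError("need 0 < af_min <= af_max <= 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        af = np.exp(rng.uniform(math.log(self.af_min), math.log(self.af_max), size=n))
        zero = rng.random(n) < self.p_zero
        af[zero] = 0.0
        return af


def _default_categorical_spec() -> dict[str, dict]:
    # six levels so the top-5 retention rule is exercised; identical
    # class-conditional probabilities keep these features uninformative.
    levels = ["L1", "L2", "L3", "L4", "L5", "L6"]
    probs = [0.30, 0.25, 0.20, 0.15, 0.07, 0.03]
    return {
        f"cat{i:02d}": {"levels": levels, "p_pathogenic": probs, "p_neutral": probs}
        for i in range(1, 12)
    }


def _default_consequence_mix() -> dict[str, tuple[float, float]]:
    # pathogenic enriched for protein-disrupting classes, neutral for
    # synonymous / non-coding, mirroring curated-vs-population sets.
    return {
        "missense": (0.45, 0.30),
        "canonical-splice": (0.12, 0.05),
        "stop-gained": (0.15, 0.05),
        "frameshift": (0.13, 0.05),
        "synonymous": (0.05, 0.30),
        "non-coding": (0.10, 0.25),
    }


@dataclass
class SimulationConfig:
    n_pathogenic: int = 1000
    n_neutral: int = 1000
    informative_shift: float = 1.0  # mean shift d of the informative feature
    informative_feature: str = "num01"
    n_noise_numerical: int = 80
    categorical_spec: dict[str, dict] = field(default_factory=_default_categorical_spec)
    consequence_mix: dict[str, tuple[float, float]] = field(
        default_factory=_default_consequence_mix
    )
    af_model_pathogenic: AlleleFrequencyModel = field(default_factory=AlleleFrequencyModel)
    af_model_neutral: AlleleFrequencyModel = field(default_factory=AlleleFrequencyModel)
    missing_rate: float = 0.05
    low_confidence_fraction: float = 0.9
    population_source_fraction: float = 0.5  # of neutral variants
    n_genes: int = 200
    dominant_gene_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.informative_shift < 0:
            raise ValueError("informative_shift must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for name, spec in self.categorical_spec.items():
            for side in ("p_pathogenic", "p_neutral"):
                p = spec[side]
                if len(p) != len(spec["levels"]) or not math.isclose(sum(p), 1.0, abs_tol=1e-9):
                    raise ValueError(f"categorical probabilities invalid for {name}/{side}")
        for side in (0, 1):
            total = sum(p[side] for p in self.consequence_mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError("consequence_mix probabilities must sum to 1 per class")

    @property
    def manifest(self) -> FeatureManifest:
        numerical = [self.informative_feature] + [
            f"num{i:02d}" for i in range(2, self.n_noise_numerical + 2)
        ]
        return FeatureManifest(
            categorical_names=tuple(self.categorical_spec),
            numerical_names=tuple(numerical),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        doc = json.loads(Path(path).read_text())
        for key in ("af_model_pathogenic", "af_model_neutral"):
            if key in doc:
                doc[key] = AlleleFrequencyModel(**doc[key])
        if "consequence_mix" in doc:
            doc["consequence_mix"] = {
                k: tuple(v) for k, v in doc["consequence_mix"].items()
            }
        return cls(**doc)


class SimulatedDataset(NamedTuple):
    variants: list[ClassifiedVariant]
    annotations: list[AnnotationRecord]
    af_lookup: dict[VariantKey, float]
    inheritance: dict[str, InheritanceEntry]


def bayes_auc(d: float) -> float:
    """Optimal AUC for two unit-variance Gaussians separated by d."""
    from scipy.stats import norm

    return float(norm.cdf(d / math.sqrt(2.0)))


def _unique_keys(rng: np.random.Generator, n: int) -> list[VariantKey]:
    chroms = rng.choice(_CHROMS, size=n)
    refs = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    return [
        VariantKey(
            chroms[i],
            10_000 + i,  # unique positions guarantee unique keys
            _BASES[refs[i]],
            _BASES[(refs[i] + alt_off[i]) % 4],
        )
        for i in range(n)
    ]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a labelled + annotated variant set per the config; fully
    deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_p, n_n = config.n_pathogenic, config.n_neutral
    n = n_p + n_n
    labels = np.array([1] * n_p + [0] * n_n)
    keys = _unique_keys(rng, n)
    manifest = config.manifest

    # numerical features: informative N(d,1)/N(0,1), noise N(0,1)
    num = rng.standard_normal((n, len(manifest.numerical_names)))
    num[:n_p, 0] += config.informative_shift

    # categorical features per class-conditional level probabilities
    cat_draws: dict[str, np.ndarray] = {}
    for name, spec in config.categorical_spec.items():
        levels = np.asarray(spec["levels"], dtype=object)
        idx = np.empty(n, dtype=int)
        idx[:n_p] = rng.choice(len(levels), size=n_p, p=spec["p_pathogenic"])
        idx[n_p:] = rng.choice(len(levels), size=n_n, p=spec["p_neutral"])
        cat_draws[name] = levels[idx]

    cons_names = list(config.consequence_mix)
    p_path = [config.consequence_mix[c][0] for c in cons_names]
    p_neut = [config.consequence_mix[c][1] for c in cons_names]
    cons = np.empty(n, dtype=object)
    cons[:n_p] = np.asarray(cons_names, dtype=object)[
        rng.choice(len(cons_names), size=n_p, p=p_path)
    ]
    cons[n_p:] = np.asarray(cons_names, dtype=object)[
        rng.choice(len(cons_names), size=n_n, p=p_neut)
    ]

    af = np.empty(n)
    af[:n_p] = config.af_model_pathogenic.sample(rng, n_p)
    af[n_p:] = config.af_model_neutral.sample(rng, n_n)

    genes = [f"GENE{int(g):04d}" for g in rng.integers(0, config.n_genes, size=n)]
    n_dom = int(round(config.dominant_gene_fraction * config.n_genes))
    dom_idx = set(rng.choice(config.n_genes, size=n_dom, replace=False).tolist())
    inheritance = {
        f"GENE{i:04d}": InheritanceEntry(
            f"GENE{i:04d}", "AD" if i in dom_idx else "AR", i in dom_idx
        )
        for i in range(config.n_genes)
    }

    low_conf = rng.random(n) < config.low_confidence_fraction
    neutral_pop = rng.random(n) < config.population_source_fraction

    # missingness mask over every annotation cell
    n_feat = len(manifest.all_names)
    miss = (
        rng.random((n, n_feat)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n, n_feat), dtype=bool)
    )

    variants: list[ClassifiedVariant] = []
    annotations: list[AnnotationRecord] = []
    af_lookup: dict[VariantKey, float] = {}
    cat_names = list(manifest.categorical_names)
    for i in range(n):
        pathogenic = labels[i] == 1
        if not pathogenic and neutral_pop[i]:
            source, review, high = "population", None, False
        else:
            if rng.random() < 0.8:
                source = "clinvar"
                high = not low_conf[i]
                review = _CLINVAR_HIGH if high else _CLINVAR_LOW
            else:
                source = "vkgl"
                high = not low_conf[i]
                review = _VKGL_HIGH if high else "1 lab, conflicting interpretations"
        variants.append(
            ClassifiedVariant(
                key=keys[i],
                label="pathogenic" if pathogenic else "neutral",
                source=source,
                confidence="high" if high else "low",
                sample_weight=1.0 if high else 0.8,
                consequence=str(cons[i]),
                allele_frequency=float(af[i]),
                review_level=review,
                genes=(genes[i],),
            )
        )
        categorical = {
            name: str(cat_draws[name][i])
            for j, name in enumerate(cat_names)
            if not miss[i, j]
        }
        numerical = {
            name: float(num[i, j])
            for j, name in enumerate(manifest.numerical_names)
            if not miss[i, len(cat_names) + j]
        }
        annotations.append(AnnotationRecord(keys[i], categorical, numerical))
        if af[i] > 0:  # variants absent from the lookup read back as AF 0
            af_lookup[keys[i]] = float(af[i])

    return SimulatedDataset(variants, annotations, af_lookup, inheritance)


def write_simulated_dataset(
    dataset: SimulatedDataset, out_dir: str | Path, manifest: FeatureManifest
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "labelled": out / "labelled.tsv",
        "annotations": out / "annotations.tsv",
        "af": out / "af.tsv",
        "inheritance": out / "inheritance.tsv",
    }
    write_labelled_variants(dataset.variants, paths["labelled"])
    write_annotations(dataset.annotations, paths["annotations"], manifest)
    write_af_lookup(dataset.af_lookup, paths["af"])
    write_inheritance_table(dataset.inheritance.values(), paths["inheritance"])
    return paths


def simulate_patient_cases(
    n_patients: int = 54,
    variants_per_patient: int = 300,
    causal_score_quantile: float = 0.99,
    seed: int = 0,
    tool: str = "boosted_tree",
    background_af_max: float = 0.5,
    causal_af: float = 1e-4,
) -> list[PatientCase]:
    """Simulate solved exomes: uniform background scores/AFs plus one
    designated causal variant whose score sits at the stated quantile of
    the patient's background score distribution (strictly above all
    background scores at quantile 1, strictly below at quantile 0)."""
    if variants_per_patient < 2:
        raise ValueError("variants_per_patient must be >= 2")
    rng = np.random.default_rng(seed)
    cons_pool = list(_default_consequence_mix())
    cases: list[PatientCase] = []
    for p in range(n_patients):
        n_bg = variants_per_patient - 1
        bg_scores = rng.random(n_bg)
        bg_af = rng.uniform(0.0, background_af_max, size=n_bg)
        if causal_score_quantile >= 1.0:
            c_score = float(bg_scores.max()) + 1e-9
        elif causal_score_quantile <= 0.0:
            c_score = max(float(bg_scores.min()) - 1e-9, 0.0)
        else:
            c_score = float(np.quantile(bg_scores, causal_score_quantile))
        keys = _unique_keys(rng, variants_per_patient)
        pvs = [
            PatientVariant(
                keys[j],
                float(bg_af[j]),
                cons_pool[int(rng.integers(len(cons_pool)))],
                {tool: float(bg_scores[j])},
            )
            for j in range(n_bg)
        ]
        causal = PatientVariant(
            keys[-1], causal_af, "missense", {tool: c_score}
        )
        pvs.append(causal)
        cases.append(PatientCase(f"P{p + 1:03d}", pvs, (causal.key,)))
    return cases


def write_patient_cases(
    cases: Sequence[PatientCase], cases_path: str | Path, causal_path: str | Path
) -> None:
    rows, causal_rows = [], []
    for case in cases:
        causal_set = set(case.causal_keys)
        for v in case.variants:
            for tool, score in v.scores.items():
                rows.append(
                    {
                        "patient_id": case.patient_id,
                        "chrom": v.key.chrom,
                        "pos": v.key.pos,
                        "ref": v.key.ref,
                        "alt": v.key.alt,
                        "af": repr(v.allele_frequency),
                        "consequence": v.consequence or "",
                        "tool": tool,
                        "score": "" if score is None else repr(score),
                    }
                )
        for k in causal_set:
            causal_rows.append(
                {
                    "patient_id": case.patient_id,
                    "chrom": k.chrom,
                    "pos": k.pos,
                    "ref": k.ref,
                    "alt": k.alt,
                }
            )
    cols = ["patient_id", "chrom", "pos", "ref", "alt", "af", "consequence", "tool", "score"]
    pd.DataFrame(rows, columns=cols).to_csv(cases_path, sep="\t", index=False)
    pd.DataFrame(
        causal_rows, columns=["patient_id", "chrom", "pos", "ref", "alt"]
    ).sort_values(["patient_id", "chrom", "pos"]).to_csv(causal_path, sep="\t", index=False)


def read_patient_cases(
    cases_path: str | Path, causal_path: str | Path
) -> list[PatientCase]:
    cases_df = pd.read_csv(cases_path, sep="\t", dtype=str, keep_default_na=False)
    causal_df = pd.read_csv(causal_path, sep="\t", dtype=str, keep_default_na=False)
    causal_by_patient: dict[str, list[VariantKey]] = {}
    for r in causal_df.to_dict("records"):
        causal_by_patient.setdefault(r["patient_id"], []).append(
            VariantKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        )
    grouped: dict[str, dict[VariantKey, dict]] = {}
    for r in cases_df.to_dict("records"):
        key = VariantKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        entry = grouped.setdefault(r["patient_id"], {}).setdefault(
            key,
            {
                "af": float(r["af"]),
                "consequence": r["consequence"] or None,
                "scores": {},
            },
        )
        entry["scores"][r["tool"]] = float(r["score"]) if r["score"] != "" else None
    cases = []
    for pid, by_key in grouped.items():
        variants = [
            PatientVariant(k, e["af"], e["consequence"], e["scores"])
            for k, e in by_key.items()
        ]
        cases.append(PatientCase(pid, variants, tuple(causal_by_patient.get(pid, ()))))
    return cases
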