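"""Domain types and table readers/writers for the pathogenicity pipeline.

Variants are identified VCF-style: 1-based positions, explicit ref/alt
alleles with anchor bases for InDels, no left-normalization (inputs are
assumed normalized). Chromosome names are normalized by stripping a
leading ``chr``. Labelled-variant tables, annotation tables and
gene-inheritance tables are all tab-separated text with a mandatory
header; empty cells or ``.`` denote missing values.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PATHOGENIC = "pathogenic"
NEUTRAL = "neutral"

VALID_CHROMS = frozenset(str(i) for i in range(1, 23)) | {"X", "Y", "MT"}

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: raw clinical-significance strings -> binary label.  "Likely" tiers are
#: collapsed onto their definite class; everything else is rejected.
LABEL_SYNONYMS: dict[str, str] = {
    "pathogenic": PATHOGENIC,
    "likely pathogenic": PATHOGENIC,
    "pathogenic/likely pathogenic": PATHOGENIC,
    "neutral": NEUTRAL,
    "likely neutral": NEUTRAL,
    "benign": NEUTRAL,
    "likely benign": NEUTRAL,
    "benign/likely benign": NEUTRAL,
}

#: inheritance-mode designations counted as dominant (case-insensitive).
DEFAULT_DOMINANT_TERMS = frozenset(
    {"ad", "xld", "autosomal dominant", "x-linked dominant"}
)

MISSING_CELL = {"", "."}


class SchemaMismatchError(ValueError):
    """An input table's columns do not match the declared feature schema."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "M":
        c = "MT"
    return c


def normalize_label(raw: str) -> str:
    key = str(raw).strip().lower().replace("_", " ")
    try:
        return LABEL_SYNONYMS[key]
    except KeyError:
        raise ValueError(f"unknown pathogenicity label: {raw!r}") from None


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a genomic variant: chrom, 1-based pos, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "pos", int(self.pos))
        if self.chrom not in VALID_CHROMS:
            raise ValueError(f"invalid chromosome: {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele or ""):
                raise ValueError(f"invalid {name} allele: {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical: {self.ref!r}")


@dataclass(frozen=True)
class ClassifiedVariant:
    """A variant with a pathogenicity label and provenance metadata.

    ``sample_weight`` encodes label trustworthiness (high-confidence 1.0,
    lower-confidence 0.8 by default; 0 excludes the variant from training).
    ``allele_frequency`` defaults to 0 for variants absent from the
    population lookup.
    """

    key: VariantKey
    label: str
    source: str = ""
    confidence: str | None = None
    sample_weight: float = 1.0
    consequence: str | None = None
    allele_frequency: float = 0.0
    review_level: str | None = None
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in (PATHOGENIC, NEUTRAL):
            raise ValueError(f"label must be pathogenic/neutral, got {self.label!r}")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele_frequency outside [0,1]: {self.allele_frequency}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant feature annotations; absent values are simply omitted
    from the mappings (distinguishable from zero)."""

    key: VariantKey
    categorical: Mapping[str, str] = field(default_factory=dict)
    numerical: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FeatureManifest:
    """Declared names of the categorical and numerical annotation features.

    Defaults to 11 categorical + 81 numerical placeholder names; real
    annotation exports supply their own manifest.
    """

    categorical_names: tuple[str, ...] = tuple(f"cat{i:02d}" for i in range(1, 12))
    numerical_names: tuple[str, ...] = tuple(f"num{i:02d}" for i in range(1, 82))

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.categorical_names + self.numerical_names


DEFAULT_MANIFEST = FeatureManifest()


@dataclass(frozen=True)
class InheritanceEntry:
    gene: str
    mode: str
    dominant: bool


class Reject(NamedTuple):
    line: int
    reason: str
    raw: str


class ParseResult(NamedTuple):
    variants: list[ClassifiedVariant]
    rejects: list[Reject]


_KEY_COLS = ["chrom", "pos", "ref", "alt"]
_REQUIRED_LABEL_COLS = _KEY_COLS + ["label", "source", "review_level"]
_OPTIONAL_LABEL_COLS = ["consequence", "af", "confidence", "sample_weight", "genes"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _row_to_variant(row: Mapping[str, str]) -> ClassifiedVariant:
    key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
    kwargs: dict = {
        "key": key,
        "label": normalize_label(row["label"]),
        "source": row.get("source", ""),
        "review_level": row.get("review_level") or None,
    }
    cons = row.get("consequence", "")
    if cons not in MISSING_CELL:
        kwargs["consequence"] = cons
    af = row.get("af", "")
    if af not in MISSING_CELL:
        kwargs["allele_frequency"] = float(af)
    conf = row.get("confidence", "")
    if conf not in MISSING_CELL:
        if conf not in ("high", "low"):
            raise ValueError(f"unknown confidence tier: {conf!r}")
        kwargs["confidence"] = conf
    w = row.get("sample_weight", "")
    if w not in MISSING_CELL:
        kwargs["sample_weight"] = float(w)
    genes = row.get("genes", "")
    if genes not in MISSING_CELL:
        kwargs["genes"] = tuple(g.strip().upper() for g in genes.split(",") if g.strip())
    return ClassifiedVariant(**kwargs)


def read_labelled_variants(
    path: str | Path,
    format: str = "tsv",
    label_info_key: str = "CLNSIG",
    review_info_key: str = "CLNREVSTAT",
    source: str | None = None,
) -> ParseResult:
    """Read a labelled-variant table; malformed rows are collected into a
    rejects report (with line numbers), never silently dropped.

    TSV columns: chrom, pos, ref, alt, label, source, review_level and
    optionally consequence, af, confidence, sample_weight, genes. For VCF,
    the label is taken from the INFO key ``label_info_key`` and
    multi-allelic rows are split into one record per alt.
    """
    if format == "tsv":
        return _read_labelled_tsv(path, source)
    if format == "vcf":
        return _read_labelled_vcf(path, label_info_key, review_info_key, source)
    raise ValueError(f"unknown format: {format!r}")


def _read_labelled_tsv(path: str | Path, source: str | None) -> ParseResult:
    df = _read_tsv(path)
    missing = [c for c in _REQUIRED_LABEL_COLS if c not in df.columns]
    if missing:
        raise SchemaMismatchError(f"labelled-variant table missing columns: {missing}")
    variants: list[ClassifiedVariant] = []
    rejects: list[Reject] = []
    for idx, row in enumerate(df.to_dict("records")):
        line = idx + 2  # 1-based, after the header
        try:
            v = _row_to_variant(row)
            if source is not None:
                v = replace(v, source=source)
            variants.append(v)
        except (ValueError, KeyError) as exc:
            rejects.append(Reject(line, str(exc), "\t".join(str(x) for x in row.values())))
    return ParseResult(variants, rejects)


def _read_labelled_vcf(
    path: str | Path, label_info_key: str, review_info_key: str, source: str | None
) -> ParseResult:
    from cyvcf2 import VCF

    variants: list[ClassifiedVariant] = []
    rejects: list[Reject] = []
    for i, rec in enumerate(VCF(str(path)), start=1):
        raw_label = rec.INFO.get(label_info_key)
        review = rec.INFO.get(review_info_key)
        for alt in rec.ALT:  # split multi-allelics per alt before keying
            raw = f"{rec.CHROM}:{rec.POS}:{rec.REF}>{alt}"
            try:
                if raw_label is None:
                    raise ValueError(f"INFO/{label_info_key} missing")
                key = VariantKey(rec.CHROM, rec.POS, rec.REF, alt)
                variants.append(
                    ClassifiedVariant(
                        key=key,
                        label=normalize_label(str(raw_label)),
                        source=source or "vcf",
                        review_level=str(review) if review is not None else None,
                    )
                )
            except ValueError as exc:
                rejects.append(Reject(i, str(exc), raw))
    return ParseResult(variants, rejects)


def write_labelled_variants(variants: Iterable[ClassifiedVariant], path: str | Path) -> None:
    """Write a labelled-variant TSV that round-trips through
    :func:`read_labelled_variants` field-by-field."""
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "label": v.label,
                "source": v.source,
                "review_level": v.review_level if v.review_level is not None else "",
                "consequence": v.consequence if v.consequence is not None else "",
                "af": repr(v.allele_frequency),
                "confidence": v.confidence if v.confidence is not None else "",
                "sample_weight": repr(v.sample_weight),
                "genes": ",".join(v.genes),
            }
        )
    cols = _REQUIRED_LABEL_COLS + _OPTIONAL_LABEL_COLS
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_annotations(
    path: str | Path, manifest: FeatureManifest = DEFAULT_MANIFEST
) -> list[AnnotationRecord]:
    """Read a per-variant annotation table (key columns + the declared
    feature columns). Empty or ``.`` cells are preserved as absent values."""
    df = _read_tsv(path)
    feature_cols = [c for c in df.columns if c not in _KEY_COLS]
    declared = set(manifest.all_names)
    observed = set(feature_cols)
    if observed != declared:
        extra = sorted(observed - declared)
        missing = sorted(declared - observed)
        raise SchemaMismatchError(
            f"annotation columns do not match declared schema; "
            f"unexpected={extra}, missing={missing}"
        )
    cat_set = set(manifest.categorical_names)
    records: list[AnnotationRecord] = []
    for row in df.to_dict("records"):
        key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        categorical: dict[str, str] = {}
        numerical: dict[str, float] = {}
        for name in manifest.all_names:
            cell = row[name]
            if cell in MISSING_CELL:
                continue
            if name in cat_set:
                categorical[name] = cell
            else:
                numerical[name] = float(cell)
        records.append(AnnotationRecord(key, categorical, numerical))
    return records


def write_annotations(
    records: Iterable[AnnotationRecord],
    path: str | Path,
    manifest: FeatureManifest = DEFAULT_MANIFEST,
) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "chrom": rec.key.chrom,
            "pos": rec.key.pos,
            "ref": rec.key.ref,
            "alt": rec.key.alt,
        }
        for name in manifest.categorical_names:
            row[name] = rec.categorical.get(name, "")
        for name in manifest.numerical_names:
            val = rec.numerical.get(name)
            row[name] = "" if val is None else repr(val)
        rows.append(row)
    cols = _KEY_COLS + list(manifest.all_names)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def classify_dominant(
    mode: str, dominant_terms: frozenset[str] | set[str] = DEFAULT_DOMINANT_TERMS
) -> bool:
    """True when an inheritance-mode string carries a dominant designation.

    Matches the whole string or any ``/``, ``,`` or ``;``-separated token
    against the (case-insensitive) dominant-term list, so compound modes
    like ``AD/AR`` count as dominant.
    """
    text = mode.strip().lower()
    terms = {t.lower() for t in dominant_terms}
    if text in terms:
        return True
    return any(tok.strip() in terms for tok in re.split(r"[/,;]", text))


def read_inheritance_table(
    path: str | Path,
    dominant_terms: frozenset[str] | set[str] = DEFAULT_DOMINANT_TERMS,
) -> dict[str, InheritanceEntry]:
    """Read a gene→inheritance-mode TSV (columns: gene, mode).

    Gene symbols are upper-cased; duplicate rows with conflicting modes
    resolve last-wins with a logged warning.
    """
    df = _read_tsv(path)
    if df.empty:
        logger.warning("inheritance table %s is empty", path)
        return {}
    if not {"gene", "mode"}.issubset(df.columns):
        raise SchemaMismatchError("inheritance table needs columns: gene, mode")
    mapping: dict[str, InheritanceEntry] = {}
    for row in df.to_dict("records"):
        gene = str(row["gene"]).strip().upper()
        mode = str(row["mode"]).strip()
        if gene in mapping and mapping[gene].mode != mode:
            logger.warning("conflicting inheritance modes for %s; keeping %r", gene, mode)
        mapping[gene] = InheritanceEntry(gene, mode, classify_dominant(mode, dominant_terms))
    return mapping


def write_inheritance_table(entries: Iterable[InheritanceEntry], path: str | Path) -> None:
    rows = [{"gene": e.gene, "mode": e.mode} for e in entries]
    pd.DataFrame(rows, columns=["gene", "mode"]).to_csv(path, sep="\t", index=False)


def read_af_lookup(path: str | Path) -> dict[VariantKey, float]:
    """Read a population allele-frequency TSV (chrom, pos, ref, alt, af)."""
    df = _read_tsv(path)
    lookup: dict[VariantKey, float] = {}
    for row in df.to_dict("records"):
        key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        lookup[key] = float(row["af"])
    return lookup


def write_af_lookup(lookup: Mapping[VariantKey, float], path: str | Path) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "af": repr(v)}
        for k, v in lookup.items()
    ]
    pd.DataFrame(rows, columns=_KEY_COLS + ["af"]).to_csv(path, sep="\t", index=False)
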