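"""Training/benchmark curation: dedup, conflict removal, carrier filter,
confidence weights, benchmark splitting and AF-balanced benchmark."""

import itertools

import pytest

from varboost.curation import (
    DEFAULT_AF_BIN_EDGES,
    CohortVariant,
    ConfidencePolicy,
    af_bin_index,
    assign_confidence,
    build_balanced_benchmark,
    build_population_neutral_set,
    curate,
    filter_dominant_population_variants,
    merge_and_deduplicate,
    split_high_confidence_benchmark,
)
from varboost.variants import ClassifiedVariant, InheritanceEntry, VariantKey


def cv(pos=100, label="pathogenic", source="clinvar", chrom="1", **kw):
    return ClassifiedVariant(
        key=VariantKey(chrom, pos, "A", "T"), label=label, source=source, **kw
    )


class TestMergeAndDeduplicate:
    def test_disjoint_sources_concatenate_with_zero_audit(self):
        a = [cv(pos=1), cv(pos=2)]
        b = [cv(pos=3, source="vkgl")]
        merged, audit = merge_and_deduplicate([a, b])
        assert merged == a + b
        assert audit.duplicates_removed == audit.conflicts_removed == 0

    @pytest.mark.parametrize(
        "la,lb", list(itertools.product(["pathogenic", "neutral"], repeat=2))
    )
    def test_label_pair_combinations(self, la, lb):
        # brute force over the 4 label pairs: conflicts drop the key,
        # agreements keep exactly one record
        a = [cv(label=la, source="clinvar")]
        b = [cv(label=lb, source="vkgl")]
        merged, audit = merge_and_deduplicate([a, b])
        if la != lb:
            assert merged == []
            assert audit.conflicts_removed == 1
            assert audit.conflict_records_removed == 2
        else:
            assert len(merged) == 1
            assert audit.duplicates_removed == 1

    def test_same_label_duplicate_keeps_priority_source(self):
        a = [cv(source="clinvar")]
        b = [cv(source="vkgl")]
        merged, _ = merge_and_deduplicate([b, a], source_priority=["clinvar", "vkgl"])
        assert merged[0].source == "clinvar"

    def test_idempotence(self):
        sources = [
            [cv(pos=1), cv(pos=2, label="neutral"), cv(pos=1)],
            [cv(pos=2, source="vkgl"), cv(pos=3)],
        ]
        merged, _ = merge_and_deduplicate(sources)
        again, audit = merge_and_deduplicate([merged])
        assert again == merged
        assert audit.duplicates_removed == 0 and audit.conflicts_removed == 0

    def test_record_conservation(self):
        sources = [
            [cv(pos=1), cv(pos=1, label="neutral"), cv(pos=2), cv(pos=2)],
        ]
        merged, audit = merge_and_deduplicate(sources)
        assert len(merged) + audit.duplicates_removed + audit.conflict_records_removed == 4

    def test_empty_input(self):
        merged, audit = merge_and_deduplicate([])
        assert merged == [] and audit.conflicts_removed == 0


DOM = {"GA": InheritanceEntry("GA", "AD", True), "GR": InheritanceEntry("GR", "AR", False)}


class TestDominantCarrierFilter:
    def test_population_variant_in_dominant_gene_removed(self):
        v = cv(label="neutral", source="population", genes=("GA",))
        kept, removed = filter_dominant_population_variants([v], DOM)
        assert kept == [] and removed == 1

    def test_population_variant_in_recessive_gene_kept(self):
        v = cv(label="neutral", source="population", genes=("GR",))
        kept, removed = filter_dominant_population_variants([v], DOM)
        assert kept == [v] and removed == 0

    def test_curated_source_untouched_even_in_dominant_gene(self):
        v = cv(label="neutral", source="clinvar", genes=("GA",))
        kept, removed = filter_dominant_population_variants([v], DOM)
        assert kept == [v] and removed == 0

    def test_unknown_gene_counts_as_non_dominant(self):
        from varboost.curation import CurationAudit

        audit = CurationAudit()
        v = cv(label="neutral", source="population", genes=("NOPE",))
        kept, _ = filter_dominant_population_variants([v], DOM, audit=audit)
        assert kept == [v]
        assert audit.unknown_gene_variants == 1


class TestConfidence:
    def test_multi_submitter_clinvar_is_high(self):
        v = cv(review_level="criteria provided, multiple submitters, no conflicts")
        out = assign_confidence(v, ConfidencePolicy())
        assert out.confidence == "high" and out.sample_weight == 1.0

    def test_single_submitter_clinvar_is_low(self):
        v = cv(review_level="criteria provided, single submitter")
        out = assign_confidence(v, ConfidencePolicy())
        assert out.confidence == "low" and out.sample_weight == 0.8

    def test_low_weight_zero_policy(self):
        v = cv(review_level="criteria provided, single submitter")
        out = assign_confidence(v, ConfidencePolicy(low_weight=0.0))
        assert out.sample_weight == 0.0

    @pytest.mark.parametrize(
        "review,expected",
        [
            ("1 lab, no conflicts", "high"),
            ("2 labs, no conflicts", "high"),
            ("1 lab, conflicting interpretations", "low"),
            (None, "low"),
        ],
    )
    def test_lab_consortium_rule(self, review, expected):
        v = cv(source="vkgl", review_level=review)
        assert assign_confidence(v, ConfidencePolicy()).confidence == expected

    def test_policy_weight_ordering_enforced(self):
        with pytest.raises(ValueError):
            ConfidencePolicy(high_weight=0.5, low_weight=0.8)


class TestBenchmarkSplit:
    def test_even_split(self):
        variants = [cv(pos=i) for i in range(1, 101)]
        bench, rest = split_high_confidence_benchmark(variants, 0.5, seed=1)
        assert len(bench) == 50 and len(rest) == 50
        assert {v.key for v in bench} | {v.key for v in rest} == {v.key for v in variants}

    def test_determinism(self):
        variants = [cv(pos=i) for i in range(1, 21)]
        b1, r1 = split_high_confidence_benchmark(variants, 0.5, seed=7)
        b2, r2 = split_high_confidence_benchmark(variants, 0.5, seed=7)
        assert b1 == b2 and r1 == r2

    def test_round_half_to_even(self):
        variants = [cv(pos=i) for i in range(1, 6)]
        bench, rest = split_high_confidence_benchmark(variants, 0.5, seed=0)
        assert (len(bench), len(rest)) == (2, 3)  # round(2.5) -> 2

    def test_empty_input(self):
        assert split_high_confidence_benchmark([], 0.5, seed=0) == ([], [])

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            split_high_confidence_benchmark([cv()], 1.0, seed=0)


def bv(pos, label, cons, af, source="clinvar"):
    return ClassifiedVariant(
        key=VariantKey("1", pos, "A", "T"),
        label=label,
        source=source,
        consequence=cons,
        allele_frequency=af,
    )


class TestBalancedBenchmark:
    def test_af_bin_indexing(self):
        assert af_bin_index(0.0) == 0
        assert af_bin_index(5e-5) == 2  # [1e-5, 1e-4)
        assert af_bin_index(1.0) == len(DEFAULT_AF_BIN_EDGES) - 2

    def test_quota_met_from_matching_bin(self):
        # 3 pathogenic missense in one AF bin; enough neutral available there
        path = [bv(i, "pathogenic", "missense", 5e-5) for i in range(1, 4)]
        neutral = [bv(100 + i, "neutral", "missense", 5e-5) for i in range(4)]
        neutral += [bv(200 + i, "neutral", "missense", 0.05) for i in range(6)]
        out, report = build_balanced_benchmark(path, neutral, seed=3)
        chosen_neutral = [v for v in out if v.label == "neutral"]
        assert len(chosen_neutral) == 3
        assert all(v.allele_frequency == 5e-5 for v in chosen_neutral)
        assert report.per_consequence["missense"]["shortfall"] == {}

    def test_shortfall_refilled_from_adjacent_bins(self):
        path = [bv(i, "pathogenic", "missense", 5e-5) for i in range(1, 4)]
        neutral = [bv(100, "neutral", "missense", 5e-5)]
        neutral += [bv(200 + i, "neutral", "missense", 5e-4) for i in range(5)]
        out, report = build_balanced_benchmark(path, neutral, seed=3)
        info = report.per_consequence["missense"]
        assert info["shortfall"] == {2: 2}
        assert sum(info["refilled"].values()) == 2
        assert len([v for v in out if v.label == "neutral"]) == 3

    def test_per_consequence_sizes_follow_min_rule(self):
        path = [bv(i, "pathogenic", "missense", 1e-5) for i in range(1, 6)]
        path += [bv(10 + i, "pathogenic", "frameshift", 1e-5) for i in range(2)]
        neutral = [bv(100 + i, "neutral", "missense", 1e-5) for i in range(5)]
        neutral += [bv(200 + i, "neutral", "frameshift", 1e-5) for i in range(9)]
        out, _ = build_balanced_benchmark(path, neutral, seed=0)
        by_cons = {}
        for v in out:
            by_cons.setdefault(v.consequence, []).append(v)
        assert len(by_cons["missense"]) == 10
        assert len(by_cons["frameshift"]) == 4

    def test_equal_class_counts_per_consequence(self, tiny_dataset):
        _, ds = tiny_dataset
        path = [v for v in ds.variants if v.label == "pathogenic"]
        neutral = [v for v in ds.variants if v.label == "neutral"]
        out, _ = build_balanced_benchmark(path, neutral, seed=5)
        per = {}
        for v in out:
            per.setdefault(v.consequence, [0, 0])[0 if v.label == "pathogenic" else 1] += 1
        for cons, (n_p, n_n) in per.items():
            assert n_p == n_n, cons

    def test_consequence_without_neutral_pool_excluded(self):
        path = [bv(1, "pathogenic", "startloss", 1e-5)]
        neutral = [bv(2, "neutral", "missense", 1e-5)]
        out, report = build_balanced_benchmark(path, neutral, seed=0)
        assert out == []
        assert report.skipped_consequences == ["startloss"]

    def test_identity_when_pool_already_matched(self):
        path = [bv(1, "pathogenic", "missense", 1e-5)]
        neutral = [bv(2, "neutral", "missense", 1e-5)]
        out, _ = build_balanced_benchmark(path, neutral, seed=0)
        assert sorted(v.key for v in out) == [path[0].key, neutral[0].key]


class TestPopulationNeutralSet:
    def key(self, pos):
        return VariantKey("1", pos, "A", "T")

    def test_selection_rules(self):
        training = {self.key(3)}
        cohort = [
            CohortVariant(self.key(1), True, 0.005),   # in
            CohortVariant(self.key(2), True, 0.02),    # AF too high
            CohortVariant(self.key(3), True, 0.005),   # seen in training
            CohortVariant(self.key(4), False, 0.005),  # failed QC
        ]
        out = build_population_neutral_set(cohort, training, af_cutoff=0.01)
        assert [v.key.pos for v in out] == [1]
        assert out[0].label == "neutral"


class TestCuratePipeline:
    def test_invariants_hold_end_to_end(self, tiny_dataset):
        _, ds = tiny_dataset
        dataset = curate([ds.variants], ds.inheritance, seed=9)
        train_keys = {v.key for v in dataset.training}
        bench_keys = {v.key for v in dataset.benchmark}
        assert train_keys.isdisjoint(bench_keys)
        assert len(train_keys) == len(dataset.training)
        assert len(bench_keys) == len(dataset.benchmark)
        # benchmark is class-balanced per consequence
        per = {}
        for v in dataset.benchmark:
            per.setdefault(v.consequence, [0, 0])[0 if v.label == "pathogenic" else 1] += 1
        assert all(p == n for p, n in per.values())
        # audit conservation across the whole pipeline
        audit = dataset.audit
        n_in = len(ds.variants)
        n_out = len(dataset.training) + len(dataset.benchmark)
        assert n_in == (
            n_out
            + audit.duplicates_removed
            + audit.conflict_records_removed
            + audit.dominant_gene_removed
        )
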