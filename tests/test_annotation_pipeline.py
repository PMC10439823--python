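"""Merging, round orchestration, iterative augmentation, length filter."""

import numpy as np
import pytest

from minite import (
    GenomeAssembly,
    IndexParams,
    PipelineParams,
    SequenceRecord,
    SimulationConfig,
    TEAnnotation,
    TELibraryEntry,
    annotate,
    annotate_round,
    build_index,
    evaluate_against_truth,
    extract_annotated_sequences,
    merge_annotations,
    simulate,
)

from conftest import coverage_array, random_annotations


class TestMergeAnnotations:
    def test_two_interval_merge_support_majority_family(self):
        merged = merge_annotations([
            TEAnnotation("chr1", 100, 300, "A", support=10),
            TEAnnotation("chr1", 250, 600, "B", support=4),
        ])
        assert len(merged) == 1
        m = merged[0]
        assert (m.first, m.last, m.family, m.support) == (100, 600, "A", 14)

    def test_family_tie_breaks_lexicographically(self):
        (m,) = merge_annotations([
            TEAnnotation("chr1", 1, 10, "Z", support=3),
            TEAnnotation("chr1", 5, 20, "B", support=3),
        ])
        assert m.family == "B"

    def test_disjoint_returned_sorted(self):
        anns = [TEAnnotation("chr2", 5, 9), TEAnnotation("chr1", 50, 60),
                TEAnnotation("chr1", 1, 10)]
        merged = merge_annotations(anns)
        assert [(a.seq_name, a.first, a.last) for a in merged] == [
            ("chr1", 1, 10), ("chr1", 50, 60), ("chr2", 5, 9)]

    def test_adjacent_but_not_overlapping_kept_separate(self):
        merged = merge_annotations([TEAnnotation("c", 1, 100),
                                    TEAnnotation("c", 101, 200)])
        assert len(merged) == 2

    def test_union_length_equals_per_base_oracle(self, rng):
        anns = random_annotations(rng, 50, ["c1", "c2"])
        merged = merge_annotations(anns)
        cov = coverage_array(anns, {"c1": 6_000, "c2": 6_000})
        oracle_bp = sum(int(v.sum()) for v in cov.values())
        assert sum(a.length for a in merged) == oracle_bp
        # merged intervals are non-overlapping per sequence
        for name in ("c1", "c2"):
            ivs = [(a.first, a.last) for a in merged if a.seq_name == name]
            for (f1, l1), (f2, l2) in zip(ivs, ivs[1:]):
                assert f2 > l1


@pytest.fixture()
def exact_dataset():
    return simulate(SimulationConfig(
        seed=17, genome_length=100_000, n_families=1,
        te_length_range=(2_000, 2_000), n_copies_per_family=10,
        substitution_rate=0.0, indel_rate=0.0, truncation_prob=0.0,
        nesting_prob=0.0))


class TestAnnotateRound:
    def test_planted_copies_recovered(self, exact_dataset):
        ds = exact_dataset
        params = PipelineParams()
        index = build_index(ds.genome, params.index)
        anns = annotate_round(ds.genome, index, ds.library, params)
        assert len(anns) == len(ds.truth)
        for a, t in zip(anns, sorted(ds.truth, key=lambda x: x.first)):
            ov = min(a.last, t.last) - max(a.first, t.first) + 1
            assert ov / t.length >= 0.95

    def test_empty_library_empty_result(self, exact_dataset):
        ds = exact_dataset
        index = build_index(ds.genome, IndexParams())
        assert annotate_round(ds.genome, index, [], PipelineParams()) == []

    def test_two_entries_same_locus_merge_to_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        genome = GenomeAssembly([SequenceRecord("chr1", seq)])
        lib = [TELibraryEntry("a", "F1", seq[2_000:2_800]),
               TELibraryEntry("b", "F2", seq[2_100:2_900])]
        index = build_index(genome, IndexParams())
        anns = annotate_round(genome, index, lib, PipelineParams())
        assert len(anns) == 1

    def test_null_genome_false_positive_rate(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        genome = GenomeAssembly([SequenceRecord("chr1", seq)])
        foreign = simulate(SimulationConfig(seed=99)).library
        index = build_index(genome, IndexParams())
        anns = annotate_round(genome, index, foreign, PipelineParams())
        assert sum(a.length for a in anns) <= 0.01 * genome.total_length


class TestExtractAnnotatedSequences:
    def test_substring_extraction(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1_000))
        genome = GenomeAssembly([SequenceRecord("chr1", seq)])
        (e,) = extract_annotated_sequences(
            genome, [TEAnnotation("chr1", 101, 500, "F")])
        assert e.seq == seq[100:500]
        assert len(e.seq) == 400
        assert e.id == "chr1_101_500"
        assert e.family == "F"

    def test_empty_annotations_empty_library(self, exact_dataset):
        assert extract_annotated_sequences(exact_dataset.genome, []) == []

    def test_extracted_entries_refind_their_locus(self, exact_dataset):
        ds = exact_dataset
        params = PipelineParams()
        index = build_index(ds.genome, params.index)
        anns = annotate_round(ds.genome, index, ds.library, params)
        extracted = extract_annotated_sequences(ds.genome, anns)
        re_anns = annotate_round(ds.genome, index, extracted, params)
        for orig in anns:
            ov = max(
                (min(orig.last, r.last) - max(orig.first, r.first) + 1
                 for r in re_anns if r.seq_name == orig.seq_name),
                default=0)
            assert ov / orig.length >= 0.95


class TestAnnotate:
    def test_single_iteration_equals_round_plus_filter(self, exact_dataset):
        ds = exact_dataset
        params = PipelineParams(iterations=1)
        direct = annotate(ds.genome, ds.library, params)
        index = build_index(ds.genome, params.index)
        manual = [a for a in
                  annotate_round(ds.genome, index, ds.library, params)
                  if a.length >= params.min_te_length]
        assert direct == manual

    def test_length_filter(self, rng):
        ds = simulate(SimulationConfig(
            seed=4, genome_length=50_000, n_families=1,
            te_length_range=(150, 150), n_copies_per_family=3,
            substitution_rate=0.0, indel_rate=0.0, truncation_prob=0.0,
            nesting_prob=0.0))
        strict = annotate(ds.genome, ds.library, PipelineParams())
        assert strict == []
        relaxed = annotate(ds.genome, ds.library,
                           PipelineParams(min_te_length=100))
        assert len(relaxed) == 3

    def test_monotone_coverage_in_iterations(self):
        ds = simulate(SimulationConfig(
            seed=21, genome_length=80_000, n_families=2,
            te_length_range=(1_000, 2_000), n_copies_per_family=5,
            substitution_rate=0.15, indel_rate=0.0, truncation_prob=0.0,
            nesting_prob=0.0))
        bp = []
        for it in (1, 2, 3):
            anns = annotate(ds.genome, ds.library,
                            PipelineParams(iterations=it, min_te_length=0))
            bp.append(sum(a.length for a in anns))
        assert bp[0] <= bp[1] <= bp[2]

    def test_output_sorted_nonoverlapping_in_bounds(self, exact_dataset):
        ds = exact_dataset
        anns = annotate(ds.genome, ds.library, PipelineParams())
        L = ds.genome.total_length
        keys = [(a.seq_name, a.first) for a in anns]
        assert keys == sorted(keys)
        for a in anns:
            assert 1 <= a.first <= a.last <= L
        for a, b in zip(anns, anns[1:]):
            if a.seq_name == b.seq_name:
                assert b.first > a.last

    def test_thread_count_does_not_change_output(self, exact_dataset):
        ds = exact_dataset
        one = annotate(ds.genome, ds.library, PipelineParams(threads=1))
        four = annotate(ds.genome, ds.library, PipelineParams(threads=4))
        assert one == four

    def test_divergent_copies_recovered(self):
        ds = simulate(SimulationConfig(
            seed=11, genome_length=100_000, n_families=3,
            te_length_range=(1_500, 2_500), n_copies_per_family=7,
            substitution_rate=0.10, indel_rate=0.0, truncation_prob=0.0,
            nesting_prob=0.0))
        anns = annotate(ds.genome, ds.library, PipelineParams())
        res = evaluate_against_truth(anns, ds.truth)
        assert res.frac_b_in_a >= 0.95  # sensitivity
        assert res.frac_a_in_b >= 0.95  # precision
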