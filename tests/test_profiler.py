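import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmove import (
    AnchoredCounts,
    CollapsedRead,
    IsoformCounts,
    MatureAnnotation,
    ModificationProfile,
    ReferenceBundle,
    anchored_counts,
    classify_anchored,
    clip_adapter,
    clip_adapters,
    collapse,
    isoform_counts,
    isoform_index,
    log_uniform_abundances,
    make_reference,
    simulate_reads,
    summarize_distribution,
    trim_tail_index,
)

from tests.oracles import (
    brute_anchored_counts,
    brute_isoform_counts,
)

ADAPTER = "TGGAATTCTCGG"


class TestClipAdapter:
    def test_full_adapter_clipped(self):
        insert = "ACGTACGTACGTACGTACGT"  # 20 nt
        assert clip_adapter(insert + ADAPTER, ADAPTER) == insert

    def test_short_insert_discarded(self):
        insert = "ACGTACGTACGT"  # 12 nt < 15
        assert clip_adapter(insert + ADAPTER, ADAPTER) is None

    def test_no_adapter_discarded(self):
        assert clip_adapter("ACGTACGTACGTACGTACGTACGT", ADAPTER) is None

    def test_partial_adapter_prefix_at_three_prime_end(self):
        insert = "ACGTACGTACGTACGTACGT"
        read = insert + ADAPTER[:8]  # partially sequenced adapter
        assert clip_adapter(read, ADAPTER) == insert
        assert clip_adapter(insert + ADAPTER[:7], ADAPTER) is None

    def test_batch_statistics(self):
        insert = "ACGTACGTACGTACGTACGT"
        reads = [insert + ADAPTER, "A" * 12 + ADAPTER, "G" * 30]
        kept, stats = clip_adapters(reads, ADAPTER)
        assert kept == [insert]
        assert (stats.n_input, stats.n_kept) == (3, 1)
        assert (stats.n_too_short, stats.n_no_adapter) == (1, 1)


class TestCollapse:
    def test_basic_grouping(self):
        out = collapse(["AAA", "AAA", "AAC"])
        assert [(c.sequence, c.count) for c in out] == [("AAA", 2), ("AAC", 1)]

    def test_empty(self):
        assert collapse([]) == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=8),
                    max_size=200))
    def test_counts_conserved_and_unique(self, reads):
        out = collapse(reads)
        assert sum(c.count for c in out) == len(reads)
        seqs = [c.sequence for c in out]
        assert len(seqs) == len(set(seqs))
        counts = [c.count for c in out]
        assert counts == sorted(counts, reverse=True) or all(
            (a > b) or (a == b and sa < sb)
            for (a, sa), (b, sb) in zip(zip(counts, seqs), zip(counts[1:], seqs[1:]))
        )


class TestClassifyAnchored:
    def test_exact(self, toy_ref):
        ann = toy_ref.annotations[0]
        assert classify_anchored(ann.mature_seq, ann, toy_ref) == "exact"

    def test_trimmed_is_shorter(self, toy_ref):
        ann = toy_ref.annotations[0]
        assert classify_anchored(ann.mature_seq[:-3], ann, toy_ref) == "shorter"

    def test_tailed_is_longer(self, toy_ref):
        ann = toy_ref.annotations[0]
        assert classify_anchored(ann.mature_seq + "TTT", ann, toy_ref) == "longer"

    def test_27nt_read_unanchored(self, toy_ref):
        ann = toy_ref.annotations[0]
        read = ann.mature_seq + "TTTTTT"  # 27 nt
        assert len(read) == 27
        assert classify_anchored(read, ann, toy_ref) == "unanchored"

    def test_internal_five_prime_start_unanchored(self, toy_ref):
        ann = toy_ref.annotations[0]
        # starts 1 nt inside the mature: 5' positions disagree
        read = ann.mature_seq[1:] + "C"
        assert classify_anchored(read, ann, toy_ref) == "unanchored"

    def test_same_length_mismatch_needs_allowance(self, toy_ref):
        ann = toy_ref.annotations[0]
        read = ann.mature_seq[:10] + ("A" if ann.mature_seq[10] != "A" else "C") \
            + ann.mature_seq[11:]
        assert classify_anchored(read, ann, toy_ref) == "unanchored"
        assert classify_anchored(read, ann, toy_ref,
                                 max_templated_mismatch=1) == "anomalous"

    def test_minus_strand_anchoring(self, small_ref):
        minus = [a for a in small_ref.annotations if a.strand == "-"]
        ann = minus[0]
        assert classify_anchored(ann.mature_seq, ann, small_ref) == "exact"
        assert classify_anchored(ann.mature_seq[:-1], ann, small_ref) == "shorter"


class TestAnchoredCounts:
    def test_constructed_partition(self, toy_ref):
        ann = toy_ref.annotations[0]
        reads = (
            [ann.mature_seq] * 10
            + [ann.mature_seq + "TT"] * 5
            + [ann.mature_seq[:-2]] * 3
        )
        (rec,) = anchored_counts(collapse(reads), toy_ref, "s1")
        assert (rec.n_mature, rec.n_longer, rec.n_shorter, rec.n_anomalous) == \
            (10, 5, 3, 0)
        assert rec.total == 18

    def test_identical_mature_at_two_loci_counted_at_both(self):
        mature = "TTAAGTGTCACGGAAATCCCT"
        genome = "A" * 20 + mature + "G" * 20 + mature + "C" * 20
        anns = [
            MatureAnnotation("m1", "chr1", 20, 41, "+", mature),
            MatureAnnotation("m2", "chr1", 61, 82, "+", mature),
        ]
        ref = ReferenceBundle(genome, anns)
        ref.validate()
        recs = anchored_counts(collapse([mature]), ref, "s1")
        assert all(r.n_mature == 1 for r in recs)
        brute = brute_anchored_counts(collapse([mature]), ref)
        assert all(brute[r.mirna_id]["exact"] == r.n_mature for r in recs)

    def test_max_loci_cap_drops_promiscuous_reads(self):
        mature = "TTAAGTGTCACGGAAATCCCT"
        genome = ("A" * 20 + mature) * 3 + "A" * 20
        anns = [
            MatureAnnotation(f"m{i}", "chr1", 20 + i * 41, 41 + i * 41, "+", mature)
            for i in range(3)
        ]
        ref = ReferenceBundle(genome, anns)
        ref.validate()
        recs = anchored_counts(collapse([mature]), ref, "s1", max_loci=2)
        assert all(r.n_mature == 0 for r in recs)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equality_with_brute_force_on_random_reads(self, seed):
        ref = make_reference(8, genome_length=2000, seed=seed)
        abund = log_uniform_abundances([a.id for a in ref.annotations], seed)
        profile = ModificationProfile(p_exact=0.5, p_trim=0.2, p_tail=0.2,
                                      p_iso=0.1)
        reads, _ = simulate_reads(ref, abund, profile, depth=1000, seed=seed + 10)
        rng = np.random.default_rng(seed)
        junk = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(16, 30))))
                for _ in range(100)]
        collapsed = collapse(reads + junk)
        recs = anchored_counts(collapsed, ref, "s1")
        brute = brute_anchored_counts(collapsed, ref)
        for rec in recs:
            b = brute[rec.mirna_id]
            assert (rec.n_mature, rec.n_shorter, rec.n_longer, rec.n_anomalous) \
                == (b["exact"], b["shorter"], b["longer"], b["anomalous"])

    def test_labels_agree_with_truth(self, small_ref):
        """Classification agrees with the simulator's expected labels for
        >= 99.9% of reads at zero mismatch allowance."""
        abund = {a.id: 1.0 for a in small_ref.annotations}
        profile = ModificationProfile(p_exact=0.5, p_trim=0.2, p_tail=0.2,
                                      p_iso=0.1)
        _, truth = simulate_reads(small_ref, abund, profile, depth=5000, seed=6)
        ann_by_id = {a.id: a for a in small_ref.annotations}
        agree = sum(
            classify_anchored(row.insert, ann_by_id[row.mirna_id], small_ref)
            == row.expected_anchor_class
            for row in truth.itertuples(index=False)
        )
        assert agree / len(truth) >= 0.999


class TestTrimTailIndex:
    def test_log2_arithmetic(self):
        rec = trim_tail_index(AnchoredCounts("m", "s", n_mature=16, n_shorter=4,
                                             n_longer=8))
        assert rec.trim_index == -2.0
        assert rec.tail_index == -1.0

    def test_zero_mature_undefined(self):
        rec = trim_tail_index(AnchoredCounts("m", "s", n_mature=0, n_shorter=4,
                                             n_longer=8))
        assert math.isnan(rec.trim_index) and math.isnan(rec.tail_index)

    def test_zero_numerator_only_that_index_undefined(self):
        rec = trim_tail_index(AnchoredCounts("m", "s", n_mature=10, n_shorter=0,
                                             n_longer=5))
        assert math.isnan(rec.trim_index)
        assert rec.tail_index == math.log2(0.5)

    def test_pseudocount_mode_defines_all(self):
        rec = trim_tail_index(AnchoredCounts("m", "s", n_mature=0, n_shorter=0,
                                             n_longer=0), pseudocount=True)
        assert rec.trim_index == 0.0 and rec.tail_index == 0.0

    def test_monotonicity_under_added_reads(self):
        base = AnchoredCounts("m", "s", n_mature=10, n_shorter=3, n_longer=4)
        tail0 = trim_tail_index(base).tail_index
        more_tail = AnchoredCounts("m", "s", 10, 3, 5)
        assert trim_tail_index(more_tail).tail_index > tail0
        more_exact = AnchoredCounts("m", "s", 11, 3, 4)
        rec = trim_tail_index(more_exact)
        assert rec.tail_index < tail0
        assert rec.trim_index < trim_tail_index(base).trim_index


class TestIsoformCounts:
    def test_exact_read_is_qualifying_not_other(self, toy_ref):
        ann = toy_ref.annotations[0]
        (rec,) = isoform_counts(collapse([ann.mature_seq]), toy_ref, "s1")
        assert (rec.n_qualifying, rec.n_exact, rec.n_other) == (1, 1, 0)

    def test_templated_five_prime_extension_counts_as_other(self, toy_ref):
        ann = toy_ref.annotations[0]
        extended = toy_ref.genome[ann.start - 1 : ann.end]  # L+1, templated
        (rec,) = isoform_counts(collapse([extended]), toy_ref, "s1")
        assert (rec.n_qualifying, rec.n_exact, rec.n_other) == (1, 0, 1)

    def test_internal_mismatch_not_qualifying(self, toy_ref):
        ann = toy_ref.annotations[0]
        seq = ann.mature_seq
        mutated = seq[:10] + ("A" if seq[10] != "A" else "C") + seq[11:]
        (rec,) = isoform_counts(collapse([mutated]), toy_ref, "s1")
        assert rec.n_qualifying == 0

    def test_length_outside_tolerance_excluded(self, toy_ref):
        ann = toy_ref.annotations[0]
        ext2 = toy_ref.genome[ann.start - 2 : ann.end]  # templated but L+2
        (rec,) = isoform_counts(collapse([ext2]), toy_ref, "s1")
        assert rec.n_qualifying == 0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_equality_with_substring_enumeration_oracle(self, seed):
        ref = make_reference(8, genome_length=2000, seed=seed)
        abund = log_uniform_abundances([a.id for a in ref.annotations], seed)
        profile = ModificationProfile(p_exact=0.4, p_trim=0.1, p_tail=0.1,
                                      p_iso=0.4)
        reads, _ = simulate_reads(ref, abund, profile, depth=1000, seed=seed)
        collapsed = collapse(reads)
        recs = isoform_counts(collapsed, ref, "s1")
        brute = brute_isoform_counts(collapsed, ref)
        for rec in recs:
            assert (rec.n_qualifying, rec.n_exact) == brute[rec.mirna_id]
            assert rec.n_other >= 0
            assert rec.n_exact + rec.n_other == rec.n_qualifying


class TestIsoformIndex:
    DESIGN = {"wt1": "WT", "wt2": "WT", "mut1": "mut", "mut2": "mut"}

    @staticmethod
    def _counts(mirna, per_sample):
        return {
            sample: [IsoformCounts(mirna, sample, n_qualifying=q, n_exact=e)]
            for sample, (q, e) in per_sample.items()
        }

    def test_retained_when_one_genotype_passes_in_all_replicates(self):
        counts = self._counts("m", {"wt1": (6, 4), "wt2": (7, 5),
                                    "mut1": (1, 1), "mut2": (2, 1)})
        out = isoform_index(counts, self.DESIGN)
        assert {r.sample_id for r in out} == {"wt1", "wt2", "mut1", "mut2"}

    def test_dropped_when_no_genotype_passes_everywhere(self):
        counts = self._counts("m", {"wt1": (4, 2), "wt2": (6, 3),
                                    "mut1": (3, 2), "mut2": (6, 3)})
        assert isoform_index(counts, self.DESIGN) == []

    def test_index_value(self):
        counts = self._counts("m", {"wt1": (10, 8), "wt2": (10, 8),
                                    "mut1": (10, 8), "mut2": (10, 8)})
        out = isoform_index(counts, self.DESIGN)
        assert all(r.iso_index == 2.0 for r in out)  # log2(8/2)

    def test_undefined_when_no_other_reads(self):
        counts = self._counts("m", {"wt1": (8, 8), "wt2": (8, 8),
                                    "mut1": (8, 8), "mut2": (8, 8)})
        out = isoform_index(counts, self.DESIGN)
        assert all(math.isnan(r.iso_index) for r in out)

    def test_unknown_sample_raises(self):
        counts = self._counts("m", {"mystery": (8, 8)})
        with pytest.raises(KeyError, match="mystery"):
            isoform_index(counts, self.DESIGN)


class TestSummarizeDistribution:
    def test_small_example(self):
        s = summarize_distribution([1, 2, 3, 4, 5])
        assert (s["median"], s["q1"], s["q3"]) == (3, 2, 4)
        assert (s["whisker_low"], s["whisker_high"]) == (1, 5)
        assert s["n_defined"] == 5

    def test_empty_input(self):
        s = summarize_distribution([])
        assert s["n_defined"] == 0
        assert math.isnan(s["median"])

    def test_nan_excluded_and_counted(self):
        s = summarize_distribution([1.0, math.nan, 3.0])
        assert (s["n_defined"], s["n_missing"]) == (2, 1)
        assert s["median"] == 2.0

    def test_normal_sample_median_near_zero(self):
        rng = np.random.default_rng(0)
        s = summarize_distribution(rng.standard_normal(10_000))
        assert abs(s["median"]) < 0.05
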