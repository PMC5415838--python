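"""Read-cleaning cascade: quality rules, trimming, contaminants, collapsing."""

from collections import Counter

import pytest

from mirstage.preprocess import (
    ADAPTER3,
    ADAPTER5,
    ReadRecord,
    classify_contaminants,
    clean_library,
    collapse_tags,
    quality_filter,
    summarize_cleaning,
    trim_adapter3,
)


def _read(seq, quals=None):
    return ReadRecord("r", seq, tuple(quals or [40] * len(seq)))


class TestQualityFilter:
    def test_n_base_fails(self):
        ok, reason = quality_filter(_read("ACGTN" + "A" * 20))
        assert not ok and reason == "N"

    def test_four_bases_below_q10_is_still_high_quality(self):
        quals = [9] * 4 + [40] * 21
        assert quality_filter(_read("A" * 25, quals))[0]

    def test_five_bases_below_q10_fails(self):
        quals = [9] * 5 + [40] * 20
        ok, reason = quality_filter(_read("A" * 25, quals))
        assert not ok and reason == "low_quality_q10"

    def test_seven_bases_below_q13_fails(self):
        quals = [12] * 7 + [40] * 18
        ok, reason = quality_filter(_read("A" * 25, quals))
        assert not ok and reason == "low_quality_q13"

    def test_length_mismatch_is_malformed(self):
        with pytest.raises(ValueError):
            ReadRecord("r", "ACGT", (40, 40))


class TestTrimAdapter:
    def test_exact_adapter_after_insert(self):
        insert = "ACGTACGT" + "TGCATGCATG"
        seq, status = trim_adapter3(insert + ADAPTER3)
        assert status is None and seq == insert

    def test_read_equal_to_adapter_is_null_insert(self):
        _, status = trim_adapter3(ADAPTER3 + "ACGT")
        assert status == "insert_null"

    def test_no_adapter_occurrence(self):
        _, status = trim_adapter3("ACGT" * 12)
        assert status == "adaptor3_null"

    def test_one_mismatch_per_10nt_tolerated(self):
        bad = "A" + ADAPTER3[1:10] + "A" + ADAPTER3[11:]  # 2 mm in 21 nt
        insert = "CGCGCGTATATACGCGCGTATA"
        seq, status = trim_adapter3(insert + bad)
        assert status is None and seq == insert

    def test_terminal_partial_prefix_match(self):
        insert = "CGCGCGTATATACGCGCGTATA"
        seq, status = trim_adapter3(insert + ADAPTER3[:7])
        assert status is None and seq == insert

    def test_empty_adapter_is_config_error(self):
        with pytest.raises(ValueError):
            trim_adapter3("ACGT", "")


class TestClassifyContaminants:
    def test_five_prime_adapter_with_one_mismatch(self):
        ins = "A" + ADAPTER5[1:] + "ACG"
        assert classify_contaminants(ins) == "adaptor5_contaminants"

    def test_17nt_is_too_short(self):
        assert classify_contaminants("CGTACGTACGTACGTAC") == "smaller_than_18nt"

    def test_pure_a_is_polya(self):
        assert classify_contaminants("A" * 22) == "polyA"

    def test_80pct_a_is_polya(self):
        ins = "A" * 16 + "CGTA"  # 17/20 A
        assert classify_contaminants(ins) == "polyA"

    def test_oversize_goes_to_dedicated_bucket(self):
        assert classify_contaminants("ACGT" * 8) == "larger_than_30nt"

    def test_ordinary_22mer_is_clean(self):
        assert classify_contaminants("ACGTACGTACGTACGTACGTAC") == "clean"


class TestSummarize:
    def test_printed_library_arithmetic(self):
        s = summarize_cleaning(6_000_000, 5_984_373, 2916, 3115, 86464, 20713, 110)
        assert s.clean_reads == 5_871_055
        assert s.percentage(s.clean_reads) == 98.11

    def test_all_zero(self):
        s = summarize_cleaning(0, 0, 0, 0, 0, 0, 0)
        assert s.clean_reads == 0 and s.percentage(0) == 0.0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            summarize_cleaning(10, 5, 4, 4, 0, 0, 0)


def test_collapse_tags_counts_and_histogram():
    per_lib = {
        "a": Counter({"ACGT" * 5: 2, "TGCA" * 5: 1}),
        "b": Counter({"ACGT" * 5: 3}),
    }
    ts = collapse_tags(per_lib)
    assert ts.counts["ACGT" * 5] == [2, 3]
    assert ts.counts["TGCA" * 5] == [1, 0]
    assert ts.length_histogram["a"] == {20: 3}
    assert ts.total("a") == 3 and ts.total("b") == 3


def test_cleaning_matches_truth_exactly_without_errors(tmp_path):
    """With error_rate=0 every provenance label lands in its own category."""
    from collections import Counter as C

    from mirstage.synthio import SyntheticConfig, generate, simulate_reads

    cfg = SyntheticConfig(
        seed=9, genome_length=150_000, n_known_precursors=6,
        n_novel_precursors=2, library_sizes=(3000, 3000, 3000),
        de_spec=(), error_rate=0.0,
    )
    ds = generate(cfg)
    reads, labels = simulate_reads(cfg, ds.truth, 0)
    res = clean_library(reads)
    truth = C(lab.split(":")[0] for lab in labels)
    s = res.summary
    assert s.total_reads == 3000
    assert s.high_quality == 3000 - truth["low_quality"]
    assert s.adaptor3_null == truth["adaptor3_null"]
    assert s.insert_null == truth["insert_null"]
    assert s.adaptor5_contaminants == truth["adaptor5_contaminants"]
    assert s.smaller_than_18nt == truth["smaller_than_18nt"]
    assert s.polyA == truth["polyA"]
    assert s.clean_reads == 3000 - sum(
        truth[k] for k in (
            "low_quality", "adaptor3_null", "insert_null",
            "adaptor5_contaminants", "smaller_than_18nt", "polyA",
        )
    )
    # category partition: counts plus clean add back to high quality
    assert (
        s.adaptor3_null + s.insert_null + s.adaptor5_contaminants
        + s.smaller_than_18nt + s.polyA + s.larger_than_30nt + s.clean_reads
        == s.high_quality
    )


def test_recleaning_collapsed_inserts_is_idempotent(small_dataset):
    from mirstage.synthio import simulate_reads

    reads, _ = simulate_reads(small_dataset.config, small_dataset.truth, 0)
    first = clean_library(reads)
    # feed the clean inserts back through as adapter-carrying reads
    again = clean_library(
        (f"r{i}", ins + ADAPTER3, [40] * (len(ins) + len(ADAPTER3)))
        for i, ins in enumerate(first.inserts.elements())
    )
    assert again.inserts == first.inserts
    assert again.summary.clean_reads == first.summary.clean_reads
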