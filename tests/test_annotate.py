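"""Genome mapping and the annotation priority cascade."""

from collections import Counter

import numpy as np
import pytest

from mirstage._fio import Feature, revcomp
from mirstage.annotate import (
    DEFAULT_PRIORITY,
    FeatureIndex,
    annotation_percentage,
    annotate_tags,
    classify_tag,
    map_tags,
    summarize_annotation,
)
from mirstage.preprocess import collapse_tags


def _naive_hits(tag, genome):
    """Sliding-window oracle for exact matching on both strands."""
    hits = []
    for contig, seq in genome.items():
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            for i in range(len(seq) - len(query) + 1):
                if seq[i : i + len(query)] == query:
                    hits.append((contig, i, strand))
    return sorted(set(hits))


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    tag = seq[1000:1022]
    return {"c1": seq}, tag


def test_planted_tag_found_at_plus_strand(toy_genome):
    genome, tag = toy_genome
    alns, _ = map_tags([tag], genome)
    hit = [a for a in alns[tag] if a.strand == "+"]
    assert any(a.start == 1000 and a.end == 1022 for a in hit)


def test_reverse_complement_found_on_minus_strand(toy_genome):
    genome, _ = toy_genome
    tag = revcomp(genome["c1"][2000:2022])
    alns, _ = map_tags([tag], genome)
    assert any(a.strand == "-" and a.start == 2000 for a in alns[tag])


def test_map_agrees_with_sliding_window_oracle(toy_genome):
    genome, _ = toy_genome
    rng = np.random.default_rng(3)
    tags = [genome["c1"][i : i + 20] for i in rng.integers(0, 4900, 15)]
    tags += ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(5)]
    alns, _ = map_tags(tags, genome)
    for t in tags:
        got = sorted({(a.contig, a.start, a.strand) for a in alns[t]})
        assert got == _naive_hits(t, genome)


def test_multilocus_tag_reports_all_loci():
    unit = "ACGTGACTGACTGGCCTAAG"
    genome = {"c1": ("T" * 30).join([unit] * 12) + "T" * 50}
    alns, _ = map_tags([unit], genome)
    assert sum(a.strand == "+" for a in alns[unit]) == 12


def test_non_acgt_tags_are_skipped(toy_genome):
    genome, tag = toy_genome
    alns, skipped = map_tags([tag, "ACGTNNACGTACGTACGTAC"], genome)
    assert skipped == 1 and tag in alns


class TestClassify:
    def _aln(self, tag, start, strand="+"):
        from mirstage.annotate import TagAlignment

        return TagAlignment(tag, "c1", start, start + len(tag), strand, 0)

    def test_mirna_outranks_repeat(self):
        idx = FeatureIndex(
            [
                Feature("c1", 100, 200, "+", "repeat", "rep1"),
                Feature("c1", 150, 220, "+", "miRNA", "mir1"),
            ]
        )
        rec = classify_tag("T" * 20, [self._aln("T" * 20, 160)], idx)
        assert rec.category == "miRNA" and rec.feature_id == "mir1"

    def test_no_feature_is_unann(self):
        rec = classify_tag("T" * 20, [self._aln("T" * 20, 10)], FeatureIndex([]))
        assert rec.category == "unann" and rec.feature_id is None

    def test_antisense_exon_strand_rule(self):
        idx = FeatureIndex([Feature("c1", 100, 400, "+", "exon", "e1")])
        rec = classify_tag("T" * 20, [self._aln("T" * 20, 150, "-")], idx)
        assert rec.category == "exon_antisense"

    def test_priority_respected_across_loci(self):
        idx = FeatureIndex(
            [
                Feature("c1", 100, 200, "+", "tRNA", "t1"),
                Feature("c1", 500, 600, "+", "rRNA", "r1"),
            ]
        )
        rec = classify_tag(
            "T" * 20, [self._aln("T" * 20, 120), self._aln("T" * 20, 520)], idx
        )
        assert rec.category == "rRNA"  # rRNA outranks tRNA in the cascade
        assert DEFAULT_PRIORITY.index("rRNA") < DEFAULT_PRIORITY.index("tRNA")


def test_percentage_formatting_matches_half_up():
    assert annotation_percentage(4844028, 5871055) == 82.51
    assert annotation_percentage(1, 1) == 100.0


def test_summary_percentages_sum_to_100(small_dataset):
    from mirstage.preprocess import clean_library
    from mirstage.synthio import simulate_reads

    per_lib = {}
    for s in range(3):
        reads, _ = simulate_reads(small_dataset.config, small_dataset.truth, s)
        per_lib[f"stage{s}"] = clean_library(reads).inserts
    tagset = collapse_tags(per_lib)
    records = annotate_tags(tagset, small_dataset.genome, small_dataset.features)
    df = summarize_annotation(records, tagset)
    for lib in ("stage0", "stage1", "stage2"):
        body = df.drop(index="Total")
        assert body[f"{lib}_reads"].sum() == df.at["Total", f"{lib}_reads"]
        assert abs(body[f"{lib}_reads_pct"].sum() - 100) <= 0.05
        assert abs(body[f"{lib}_unique_pct"].sum() - 100) <= 0.05


def test_classification_agrees_with_truth_labels():
    """Error-free reads annotate to their planted class >= 99.9 % of reads."""
    from mirstage.preprocess import clean_library
    from mirstage.synthio import SyntheticConfig, generate, simulate_reads

    cfg = SyntheticConfig(
        seed=9, genome_length=150_000, n_known_precursors=6,
        n_novel_precursors=2, library_sizes=(3000, 3000, 3000),
        de_spec=(), error_rate=0.0,
    )
    ds = generate(cfg)
    reads, labels = simulate_reads(cfg, ds.truth, 0)
    res = clean_library(reads)
    tagset = collapse_tags({"stage0": res.inserts})
    records = annotate_tags(tagset, ds.genome, ds.features)

    from mirstage.preprocess import classify_contaminants, trim_adapter3

    agree = total = 0
    truth_by_insert: dict[str, Counter] = {}
    for (rid, seq, q), lab in zip(reads, labels):
        ins, status = trim_adapter3(seq)
        if status is not None or classify_contaminants(ins) != "clean":
            continue
        cls = lab.split(":")[0]
        if cls in ("novel", "novel_star"):
            cls = "unann"
        truth_by_insert.setdefault(ins, Counter())[cls] += 1
    for ins, cats in truth_by_insert.items():
        n = sum(cats.values())
        total += n
        if records[ins].category in cats:
            agree += n
    assert total > 0
    assert agree / total >= 0.999
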