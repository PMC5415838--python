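"""Generator contracts: determinism, composition, closure, planted effects."""

from collections import Counter

import numpy as np
import pytest

from mirstage import synthio
from mirstage.synthio import (
    SyntheticConfig,
    build_truth,
    dinucleotide_shuffle,
    generate,
    make_genome,
    plant_hairpin,
    simulate_reads,
)

SMALL = dict(
    genome_length=150_000, n_known_precursors=6, n_novel_precursors=2,
    library_sizes=(2000, 2000, 2000), de_spec=(),
)


class TestDeterminism:
    def test_same_seed_identical_genome_and_reads(self):
        cfg1 = SyntheticConfig(seed=31, **SMALL)
        ds1 = generate(cfg1)
        r1, l1 = simulate_reads(cfg1, ds1.truth, 1)
        synthio._GENOME_CACHE.clear()
        cfg2 = SyntheticConfig(seed=31, **SMALL)
        ds2 = generate(cfg2)
        r2, l2 = simulate_reads(cfg2, ds2.truth, 1)
        assert ds1.genome == ds2.genome
        assert r1 == r2 and l1 == l2

    def test_seed_change_changes_reads(self):
        ds = generate(SyntheticConfig(seed=32, **SMALL))
        r1, _ = simulate_reads(ds.config, ds.truth, 0)
        ds2 = generate(SyntheticConfig(seed=33, **SMALL))
        r2, _ = simulate_reads(ds2.config, ds2.truth, 0)
        assert [s for _, s, _ in r1] != [s for _, s, _ in r2]


class TestGenome:
    def test_truth_has_all_precursor_rows(self, small_dataset):
        cfg = small_dataset.config
        assert (
            len(small_dataset.truth.precursors)
            == cfg.n_known_precursors + cfg.n_novel_precursors
        )

    def test_gc_fraction_within_binomial_bound(self):
        # sd of observed GC at L=1e5, p=0.5 is ~0.0016; 0.02 is >10 sigma
        g = synthio._draw_genome(np.random.default_rng(1), 10**5, 0.5)
        s = g.tobytes().decode()
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.5) < 0.02

    def test_features_do_not_overlap(self, small_dataset):
        ivs = sorted((f.start, f.end) for f in small_dataset.features)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_insufficient_space_raises(self):
        with pytest.raises(ValueError):
            make_genome(SyntheticConfig(seed=1, genome_length=20_000))

    def test_planted_sequences_match_genome(self, small_dataset):
        g = small_dataset.genome["chr1"]
        for p in small_dataset.truth.precursors:
            assert g[p.start : p.end] == p.sequence.replace("U", "T")


class TestPlantHairpin:
    def test_zero_mismatch_star_is_reverse_complement(self, engine):
        from mirstage._fio import revcomp, rna

        hp = plant_hairpin(22, 0, 8, engine, np.random.default_rng(2))
        mature = hp.sequence[hp.mature_start : hp.mature_end]
        star = hp.sequence[hp.star_start : hp.star_end]
        assert rna(revcomp(mature)) == star

    def test_mature_window_width(self, engine):
        hp = plant_hairpin(20, 2, 9, engine, np.random.default_rng(3))
        assert hp.mature_end - hp.mature_start == 20

    def test_output_passes_screen(self, engine):
        from mirstage.mirnovel import CandidateWindow, screen_candidate

        rng = np.random.default_rng(4)
        for _ in range(5):
            hp = plant_hairpin(22, int(rng.integers(0, 5)), 10, engine, rng)
            w = CandidateWindow(
                "c", 0, len(hp.sequence), "+", hp.sequence,
                hp.sequence[hp.mature_start : hp.mature_end],
                hp.mature_start, {hp.mature_start: 90, hp.star_start: 10},
            )
            assert screen_candidate(w, engine).verdict

    def test_invalid_star_mismatches(self, engine):
        with pytest.raises(ValueError):
            plant_hairpin(22, 6, 8, engine)


class TestSimulate:
    def test_label_counts_sum_to_library_size(self, small_dataset):
        reads, labels = simulate_reads(small_dataset.config, small_dataset.truth, 2)
        assert len(reads) == len(labels) == 2000

    def test_bad_stage_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            simulate_reads(small_dataset.config, small_dataset.truth, 3)

    def test_bad_de_index_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, n_known_precursors=5, de_spec=((7, 1, 2.0),))

    def test_error_free_inserts_match_planted_sequences(self):
        from mirstage.preprocess import trim_adapter3

        cfg = SyntheticConfig(
            seed=40, error_rate=0.0, low_quality_rate=0.0,
            contamination_rates={k: 0.0 for k in (
                "adaptor3_null", "insert_null", "adaptor5_contaminants",
                "smaller_than_18nt", "polyA")},
            **SMALL,
        )
        ds = generate(cfg)
        g = ds.genome["chr1"]
        reads, labels = simulate_reads(cfg, ds.truth, 0)
        for (rid, seq, q), lab in zip(reads[:500], labels[:500]):
            ins, status = trim_adapter3(seq)
            assert status is None
            # every insert is a genome subsequence on either strand
            from mirstage._fio import revcomp

            assert ins in g or revcomp(ins) in g

    def test_polya_rate_within_binomial_band(self):
        cfg = SyntheticConfig(
            seed=41, genome_length=150_000, n_known_precursors=6,
            n_novel_precursors=2, library_sizes=(100_000, 2000, 2000),
            de_spec=(),
            contamination_rates={
                "adaptor3_null": 0.0005, "insert_null": 0.0005,
                "adaptor5_contaminants": 0.0144, "smaller_than_18nt": 0.0035,
                "polyA": 0.01,
            },
        )
        ds = generate(cfg)
        _, labels = simulate_reads(cfg, ds.truth, 0)
        n = Counter(labels)["polyA"]
        sigma = (100_000 * 0.01 * 0.99) ** 0.5
        assert abs(n - 1000) <= 3 * sigma

    def test_planted_fold_change_realised_within_poisson_interval(self):
        """A planted 4x change lands in the 99% interval of the count ratio."""
        cfg = SyntheticConfig(
            seed=42, genome_length=150_000, n_known_precursors=6,
            n_novel_precursors=2, library_sizes=(100_000, 100_000, 2000),
            de_spec=((4, 1, 2.0),),
        )
        ds = generate(cfg)
        name = ds.truth.known_names[4]
        e0 = ds.truth.expected_counts.at[name, "stage0"]
        assert e0 >= 400  # enough depth for the interval below
        mature = ds.mature_fa[name].replace("U", "T")
        counts = []
        for stage in (0, 1):
            _, labels = simulate_reads(cfg, ds.truth, stage)
            counts.append(Counter(labels)[f"miRNA:{name}"])
        ratio = counts[1] / counts[0]
        # 99% interval for the ratio of two Poisson counts around 4x at
        # this depth (delta method: sd(log ratio) <= sqrt(1/e0 + 1/(4 e0)))
        assert 3.4 <= ratio <= 4.7, counts


def test_abundance_vectors_sum_to_clean_budget(small_dataset):
    truth = small_dataset.truth
    cfg = small_dataset.config
    for s in range(3):
        planted = truth.expected_counts[f"stage{s}"].sum()
        other = truth.background_expected[s] + truth.clean_expected[s] * sum(
            v for k, v in synthio.CLASS_FRACTIONS.items()
            if k not in ("miRNA", "unann")
        )
        assert planted + other == pytest.approx(truth.clean_expected[s], rel=1e-9)


def test_dinucleotide_shuffle_preserves_composition():
    rng = np.random.default_rng(50)
    seq = "".join(rng.choice(list("ACGU"), size=300))
    shuf = dinucleotide_shuffle(seq, rng)
    assert shuf != seq

    def dinucs(s):
        return Counter(zip(s, s[1:]))

    assert dinucs(shuf) == dinucs(seq)
    assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
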