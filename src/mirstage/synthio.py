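"""Self-contained synthetic small-RNA-seq dataset with planted truth.

Generates a toy genome carrying planted miRNA hairpins (known + novel),
decoy features for every annotation class, and three stage libraries of
adapter-carrying reads with configured contaminant rates, so that every
pipeline stage can be exercised offline against exact per-read provenance.

Determinism: one master seed; each operation draws from a substream keyed
by a fixed offset (genome 101, abundances 501, reads 201+stage,
transcripts 301), so stages can be regenerated independently and identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._engines import get_engine
from ._fio import Feature, dna, revcomp, rna, write_fasta, write_fastq, write_gff3
from .mirnovel import (
    DEFAULT_THRESHOLDS,
    CandidateWindow,
    Thresholds,
    evaluate_hairpin,
    mfei,
    screen_candidate,
)
from .preprocess import ADAPTER3, ADAPTER5, classify_contaminants, trim_adapter3

#: length mix of clean inserts (18..30 nt), dominated by 22-mers as in real
#: small-RNA libraries.
LENGTH_WEIGHTS = {
    18: 0.02, 19: 0.03, 20: 0.06, 21: 0.12, 22: 0.45, 23: 0.12,
    24: 0.06, 25: 0.04, 26: 0.03, 27: 0.025, 28: 0.02, 29: 0.015, 30: 0.01,
}

#: clean-read composition by annotation class (miRNA-dominant profile of a
#: differentiating-myoblast library; unann includes the novel-miRNA reads).
CLASS_FRACTIONS = {
    "miRNA": 0.8251,
    "exon_antisense": 0.0002,
    "exon_sense": 0.0012,
    "intron_antisense": 0.0008,
    "intron_sense": 0.0013,
    "rRNA": 0.0109,
    "repeat": 0.0027,
    "scRNA": 0.0002,
    "snRNA": 0.0004,
    "snoRNA": 0.0003,
    "srpRNA": 0.0001,
    "tRNA": 0.0082,
    "unann": 0.1486,
}

DECOY_LENGTHS = {
    "rRNA": 500, "tRNA": 75, "snRNA": 150, "snoRNA": 100,
    "scRNA": 120, "srpRNA": 300, "repeat": 400, "exon": 300, "intron": 500,
}

CONTAMINANT_CLASSES = (
    "adaptor3_null",
    "insert_null",
    "adaptor5_contaminants",
    "smaller_than_18nt",
    "polyA",
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.42
    n_known_precursors: int = 20
    n_novel_precursors: int = 10
    n_decoy_features: dict = field(
        default_factory=lambda: {
            "rRNA": 4, "tRNA": 6, "snRNA": 3, "snoRNA": 3,
            "scRNA": 2, "srpRNA": 2, "repeat": 6, "exon": 8, "intron": 8,
        }
    )
    library_sizes: tuple = (100_000, 100_000, 100_000)
    #: (known-miRNA weight rank, stage, target log2 fold change vs stage 0);
    #: interleaved up/down entries on mid-to-low-weight miRNAs keep the
    #: read-mass shift small so the background budget can absorb it.
    de_spec: tuple = (
        (12, 1, 2.0), (13, 1, -2.0), (14, 1, 2.0), (15, 1, -2.0),
        (16, 2, 2.0), (17, 2, -2.0), (18, 2, 2.0), (19, 2, -2.0),
    )
    contamination_rates: dict = field(
        default_factory=lambda: {
            "adaptor3_null": 0.0005,
            "insert_null": 0.0005,
            "adaptor5_contaminants": 0.0144,
            "smaller_than_18nt": 0.0035,
            "polyA": 0.00002,
        }
    )
    low_quality_rate: float = 0.0026
    error_rate: float = 0.001
    quality_mean: float = 38.0
    quality_sd: float = 3.0
    read_length: int = 50
    abundance_sigma: float = 1.5
    max_weight_share: float = 0.2
    novel_fraction_of_unann: float = 0.2
    #: abundance-weight floor for planted novel precursors: a novel miRNA is
    #: only discoverable with adequate read depth, so planting below it
    #: would make the truth unreachable by any screen.
    novel_min_weight: float = 0.02
    star_fraction: float = 0.1
    engine_name: str = "builtin"
    thresholds: Thresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)

    def __post_init__(self):
        rates = list(self.contamination_rates.values()) + [self.low_quality_rate]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("contamination rates must be in [0, 1]")
        if any(n <= 0 for n in self.library_sizes):
            raise ValueError("library sizes must be positive")
        for idx, stage, _ in self.de_spec:
            if not 0 <= idx < self.n_known_precursors:
                raise ValueError(f"de_spec references unknown miRNA index {idx}")
            if not 1 <= stage < len(self.library_sizes):
                raise ValueError("de_spec stage must index a non-baseline library")


@dataclass(frozen=True)
class PlantedHairpin:
    sequence: str  # RNA alphabet
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int
    arm: str


@dataclass
class PrecursorRecord:
    name: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str  # RNA
    mature_start: int  # local, within sequence
    mature_end: int
    star_start: int
    star_end: int
    novel: bool
    arm: str

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature_start : self.mature_end]

    def mature_genomic(self) -> tuple[int, int]:
        return self.start + self.mature_start, self.start + self.mature_end

    def star_genomic(self) -> tuple[int, int]:
        return self.start + self.star_start, self.start + self.star_end


@dataclass
class TruthTable:
    precursors: list[PrecursorRecord]
    known_names: list[str]  # mature names ordered by abundance rank
    novel_names: list[str]
    expected_counts: pd.DataFrame  # rows: mature/novel names; cols: stage0..
    de_spec: tuple
    clean_expected: dict[int, float]  # stage -> expected clean reads
    background_expected: dict[int, float] | None = None  # stage -> unann reads


_NONPAIRING = {"A": "ACG", "C": "ACU", "G": "AG", "U": "CU"}
_LOOP_ALPHABET = list("AC")


def _random_mature(rng, length: int) -> str:
    au = rng.uniform(0.40, 0.60)
    p = [au / 2, (1 - au) / 2, (1 - au) / 2, au / 2]
    return "U" + "".join(rng.choice(list("AUCG"), size=length - 1, p=[p[0], p[1], p[2], p[3]]))


def plant_hairpin(
    mature_length: int = 22,
    star_mismatches: int = 2,
    loop_length: int = 10,
    engine=None,
    rng=None,
    arm: str = "5p",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    max_attempts: int = 1000,
) -> PlantedHairpin:
    """Construct a precursor that passes the hairpin screen, by rejection.

    The mature (5' U forced, AU content drawn within limits) is paired with
    a reverse-complement star carrying ``star_mismatches`` non-pairing
    substitutions, joined by a low-pairing loop and short unpaired pads,
    and accepted only when the folded product satisfies the structural and
    energy criteria of the screen.  Raises after ``max_attempts``
    consecutive rejections, reporting the most frequent failing criterion.
    """
    if not 0 <= star_mismatches < 6:
        raise ValueError("star_mismatches must be in [0, 6)")
    if engine is None:
        engine = get_engine("builtin")
    if rng is None:
        rng = np.random.default_rng(0)
    failures: Counter = Counter()
    for _ in range(max_attempts):
        mature = _random_mature(rng, mature_length)
        au = (mature.count("A") + mature.count("U")) / mature_length
        if not thresholds.au_min <= au <= thresholds.au_max:
            failures["au"] += 1
            continue
        star = list(rna(revcomp(mature)))
        if star_mismatches:
            # disrupt interior faces only, so the mature ends stay paired
            positions = rng.choice(
                np.arange(3, mature_length - 3), size=star_mismatches, replace=False
            )
            for mpos in positions:
                spos = mature_length - 1 - int(mpos)
                options = _NONPAIRING[mature[int(mpos)]]
                star[spos] = options[int(rng.integers(len(options)))]
        star_s = "".join(star)
        loop = "".join(rng.choice(_LOOP_ALPHABET, size=loop_length))
        pad5 = "".join(rng.choice(_LOOP_ALPHABET, size=3))
        pad3 = "".join(rng.choice(_LOOP_ALPHABET, size=3))
        if arm == "5p":
            pre = pad5 + mature + loop + star_s + pad3
            ms = len(pad5)
        else:
            pre = pad5 + star_s + loop + mature + pad3
            ms = len(pad5) + len(star_s) + loop_length
        me = ms + mature_length
        fr = engine.fold(pre)
        ev = evaluate_hairpin(fr, ms, me, thresholds)
        if not ev.structural_pass:
            bad = next(c for c in ("length", "arm", "star", "au") if not ev.flags[c])
            failures[bad] += 1
            continue
        if fr.mfe >= thresholds.mfe_max:
            failures["mfe"] += 1
            continue
        gc = (pre.count("G") + pre.count("C")) / len(pre)
        if mfei(fr.mfe, len(pre), gc) > thresholds.mfei_max:
            failures["mfei"] += 1
            continue
        if not _clean_insert(dna(mature)):
            failures["insert"] += 1
            continue
        return PlantedHairpin(pre, ms, me, ev.star_start, ev.star_end, arm)
    worst = failures.most_common(1)[0][0] if failures else "unknown"
    raise RuntimeError(
        f"hairpin construction failed after {max_attempts} attempts; "
        f"most frequent failing criterion: {worst} ({dict(failures)})"
    )


def _clean_insert(insert_dna: str) -> bool:
    """True when the insert survives trimming+classification unchanged."""
    trimmed, status = trim_adapter3(insert_dna + ADAPTER3)
    return (
        status is None
        and trimmed == insert_dna
        and classify_contaminants(trimmed) == "clean"
    )


def _draw_genome(rng, length: int, gc: float) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(bases, size=length, p=probs)


class _Placer:
    """Non-overlapping feature placement with a safety margin."""

    def __init__(self, rng, genome_length: int, margin: int = 160):
        self.rng = rng
        self.length = genome_length
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def place(self, size: int, max_tries: int = 2000) -> int:
        for _ in range(max_tries):
            start = int(
                self.rng.integers(self.margin, self.length - size - self.margin)
            )
            if all(
                start >= e + self.margin or start + size <= s - self.margin
                for s, e in self.occupied
            ):
                self.occupied.append((start, start + size))
                return start
        raise RuntimeError("insufficient genome space to place features without overlap")


_GENOME_CACHE: dict = {}


def _genome_key(cfg: SyntheticConfig):
    return (
        cfg.seed,
        cfg.genome_length,
        round(cfg.gc_fraction, 6),
        cfg.n_known_precursors,
        cfg.n_novel_precursors,
        tuple(sorted(cfg.n_decoy_features.items())),
        cfg.engine_name,
    )


def make_genome(cfg: SyntheticConfig, engine=None):
    """Genome + features + planted precursor records (deterministic in seed).

    Novel precursors are re-rolled until their flanked genomic window passes
    the full candidate screen under the configured engine, so generator
    closure holds by construction.  Results are memoised per config so the
    per-stage read simulators can re-derive the genome cheaply.
    """
    key = _genome_key(cfg)
    if key in _GENOME_CACHE:
        return _GENOME_CACHE[key]
    if engine is None:
        engine = get_engine(cfg.engine_name)
    rng = np.random.default_rng([cfg.seed, 101])
    th = cfg.thresholds
    arms = ["5p", "3p"]

    def _new_hairpin(i: int) -> PlantedHairpin:
        return plant_hairpin(
            mature_length=int(rng.choice([20, 21, 22], p=[0.15, 0.2, 0.65])),
            star_mismatches=int(rng.integers(1, 4)),
            loop_length=int(rng.integers(8, 14)),
            engine=engine,
            rng=rng,
            arm=arms[i % 2],
            thresholds=th,
        )

    planted_known = [_new_hairpin(i) for i in range(cfg.n_known_precursors)]

    total_feature_len = (
        sum(len(h.sequence) for h in planted_known)
        + cfg.n_novel_precursors * 70
        + sum(DECOY_LENGTHS[c] * n for c, n in cfg.n_decoy_features.items())
    )
    if cfg.genome_length < 10 * total_feature_len:
        raise ValueError(
            f"genome_length {cfg.genome_length} < 10x planted feature length "
            f"{total_feature_len}"
        )

    genome = _draw_genome(rng, cfg.genome_length, cfg.gc_fraction)
    placer = _Placer(rng, cfg.genome_length)
    contig = "chr1"
    features: list[Feature] = []
    precursors: list[PrecursorRecord] = []

    def _write(pos: int, seq_dna: str) -> None:
        genome[pos : pos + len(seq_dna)] = np.frombuffer(seq_dna.encode(), dtype=np.uint8)

    for i, hp in enumerate(planted_known):
        pos = placer.place(len(hp.sequence))
        _write(pos, dna(hp.sequence))
        pre_name = f"syn-mir-{100 + i}"
        features.append(Feature(contig, pos, pos + len(hp.sequence), "+", "miRNA", pre_name))
        precursors.append(
            PrecursorRecord(
                pre_name, contig, pos, pos + len(hp.sequence), "+", hp.sequence,
                hp.mature_start, hp.mature_end, hp.star_start, hp.star_end,
                novel=False, arm=hp.arm,
            )
        )

    for i in range(cfg.n_novel_precursors):
        placed = False
        for _attempt in range(60):
            hp = _new_hairpin(i)
            pos = placer.place(len(hp.sequence))
            saved = genome[pos : pos + len(hp.sequence)].copy()
            _write(pos, dna(hp.sequence))
            rec = PrecursorRecord(
                f"syn-novel-{i}", contig, pos, pos + len(hp.sequence), "+",
                hp.sequence, hp.mature_start, hp.mature_end,
                hp.star_start, hp.star_end, novel=True, arm=hp.arm,
            )
            if _window_passes(rec, genome, engine, th):
                precursors.append(rec)
                placed = True
                break
            genome[pos : pos + len(saved)] = saved
            placer.occupied.pop()
        if not placed:
            raise RuntimeError(f"could not plant novel precursor {i} passing the screen")

    for ftype, n in cfg.n_decoy_features.items():
        for k in range(n):
            size = DECOY_LENGTHS[ftype]
            pos = placer.place(size)
            strand = "+"
            if ftype in ("exon", "intron"):
                strand = "+" if rng.random() < 0.5 else "-"
            features.append(Feature(contig, pos, pos + size, strand, ftype, f"{ftype}_{k}"))

    result = (
        {contig: genome.tobytes().decode()},
        features,
        precursors,
        sorted(placer.occupied),
    )
    _GENOME_CACHE[key] = result
    return result


def _window_passes(rec: PrecursorRecord, genome_arr: np.ndarray, engine, th) -> bool:
    gstart, gend = rec.start + rec.mature_start, rec.start + rec.mature_end
    w_start = max(0, gstart - 150)
    w_end = min(genome_arr.size, gend + 150)
    seq = rna(genome_arr[w_start:w_end].tobytes().decode())
    ss, _se = rec.star_genomic()
    window = CandidateWindow(
        rec.contig, w_start, w_end, "+", seq, rec.mature_seq, gstart - w_start,
        read_support={gstart - w_start: 90, ss - w_start: 10},
    )
    return screen_candidate(window, engine, th).verdict


def _abundances(cfg: SyntheticConfig):
    rng = np.random.default_rng([cfg.seed, 501])
    wk = np.sort(rng.lognormal(0.0, cfg.abundance_sigma, cfg.n_known_precursors))[::-1]
    wk /= wk.sum()
    wk = np.minimum(wk, cfg.max_weight_share)
    wk /= wk.sum()
    wn = np.sort(rng.lognormal(0.0, cfg.abundance_sigma, cfg.n_novel_precursors))[::-1]
    wn /= wn.sum()
    wn = np.maximum(wn, cfg.novel_min_weight)
    wn /= wn.sum()
    return wk, wn


def _mature_name(p: PrecursorRecord) -> str:
    num = p.name.rsplit("-", 1)[-1]
    return f"syn-miR-{num}-{p.arm}"


def build_truth(cfg: SyntheticConfig, precursors: list[PrecursorRecord]) -> TruthTable:
    """Per-stage expected clean-read counts realising the planted DE spec.

    DE miRNAs get expected counts scaled by exactly 2^lfc relative to stage
    0 while non-DE miRNAs stay at their baseline expectation; the read-mass
    difference is absorbed by the unannotated background budget, so with
    equal stage totals the planted NE ratios hold exactly in expectation
    and non-DE miRNAs stay flat.  When a shift is too large for the
    background to absorb (it may not drop below 20 % of its baseline), the
    remainder is spread proportionally over the non-DE miRNAs.
    """
    wk, wn = _abundances(cfg)
    known = [p for p in precursors if not p.novel]
    novel = [p for p in precursors if p.novel]
    known_names = [_mature_name(p) for p in known]
    novel_names = [p.name for p in novel]

    contam = sum(cfg.contamination_rates.values()) + cfg.low_quality_rate
    clean_expected = {
        s: cfg.library_sizes[s] * (1 - contam) for s in range(len(cfg.library_sizes))
    }
    de_by_stage: dict[int, dict[int, float]] = {}
    for idx, stage, lfc in cfg.de_spec:
        de_by_stage.setdefault(stage, {})[idx] = lfc

    rows = {}
    background = {}
    for s in range(len(cfg.library_sizes)):
        B = clean_expected[s] * CLASS_FRACTIONS["miRNA"]
        e0 = B * wk
        e = e0.copy()
        de = de_by_stage.get(s, {})
        for idx, lfc in de.items():
            e[idx] = e0[idx] * 2.0 ** lfc
        delta = e.sum() - B
        bg0 = (
            clean_expected[s]
            * CLASS_FRACTIONS["unann"]
            * (1 - cfg.novel_fraction_of_unann)
        )
        bg = bg0 - delta
        floor = 0.2 * bg0
        if bg < floor:
            spill = floor - bg
            bg = floor
            non_de = [i for i in range(len(e)) if i not in de]
            non_de_mass = sum(e[i] for i in non_de)
            if spill >= non_de_mass:
                raise ValueError("de_spec fold changes exceed the read budget")
            scale = (non_de_mass - spill) / non_de_mass
            for i in non_de:
                e[i] *= scale
        background[s] = bg
        novel_budget = (
            clean_expected[s] * CLASS_FRACTIONS["unann"] * cfg.novel_fraction_of_unann
        )
        rows[f"stage{s}"] = np.concatenate([e, novel_budget * wn])
    expected = pd.DataFrame(rows, index=known_names + novel_names)
    return TruthTable(
        precursors, known_names, novel_names, expected, cfg.de_spec,
        clean_expected, background,
    )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    features: list[Feature]
    truth: TruthTable
    mature_fa: dict[str, str]  # name -> RNA sequence
    hairpin_fa: dict[str, str]
    mature_windows: list[tuple[str, str, int, int]]  # mature, precursor, start, end

    def reads(self, stage: int):
        return simulate_reads(self.config, self.truth, stage)


def generate(cfg: SyntheticConfig, engine=None) -> SyntheticDataset:
    """Build the full synthetic dataset (genome, annotation, reference, truth)."""
    genome, features, precursors, _occ = make_genome(cfg, engine)
    truth = build_truth(cfg, precursors)
    mature_fa, hairpin_fa, windows = {}, {}, []
    for p in precursors:
        if p.novel:
            continue
        name = _mature_name(p)
        mature_fa[name] = p.mature_seq
        hairpin_fa[p.name] = p.sequence
        windows.append((name, p.name, p.mature_start, p.mature_end))
    return SyntheticDataset(cfg, genome, features, truth, mature_fa, hairpin_fa, windows)


_DECOY_CLASS_TO_FTYPE = {
    "exon_sense": "exon", "exon_antisense": "exon",
    "intron_sense": "intron", "intron_antisense": "intron",
}


def simulate_reads(
    cfg: SyntheticConfig, truth: TruthTable, stage: int
) -> tuple[list[tuple[str, str, list[int]]], list[str]]:
    """One stage library: FASTQ-ready reads plus per-read provenance labels.

    Reads are insert + 3' adapter + random filler truncated to the
    instrument length, with per-base substitution errors and Gaussian
    Phred qualities; contaminant classes are injected at the configured
    rates and the residual multinomial mass goes to unannotated background.
    """
    if not 0 <= stage < len(cfg.library_sizes):
        raise ValueError(f"stage must be in 0..{len(cfg.library_sizes) - 1}")
    rng = np.random.default_rng([cfg.seed, 201 + stage])
    lib = cfg.library_sizes[stage]

    genome, features, precursors, occupied = make_genome(cfg)
    gseq = genome[next(iter(genome))]
    feats_by_type: dict[str, list[Feature]] = {}
    for f in features:
        feats_by_type.setdefault(f.ftype, []).append(f)
    occ_starts = [s for s, _ in occupied]

    known = {_mature_name(p): p for p in truth.precursors if not p.novel}
    novel = {p.name: p for p in truth.precursors if p.novel}
    exp = truth.expected_counts[f"stage{stage}"]

    sources: list[tuple[str, float]] = [("low_quality", cfg.low_quality_rate)]
    for c in CONTAMINANT_CLASSES:
        sources.append((c, cfg.contamination_rates[c]))
    for name in truth.known_names:
        sources.append((f"miRNA:{name}", exp[name] / lib))
    for name in truth.novel_names:
        e = exp[name] / lib
        sources.append((f"novel:{name}", e * (1 - cfg.star_fraction)))
        sources.append((f"novel_star:{name}", e * cfg.star_fraction))
    clean_e = truth.clean_expected[stage]
    for cls, frac in CLASS_FRACTIONS.items():
        if cls in ("miRNA", "unann"):
            continue
        sources.append((cls, clean_e * frac / lib))
    if truth.background_expected is not None:
        bg = truth.background_expected[stage]
    else:
        bg = clean_e * CLASS_FRACTIONS["unann"] * (1 - cfg.novel_fraction_of_unann)
    sources.append(("unann:genomic", bg / lib))
    probs = np.array([p for _, p in sources])
    if probs.sum() > 1 + 1e-9:
        raise ValueError("source probabilities exceed 1")
    probs = np.append(probs, max(1.0 - probs.sum(), 0.0))
    counts = rng.multinomial(lib, probs / probs.sum())
    counts[-2] += counts[-1]  # residual mass -> unannotated background
    counts = counts[:-1]

    lengths = np.array(sorted(LENGTH_WEIGHTS))
    length_p = np.array([LENGTH_WEIGHTS[x] for x in lengths])
    length_p = length_p / length_p.sum()

    reads: list[tuple[str, str, list[int]]] = []
    labels: list[str] = []

    def _finish(insert_dna: str, label: str, lowq: bool = False):
        seq, quals = _assemble_read(cfg, rng, insert_dna, lowq)
        reads.append((f"s{stage}_r{len(reads)}", seq, quals))
        labels.append(label)

    for (label, _), n in zip(sources, counts):
        for _ in range(int(n)):
            if label == "low_quality":
                _finish(_random_dna(rng, cfg.read_length), label, lowq=True)
            elif label == "adaptor3_null":
                seq = _no_adapter_read(cfg, rng)
                reads.append((f"s{stage}_r{len(reads)}", seq, _qualities(cfg, rng, len(seq))))
                labels.append(label)
            elif label == "insert_null":
                _finish("", label)
            elif label == "adaptor5_contaminants":
                _finish(ADAPTER5 + _random_dna(rng, int(rng.integers(0, 4))), label)
            elif label == "smaller_than_18nt":
                _finish(_short_insert(rng), label)
            elif label == "polyA":
                _finish("A" * int(rng.integers(20, 28)), label)
            elif label.startswith("miRNA:"):
                _finish(dna(known[label.split(":", 1)[1]].mature_seq), label)
            elif label.startswith("novel_star:"):
                s, e = novel[label.split(":", 1)[1]].star_genomic()
                _finish(gseq[s:e], label)
            elif label.startswith("novel:"):
                s, e = novel[label.split(":", 1)[1]].mature_genomic()
                _finish(gseq[s:e], label)
            elif label == "unann:genomic":
                _finish(
                    _sample_background(rng, gseq, occupied, occ_starts, lengths, length_p),
                    label,
                )
            else:  # decoy annotation class
                ftype = _DECOY_CLASS_TO_FTYPE.get(label, label)
                feats = feats_by_type[ftype]
                f = feats[int(rng.integers(len(feats)))]
                _finish(
                    _sample_feature_read(rng, gseq, f, label, lengths, length_p),
                    f"{label}:{f.fid}",
                )
    return reads, labels


def _no_adapter_read(cfg, rng) -> str:
    for _ in range(100):
        seq = _random_dna(rng, cfg.read_length)
        _, status = trim_adapter3(seq)
        if status == "adaptor3_null":
            return seq
    raise RuntimeError("failed to build an adapter-free read")


def _short_insert(rng) -> str:
    for _ in range(50):
        ins = _random_dna(rng, int(rng.integers(10, 18)))
        if classify_contaminants(ins) == "smaller_than_18nt":
            return ins
    raise RuntimeError("failed to build a short insert")


def _sample_background(rng, gseq, occupied, occ_starts, lengths, length_p) -> str:
    n = len(gseq)
    for _ in range(200):
        L = int(rng.choice(lengths, p=length_p))
        pos = int(rng.integers(0, n - L))
        i = bisect.bisect_right(occ_starts, pos)
        if i > 0 and occupied[i - 1][1] > pos:
            continue
        if i < len(occupied) and occupied[i][0] < pos + L:
            continue
        ins = gseq[pos : pos + L]
        if _clean_insert(ins):
            return ins
    raise RuntimeError("failed to sample a background read")


def _sample_feature_read(rng, gseq, f: Feature, label: str, lengths, length_p) -> str:
    for _ in range(100):
        L = min(int(rng.choice(lengths, p=length_p)), f.end - f.start)
        pos = int(rng.integers(f.start, f.end - L + 1))
        ins = gseq[pos : pos + L]
        sense = not label.endswith("_antisense")
        if (f.strand == "-") == sense:
            # the sense read of a '-' feature (or antisense of '+') is the
            # reverse complement of the + strand slice
            ins = revcomp(ins)
        if _clean_insert(ins):
            return ins
    raise RuntimeError(f"failed to sample a read from {f.fid}")


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def _qualities(cfg, rng, n: int) -> list[int]:
    q = rng.normal(cfg.quality_mean, cfg.quality_sd, n)
    return [int(v) for v in np.clip(np.rint(q), 2, 41)]


def _assemble_read(cfg, rng, insert_dna: str, lowq: bool = False):
    raw = insert_dna + ADAPTER3
    if len(raw) < cfg.read_length:
        raw += _random_dna(rng, cfg.read_length - len(raw))
    seq = list(raw[: cfg.read_length])
    if cfg.error_rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < cfg.error_rate)[0]
        for i in hits:
            seq[i] = "ACGT"[("ACGT".index(seq[i]) + int(rng.integers(1, 4))) % 4]
    quals = _qualities(cfg, rng, len(seq))
    if lowq:
        if rng.random() < 0.5:
            for i in rng.choice(len(seq), size=2, replace=False):
                seq[i] = "N"
                quals[i] = 2
        else:
            for i in rng.choice(len(seq), size=6, replace=False):
                quals[i] = 5
    return "".join(seq), quals


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Shuffle preserving dinucleotide composition (Eulerian-walk rejection)."""
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    for _ in range(2000):
        trial = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        out = [s[0]]
        node = s[0]
        ok = True
        for _ in range(len(s) - 1):
            bucket = trial[node]
            if not bucket:
                ok = False
                break
            node = str(bucket.pop(0))
            out.append(node)
        if ok:
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to converge")


def make_transcripts(
    dataset: SyntheticDataset, n_transcripts: int = 8, length: int = 400
) -> tuple[dict[str, str], list[tuple[str, str, int]]]:
    """Random transcripts with one planted perfect-complement miRNA site each.

    Returns (transcripts, sites) where each site is (miRNA, transcript,
    start).  Used to exercise target prediction with known recall.
    """
    rng = np.random.default_rng([dataset.config.seed, 301])
    names = dataset.truth.known_names
    transcripts: dict[str, str] = {}
    sites: list[tuple[str, str, int]] = []
    for i in range(n_transcripts):
        tname = f"tx_{i}"
        seq = _random_dna(rng, length)
        mir = names[int(rng.integers(len(names)))]
        site = revcomp(dna(dataset.mature_fa[mir]))
        pos = int(rng.integers(0, length - len(site)))
        seq = seq[:pos] + site + seq[pos + len(site) :]
        transcripts[tname] = seq
        sites.append((mir, tname, pos))
    return transcripts, sites


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write genome, annotations, miRNA reference, reads and truth to disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    write_fasta(paths["genome"], dataset.genome.items())
    paths["features"] = out / "features.gff3"
    write_gff3(paths["features"], dataset.features)
    paths["mature"] = out / "mature.fa"
    write_fasta(paths["mature"], dataset.mature_fa.items())
    paths["hairpin"] = out / "hairpin.fa"
    write_fasta(paths["hairpin"], dataset.hairpin_fa.items())
    paths["windows"] = out / "mature_windows.tsv"
    with open(paths["windows"], "w") as fh:
        fh.write("mature\tprecursor\tstart\tend\n")
        for m, p, s, e in dataset.mature_windows:
            fh.write(f"{m}\t{p}\t{s}\t{e}\n")
    truth_rows = []
    for s in range(len(dataset.config.library_sizes)):
        reads, labels = dataset.reads(s)
        paths[f"reads_{s}"] = out / f"reads_stage{s}.fastq"
        write_fastq(paths[f"reads_{s}"], reads)
        truth_rows.extend((r[0], s, lab) for r, lab in zip(reads, labels))
    paths["truth"] = out / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tstage\tlabel\n")
        for rid, s, lab in truth_rows:
            fh.write(f"{rid}\t{s}\t{lab}\n")
    paths["expected"] = out / "expected_counts.tsv"
    dataset.truth.expected_counts.to_csv(paths["expected"], sep="\t")
    return paths
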