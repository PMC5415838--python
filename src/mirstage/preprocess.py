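"""Raw-read cleaning: quality filter, 3' adapter trimming, contaminant
classification, and collapsing of clean inserts into unique tags.

The cascade assigns every high-quality read to exactly one category —
no-3'-adapter, null insert, 5'-adapter contaminant, shorter than 18 nt,
polyA, (oversize), or clean — so that category counts plus clean reads add
back up to the high-quality total, mirroring standard small-RNA library QC
summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

# cleaning defaults: Illumina TruSeq small-RNA adapters
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
MIN_TAG_LEN = 18
MAX_TAG_LEN = 30

CATEGORIES = (
    "adaptor3_null",
    "insert_null",
    "adaptor5_contaminants",
    "smaller_than_18nt",
    "polyA",
    "larger_than_30nt",
    "clean",
)


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )


def quality_filter(read: ReadRecord) -> tuple[bool, str | None]:
    """High-quality test: no N, at most 4 bases below Q10, at most 6 below Q13.

    Returns ``(passed, reason)``; reason is ``None`` on pass.
    """
    if "N" in read.sequence.upper():
        return False, "N"
    below10 = sum(1 for q in read.quality if q < 10)
    if below10 > 4:
        return False, "low_quality_q10"
    below13 = sum(1 for q in read.quality if q < 13)
    if below13 > 6:
        return False, "low_quality_q13"
    return True, None


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_adapter3(
    sequence: str, adapter: str = ADAPTER3, min_partial: int = 6
) -> tuple[str, str | None]:
    """Locate the leftmost 3' adapter occurrence and return the 5' insert.

    A full-length adapter occurrence tolerates one mismatch per 10 nt of
    adapter; a terminal partial occurrence must match an adapter prefix of at
    least ``min_partial`` nt (one mismatch per 10 nt of the compared prefix).
    Returns ``(insert, None)`` on success, ``("", "insert_null")`` for an
    adapter starting at position 0, and ``(sequence, "adaptor3_null")`` when
    no occurrence is found.
    """
    if not adapter:
        raise ValueError("empty 3' adapter")
    if len(adapter) < 6:
        raise ValueError("3' adapter shorter than 6 nt")
    seq = sequence.upper()
    ad = adapter.upper()
    n, m = len(seq), len(ad)
    for s in range(0, n - min_partial + 1):
        span = min(m, n - s)
        allowed = span // 10
        if _mismatches(seq[s : s + span], ad[:span]) <= allowed:
            if s == 0:
                return "", "insert_null"
            return seq[:s], None
    return seq, "adaptor3_null"


def classify_contaminants(
    insert: str,
    adapter5: str = ADAPTER5,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    polya_fraction: float = 0.8,
) -> str:
    """Route a trimmed insert: 5'-contaminant, then length, then polyA, then keep.

    The 5'-contaminant test compares the insert head against the 5' adapter
    over ``min(len(insert), len(adapter5))`` bases allowing one mismatch;
    an insert with >= 80 % A is polyA.
    """
    seq = insert.upper()
    k = min(len(seq), len(adapter5))
    if k >= 8 and _mismatches(seq[:k], adapter5[:k].upper()) <= 1:
        return "adaptor5_contaminants"
    if len(seq) < min_len:
        return "smaller_than_18nt"
    if seq.count("A") >= polya_fraction * len(seq):
        return "polyA"
    if len(seq) > max_len:
        return "larger_than_30nt"
    return "clean"


@dataclass
class CleaningSummary:
    """Per-library cleaning tally in the conventional QC-table layout."""

    total_reads: int
    high_quality: int
    adaptor3_null: int
    insert_null: int
    adaptor5_contaminants: int
    smaller_than_18nt: int
    polyA: int
    larger_than_30nt: int = 0
    clean_reads: int = field(init=False)

    def __post_init__(self):
        removed = (
            self.adaptor3_null
            + self.insert_null
            + self.adaptor5_contaminants
            + self.smaller_than_18nt
            + self.polyA
            + self.larger_than_30nt
        )
        self.clean_reads = self.high_quality - removed
        if self.clean_reads < 0:
            raise ValueError("category counts exceed high-quality reads")

    def percentage(self, count: int) -> float:
        """Percentage of high-quality reads, rounded half-up to 2 decimals."""
        if self.high_quality == 0:
            return 0.0
        pct = Decimal(count) / Decimal(self.high_quality) * 100
        return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def as_rows(self) -> list[tuple[str, int, float]]:
        rows = [
            ("total_reads", self.total_reads, float("nan")),
            ("high_quality", self.high_quality, self.percentage(self.high_quality)),
            ("3'adaptor_null", self.adaptor3_null, self.percentage(self.adaptor3_null)),
            ("insert_null", self.insert_null, self.percentage(self.insert_null)),
            (
                "5'adaptor_contaminants",
                self.adaptor5_contaminants,
                self.percentage(self.adaptor5_contaminants),
            ),
            (
                "smaller_than_18nt",
                self.smaller_than_18nt,
                self.percentage(self.smaller_than_18nt),
            ),
            ("polyA", self.polyA, self.percentage(self.polyA)),
        ]
        if self.larger_than_30nt:
            rows.append(
                (
                    "larger_than_30nt",
                    self.larger_than_30nt,
                    self.percentage(self.larger_than_30nt),
                )
            )
        rows.append(("clean_reads", self.clean_reads, self.percentage(self.clean_reads)))
        return rows


def summarize_cleaning(
    total_reads: int,
    high_quality: int,
    adaptor3_null: int,
    insert_null: int,
    adaptor5_contaminants: int,
    smaller_than_18nt: int,
    polyA: int,
    larger_than_30nt: int = 0,
) -> CleaningSummary:
    counts = [
        total_reads,
        high_quality,
        adaptor3_null,
        insert_null,
        adaptor5_contaminants,
        smaller_than_18nt,
        polyA,
        larger_than_30nt,
    ]
    if any(c < 0 for c in counts):
        raise ValueError("negative category count")
    return CleaningSummary(
        total_reads,
        high_quality,
        adaptor3_null,
        insert_null,
        adaptor5_contaminants,
        smaller_than_18nt,
        polyA,
        larger_than_30nt,
    )


@dataclass
class CleanResult:
    """Outcome of cleaning one library."""

    summary: CleaningSummary
    inserts: Counter  # clean insert sequence -> read count
    quality_fail_reasons: Counter


def clean_library(
    reads,
    adapter3: str = ADAPTER3,
    adapter5: str = ADAPTER5,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> CleanResult:
    """Run the full cascade over an iterable of (id, sequence, quality) reads."""
    total = 0
    high_quality = 0
    cat = Counter()
    reasons = Counter()
    inserts: Counter = Counter()
    for rid, seq, quals in reads:
        total += 1
        read = ReadRecord(rid, seq, tuple(quals))
        ok, reason = quality_filter(read)
        if not ok:
            reasons[reason] += 1
            continue
        high_quality += 1
        insert, status = trim_adapter3(seq, adapter3)
        if status is not None:
            cat[status] += 1
            continue
        bucket = classify_contaminants(insert, adapter5, min_len, max_len)
        cat[bucket] += 1
        if bucket == "clean":
            inserts[insert] += 1
    summary = summarize_cleaning(
        total,
        high_quality,
        cat["adaptor3_null"],
        cat["insert_null"],
        cat["adaptor5_contaminants"],
        cat["smaller_than_18nt"],
        cat["polyA"],
        cat["larger_than_30nt"],
    )
    return CleanResult(summary, inserts, reasons)


@dataclass
class TagSet:
    """Unique tags with per-library counts plus per-library length histograms."""

    libraries: list[str]
    counts: dict[str, list[int]]  # sequence -> count per library
    length_histogram: dict[str, dict[int, int]]  # library -> length -> reads

    def total(self, library: str) -> int:
        i = self.libraries.index(library)
        return sum(v[i] for v in self.counts.values())


def collapse_tags(per_library_inserts: dict[str, Counter]) -> TagSet:
    """Collapse identical clean inserts across libraries into unique tags."""
    libraries = list(per_library_inserts)
    counts: dict[str, list[int]] = {}
    hist: dict[str, dict[int, int]] = {lib: {} for lib in libraries}
    for i, lib in enumerate(libraries):
        for seq, n in per_library_inserts[lib].items():
            if seq not in counts:
                counts[seq] = [0] * len(libraries)
            counts[seq][i] += n
            hist[lib][len(seq)] = hist[lib].get(len(seq), 0) + n
    return TagSet(libraries, counts, hist)
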