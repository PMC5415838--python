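"""Genome mapping of unique tags and annotation-category assignment.

Tags are located on both genome strands (exact by default), then each tag is
assigned exactly one category from the small-RNA annotation system
(miRNA, rRNA, tRNA, sn/sno/sc/srpRNA, repeat, exon/intron sense/antisense,
unann) by a fixed priority cascade over all of its genomic loci.  A
multi-locus tag contributes its full read count once, to its single winning
category, so the per-category read counts partition the clean total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from ._fio import Feature, revcomp
from .preprocess import TagSet

#: Category priority, highest first.  miRNA dominance in small-RNA libraries
#: implies it outranks the structural-RNA and genic classes.
DEFAULT_PRIORITY = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "srpRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
)

CATEGORIES = ("miRNA",) + tuple(
    c
    for c in (
        "exon_antisense",
        "exon_sense",
        "intron_antisense",
        "intron_sense",
        "rRNA",
        "repeat",
        "scRNA",
        "snRNA",
        "snoRNA",
        "srpRNA",
        "tRNA",
    )
) + ("unann",)


@dataclass(frozen=True)
class TagAlignment:
    tag: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    mismatches: int


@dataclass
class AnnotationRecord:
    tag: str
    category: str
    feature_id: str | None = None
    n_loci: int = 0
    alignments: list = field(default_factory=list)


def _kmer_index(genome: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for contig, seq in genome.items():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            index.setdefault(s[i : i + k], []).append((contig, i))
    return index


class GenomeIndex:
    """Seed-and-verify exact/near-exact search over small genomes."""

    def __init__(self, genome: dict[str, str], seed_length: int = 18):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_length = seed_length
        self._index = _kmer_index(self.genome, seed_length)

    def find(self, tag: str, max_mismatches: int = 0) -> list[TagAlignment]:
        """All loci of ``tag`` on both strands, up to the mismatch limit."""
        tag = tag.upper().replace("U", "T")
        hits: list[TagAlignment] = []
        seen: set[tuple[str, int, str]] = set()
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            if max_mismatches == 0:
                for contig, pos in self._index.get(query[: self.seed_length], []):
                    seq = self.genome[contig]
                    if seq[pos : pos + len(query)] == query:
                        key = (contig, pos, strand)
                        if key not in seen:
                            seen.add(key)
                            hits.append(
                                TagAlignment(tag, contig, pos, pos + len(tag), strand, 0)
                            )
            else:
                for contig, seq in self.genome.items():
                    for pos in range(len(seq) - len(query) + 1):
                        mm = sum(
                            1 for a, b in zip(seq[pos : pos + len(query)], query) if a != b
                        )
                        if mm <= max_mismatches:
                            key = (contig, pos, strand)
                            if key not in seen:
                                seen.add(key)
                                hits.append(
                                    TagAlignment(
                                        tag, contig, pos, pos + len(tag), strand, mm
                                    )
                                )
        hits.sort(key=lambda h: (h.contig, h.start, h.strand))
        return hits


def map_tags(
    tags, genome: dict[str, str], max_mismatches: int = 0
) -> tuple[dict[str, list[TagAlignment]], int]:
    """Map tag sequences to the genome; returns (alignments, skipped count).

    Tags containing non-ACGT characters are skipped (counted, not raised).
    """
    index = GenomeIndex(genome)
    out: dict[str, list[TagAlignment]] = {}
    skipped = 0
    for tag in tags:
        t = tag.upper().replace("U", "T")
        if any(c not in "ACGT" for c in t):
            skipped += 1
            continue
        out[tag] = index.find(t, max_mismatches)
    return out, skipped


class FeatureIndex:
    """Interval lookup of annotation features per contig."""

    def __init__(self, features: list[Feature]):
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self._trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, contig: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def classify_tag(
    tag: str,
    alignments: list[TagAlignment],
    features: FeatureIndex,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> AnnotationRecord:
    """Assign one category to a tag from all of its genomic loci.

    Exonic/intronic hits split into sense/antisense by strand agreement
    between the tag locus and the feature; the cascade then keeps the
    highest-priority category seen at any locus.
    """
    candidates: dict[str, str] = {}  # category -> feature id
    for aln in alignments:
        for feat in features.overlapping(aln.contig, aln.start, aln.end):
            cat = feat.ftype
            if cat in ("exon", "intron"):
                rel = "sense" if feat.strand == aln.strand else "antisense"
                cat = f"{cat}_{rel}"
            if cat not in candidates:
                candidates[cat] = feat.fid
    for cat in priority:
        if cat in candidates:
            return AnnotationRecord(tag, cat, candidates[cat], len(alignments), alignments)
    return AnnotationRecord(tag, "unann", None, len(alignments), alignments)


def annotate_tags(
    tagset: TagSet,
    genome: dict[str, str],
    features: list[Feature],
    max_mismatches: int = 0,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> dict[str, AnnotationRecord]:
    """Map and classify every tag of a collapsed tag set."""
    alignments, _ = map_tags(tagset.counts.keys(), genome, max_mismatches)
    index = FeatureIndex(features)
    return {
        tag: classify_tag(tag, alignments.get(tag, []), index, priority)
        for tag in tagset.counts
    }


def _pct(count: int, total: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    if total == 0:
        return 0.0
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def summarize_annotation(
    records: dict[str, AnnotationRecord], tagset: TagSet
) -> pd.DataFrame:
    """Annotation-class matrix: unique-tag and read counts (+%) per library.

    One row per category plus a Total row; unique and read columns each sum
    to their library totals because every tag carries one category.
    """
    libs = tagset.libraries
    rows = []
    lib_tag_totals = {
        lib: sum(1 for v in tagset.counts.values() if v[i] > 0)
        for i, lib in enumerate(libs)
    }
    lib_read_totals = {lib: tagset.total(lib) for lib in libs}
    for cat in CATEGORIES:
        tags_in_cat = [t for t, r in records.items() if r.category == cat]
        row: dict[str, object] = {"category": cat}
        for i, lib in enumerate(libs):
            uniq = sum(1 for t in tags_in_cat if tagset.counts[t][i] > 0)
            reads = sum(tagset.counts[t][i] for t in tags_in_cat)
            row[f"{lib}_unique"] = uniq
            row[f"{lib}_unique_pct"] = _pct(uniq, lib_tag_totals[lib])
            row[f"{lib}_reads"] = reads
            row[f"{lib}_reads_pct"] = _pct(reads, lib_read_totals[lib])
        rows.append(row)
    total_row: dict[str, object] = {"category": "Total"}
    for lib in libs:
        total_row[f"{lib}_unique"] = lib_tag_totals[lib]
        total_row[f"{lib}_unique_pct"] = 100.0
        total_row[f"{lib}_reads"] = lib_read_totals[lib]
        total_row[f"{lib}_reads_pct"] = 100.0
    df = pd.DataFrame([total_row] + rows)
    return df.set_index("category")


def annotation_percentage(count: int, total: int) -> float:
    """Share of a category in a library total, half-up to 2 decimals."""
    return _pct(count, total)
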