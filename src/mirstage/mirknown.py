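"""Conserved (known) miRNA identification against a miRBase-style reference.

A tag is a conserved miRNA when it matches a reference precursor with zero
mismatches and its position overlaps the annotated mature window (within a
small shift tolerance for 5'/3' length variants).  Tags that fail the
perfect-match rule feed the single-base edit detector; matched sets drive
the arm tallies, name-based family assignment, and positional nucleotide
bias profiles.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fio import rna

DEFAULT_MATURE_SHIFT = 2


@dataclass(frozen=True)
class MatureRecord:
    name: str
    sequence: str  # RNA alphabet
    precursor: str
    precursor_seq: str
    window_start: int  # mature offset within precursor
    window_end: int

    def __post_init__(self):
        if (
            self.precursor_seq[self.window_start : self.window_end]
            != self.sequence
        ):
            raise ValueError(
                f"{self.name}: mature is not at {self.window_start}:{self.window_end} "
                f"of {self.precursor}"
            )


class MirnaReference:
    """Mature+precursor reference with mature-within-precursor coordinates."""

    def __init__(self, matures: list[MatureRecord]):
        self.matures = matures
        self.by_precursor: dict[str, list[MatureRecord]] = defaultdict(list)
        self.precursors: dict[str, str] = {}
        for m in matures:
            self.by_precursor[m.precursor].append(m)
            self.precursors[m.precursor] = m.precursor_seq

    @classmethod
    def from_files(cls, mature_fa, hairpin_fa, window_tsv) -> "MirnaReference":
        from ._fio import read_fasta

        matures = read_fasta(mature_fa)
        hairpins = read_fasta(hairpin_fa)
        recs = []
        with open(window_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                name = cols[idx["mature"]]
                pre = cols[idx["precursor"]]
                if name not in matures or pre not in hairpins:
                    raise ValueError(f"reference integrity: {name}/{pre} missing")
                recs.append(
                    MatureRecord(
                        name,
                        rna(matures[name]),
                        pre,
                        rna(hairpins[pre]),
                        int(cols[idx["start"]]),
                        int(cols[idx["end"]]),
                    )
                )
        return cls(recs)


@dataclass(frozen=True)
class KnownHit:
    tag: str
    mature: str
    precursor: str
    arm: str  # miR | miR* | miR-5p | miR-3p
    offset: int  # tag start within precursor


def _arm_class(name: str) -> str:
    if name.endswith("-5p"):
        return "miR-5p"
    if name.endswith("-3p"):
        return "miR-3p"
    if name.endswith("*") or name.endswith("-star"):
        return "miR*"
    return "miR"


def match_known(
    tag: str, reference: MirnaReference, mature_shift: int = DEFAULT_MATURE_SHIFT
) -> KnownHit | None:
    """Perfect precursor match overlapping the mature window, or ``None``.

    The tag (T->U normalised) must occur in a reference precursor with zero
    mismatches, starting within ``mature_shift`` nt of the annotated mature
    start.  One substitution anywhere breaks the match — such tags are left
    for the base-edit detector.
    """
    t = rna(tag)
    for pre_name, pre_seq in reference.precursors.items():
        start = pre_seq.find(t)
        while start != -1:
            for m in reference.by_precursor[pre_name]:
                if abs(start - m.window_start) <= mature_shift:
                    return KnownHit(t, m.name, pre_name, _arm_class(m.name), start)
            start = pre_seq.find(t, start + 1)
    return None


def match_library(
    tag_counts: dict[str, int],
    reference: MirnaReference,
    mature_shift: int = DEFAULT_MATURE_SHIFT,
) -> tuple[dict[str, KnownHit], dict[str, int]]:
    """Match all tags of one library; returns (hits by tag, counts by mature)."""
    hits: dict[str, KnownHit] = {}
    per_mature: Counter = Counter()
    for tag, count in tag_counts.items():
        hit = match_known(tag, reference, mature_shift)
        if hit is not None:
            hits[tag] = hit
            per_mature[hit.mature] += count
    return hits, dict(per_mature)


def tally_known(
    hits: dict[str, KnownHit], tag_counts: dict[str, int]
) -> dict[str, int]:
    """Arm-class tallies for one library (distinct matures, precursors, reads)."""
    by_arm: dict[str, set] = defaultdict(set)
    precursors = set()
    reads = 0
    for tag, hit in hits.items():
        by_arm[hit.arm].add(hit.mature)
        precursors.add(hit.precursor)
        reads += tag_counts.get(tag, 0)
    return {
        "miR": len(by_arm["miR"]),
        "miR*": len(by_arm["miR*"]),
        "miR-5p": len(by_arm["miR-5p"]),
        "miR-3p": len(by_arm["miR-3p"]),
        "pre_miRs": len(precursors),
        "unique_matched": len(hits),
        "reads_matched": reads,
    }


@dataclass(frozen=True)
class BaseEdit:
    tag: str
    mature: str
    position: int  # 1-based along the compared mature prefix
    reference_base: str
    observed_base: str
    count: int


def detect_base_edits(
    tag_counts: dict[str, int],
    reference: MirnaReference,
    length_slack: int = 2,
) -> tuple[list[BaseEdit], float]:
    """Single-substitution matches between unannotated tags and matures.

    Tags are compared to each mature over the 5'-anchored common prefix when
    lengths differ by at most ``length_slack``; a tag with exactly one best
    alignment at Hamming distance 1 yields an edit.  Ties between matures at
    distance 1 go to the lexicographically smallest mature name.  Returns
    the edits plus the fraction of candidate tags carrying an edit.
    """
    matures = sorted(reference.matures, key=lambda m: m.name)
    edits: list[BaseEdit] = []
    n_candidates = 0
    n_edited = 0
    for tag, count in tag_counts.items():
        t = rna(tag)
        n_candidates += 1
        best: tuple[str, int, str, str] | None = None
        for m in matures:
            if abs(len(t) - len(m.sequence)) > length_slack:
                continue
            k = min(len(t), len(m.sequence))
            mism = [
                i for i in range(k) if t[i] != m.sequence[i]
            ]
            if len(mism) == 1 and best is None:
                i = mism[0]
                best = (m.name, i + 1, m.sequence[i], t[i])
        if best is not None:
            n_edited += 1
            edits.append(BaseEdit(t, best[0], best[1], best[2], best[3], count))
    fraction = n_edited / n_candidates if n_candidates else 0.0
    return edits, fraction


_FAMILY_RE = re.compile(
    r"""^(?:[a-z]{2,4}-)?          # species prefix
        (let|miR|mir)-?(\d+)       # stem
        ([a-z]*)                   # variant letters
        ((?:-\d+)*)                # duplicate-locus numerals
        (?:-(5p|3p|star|\*))?$""",
    re.VERBOSE,
)


def assign_family(name: str) -> str:
    """miRNA gene family from a miRBase-style name.

    Strips the species prefix, arm suffixes, trailing variant letters and
    duplicate-locus numerals; ``let-7`` keeps its stem.  Unparseable names
    map to ``unassigned``.
    """
    m = _FAMILY_RE.match(name.strip().rstrip("*"))
    if not m:
        return "unassigned"
    stem, number = m.group(1), m.group(2)
    prefix = "let" if stem == "let" else "miR"
    return f"{prefix}-{number}"


def family_table(names) -> pd.DataFrame:
    rows = [(n, assign_family(n)) for n in names]
    return pd.DataFrame(rows, columns=["miRNA", "family"])


def position_bias(
    tag_counts: dict[str, int], max_length: int = 30
) -> pd.DataFrame:
    """Count-weighted base fraction per position (1-based) over matched tags.

    Fractions at each populated position sum to 1; the first/ninth/terminal
    position U enrichments conventionally reported for miRNAs can be read
    off rows 1, 9 and each tag's last position.
    """
    counts = np.zeros((max_length, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    for tag, n in tag_counts.items():
        t = rna(tag)
        if len(t) > max_length:
            continue
        for i, c in enumerate(t):
            counts[i, base_idx[c]] += n
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, counts / totals, 0.0)
    df = pd.DataFrame(frac, columns=["A", "C", "G", "U"])
    df.index = pd.RangeIndex(1, max_length + 1, name="position")
    return df
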