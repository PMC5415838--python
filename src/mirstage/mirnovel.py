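"""Novel miRNA discovery from unannotated tags.

Candidate loci are unannotated tag positions extended by 150 nt of flanking
genome on each side.  Each window is folded and screened with explicit
hairpin criteria: a 20-22 nt mature lying entirely within one arm of the
stem (no mature base inside the terminal loop, no internal unpaired stretch
longer than 3 nt), fewer than six unpaired mature positions against the
star arm, mature AU content within 30-70 %, precursor free energy below
-20 kcal/mol, and MFEI at or below -0.85; read support must additionally be
concentrated at the mature 5' end (Dicer-consistent processing).  Energy
criteria are evaluated on the refolded mature..star precursor span, not the
full extraction window, because pre-miRNA energy thresholds are meaningless
for a 320-nt window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ._engines import FoldResult, get_engine, pair_table
from ._fio import revcomp, rna
from .annotate import AnnotationRecord, TagAlignment

FLANK = 150


@dataclass(frozen=True)
class Thresholds:
    mature_min: int = 20
    mature_max: int = 22
    au_min: float = 0.30
    au_max: float = 0.70
    max_star_mismatches: int = 6  # criterion: strictly fewer than this
    mfe_max: float = -20.0
    mfei_max: float = -0.85
    max_loci: int = 10
    dicer_fraction: float = 0.8
    max_internal_unpaired: int = 3


DEFAULT_THRESHOLDS = Thresholds()

CRITERIA = ("length", "arm", "star", "au", "mfe", "mfei", "dicer")


def mfei(mfe: float, length: int, gc_fraction: float) -> float:
    """Minimal free energy index: AMFE / GC%, AMFE = MFE*100/length."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    amfe = mfe * 100.0 / length
    return amfe / (gc_fraction * 100.0)


def fold(sequence: str, engine=None) -> FoldResult:
    """Fold an RNA sequence with the configured engine (builtin by default)."""
    if engine is None:
        engine = get_engine("builtin")
    return engine.fold(sequence)


@dataclass
class HairpinEvaluation:
    flags: dict[str, bool]
    mature_start: int
    mature_end: int
    star_start: int = -1
    star_end: int = -1
    star_mismatches: int = -1
    au_fraction: float = float("nan")
    arm: str = ""

    @property
    def structural_pass(self) -> bool:
        return all(self.flags.get(c, False) for c in ("length", "arm", "star", "au"))


def evaluate_hairpin(
    fr: FoldResult, mature_start: int, mature_end: int, th: Thresholds = DEFAULT_THRESHOLDS
) -> HairpinEvaluation:
    """Structural criteria of a mature window within a folded sequence.

    Checks mature length, one-arm placement (all pairing partners on one
    side, last mature base toward the loop paired, no extra stem inside the
    terminal loop), internal unpaired runs, star mismatches and AU content.
    Energy criteria are evaluated separately on the precursor span.
    """
    ev = HairpinEvaluation({c: False for c in ("length", "arm", "star", "au")},
                           mature_start, mature_end)
    L = mature_end - mature_start
    ev.flags["length"] = th.mature_min <= L <= th.mature_max
    seq = fr.sequence
    mature = seq[mature_start:mature_end]
    au = (mature.count("A") + mature.count("U")) / max(L, 1)
    ev.au_fraction = au
    ev.flags["au"] = th.au_min <= au <= th.au_max
    pt = pair_table(fr.structure)
    paired = [i for i in range(mature_start, mature_end) if pt[i] != -1]
    if not paired:
        return ev
    partners = [pt[i] for i in paired]
    if min(partners) >= mature_end:
        arm = "5p"
        inner = max(paired)
    elif max(partners) < mature_start:
        arm = "3p"
        inner = min(paired)
    else:
        return ev  # mature straddles the loop or pairs with itself
    ev.arm = arm
    # terminal-loop integrity: the pair closing the loop on the mature side
    # must be the mature's own innermost paired base, with no stem inside.
    j = pt[inner]
    lo, hi = (inner, j) if inner < j else (j, inner)
    if any(pt[k] != -1 for k in range(lo + 1, hi)):
        return ev
    # no mature base inside the terminal loop
    if arm == "5p" and inner != mature_end - 1:
        return ev
    if arm == "3p" and inner != mature_start:
        return ev
    # no internal unpaired stretch longer than the allowed break
    run = best_run = 0
    for i in range(mature_start, mature_end):
        run = run + 1 if pt[i] == -1 else 0
        best_run = max(best_run, run)
    if best_run > th.max_internal_unpaired:
        return ev
    ev.flags["arm"] = True
    mismatches = L - len(paired)
    ev.star_mismatches = mismatches
    ev.flags["star"] = mismatches < th.max_star_mismatches
    star_lo = min(pt[i] for i in paired)
    star_hi = max(pt[i] for i in paired) + 1
    ev.star_start, ev.star_end = star_lo, star_hi
    return ev


@dataclass
class CandidateWindow:
    """A flanked genomic locus to be screened, in window-local coordinates."""

    contig: str
    start: int  # genomic start of the window (0-based)
    end: int
    strand: str
    sequence: str  # + strand reads 5'->3'; '-' windows are reverse-complemented
    tag: str
    tag_offset: int  # mature start within sequence
    read_support: dict[int, int] = field(default_factory=dict)  # offset -> reads


@dataclass
class HairpinCandidate:
    window: CandidateWindow
    precursor_seq: str = ""
    precursor_start: int = -1  # window-local
    precursor_end: int = -1
    fold: FoldResult | None = None
    mature_start: int = -1
    mature_end: int = -1
    star_start: int = -1
    star_end: int = -1
    mismatches_vs_star: int = -1
    au_fraction: float = float("nan")
    mfe: float = float("nan")
    mfei: float = float("nan")
    n_genome_loci: int = 0
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def verdict(self) -> bool:
        return all(self.flags.get(c, False) for c in CRITERIA)


def extract_candidates(
    records: dict[str, AnnotationRecord],
    tag_counts: dict[str, int],
    genome: dict[str, str],
    flank: int = FLANK,
    max_loci: int = DEFAULT_THRESHOLDS.max_loci,
    min_count: int = 3,
) -> list[CandidateWindow]:
    """Flanked windows around unannotated tag loci.

    Tags with more than ``max_loci`` genomic hits, a non-unann annotation,
    or fewer than ``min_count`` supporting reads (noise floor: sequencing
    errors and stray background are dominated by singletons) are excluded;
    windows are clipped at contig edges and minus-strand windows
    reverse-complemented.  Read support collects the starts of all eligible
    tags aligning same-strand inside each window.
    """
    eligible: list[tuple[str, TagAlignment]] = []
    for tag, rec in records.items():
        if rec.category != "unann" or rec.n_loci == 0 or rec.n_loci > max_loci:
            continue
        if tag_counts.get(tag, 0) < min_count:
            continue
        for aln in rec.alignments:
            eligible.append((tag, aln))

    windows: list[CandidateWindow] = []
    for tag, aln in eligible:
        contig_seq = genome[aln.contig]
        w_start = max(0, aln.start - flank)
        w_end = min(len(contig_seq), aln.end + flank)
        seq = contig_seq[w_start:w_end].upper()
        if aln.strand == "+":
            offset = aln.start - w_start
        else:
            seq = revcomp(seq)
            offset = w_end - aln.end
        support: dict[int, int] = {}
        for t2, a2 in eligible:
            if (
                a2.contig == aln.contig
                and a2.strand == aln.strand
                and w_start <= a2.start
                and a2.end <= w_end
            ):
                off2 = (
                    a2.start - w_start if aln.strand == "+" else w_end - a2.end
                )
                support[off2] = support.get(off2, 0) + tag_counts.get(t2, 0)
        windows.append(
            CandidateWindow(
                aln.contig, w_start, w_end, aln.strand, rna(seq), rna(tag),
                offset, support,
            )
        )
    return _merge_windows(windows, tag_counts)


def _merge_windows(
    windows: list[CandidateWindow], tag_counts: dict[str, int]
) -> list[CandidateWindow]:
    """Merge overlapping windows; the highest-count tag defines the mature."""
    windows = sorted(
        windows,
        key=lambda w: (w.contig, w.strand, -tag_counts.get(w.tag.replace("U", "T"), 0)),
    )
    kept: list[CandidateWindow] = []
    for w in windows:
        overlaps = any(
            k.contig == w.contig
            and k.strand == w.strand
            and k.start < w.end
            and w.start < k.end
            for k in kept
        )
        if not overlaps:
            kept.append(w)
    kept.sort(key=lambda w: (w.contig, w.start, w.strand))
    return kept


def screen_candidate(
    window: CandidateWindow,
    engine=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> HairpinCandidate:
    """Apply the hairpin criteria to one candidate window.

    The window fold locates the arms; the mature..star span is then refolded
    as the precursor and all structural and energy criteria are evaluated on
    that fold.  Every criterion flag is recorded; the verdict is their AND.
    """
    if engine is None:
        engine = get_engine("builtin")
    cand = HairpinCandidate(window=window)
    ms = window.tag_offset
    me = ms + len(window.tag)
    wfold = engine.fold(window.sequence)
    wev = evaluate_hairpin(wfold, ms, me, thresholds)
    cand.flags = {c: False for c in CRITERIA}
    cand.flags["length"] = wev.flags["length"]
    cand.flags["dicer"] = _dicer_consistent(window, thresholds)
    if not (wev.flags["arm"] and wev.star_start >= 0):
        cand.flags["au"] = wev.flags["au"]
        cand.fold = wfold
        cand.mature_start, cand.mature_end = ms, me
        return cand
    # refold the precursor span and re-evaluate there
    p_lo = min(ms, wev.star_start)
    p_hi = max(me, wev.star_end)
    pre_seq = window.sequence[p_lo:p_hi]
    pfold = engine.fold(pre_seq)
    pev = evaluate_hairpin(pfold, ms - p_lo, me - p_lo, thresholds)
    cand.precursor_seq = pre_seq
    cand.precursor_start, cand.precursor_end = p_lo, p_hi
    cand.fold = pfold
    cand.mature_start, cand.mature_end = ms - p_lo, me - p_lo
    cand.star_start, cand.star_end = pev.star_start, pev.star_end
    cand.mismatches_vs_star = pev.star_mismatches
    cand.au_fraction = pev.au_fraction
    cand.mfe = pfold.mfe
    gc = (pre_seq.count("G") + pre_seq.count("C")) / len(pre_seq)
    cand.mfei = mfei(pfold.mfe, len(pre_seq), gc) if 0 < gc < 1 else 0.0
    cand.flags["length"] = pev.flags["length"]
    cand.flags["arm"] = pev.flags["arm"]
    cand.flags["star"] = pev.flags["star"]
    cand.flags["au"] = pev.flags["au"]
    cand.flags["mfe"] = pfold.mfe < thresholds.mfe_max
    cand.flags["mfei"] = cand.mfei <= thresholds.mfei_max
    return cand


def _dicer_consistent(window: CandidateWindow, th: Thresholds) -> bool:
    """>= the configured fraction of locus reads start at the mature 5' +-2."""
    total = sum(window.read_support.values())
    if total == 0:
        return False
    near = sum(
        n
        for off, n in window.read_support.items()
        if abs(off - window.tag_offset) <= 2
    )
    return near / total >= th.dicer_fraction


def screen_all(
    windows: list[CandidateWindow],
    engine=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[HairpinCandidate]:
    return [screen_candidate(w, engine, thresholds) for w in windows]


def with_thresholds(base: Thresholds = DEFAULT_THRESHOLDS, **kwargs) -> Thresholds:
    return replace(base, **kwargs)
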