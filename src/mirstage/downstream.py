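"""Seed-based miRNA target prediction and qPCR relative quantification.

Target sites are scored by scanning every transcript window of miRNA
length with an ungapped complementarity penalty: matches cost 0, G:U
wobbles 0.5, mismatches 1.0, with penalties doubled across miRNA positions
2-13 (the seed-proximal region).  Hits must stay at or below a penalty
cutoff (default 4.0) and form a sufficiently stable duplex under the
intermolecular pair energies of the reference folding engine (default
<= -10 kcal/mol).  The qPCR utility computes relative expression as
N = 2^-ddCt against a reference gene and a control condition.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._engines import _BIG, pair_energy
from ._fio import rna

WOBBLE_PENALTY = 0.5
MISMATCH_PENALTY = 1.0
CORE_START = 2  # 1-based, inclusive
CORE_END = 13
CORE_MULTIPLIER = 2.0
DEFAULT_MAX_SCORE = 4.0
DEFAULT_ENERGY_MAX = -10.0

_WOBBLE = {("G", "U"), ("U", "G")}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class TargetHit:
    mirna: str
    transcript: str
    start: int  # 0-based site start on the transcript
    alignment: str
    penalty_score: float
    duplex_energy: float


def penalty_score(mirna_seq: str, site_seq: str) -> float:
    """Allen-style complementarity penalty for an ungapped miRNA:site duplex.

    The miRNA (5'->3') pairs antiparallel with the site, so miRNA position i
    (1-based) faces site position L-i.  Per position: Watson-Crick match 0,
    G:U wobble 0.5, mismatch 1.0; doubled at miRNA positions 2-13.
    """
    mi = rna(mirna_seq)
    site = rna(site_seq)
    if len(mi) != len(site):
        raise ValueError("miRNA and site must have equal length")
    score = 0.0
    L = len(mi)
    for i, base in enumerate(mi):  # i = 0-based miRNA position
        partner = site[L - 1 - i]
        duo = (base, partner)
        if duo in _WC:
            pen = 0.0
        elif duo in _WOBBLE:
            pen = WOBBLE_PENALTY
        else:
            pen = MISMATCH_PENALTY
        if CORE_START <= i + 1 <= CORE_END:
            pen *= CORE_MULTIPLIER
        score += pen
    return score


def duplex_energy(mirna_seq: str, site_seq: str) -> float:
    """Intermolecular duplex energy: sum of pair energies over paired faces.

    Uses the reference engine pair terms (GC -3, AU -2, GU -1); non-pairing
    faces contribute 0.  No intramolecular folding is considered.
    """
    mi = rna(mirna_seq)
    site = rna(site_seq)
    if len(mi) != len(site):
        raise ValueError("miRNA and site must have equal length")
    L = len(mi)
    total = 0.0
    for i, base in enumerate(mi):
        e = pair_energy(base, site[L - 1 - i])
        if e < _BIG / 2:
            total += e
    return total


def _alignment_text(mirna_seq: str, site_seq: str) -> str:
    mi = rna(mirna_seq)
    site = rna(site_seq)
    L = len(mi)
    marks = []
    for i, base in enumerate(mi):
        duo = (base, site[L - 1 - i])
        marks.append("|" if duo in _WC else ("o" if duo in _WOBBLE else " "))
    return f"3'-{site[::-1]}-5'\n   {''.join(marks)}\n5'-{mi}-3'"


def find_targets(
    mirna_name: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
    energy_max: float = DEFAULT_ENERGY_MAX,
) -> list[TargetHit]:
    """Scan transcripts for sites of one miRNA; report every qualifying hit."""
    mi = rna(mirna_seq)
    L = len(mi)
    hits: list[TargetHit] = []
    for tname, tseq in transcripts.items():
        t = rna(tseq)
        for s in range(0, len(t) - L + 1):
            site = t[s : s + L]
            score = penalty_score(mi, site)
            if score > max_score:
                continue
            energy = duplex_energy(mi, site)
            if energy > energy_max:
                continue
            hits.append(
                TargetHit(mirna_name, tname, s, _alignment_text(mi, site), score, energy)
            )
    return hits


@dataclass(frozen=True)
class QpcrResult:
    dct_treatment: float
    dct_control: float
    ddct: float
    fold: float  # N = 2^-ddct


def ddct(
    target_ct_treatment: float,
    reference_ct_treatment: float,
    target_ct_control: float,
    reference_ct_control: float,
) -> QpcrResult:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt is treatment minus
    control; the fold is exactly 2^-ddCt.
    """
    for v in (
        target_ct_treatment,
        reference_ct_treatment,
        target_ct_control,
        reference_ct_control,
    ):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError("Ct values must be finite")
    dct_t = target_ct_treatment - reference_ct_treatment
    dct_c = target_ct_control - reference_ct_control
    dd = dct_t - dct_c
    return QpcrResult(dct_t, dct_c, dd, 2.0 ** (-dd))
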