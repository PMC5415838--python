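"""File-format helpers: FASTA/FASTQ via Biopython, flat GFF3 interval records.

Coordinates are 0-based half-open in memory and converted to 1-based
inclusive on GFF3 write (and back on read).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Feature:
    """A genomic interval annotation (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    ftype: str
    fid: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval {self.start}:{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, list[int]]]) -> None:
    """Write (id, sequence, phred-scores) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]


def write_gff3(path: str | Path, features: Iterable[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\tmirstage\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.fid}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                Feature(
                    contig=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    ftype=cols[2],
                    fid=attrs.get("ID", f"{cols[2]}:{cols[0]}:{cols[3]}"),
                )
            )
    return feats


_COMP = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output; U treated as T)."""
    return seq.translate(_COMP)[::-1]


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")
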