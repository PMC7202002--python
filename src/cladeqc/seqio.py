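"""Sequence and interval file I/O helpers.

FASTA and FASTQ pass through Bio.SeqIO (60-column FASTA wrap, Phred+33
FASTQ). BED6 and the small VCF v4.2 emitter are plain-text writers so that
every artifact this package produces is diff-able text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    """Load FASTQ as (id, bases, phred qualities) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(path, reads: Iterable[tuple[str, str, list[int]]]) -> None:
    records = []
    for rid, bases, quals in reads:
        rec = SeqRecord(Seq(bases), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


@dataclass(frozen=True)
class BedInterval:
    """A BED6 interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path) -> list[BedInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(BedInterval(f[0], int(f[1]), int(f[2]),
                               f[3] if len(f) > 3 else ".",
                               float(f[4]) if len(f) > 4 else 0,
                               f[5] if len(f) > 5 else "+"))
    return out


def write_bed(path, intervals: Iterable[BedInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{iv.score:g}\t{iv.strand}\n")
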