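"""Readers and writers for the formats the pipeline consumes and emits.

Conventions used throughout the package:

* internal coordinates are **1-based inclusive** (GFF3-native);
* BED files are converted at the boundary (0-based half-open on disk);
* FASTA/FASTQ sequences are normalised to uppercase on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A malformed record in an input file (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


# ---------------------------------------------------------------------------
# genome container
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Named chromosome/contig sequences, 1-based inclusive coordinates."""

    sequences: dict[str, str] = field(default_factory=dict)
    coordinate_system: str = "1-based inclusive"

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice [start, end] 1-based inclusive."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.sequences[chrom][start - 1:end]


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return Genome(sequences=seqs)


def write_fasta(genome: Genome | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    seqs = genome.sequences if isinstance(genome, Genome) else genome
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Return (read_id, sequence) pairs; qualities are not retained."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive)
# ---------------------------------------------------------------------------

@dataclass
class GffRecord:
    chrom: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int
    score: str = "."
    strand: str = "+"
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def attribute_string(self) -> str:
        if not self.attributes:
            return "."
        return ";".join(f"{k}={v}" for k, v in self.attributes.items())


def read_gff3(path: str | Path) -> list[GffRecord]:
    records: list[GffRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"GFF3 record has {len(fields)} fields, expected 9",
                                  line=lineno)
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError("non-integer GFF3 coordinates", line=lineno)
            attrs: dict[str, str] = {}
            if fields[8] != ".":
                for item in fields[8].split(";"):
                    if not item:
                        continue
                    key, _, value = item.partition("=")
                    attrs[key] = value
            records.append(GffRecord(chrom=fields[0], source=fields[1],
                                     type=fields[2], start=start, end=end,
                                     score=fields[5], strand=fields[6],
                                     phase=fields[7], attributes=attrs))
    return records


def write_gff3(records: Iterable[GffRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write("\t".join([rec.chrom, rec.source, rec.type,
                                str(rec.start), str(rec.end), rec.score,
                                rec.strand, rec.phase, rec.attribute_string()])
                     + "\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; converted to 1-based inclusive)
# ---------------------------------------------------------------------------

@dataclass
class Interval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    name: str = "."
    strand: str = "+"


def read_bed(path: str | Path) -> list[Interval]:
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("BED record needs at least 3 fields", line=lineno)
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError("non-integer BED coordinates", line=lineno)
            intervals.append(Interval(
                chrom=fields[0], start=start0 + 1, end=end0,
                name=fields[3] if len(fields) > 3 else ".",
                strand=fields[5] if len(fields) > 5 else "+"))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# marker matrices (TSV: first column accession id, remaining columns 0/1)
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all(axis=None)
    if bad:
        raise FormatError("marker matrix entries must be 0/1")
    return df.astype(int)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def bundled_data(name: str) -> pd.DataFrame:
    """Load one of the TSV tables shipped with the package."""
    return pd.read_csv(Path(__file__).parent / "data" / name, sep="\t")
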