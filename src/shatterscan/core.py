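"""Shared containers: genomes, read sets, and small sequence utilities.

Sequences are held as ASCII ``bytes`` over the A/C/G/T alphabet (plus N for
real input) and all internal coordinates are 0-based half-open; conversion to
1-based happens only at FASTA/GFF/SAM/TSV boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "ShatterscanError",
    "ParameterError",
    "FormatError",
    "Genome",
    "ReadSet",
    "revcomp",
    "seq_to_codes",
    "codes_to_seq",
    "BASES",
]

BASES = b"ACGT"

# uint8 ASCII -> 0..3 code; 255 marks non-ACGT
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[_b] = _i
    _CODE_LUT[ord(chr(_b).lower())] = _i

_COMP_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


class ShatterscanError(Exception):
    """Base class for package errors."""


class ParameterError(ShatterscanError, ValueError):
    """Invalid parameter value."""


class FormatError(ShatterscanError, ValueError):
    """Malformed input file."""


def revcomp(seq: bytes) -> bytes:
    """Reverse complement of an ACGT(N) byte string."""
    return seq.translate(_COMP_TABLE)[::-1]


def seq_to_codes(seq: bytes) -> np.ndarray:
    """ASCII bytes -> uint8 codes in 0..3 (255 for non-ACGT)."""
    return _CODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> bytes:
    """uint8 codes in 0..3 -> ASCII bytes."""
    lut = np.frombuffer(BASES, dtype=np.uint8)
    return lut[codes].tobytes()


@dataclass
class Genome:
    """A set of named chromosome sequences.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to ASCII sequence bytes.
    strict
        When True (simulation default) restrict the alphabet to ACGT;
        real input may additionally contain N.
    """

    sequences: dict[str, bytes]
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ParameterError("genome has no chromosomes")
        allowed = set(b"ACGT") if self.strict else set(b"ACGTN")
        for name, seq in self.sequences.items():
            if not seq:
                raise ParameterError(f"chromosome {name!r} is empty")
            if not set(seq) <= allowed:
                raise ParameterError(
                    f"chromosome {name!r} contains bases outside "
                    f"{'ACGT' if self.strict else 'ACGTN'}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> bytes:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def array(self, name: str) -> np.ndarray:
        """Chromosome as a uint8 ASCII array (zero-copy view)."""
        return np.frombuffer(self.sequences[name], dtype=np.uint8)

    @classmethod
    def from_fasta(cls, path: str | Path, strict: bool = False) -> "Genome":
        from Bio import SeqIO

        seqs: dict[str, bytes] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise FormatError(f"duplicate FASTA record {rec.id!r}")
            seqs[rec.id] = bytes(str(rec.seq).upper(), "ascii")
        if not seqs:
            raise FormatError(f"no FASTA records in {path}")
        return cls(seqs, strict=strict)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width].decode("ascii"))
                    fh.write("\n")


@dataclass
class ReadSet:
    """Simulated or ingested short reads.

    For paired data mates of fragment ``i`` are stored at indices ``2*i``
    (mate 1, forward fragment end) and ``2*i + 1`` (mate 2, reverse
    complement of the other fragment end) and share the id ``f{i}``.
    Unpaired reads get id ``r{i}`` and mate index 0.
    """

    sequences: list[bytes]
    paired: bool = False
    qualities: list[bytes] | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.paired and len(self.sequences) % 2:
            raise ParameterError("paired ReadSet must hold an even read count")
        for seq in self.sequences:
            if not seq:
                raise ParameterError("empty read sequence")

    def __len__(self) -> int:
        return len(self.sequences)

    def read_id(self, i: int) -> str:
        if self.ids is not None:
            return self.ids[i]
        return f"f{i // 2}" if self.paired else f"r{i}"

    def mate_index(self, i: int) -> int:
        return (i % 2) + 1 if self.paired else 0

    def mate_of(self, i: int) -> int | None:
        """Index of the mate read, or None for unpaired data."""
        if not self.paired:
            return None
        return i + 1 if i % 2 == 0 else i - 1

    def quality(self, i: int) -> bytes:
        if self.qualities is not None:
            return self.qualities[i]
        return b"I" * len(self.sequences[i])  # constant Q40

    def records(self) -> Iterator[tuple[str, bytes, bytes, int]]:
        """Yield (id, sequence, quality, mate index in {0,1,2})."""
        for i, seq in enumerate(self.sequences):
            yield self.read_id(i), seq, self.quality(i), self.mate_index(i)

    def to_fastq(self, path: str | Path, gzip_out: bool | None = None) -> None:
        import gzip as _gzip

        path = Path(path)
        if gzip_out is None:
            gzip_out = path.suffix == ".gz"
        opener = _gzip.open if gzip_out else open
        with opener(path, "wt") as fh:
            for rid, seq, qual, mate in self.records():
                suffix = f"/{mate}" if mate else ""
                fh.write(f"@{rid}{suffix}\n{seq.decode()}\n+\n{qual.decode()}\n")

    @classmethod
    def from_fastq(cls, path: str | Path, paired: bool = False) -> "ReadSet":
        import gzip as _gzip

        path = Path(path)
        opener = _gzip.open if path.suffix == ".gz" else open
        seqs: list[bytes] = []
        quals: list[bytes] = []
        ids: list[str] = []
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                if not header.startswith("@"):
                    raise FormatError(f"bad FASTQ header line: {header!r}")
                seq = fh.readline().strip()
                plus = fh.readline()
                qual = fh.readline().strip()
                if not qual or not plus.startswith("+"):
                    raise FormatError(f"truncated FASTQ record {header.strip()!r}")
                ids.append(header[1:].strip().split()[0].split("/")[0])
                seqs.append(seq.encode("ascii").upper())
                quals.append(qual.encode("ascii"))
        return cls(seqs, paired=paired, qualities=quals, ids=ids)
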