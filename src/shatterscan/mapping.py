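"""Read filtering, a built-in unique short-read mapper, SAM ingest, pileups.

The built-in mapper is deliberately minimal: it places a read only when it
matches the reference uniquely over its full length (Hamming distance up to a
configurable ``max_mismatches``, default 0).  Clean synthetic reads need no
more than that; the mismatch allowance exists so that reads from the
non-reference parental haplotype, which differ from the reference at SNPs,
can still be placed.  Real or noisy data should come in as SAM instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    FormatError,
    Genome,
    ParameterError,
    ReadSet,
    revcomp,
    seq_to_codes,
)

__all__ = [
    "AlignmentSet",
    "Pileup",
    "GenomeIndex",
    "filter_reads",
    "map_reads",
    "read_sam",
    "build_pileup",
]


@dataclass
class AlignmentSet:
    """Unique alignments of a read set against one reference.

    Arrays are parallel over mapped reads; ``read_index`` refers back into
    the originating :class:`~shatterscan.core.ReadSet`.  ``n_reads`` is the
    total read count including unmapped/non-unique reads.
    """

    chrom_names: list[str]
    read_index: np.ndarray  # int64
    chrom_id: np.ndarray  # int32
    start: np.ndarray  # int64, 0-based
    strand: np.ndarray  # int8: 0 = forward, 1 = reverse
    length: np.ndarray  # int32
    n_reads: int
    mismatches: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.read_index)

    def mapped_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_reads, dtype=bool)
        mask[self.read_index] = True
        return mask

    def position_of(self) -> dict[int, int]:
        """read index -> row number, for mate lookups."""
        return {int(r): i for i, r in enumerate(self.read_index)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_index": self.read_index,
                "chrom": [self.chrom_names[c] for c in self.chrom_id],
                "start": self.start,
                "strand": np.where(self.strand == 0, "+", "-"),
                "length": self.length,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def filter_reads(
    reads: ReadSet, quality_threshold: int = 20, min_length: int = 30
) -> ReadSet:
    """Drop N-containing reads, trim low-quality 3' tails, enforce a minimum
    surviving length.  For paired data a pair is dropped when either mate
    fails, keeping mate bookkeeping intact."""
    keep: list[int] = []
    trimmed: list[bytes] = []
    quals: list[bytes] = []
    for i, seq in enumerate(reads.sequences):
        if b"N" in seq:
            trimmed.append(b"")
            quals.append(b"")
            continue
        q = reads.quality(i)
        cut = len(seq)
        while cut > 0 and q[cut - 1] - 33 < quality_threshold:
            cut -= 1
        trimmed.append(seq[:cut])
        quals.append(q[:cut])
    ok = [len(t) >= min_length for t in trimmed]
    if reads.paired:
        ok = [ok[i] and ok[i + 1 if i % 2 == 0 else i - 1] for i in range(len(ok))]
    keep = [i for i, good in enumerate(ok) if good]
    return ReadSet(
        [trimmed[i] for i in keep],
        paired=reads.paired,
        qualities=[quals[i] for i in keep],
        ids=[reads.read_id(i) for i in keep],
    )


class GenomeIndex:
    """Exact k-mer index over both strands' forward sequence, reused across
    samples mapped to the same reference."""

    def __init__(self, genome: Genome, seed_len: int = 20):
        if seed_len < 8:
            raise ParameterError("seed_len must be >= 8")
        self.genome = genome
        self.seed_len = seed_len
        self.chrom_names = genome.names
        self.seqs = [genome[name] for name in self.chrom_names]
        self.index: dict[bytes, list[tuple[int, int]]] = {}
        for cid, seq in enumerate(self.seqs):
            k = seed_len
            idx = self.index
            for p in range(len(seq) - k + 1):
                key = seq[p : p + k]
                bucket = idx.get(key)
                if bucket is None:
                    idx[key] = [(cid, p)]
                else:
                    bucket.append((cid, p))

    def candidates(self, read: bytes) -> set[tuple[int, int]]:
        """Candidate (chrom, start) placements from non-overlapping seeds."""
        k = self.seed_len
        L = len(read)
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        out: set[tuple[int, int]] = set()
        for off in offsets:
            for cid, p in self.index.get(read[off : off + k], ()):
                s = p - off
                if 0 <= s <= len(self.seqs[cid]) - L:
                    out.add((cid, s))
        return out


def _hamming(a: bytes, b: bytes, limit: int) -> int:
    if a == b:
        return 0
    if limit == 0:
        return limit + 1
    diff = np.frombuffer(a, np.uint8) != np.frombuffer(b, np.uint8)
    return int(diff.sum())


def map_reads(
    genome: Genome | GenomeIndex,
    reads: ReadSet,
    seed_len: int = 20,
    max_mismatches: int = 0,
) -> AlignmentSet:
    """Place each read at its unique full-length match (either strand).

    A read is reported iff exactly one placement over both strands matches
    within ``max_mismatches`` Hamming distance; reads matching at several
    sites are non-unique and excluded, reads matching nowhere are unmapped.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, seed_len)
    seqs = index.seqs
    ridx: list[int] = []
    cids: list[int] = []
    starts: list[int] = []
    strands: list[int] = []
    lens: list[int] = []
    mms: list[int] = []
    for i, read in enumerate(reads.sequences):
        if len(read) < index.seed_len:
            continue
        rc = revcomp(read)
        hits: list[tuple[int, int, int, int]] = []
        for strand, oriented in ((0, read), (1, rc)):
            for cid, s in index.candidates(oriented):
                mm = _hamming(seqs[cid][s : s + len(read)], oriented, max_mismatches)
                if mm <= max_mismatches:
                    hits.append((cid, s, strand, mm))
        # the same placement can surface on both strands for palindromes;
        # uniqueness is over distinct (chrom, start)
        distinct = {(c, s) for c, s, _, _ in hits}
        if len(distinct) != 1:
            continue
        cid, s, strand, mm = min(hits, key=lambda h: h[3])
        ridx.append(i)
        cids.append(cid)
        starts.append(s)
        strands.append(strand)
        lens.append(len(read))
        mms.append(mm)
    return AlignmentSet(
        chrom_names=index.chrom_names,
        read_index=np.array(ridx, dtype=np.int64),
        chrom_id=np.array(cids, dtype=np.int32),
        start=np.array(starts, dtype=np.int64),
        strand=np.array(strands, dtype=np.int8),
        length=np.array(lens, dtype=np.int32),
        n_reads=len(reads),
        mismatches=np.array(mms, dtype=np.int16),
    )


def read_sam(path: str | Path, mapq_floor: int = 20) -> tuple[AlignmentSet, ReadSet]:
    """Ingest primary mapped SAM records.

    POS is converted from 1-based to the internal 0-based convention.
    Records below ``mapq_floor`` are treated as non-unique and skipped, as
    are unmapped, secondary and supplementary records.  Returns the
    alignments together with the read sequences they carry.
    """
    import pysam

    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("@"):
        raise FormatError(f"{path}: missing SAM header (line 1)")
    chrom_names: list[str] = []
    chrom_ids: dict[str, int] = {}
    ridx: list[int] = []
    cids: list[int] = []
    starts: list[int] = []
    strands: list[int] = []
    lens: list[int] = []
    seqs: list[bytes] = []
    ids: list[str] = []
    n = 0
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    with sam:
        for lineno, rec in enumerate(sam, start=1):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                chrom = rec.reference_name
                if chrom not in chrom_ids:
                    chrom_ids[chrom] = len(chrom_names)
                    chrom_names.append(chrom)
                seq = (rec.query_sequence or "").encode("ascii").upper()
                if not seq:
                    continue
                if rec.mapping_quality < mapq_floor:
                    continue
                ridx.append(n)
                cids.append(chrom_ids[chrom])
                starts.append(rec.reference_start)  # pysam is already 0-based
                strands.append(1 if rec.is_reverse else 0)
                lens.append(rec.query_alignment_length or len(seq))
                seqs.append(seq if not rec.is_reverse else revcomp(seq))
                ids.append(rec.query_name)
                n += 1
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: malformed SAM record {lineno}: {exc}")
    reads = ReadSet(seqs, paired=False, ids=ids)
    aln = AlignmentSet(
        chrom_names=chrom_names,
        read_index=np.array(ridx, dtype=np.int64),
        chrom_id=np.array(cids, dtype=np.int32),
        start=np.array(starts, dtype=np.int64),
        strand=np.array(strands, dtype=np.int8),
        length=np.array(lens, dtype=np.int32),
        n_reads=n,
    )
    return aln, reads


@dataclass
class Pileup:
    """Per-position A/C/G/T counts from unique alignments.

    ``counts[chrom]`` is a (4, chrom_len) uint32 array in A,C,G,T order.
    """

    counts: dict[str, np.ndarray]

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)

    def at(self, chrom: str, pos: int) -> dict[str, int]:
        col = self.counts[chrom][:, pos]
        return {base: int(col[i]) for i, base in enumerate("ACGT")}

    def write_tsv(self, path: str | Path, min_depth: int = 1) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos1\tA\tC\tG\tT\n")
            for chrom, mat in self.counts.items():
                nz = np.flatnonzero(mat.sum(axis=0) >= min_depth)
                for p in nz:
                    a, c, g, t = mat[:, p]
                    fh.write(f"{chrom}\t{p + 1}\t{a}\t{c}\t{g}\t{t}\n")


def build_pileup(
    alignments: AlignmentSet,
    reads: ReadSet,
    genome: Genome,
    positions: dict[str, np.ndarray] | None = None,
    chunk: int = 100_000,
) -> Pileup:
    """Accumulate allele counts from unique alignments.

    Mismatching read bases are counted as observed (no realignment).  When
    ``positions`` is given, counts outside those positions are zeroed; a
    position beyond the chromosome end raises an error.
    """
    counts = {
        name: np.zeros((4, length), dtype=np.uint32)
        for name, length in genome.lengths.items()
    }
    if positions is not None:
        for chrom, pos in positions.items():
            if len(pos) and (pos.max() >= len(genome[chrom]) or pos.min() < 0):
                raise ParameterError(f"pileup position outside {chrom}")
    name_of = alignments.chrom_names
    for cid, chrom in enumerate(name_of):
        if chrom not in counts:
            continue
        sel = np.flatnonzero(alignments.chrom_id == cid)
        clen = len(genome[chrom])
        for lo in range(0, len(sel), chunk):
            rows = sel[lo : lo + chunk]
            if not len(rows):
                continue
            # oriented (reference-frame) read bases
            blobs = []
            offsets = []
            for r in rows:
                ri = int(alignments.read_index[r])
                seq = reads.sequences[ri]
                if alignments.strand[r]:
                    seq = revcomp(seq)
                blobs.append(seq)
                offsets.append(len(seq))
            lens = np.array(offsets, dtype=np.int64)
            codes = seq_to_codes(b"".join(blobs)).astype(np.int64)
            starts = alignments.start[rows]
            pos = np.repeat(starts, lens) + _ragged_arange(lens)
            valid = codes < 4
            flat = codes[valid] * clen + pos[valid]
            add = np.bincount(flat, minlength=4 * clen).astype(np.uint32)
            counts[chrom] += add.reshape(4, clen)
    if positions is not None:
        for chrom, mat in counts.items():
            keep = positions.get(chrom)
            mask = np.zeros(mat.shape[1], dtype=bool)
            if keep is not None and len(keep):
                mask[keep] = True
            mat[:, ~mask] = 0
    return Pileup(counts)


def _ragged_arange(lengths: np.ndarray) -> np.ndarray:
    """Concatenated [0..l) ranges for each l in lengths."""
    total = int(lengths.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(lengths)[:-1]
    out[ends] = -lengths[:-1] + 1
    return np.cumsum(out)
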