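"""Synthetic genomes, planted shattered chromosomes, reads and truth sets.

The generator emulates a Col-0/Ler-like hybrid: two parental haplotypes that
differ only at planted SNPs, a diploid background, and one restructured
("shattered") chromosome assembled from blocks of one parent joined by
junctions with microhomology, blunt fusion, or novel-insertion chemistry.

Copy-number semantics follow the replacement model of genome elimination: the
shattered chromosome replaces the haploid-inducer (parent A) homolog, so a
source interval present ``n`` times in the derived chromosome has total copy
state ``1 + n`` (the remaining parent-B homolog plus the derived copies).
Intervals absent from the derived chromosome are copy state 1 with loss of
heterozygosity; duplicated (state 3) and triplicated (state 4) intervals carry
extra parent-A copies.

Microhomology is only observable when the reference itself carries the shared
bases on both sides of the join, so planting a k-bp microhomology edits the
opening k bases of the right-hand block *in the source genome*; the same edits
must be applied to both parental haplotypes (a shared ancestral flank), which
:func:`plant_shattered` does while keeping the SNP table exact.  One guard
base on each side of every junction is likewise fixed so that the realized
maximal overlap equals the planted value instead of being inflated by chance
1-in-4 flank matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    BASES,
    Genome,
    ParameterError,
    ReadSet,
    codes_to_seq,
    revcomp,
)

__all__ = [
    "Block",
    "JunctionSpec",
    "BlockPlan",
    "TruthSet",
    "make_parental_genomes",
    "random_plan",
    "build_shattered_chromosome",
    "apply_edits",
    "plant_shattered",
    "simulate_reads",
    "simulate_annotations",
    "hybrid_nucleus",
    "trisomic_nucleus",
    "truncated_nucleus",
    "shattered_nucleus",
]

_COMP = {65: 84, 84: 65, 67: 71, 71: 67}  # A<->T, C<->G on ASCII codes

JUNCTION_TYPES = ("microhomology", "blunt", "insertion")


# ---------------------------------------------------------------------------
# plan containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """One occurrence of a source interval in the derived chromosome."""

    chrom: str
    start: int
    end: int
    orientation: str  # '+' or '-'
    state: int  # intended total copy state of the source interval (1..4)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError("block end must exceed start")
        if self.orientation not in "+-":
            raise ParameterError("orientation must be '+' or '-'")
        if self.state not in (1, 2, 3, 4):
            raise ParameterError("copy state must be in 1..4")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class JunctionSpec:
    """Chemistry of the join between two adjacent blocks."""

    jtype: str  # 'microhomology' | 'blunt' | 'insertion'
    mh_len: int = 0
    ins_len: int = 0

    def __post_init__(self) -> None:
        if self.jtype not in JUNCTION_TYPES:
            raise ParameterError(f"unknown junction type {self.jtype!r}")
        if self.jtype == "microhomology" and not 2 <= self.mh_len <= 15:
            raise ParameterError("microhomology length must lie in [2, 15]")
        if self.jtype == "insertion" and self.ins_len < 1:
            raise ParameterError("insertion length must be >= 1")


@dataclass
class BlockPlan:
    """Ordered block occurrences plus the junction chemistry between them.

    ``intervals`` lists every distinct source interval with its intended copy
    state, including state-1 intervals that never appear in the derived
    sequence (pure losses).
    """

    entries: list[Block]
    junctions: list[JunctionSpec]
    intervals: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.junctions) != max(len(self.entries) - 1, 0):
            raise ParameterError(
                "need exactly one junction spec per adjacent entry pair"
            )
        if not self.intervals:
            seen = {}
            for e in self.entries:
                seen[(e.chrom, e.start, e.end)] = e
            self.intervals = list(seen.values())


@dataclass
class TruthSet:
    """Machine-readable ground truth for a planted shattered chromosome."""

    blocks: pd.DataFrame  # chrom, start, end, state, n_occurrences
    entries: pd.DataFrame  # order, chrom, start, end, orientation
    junctions: pd.DataFrame  # anchors, chemistry, derived coordinates
    edits: pd.DataFrame  # chrom, pos, old, new (reference flank edits)
    snps: pd.DataFrame | None = None
    chrom_classes: dict[str, str] = field(default_factory=dict)
    derived_name: str = "shattered"
    source_chrom: str = ""

    def dosage_truth(self, chrom_len: int) -> pd.DataFrame:
        """Tile the source chromosome with true copy states.

        Gaps between planted intervals are copy state 1 (the parent-A homolog
        was replaced by the derived chromosome, which omits them).
        """
        blocks = self.blocks.sort_values("start")
        rows = []
        pos = 0
        for _, b in blocks.iterrows():
            if b.start > pos:
                rows.append((self.source_chrom, pos, int(b.start), 1))
            rows.append((self.source_chrom, int(b.start), int(b.end), int(b.state)))
            pos = int(b.end)
        if pos < chrom_len:
            rows.append((self.source_chrom, pos, chrom_len, 1))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        # merge adjacent equal states
        keep = []
        for _, r in df.iterrows():
            if keep and keep[-1][3] == r.state:
                keep[-1][2] = r.end
            else:
                keep.append([r.chrom, r.start, r.end, r.state])
        return pd.DataFrame(keep, columns=["chrom", "start", "end", "state"])

    def write(self, out_dir) -> None:
        """Write blocks (BED, state in score), junction TSV and SNP TSV."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bed = self.blocks.copy()
        bed["name"] = [f"block{i}" for i in range(len(bed))]
        bed[["chrom", "start", "end", "name", "state"]].to_csv(
            out / "truth_blocks.bed", sep="\t", header=False, index=False
        )
        jt = self.junctions.copy()
        jt.to_csv(out / "truth_junctions.tsv", sep="\t", index=False)
        if self.snps is not None:
            snp = self.snps.copy()
            snp["pos1"] = snp["pos"] + 1
            snp[["chrom", "pos1", "allele_a", "allele_b"]].to_csv(
                out / "truth_snps.tsv", sep="\t", index=False
            )


# ---------------------------------------------------------------------------
# parental genomes
# ---------------------------------------------------------------------------


def make_parental_genomes(
    n_chrom: int,
    chrom_len: int,
    snp_rate: float,
    seed: int,
) -> tuple[Genome, Genome, pd.DataFrame]:
    """Generate two parental haplotypes differing only at planted SNPs.

    Returns ``(parent_a, parent_b, snp_table)`` where the SNP table has
    columns ``chrom, pos`` (0-based), ``allele_a, allele_b``.  Parent A plays
    the role of the haploid inducer and of the mapping reference.
    """
    if not 0 < snp_rate <= 0.05:
        raise ParameterError("snp_rate must lie in (0, 0.05]")
    if chrom_len < 10_000:
        raise ParameterError("chrom_len must be >= 10,000")
    if n_chrom < 1:
        raise ParameterError("n_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    seqs_a: dict[str, bytes] = {}
    seqs_b: dict[str, bytes] = {}
    records = []
    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        codes = rng.integers(0, 4, chrom_len, dtype=np.uint8)
        positions = np.flatnonzero(rng.random(chrom_len) < snp_rate)
        codes_b = codes.copy()
        if positions.size:
            shift = rng.integers(1, 4, positions.size, dtype=np.uint8)
            codes_b[positions] = (codes[positions] + shift) % 4
        seqs_a[name] = codes_to_seq(codes)
        seqs_b[name] = codes_to_seq(codes_b)
        for p in positions:
            records.append((name, int(p), chr(BASES[codes[p]]), chr(BASES[codes_b[p]])))
    snps = pd.DataFrame(records, columns=["chrom", "pos", "allele_a", "allele_b"])
    return Genome(seqs_a), Genome(seqs_b), snps


# ---------------------------------------------------------------------------
# random plans
# ---------------------------------------------------------------------------

DEFAULT_STATE_PROBS = {1: 0.20, 2: 0.25, 3: 0.35, 4: 0.20}
DEFAULT_CHEM_PROBS = {"microhomology": 0.45, "blunt": 0.25, "insertion": 0.30}


def random_plan(
    genome: Genome,
    source_chrom: str,
    n_junctions: int,
    seed: int,
    min_block: int = 6_000,
    max_block: int = 18_000,
    gap_min: int = 500,
    state_probs: dict[int, float] | None = None,
    chem_probs: dict[str, float] | None = None,
    inv_prob: float = 0.5,
    mh_range: tuple[int, int] = (2, 15),
    ins_range: tuple[int, int] = (1, 125),
) -> BlockPlan:
    """Sample a random shattering plan with ``n_junctions`` junctions.

    Intervals are disjoint in the source; copy states are drawn from
    ``state_probs`` (state s contributes ``s - 1`` derived occurrences) and
    occurrence order, orientations and junction chemistry are randomized.
    About ``inv_prob`` of the occurrences are inverted, giving roughly the
    same fraction of head-to-head / tail-to-tail joins.
    """
    if n_junctions < 1:
        raise ParameterError("n_junctions must be >= 1")
    if source_chrom not in genome:
        raise ParameterError(f"unknown chromosome {source_chrom!r}")
    state_probs = dict(state_probs or DEFAULT_STATE_PROBS)
    chem_probs = dict(chem_probs or DEFAULT_CHEM_PROBS)
    rng = np.random.default_rng(seed)
    chrom_len = len(genome[source_chrom])

    target_occ = n_junctions + 1
    states: list[int] = []
    occ = 0
    svals = np.array(sorted(state_probs))
    spro = np.array([state_probs[s] for s in svals], dtype=float)
    spro /= spro.sum()
    while occ < target_occ:
        s = int(rng.choice(svals, p=spro))
        if occ + max(s - 1, 0) > target_occ:
            s = target_occ - occ + 1  # trim the last interval's state
        states.append(s)
        occ += s - 1
    if 1 not in states:
        states.append(1)

    lengths = rng.integers(min_block, max_block + 1, len(states))
    gaps_total = (len(states) + 1) * gap_min
    if int(lengths.sum()) + gaps_total > chrom_len:
        # shrink blocks proportionally so the plan fits, respecting min_block
        budget = chrom_len - gaps_total
        if budget < len(states) * min_block:
            raise ParameterError(
                f"plan needs more than {chrom_len} bp on {source_chrom}; "
                "reduce n_junctions or block sizes"
            )
        scale = 0.98 * budget / lengths.sum()
        lengths = np.maximum((lengths * scale).astype(np.int64), min_block)
    need = int(lengths.sum()) + gaps_total
    slack = chrom_len - need
    cuts = np.sort(rng.integers(0, slack + 1, len(states) + 1))
    extra = np.diff(np.concatenate([[0], cuts]))
    intervals: list[Block] = []
    pos = 0
    order = rng.permutation(len(states))
    for k, idx in enumerate(order):
        pos += gap_min + int(extra[k])
        intervals.append(
            Block(source_chrom, pos, pos + int(lengths[idx]), "+", int(states[idx]))
        )
        pos += int(lengths[idx])

    base_occurrences: list[Block] = []
    for iv in intervals:
        for _ in range(max(iv.state - 1, 0)):
            base_occurrences.append(iv)

    def _adjacency_key(left: Block, right: Block) -> frozenset:
        side_l = "end" if left.orientation == "+" else "start"
        side_r = "start" if right.orientation == "+" else "end"
        return frozenset(
            [(left.start, left.end, side_l), (right.start, right.end, side_r)]
        )

    # two junctions joining the same pair of oriented block ends would be
    # indistinguishable in reference coordinates; redraw until every
    # adjacency is unique (random ligation of distinct fragment ends)
    for _ in range(200):
        occurrences = [
            replace(
                base_occurrences[i],
                orientation="-" if rng.random() < inv_prob else "+",
            )
            for i in rng.permutation(len(base_occurrences))
        ]
        keys = [
            _adjacency_key(a, b) for a, b in zip(occurrences, occurrences[1:])
        ]
        if len(set(keys)) == len(keys):
            break

    cvals = list(chem_probs)
    cpro = np.array([chem_probs[c] for c in cvals], dtype=float)
    cpro /= cpro.sum()
    junctions = []
    for _ in range(len(occurrences) - 1):
        jt = str(rng.choice(cvals, p=cpro))
        if jt == "microhomology":
            junctions.append(
                JunctionSpec(jt, mh_len=int(rng.integers(mh_range[0], mh_range[1] + 1)))
            )
        elif jt == "insertion":
            junctions.append(
                JunctionSpec(jt, ins_len=int(rng.integers(ins_range[0], ins_range[1] + 1)))
            )
        else:
            junctions.append(JunctionSpec(jt))
    return BlockPlan(occurrences, junctions, intervals=intervals)


# ---------------------------------------------------------------------------
# shattered chromosome construction
# ---------------------------------------------------------------------------


def _oriented_seq(chrom_seq: bytes, b: Block) -> bytes:
    seg = chrom_seq[b.start : b.end]
    return seg if b.orientation == "+" else revcomp(seg)


class _Flanks:
    """Oriented coordinate accessors for junction bookkeeping on one block."""

    def __init__(self, seq: bytearray, block: Block):
        self.seq = seq
        self.b = block
        self.fwd = block.orientation == "+"

    # --- junction-facing END of the block (when it is the left partner) ---
    @property
    def end_terminal_pos(self) -> int:
        return self.b.end - 1 if self.fwd else self.b.start

    @property
    def end_side(self) -> str:
        return "upstream" if self.fwd else "downstream"

    def tail(self, k: int) -> bytes:
        """Last k oriented bases of the block."""
        if self.fwd:
            return bytes(self.seq[self.b.end - k : self.b.end])
        return revcomp(bytes(self.seq[self.b.start : self.b.start + k]))

    def tail_positions(self, k: int) -> list[int]:
        if self.fwd:
            return list(range(self.b.end - k, self.b.end))
        return list(range(self.b.start, self.b.start + k))

    @property
    def next_pos(self) -> int | None:
        """Reference position read when the left anchor extends past the block."""
        p = self.b.end if self.fwd else self.b.start - 1
        return p if 0 <= p < len(self.seq) else None

    def next_base(self) -> int | None:
        p = self.next_pos
        if p is None:
            return None
        v = self.seq[p]
        return v if self.fwd else _COMP[v]

    # --- junction-facing START of the block (when it is the right partner) ---
    @property
    def start_terminal_pos(self) -> int:
        return self.b.start if self.fwd else self.b.end - 1

    @property
    def start_side(self) -> str:
        return "downstream" if self.fwd else "upstream"

    def head_base(self, t: int) -> int:
        """Oriented base at offset t from the block start."""
        if self.fwd:
            return self.seq[self.b.start + t]
        return _COMP[self.seq[self.b.end - 1 - t]]

    def head_pos(self, t: int) -> int:
        return self.b.start + t if self.fwd else self.b.end - 1 - t

    def head_value_for(self, t: int, oriented_base: int) -> int:
        """Reference byte that makes oriented base t equal ``oriented_base``."""
        return oriented_base if self.fwd else _COMP[oriented_base]

    @property
    def prev_pos(self) -> int | None:
        """Reference position read when the right anchor extends backwards."""
        p = self.b.start - 1 if self.fwd else self.b.end
        return p if 0 <= p < len(self.seq) else None

    def prev_base(self) -> int | None:
        p = self.prev_pos
        if p is None:
            return None
        v = self.seq[p]
        return v if self.fwd else _COMP[v]

    def prev_value_for(self, oriented_base: int) -> int:
        return oriented_base if self.fwd else _COMP[oriented_base]


def _other_base(rng: np.random.Generator, *avoid: int | None) -> int:
    choices = [b for b in BASES if b not in avoid]
    return int(choices[rng.integers(0, len(choices))])


def build_shattered_chromosome(
    parent: Genome,
    source_chrom: str,
    plan: BlockPlan,
    seed: int = 0,
) -> tuple[bytes, TruthSet]:
    """Assemble the derived chromosome sequence and its truth set.

    Microhomology junctions require editing the opening bases of the right
    block in the *source* genome (see module docstring); the edits are
    returned in ``truth.edits`` and must be applied to every haplotype the
    reads are later simulated from (:func:`apply_edits` / :func:`plant_shattered`).
    When an edit would conflict with sequence another junction already
    depends on, the junction chemistry is downgraded to a novel insertion and
    flagged in the truth table.
    """
    if source_chrom not in parent:
        raise ParameterError(f"unknown chromosome {source_chrom!r}")
    chrom_len = len(parent[source_chrom])
    for b in plan.entries + plan.intervals:
        if b.chrom != source_chrom or b.start < 0 or b.end > chrom_len:
            raise ParameterError(f"block {b} outside {source_chrom}")

    rng = np.random.default_rng(seed)
    seq = bytearray(parent[source_chrom])
    locked: set[int] = set()
    edits: list[tuple[int, int, int]] = []  # pos, old, new

    def lock(*positions: int | None) -> None:
        locked.update(p for p in positions if p is not None)

    def try_writes(writes: list[tuple[int, int]]) -> bool:
        """Apply (pos, value) edits atomically unless any position is locked."""
        for p, _ in writes:
            if p in locked:
                return False
        for p, v in writes:
            if seq[p] != v:
                edits.append((p, seq[p], v))
                seq[p] = v
            lock(p)
        return True

    specs = list(plan.junctions)
    downgraded = [False] * len(specs)
    ins_seqs: dict[int, bytes] = {}

    for ji, spec in enumerate(specs):
        left = _Flanks(seq, plan.entries[ji])
        right = _Flanks(seq, plan.entries[ji + 1])

        if spec.jtype == "microhomology":
            k = spec.mh_len
            tail = left.tail(k)
            lock(*left.tail_positions(k))
            writes = [
                (right.head_pos(t), right.head_value_for(t, tail[t])) for t in range(k)
            ]
            # forward guard: reference beyond the left block must not match
            # the first contig base after the homology (right block base k)
            lnext = left.next_base()
            if lnext is not None and right.head_base(k) == lnext:
                writes.append(
                    (right.head_pos(k), right.head_value_for(k, _other_base(rng, lnext)))
                )
            # backward guard: reference before the right block must not match
            # the contig base preceding the homology (left block base -k-1)
            lprev = left.tail(k + 1)[0]
            rp = right.prev_pos
            if rp is not None and right.prev_base() == lprev:
                writes.append((rp, right.prev_value_for(_other_base(rng, lprev))))
            if not try_writes(writes):
                downgraded[ji] = True
                specs[ji] = JunctionSpec(
                    "insertion", ins_len=int(rng.integers(1, 126))
                )
                spec = specs[ji]
            else:
                lock(left.next_pos, right.prev_pos, right.head_pos(k))
                continue

        if spec.jtype == "blunt":
            writes = []
            lnext = left.next_base()
            if lnext is not None and right.head_base(0) == lnext:
                # break the chance forward extension at the left flank
                lp = left.next_pos
                writes.append(
                    (lp, _forward_guard_value(left, rng, right.head_base(0)))
                )
            lprev = left.tail(1)[0]
            rp = right.prev_pos
            if rp is not None and right.prev_base() == lprev:
                writes.append((rp, right.prev_value_for(_other_base(rng, lprev))))
            if not try_writes(writes):
                downgraded[ji] = True
                specs[ji] = JunctionSpec(
                    "insertion", ins_len=int(rng.integers(1, 126))
                )
                spec = specs[ji]
            else:
                lock(left.next_pos, right.prev_pos)
                lock(*left.tail_positions(1))
                lock(right.head_pos(0))
                continue

        # insertion (planted or downgraded): draw the novel sequence so its
        # terminal bases cannot extend either reference anchor
        lnext = left.next_base()
        rprev = right.prev_base()
        n = spec.ins_len
        ins = bytearray(
            BASES[i] for i in np.random.default_rng(seed * 7919 + ji).integers(0, 4, n)
        )
        ins[0] = _other_base(rng, lnext) if lnext is not None else ins[0]
        if n > 1:
            ins[-1] = _other_base(rng, rprev) if rprev is not None else ins[-1]
        else:
            ins[0] = _other_base(rng, lnext, rprev)
        ins_seqs[ji] = bytes(ins)
        lock(left.next_pos, right.prev_pos)
        lock(*left.tail_positions(1))
        lock(right.head_pos(0))

    # --- assemble the derived sequence from the edited reference ---
    parts: list[bytes] = []
    derived_positions: list[int] = []
    total = 0
    for i, entry in enumerate(plan.entries):
        block_seq = _oriented_seq(bytes(seq), entry)
        if i > 0:
            spec = specs[i - 1]
            derived_positions.append(total)
            if spec.jtype == "microhomology":
                block_seq = block_seq[spec.mh_len :]
            elif spec.jtype == "insertion":
                parts.append(ins_seqs[i - 1])
                total += len(ins_seqs[i - 1])
        parts.append(block_seq)
        total += len(block_seq)
    derived = b"".join(parts)

    # --- truth tables ---
    jrows = []
    for ji, spec in enumerate(specs):
        left = _Flanks(seq, plan.entries[ji])
        right = _Flanks(seq, plan.entries[ji + 1])
        f_ext, r_ext = _chance_extensions(seq, left, right, spec, ins_seqs.get(ji))
        jrows.append(
            {
                "chrom_left": source_chrom,
                "pos_left": left.end_terminal_pos,
                "side_left": left.end_side,
                "chrom_right": source_chrom,
                "pos_right": right.start_terminal_pos,
                "side_right": right.start_side,
                "type": spec.jtype,
                "mh_len": spec.mh_len if spec.jtype == "microhomology" else 0,
                "insertion_seq": ins_seqs.get(ji, b"").decode("ascii"),
                "inverted": left.end_side == right.start_side,
                "derived_pos": derived_positions[ji],
                "f_ext": f_ext,
                "r_ext": r_ext,
                "downgraded": downgraded[ji],
            }
        )
    occ_count: dict[tuple[int, int], int] = {}
    for e in plan.entries:
        occ_count[(e.start, e.end)] = occ_count.get((e.start, e.end), 0) + 1
    brows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "state": 1 + occ_count.get((iv.start, iv.end), 0),
            "n_occurrences": occ_count.get((iv.start, iv.end), 0),
        }
        for iv in sorted(plan.intervals, key=lambda b: b.start)
    ]
    erows = [
        {
            "order": i,
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "orientation": e.orientation,
        }
        for i, e in enumerate(plan.entries)
    ]
    truth = TruthSet(
        blocks=pd.DataFrame(brows),
        entries=pd.DataFrame(erows),
        junctions=pd.DataFrame(jrows),
        edits=pd.DataFrame(edits, columns=["pos", "old", "new"]).assign(
            chrom=source_chrom
        )[["chrom", "pos", "old", "new"]],
        source_chrom=source_chrom,
        derived_name=f"{source_chrom}_shattered",
    )
    return derived, truth


def _forward_guard_value(left: "_Flanks", rng: np.random.Generator, avoid_oriented: int) -> int:
    """Reference byte at left.next_pos whose oriented reading differs from avoid."""
    v = _other_base(rng, avoid_oriented)
    return v if left.fwd else _COMP[v]


def _chance_extensions(
    seq: bytearray,
    left: "_Flanks",
    right: "_Flanks",
    spec: JunctionSpec,
    ins: bytes | None,
) -> tuple[int, int]:
    """Realized chance extensions of the two anchors beyond the planted join.

    With guard bases in place both are 0, so realized chemistry equals the
    planted chemistry; computed here independently of the junction caller so
    tests can assert it.
    """
    k = spec.mh_len if spec.jtype == "microhomology" else 0

    # contig bases following the junction, in the left block's frame
    def contig_after(t: int) -> int | None:
        if spec.jtype == "insertion" and ins:
            if t < len(ins):
                return ins[t]
            t2 = t - len(ins)
        else:
            t2 = k + t
        if t2 < right.b.length:
            return right.head_base(t2)
        return None

    def ref_after(t: int) -> int | None:
        if left.fwd:
            p = left.b.end + t
            return seq[p] if p < len(seq) else None
        p = left.b.start - 1 - t
        return _COMP[seq[p]] if p >= 0 else None

    f = 0
    while f < 25:
        a, b = contig_after(f), ref_after(f)
        if a is None or b is None or a != b:
            break
        f += 1

    # contig bases preceding the junction, in the right block's frame
    def contig_before(t: int) -> int | None:
        if spec.jtype == "insertion" and ins:
            if t < len(ins):
                return ins[len(ins) - 1 - t]
            t2 = t - len(ins)
        else:
            t2 = t
        idx = left.b.length - k - 1 - t2
        if idx >= 0:
            tail = left.tail(left.b.length)
            return tail[idx]
        return None

    def ref_before(t: int) -> int | None:
        if right.fwd:
            p = right.b.start - 1 - t
            return seq[p] if p >= 0 else None
        p = right.b.end + t
        return _COMP[seq[p]] if p < len(seq) else None

    r = 0
    while r < 25:
        a, b = contig_before(r), ref_before(r)
        if a is None or b is None or a != b:
            break
        r += 1
    return f, r


def apply_edits(genome: Genome, edits: pd.DataFrame) -> Genome:
    """Return a copy of ``genome`` with the truth-set flank edits applied."""
    seqs = {name: bytearray(s) for name, s in genome.sequences.items()}
    for _, e in edits.iterrows():
        seqs[e.chrom][int(e.pos)] = int(e.new)
    return Genome({name: bytes(s) for name, s in seqs.items()})


@dataclass
class ShatteredPlant:
    """A planted shattered chromosome with haplotypes kept consistent."""

    derived: bytes
    truth: TruthSet
    parent_a: Genome
    parent_b: Genome
    snps: pd.DataFrame


def plant_shattered(
    parent_a: Genome,
    parent_b: Genome,
    snps: pd.DataFrame,
    source_chrom: str,
    plan: BlockPlan,
    seed: int = 0,
) -> ShatteredPlant:
    """Build the derived chromosome and apply its flank edits to both parents.

    Applying identical edits to both haplotypes models a shared ancestral
    flank; any planted SNP falling inside an edited position is removed from
    the SNP table (both parents now agree there), keeping the table exact.
    """
    derived, truth = build_shattered_chromosome(parent_a, source_chrom, plan, seed)
    pa = apply_edits(parent_a, truth.edits)
    pb = apply_edits(parent_b, truth.edits)
    if len(truth.edits):
        edited = set(zip(truth.edits.chrom, truth.edits.pos.astype(int)))
        keep = ~snps.apply(lambda r: (r.chrom, int(r.pos)) in edited, axis=1)
        snps = snps[keep].reset_index(drop=True)
    truth.snps = snps
    truth.chrom_classes = {
        name: ("shattered" if name == source_chrom else "euploid")
        for name in parent_a.names
    }
    return ShatteredPlant(derived, truth, pa, pb, snps)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


def _as_seq_dict(obj) -> dict[str, bytes]:
    if isinstance(obj, Genome):
        return obj.sequences
    return obj


def simulate_reads(
    nucleus: list[tuple[Genome | dict[str, bytes], int]],
    coverage: float,
    read_len: int = 100,
    paired: bool = True,
    insert_mean: int = 300,
    insert_sd: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Simulate uniform short reads from a nucleus of weighted sequences.

    ``coverage`` is the expected total depth of the diploid background, i.e.
    a sequence present in ``c`` copies is sequenced to ``c * coverage / 2``.
    Mates are emitted on opposite strands flanking the insert (FR).
    """
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    if paired and insert_mean <= 2 * read_len:
        raise ParameterError("insert_mean must exceed 2 * read_len for paired reads")
    rng = np.random.default_rng(seed)
    out: list[bytes] = []
    per_copy = coverage / 2.0
    for seqs, copies in nucleus:
        for name, seq in _as_seq_dict(seqs).items():
            L = len(seq)
            if read_len > L:
                raise ParameterError(
                    f"read_len {read_len} exceeds sequence {name!r} length {L}"
                )
            arr = np.frombuffer(seq, dtype=np.uint8)
            if paired:
                n_frag = int(round(copies * per_copy * L / (2 * read_len)))
                if n_frag == 0:
                    continue
                flen = np.clip(
                    np.rint(rng.normal(insert_mean, insert_sd, n_frag)).astype(np.int64),
                    2 * read_len,
                    L,
                )
                starts = (rng.random(n_frag) * (L - flen + 1)).astype(np.int64)
                offs = np.arange(read_len)
                r1 = arr[starts[:, None] + offs]
                r2 = _COMP_LUT[arr[(starts + flen - read_len)[:, None] + offs]][:, ::-1]
                mat = np.stack([r1, r2], axis=1).reshape(2 * n_frag, read_len)
            else:
                n = int(round(copies * per_copy * L / read_len))
                if n == 0:
                    continue
                starts = rng.integers(0, L - read_len + 1, n)
                mat = arr[starts[:, None] + np.arange(read_len)]
            if error_rate > 0:
                hit = rng.random(mat.shape) < error_rate
                n_hit = int(hit.sum())
                if n_hit:
                    # substitute a uniformly chosen different base
                    lut = np.zeros(256, np.uint8)
                    for i, bse in enumerate(BASES):
                        lut[bse] = i
                    cur = lut[mat[hit]]
                    mat = mat.copy()
                    mat[hit] = np.frombuffer(BASES, np.uint8)[
                        (cur + rng.integers(1, 4, n_hit)) % 4
                    ]
            out.extend(row.tobytes() for row in mat)
    return ReadSet(out, paired=paired)


def hybrid_nucleus(parent_a: Genome, parent_b: Genome) -> list:
    """Diploid F1 hybrid: one copy of each parental haplotype."""
    return [(parent_a, 1), (parent_b, 1)]


def trisomic_nucleus(parent_a: Genome, parent_b: Genome, chrom: str) -> list:
    """Primary trisomic: hybrid plus a whole extra parent-A chromosome."""
    return hybrid_nucleus(parent_a, parent_b) + [({chrom: parent_a[chrom]}, 1)]


def truncated_nucleus(
    parent_a: Genome, parent_b: Genome, chrom: str, break_pos: int
) -> list:
    """Truncated trisomic: hybrid plus an extra distal parent-A fragment."""
    seq = parent_a[chrom]
    if not 0 < break_pos < len(seq):
        raise ParameterError("break_pos must lie inside the chromosome")
    frag = seq[break_pos:]
    return hybrid_nucleus(parent_a, parent_b) + [({f"{chrom}_frag": frag}, 1)]


def shattered_nucleus(plant: ShatteredPlant) -> list:
    """Replacement-model nucleus: the derived chromosome stands in for the
    parent-A homolog of the source chromosome."""
    pa_rest = {
        name: seq
        for name, seq in plant.parent_a.sequences.items()
        if name != plant.truth.source_chrom
    }
    return [
        (pa_rest, 1),
        (plant.parent_b, 1),
        ({plant.truth.derived_name: plant.derived}, 1),
    ]


# ---------------------------------------------------------------------------
# synthetic feature annotations
# ---------------------------------------------------------------------------


def _tile_intervals(
    rng: np.random.Generator, length: int, frac: float, mean_len: float
) -> np.ndarray:
    """Disjoint intervals covering about ``frac`` of [0, length)."""
    mean_gap = mean_len * (1 - frac) / frac
    ivs = []
    pos = 0
    while True:
        pos += 1 + int(rng.exponential(mean_gap))
        flen = 1 + int(rng.exponential(mean_len - 1))
        if pos + flen >= length:
            break
        ivs.append((pos, pos + flen))
        pos += flen
    return np.array(ivs if ivs else np.empty((0, 2)), dtype=np.int64)


def simulate_annotations(
    genome: Genome, seed: int = 0
) -> tuple[dict[str, dict[str, np.ndarray]], pd.DataFrame]:
    """Random genomic feature tracks mimicking the Arabidopsis annotation mix.

    Returns ``(features, genes)`` where features maps class name ->
    chrom -> (n, 2) interval array, and genes is a stranded DataFrame used
    for chimeric-transcript prediction.  Coverages approximate the real
    genome: ~50% genic, ~15% transposon, ~2% satellite, ~3.5% replication
    origins, ~5% DHS, plus nine chromatin states partitioning each
    chromosome.
    """
    rng = np.random.default_rng(seed)
    spec = {
        "gene": (0.50, 2000.0),
        "transposon": (0.15, 3000.0),
        "satellite": (0.02, 1000.0),
        "replication_origin": (0.035, 1500.0),
        "dhs": (0.05, 500.0),
    }
    features: dict[str, dict[str, np.ndarray]] = {name: {} for name in spec}
    gene_rows = []
    for chrom, length in genome.lengths.items():
        for name, (frac, mean_len) in spec.items():
            ivs = _tile_intervals(rng, length, frac, mean_len)
            features[name][chrom] = ivs
            if name == "gene":
                for s, e in ivs:
                    strand = "+" if rng.random() < 0.5 else "-"
                    gene_rows.append((chrom, int(s), int(e), strand))
        # chromatin states: an exhaustive partition into nine states
        bounds = [0]
        while bounds[-1] < length:
            bounds.append(bounds[-1] + 500 + int(rng.exponential(4500)))
        bounds[-1] = length
        labels = rng.integers(1, 10, len(bounds) - 1)
        for st in range(1, 10):
            key = f"chromatin_state_{st}"
            features.setdefault(key, {})
            sel = [
                (bounds[i], bounds[i + 1])
                for i in range(len(bounds) - 1)
                if labels[i] == st
            ]
            features[key][chrom] = np.array(
                sel if sel else np.empty((0, 2)), dtype=np.int64
            )
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand"])
    return features, genes


def features_to_gff3(
    features: dict[str, dict[str, np.ndarray]],
    path,
    genes: pd.DataFrame | None = None,
) -> None:
    """Write feature tracks as GFF3 (1-based inclusive)."""
    strands: dict[tuple[str, int, int], str] = {}
    if genes is not None:
        strands = {
            (r.chrom, int(r.start), int(r.end)): r.strand for r in genes.itertuples()
        }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cls, per_chrom in features.items():
            for chrom, ivs in per_chrom.items():
                for s, e in ivs:
                    strand = strands.get((chrom, int(s), int(e)), ".")
                    fh.write(
                        f"{chrom}\tshatterscan\t{cls}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"ID={cls}:{chrom}:{s + 1}\n"
                    )
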