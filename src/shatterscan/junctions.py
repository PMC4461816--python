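"""Breakpoint detection, local junction assembly and junction typing.

Breakpoints are read off a high-resolution (500 bp bin) dosage segmentation;
reads around each breakpoint whose pair signals a rearrangement (unmapped
mate, or a discordant insert) are assembled with a greedy exact-overlap
assembler, and each contig is split-aligned back to the reference: the
longest exact prefix match and longest exact suffix match define the two
junction anchors.  The arithmetic of those two placements types the join:

* anchors overlapping on the contig by k >= 2 bases -> microhomology (k bp);
* abutting placements (overlap 0 or 1) -> blunt fusion;
* a gap of unaligned middle bases -> novel sequence insertion.

A junction is inverted when its anchors join head-to-head or tail-to-tail,
i.e. the two placements lie on opposite reference strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genome, ParameterError, ReadSet, revcomp
from .dosage import DosageProfile
from .mapping import AlignmentSet

__all__ = [
    "Placement",
    "SplitResult",
    "Junction",
    "detect_breakpoints",
    "extract_breakpoint_reads",
    "select_junction_support",
    "assemble_local",
    "split_align",
    "classify_junction",
    "junctions_from_breakpoints",
    "junctions_to_frame",
    "read_junction_tsv",
    "summarize_junctions",
    "predict_chimeric",
    "match_junctions",
]

_COMP = {65: 84, 84: 65, 67: 71, 71: 67}


@dataclass(frozen=True)
class Placement:
    """One exact anchor match of a contig end on the reference."""

    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    length: int  # matched contig bases


@dataclass
class SplitResult:
    contig: bytes
    prefix: Placement
    suffix: Placement
    overlap: int  # >0: contig bases claimed by both anchors
    gap: int  # >0: contig bases claimed by neither
    middle: bytes  # unaligned middle (insertion candidates)
    ambiguous: bool = False


@dataclass
class Junction:
    """A reconstructed breakpoint join between two reference anchors.

    ``side`` is the retained side of each anchor: 'upstream' means reference
    sequence up to and including ``pos`` is retained in the derived
    chromosome, 'downstream' means sequence from ``pos`` onwards.
    """

    chrom_left: str
    pos_left: int
    side_left: str
    chrom_right: str
    pos_right: int
    side_right: str
    jtype: str  # microhomology | blunt | insertion
    mh_len: int
    insertion_seq: str
    inverted: bool
    contig: bytes = b""
    support: int = 0
    ambiguous: bool = False

    def key(self) -> tuple:
        a = (self.chrom_left, self.pos_left, self.side_left)
        b = (self.chrom_right, self.pos_right, self.side_right)
        lo, hi = (a, b) if a <= b else (b, a)
        return (lo, hi, self.jtype, self.mh_len, len(self.insertion_seq))


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------


def detect_breakpoints(segments: pd.DataFrame, profile: DosageProfile | None = None) -> pd.DataFrame:
    """One breakpoint per copy-state transition.

    The breakpoint is placed at the boundary between the two bins flanking
    the transition (the shared segment edge).  Returns a frame with columns
    chrom, pos, left_state, right_state.
    """
    if profile is not None and profile.bin_size > 1000:
        raise ParameterError("breakpoint detection expects bins of <= 1000 bp")
    rows = []
    for chrom in segments.chrom.unique():
        sub = segments[segments.chrom == chrom].sort_values("start_bin")
        states = sub.state.to_numpy()
        ends = sub.end.to_numpy()
        for i in range(len(sub) - 1):
            rows.append((chrom, int(ends[i]), int(states[i]), int(states[i + 1])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "left_state", "right_state"])


def extract_breakpoint_reads(
    alignments: AlignmentSet,
    reads: ReadSet,
    chrom: str,
    pos: int,
    radius: int = 2000,
) -> ReadSet:
    """Reads aligned within ``pos +- radius`` plus their mates wherever the
    mates map (including unmapped mates).  Windows are clipped to the
    chromosome."""
    cid = alignments.chrom_names.index(chrom)
    lo, hi = pos - radius, pos + radius
    in_window = (
        (alignments.chrom_id == cid)
        & (alignments.start >= lo)
        & (alignments.start <= hi)
    )
    picked: set[int] = set(int(alignments.read_index[r]) for r in np.flatnonzero(in_window))
    if reads.paired:
        mates = set()
        for ri in picked:
            mates.add(ri + 1 if ri % 2 == 0 else ri - 1)
        picked |= mates
    idx = sorted(picked)
    return ReadSet(
        [reads.sequences[i] for i in idx],
        paired=False,
        ids=[reads.read_id(i) for i in idx],
    )


def select_junction_support(
    alignments: AlignmentSet,
    reads: ReadSet,
    chrom: str,
    pos: int,
    radius: int = 2000,
    insert_mean: int = 300,
    insert_sd: int = 50,
    aln_row_of: dict[int, int] | None = None,
) -> list[bytes]:
    """Junction-informative reads near a breakpoint, for local assembly.

    Keeps read pairs with one mate aligned in the window and the other
    unmapped (junction-spanning), plus aligned pairs whose insert is
    discordant (wrong strand pairing or an implausible span).  Fully
    concordant reference-consistent pairs are excluded so that the
    assembly input is effectively a single haplotype around the junction.
    """
    if not reads.paired:
        raise ParameterError("junction assembly requires paired reads")
    if aln_row_of is None:
        aln_row_of = alignments.position_of()
    cid = alignments.chrom_names.index(chrom)
    lo, hi = pos - radius, pos + radius
    in_window = np.flatnonzero(
        (alignments.chrom_id == cid)
        & (alignments.start >= lo)
        & (alignments.start <= hi)
    )
    max_span = insert_mean + 6 * insert_sd
    picked: set[int] = set()
    for r in in_window:
        ri = int(alignments.read_index[r])
        mi = ri + 1 if ri % 2 == 0 else ri - 1
        mrow = aln_row_of.get(mi)
        if mrow is None:
            picked.add(ri)
            picked.add(mi)
            continue
        # both mates aligned: keep only discordant pairs
        same_chrom = alignments.chrom_id[mrow] == alignments.chrom_id[r]
        span_lo = min(alignments.start[r], alignments.start[mrow])
        span_hi = max(
            alignments.start[r] + alignments.length[r],
            alignments.start[mrow] + alignments.length[mrow],
        )
        proper = (
            bool(same_chrom)
            and alignments.strand[r] != alignments.strand[mrow]
            and (span_hi - span_lo) <= max_span
        )
        if proper:
            fwd_row = r if alignments.strand[r] == 0 else mrow
            rev_row = mrow if fwd_row == r else r
            proper = alignments.start[fwd_row] <= alignments.start[rev_row]
        if not proper:
            picked.add(ri)
            picked.add(mi)
    return [reads.sequences[i] for i in sorted(picked)]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _max_suffix_prefix(contig: bytes, seq: bytes, min_overlap: int) -> int:
    """Largest ov >= min_overlap with contig[-ov:] == seq[:ov], else 0."""
    probe = seq[:min_overlap]
    start = max(0, len(contig) - len(seq))
    i = contig.find(probe, start)
    while i != -1:
        ov = len(contig) - i
        if ov >= min_overlap and contig[i:] == seq[:ov]:
            return ov
        i = contig.find(probe, i + 1)
    return 0


def assemble_local(
    reads: list[bytes] | ReadSet,
    min_overlap: int = 31,
    min_reads: int = 3,
    min_contig_len: int | None = None,
) -> list[tuple[bytes, int]]:
    """Greedy exact suffix-prefix overlap assembly of error-free reads.

    Both orientations are considered.  Contigs supported by fewer than
    ``min_reads`` reads, or shorter than ``min_contig_len`` (default twice
    the longest read), are discarded; an empty result means the junction is
    unresolved.
    """
    if min_overlap < 15:
        raise ParameterError("min_overlap must be >= 15")
    seqs = list(reads.sequences) if isinstance(reads, ReadSet) else list(reads)
    if not seqs:
        return []
    if min_contig_len is None:
        min_contig_len = 2 * max(len(s) for s in seqs)
    counts: dict[bytes, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    pool = sorted(counts, key=len, reverse=True)
    contigs: list[tuple[bytes, int]] = []
    while pool:
        contig = pool.pop(0)
        support = counts[contig]
        grown = True
        while grown:
            grown = False
            # absorb reads fully contained in the contig
            remaining = []
            contig_rc = revcomp(contig)
            for s in pool:
                if contig.find(s) != -1 or contig_rc.find(s) != -1:
                    support += counts[s]
                else:
                    remaining.append(s)
            pool = remaining
            for _ in range(2):  # right end, then (reverse-complemented) left end
                best_ov, best_idx, best_seq = 0, -1, b""
                for idx, s in enumerate(pool):
                    for oriented in (s, revcomp(s)):
                        ov = _max_suffix_prefix(contig, oriented, min_overlap)
                        if ov > best_ov and ov < len(oriented):
                            best_ov, best_idx, best_seq = ov, idx, oriented
                if best_idx >= 0:
                    contig = contig + best_seq[best_ov:]
                    support += counts[pool.pop(best_idx)]
                    grown = True
                contig = revcomp(contig)
        contigs.append((contig, support))
    return [
        (c, n)
        for c, n in contigs
        if n >= min_reads and len(c) >= min_contig_len
    ]


# ---------------------------------------------------------------------------
# split alignment
# ---------------------------------------------------------------------------


def _find_all(hay: bytes, needle: bytes) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _prefix_placements(contig: bytes, genome: Genome, min_anchor: int) -> list[Placement]:
    seed = contig[:min_anchor]
    seed_rc = revcomp(seed)
    out: list[Placement] = []
    for chrom in genome.names:
        seq = genome[chrom]
        for p in _find_all(seq, seed):
            l = min_anchor
            while p + l < len(seq) and l < len(contig) and seq[p + l] == contig[l]:
                l += 1
            out.append(Placement(chrom, p, p + l, "+", l))
        for q in _find_all(seq, seed_rc):
            a, l = q, min_anchor
            while a - 1 >= 0 and l < len(contig) and contig[l] == _COMP.get(seq[a - 1], 0):
                a -= 1
                l += 1
            out.append(Placement(chrom, a, q + min_anchor, "-", l))
    return out


def _suffix_placements(contig: bytes, genome: Genome, min_anchor: int) -> list[Placement]:
    seed = contig[-min_anchor:]
    seed_rc = revcomp(seed)
    n = len(contig)
    out: list[Placement] = []
    for chrom in genome.names:
        seq = genome[chrom]
        for p in _find_all(seq, seed):
            end, l = p + min_anchor, min_anchor
            while end - l - 1 >= 0 and l < n and contig[n - l - 1] == seq[end - l - 1]:
                l += 1
            out.append(Placement(chrom, end - l, end, "+", l))
        for q in _find_all(seq, seed_rc):
            l = min_anchor
            while q + l < len(seq) and l < n and contig[n - l - 1] == _COMP.get(seq[q + l], 0):
                l += 1
            out.append(Placement(chrom, q, q + l, "-", l))
    return out


def _pick(
    placements: list[Placement], breakpoint: tuple[str, int] | None
) -> tuple[Placement | None, bool]:
    """Longest placement; ties broken by distance to the dosage breakpoint,
    remaining ties flagged ambiguous."""
    if not placements:
        return None, False
    best_len = max(p.length for p in placements)
    top = [p for p in placements if p.length == best_len]
    if len(top) == 1:
        return top[0], False
    if breakpoint is not None:
        chrom, pos = breakpoint

        def dist(p: Placement) -> int:
            if p.chrom != chrom:
                return 10**12
            return min(abs(p.start - pos), abs(p.end - pos))

        dmin = min(dist(p) for p in top)
        top = [p for p in top if dist(p) == dmin]
        if len(top) == 1:
            return top[0], False
    return top[0], True


def split_align(
    contig: bytes,
    genome: Genome,
    min_anchor: int = 30,
    breakpoint: tuple[str, int] | None = None,
) -> SplitResult | None:
    """Place the longest exact prefix and suffix of a contig on the reference.

    Returns None when either anchor cannot reach ``min_anchor`` bases.
    """
    if len(contig) < 2 * min_anchor:
        raise ParameterError("contig shorter than two anchor lengths")
    prefix, amb_p = _pick(_prefix_placements(contig, genome, min_anchor), breakpoint)
    suffix, amb_s = _pick(_suffix_placements(contig, genome, min_anchor), breakpoint)
    if prefix is None or suffix is None:
        return None
    ov = prefix.length + suffix.length - len(contig)
    gap = max(-ov, 0)
    middle = contig[prefix.length : len(contig) - suffix.length] if gap else b""
    return SplitResult(
        contig=contig,
        prefix=prefix,
        suffix=suffix,
        overlap=max(ov, 0),
        gap=gap,
        middle=middle,
        ambiguous=amb_p or amb_s,
    )


def classify_junction(
    split: SplitResult,
    mh_min: int = 2,
    support: int = 0,
) -> Junction:
    """Type a split-aligned contig as microhomology / blunt / insertion.

    An overlap of exactly 1 bp is classified blunt (the microhomology band
    starts at ``mh_min`` = 2 by convention); anchors on opposite strands
    mark an inversion-type (head-to-head or tail-to-tail) join.
    """
    pre, suf = split.prefix, split.suffix
    if pre.strand == "+":
        pos_left, side_left = pre.end - 1, "upstream"
    else:
        pos_left, side_left = pre.start, "downstream"
    if suf.strand == "+":
        pos_right, side_right = suf.start, "downstream"
    else:
        pos_right, side_right = suf.end - 1, "upstream"
    if split.gap >= 1:
        jtype, mh, ins = "insertion", 0, split.middle.decode("ascii")
    elif split.overlap >= mh_min:
        jtype, mh, ins = "microhomology", split.overlap, ""
    else:
        jtype, mh, ins = "blunt", 0, ""
    return Junction(
        chrom_left=pre.chrom,
        pos_left=pos_left,
        side_left=side_left,
        chrom_right=suf.chrom,
        pos_right=pos_right,
        side_right=side_right,
        jtype=jtype,
        mh_len=mh,
        insertion_seq=ins,
        inverted=pre.strand != suf.strand,
        contig=split.contig,
        support=support,
        ambiguous=split.ambiguous,
    )


def junctions_from_breakpoints(
    alignments: AlignmentSet,
    reads: ReadSet,
    genome: Genome,
    breakpoints: pd.DataFrame,
    radius: int = 2000,
    insert_mean: int = 300,
    insert_sd: int = 50,
    min_overlap: int = 31,
    min_reads: int = 3,
    min_anchor: int = 30,
) -> list[Junction]:
    """Assemble and classify junctions around every detected breakpoint,
    de-duplicating joins discovered from both of their flanking blocks."""
    aln_row_of = alignments.position_of()
    seen: dict[tuple, Junction] = {}
    for bp in breakpoints.itertuples():
        support = select_junction_support(
            alignments,
            reads,
            bp.chrom,
            int(bp.pos),
            radius=radius,
            insert_mean=insert_mean,
            insert_sd=insert_sd,
            aln_row_of=aln_row_of,
        )
        if len(support) < min_reads:
            continue
        for contig, nsup in assemble_local(
            support, min_overlap=min_overlap, min_reads=min_reads
        ):
            if len(contig) < 2 * min_anchor:
                continue
            split = split_align(
                contig, genome, min_anchor=min_anchor, breakpoint=(bp.chrom, int(bp.pos))
            )
            if split is None:
                continue
            # a contig matching the reference end to end is not a junction
            if split.prefix.length >= len(contig) or split.suffix.length >= len(contig):
                continue
            junction = classify_junction(split, support=nsup)
            key = junction.key()
            if key not in seen or seen[key].support < junction.support:
                seen[key] = junction
    return list(seen.values())


# ---------------------------------------------------------------------------
# tables, summaries, chimeric-gene prediction
# ---------------------------------------------------------------------------

_JUNCTION_COLUMNS = [
    "chrom_left",
    "pos_left",
    "side_left",
    "chrom_right",
    "pos_right",
    "side_right",
    "type",
    "mh_len",
    "insertion_seq",
    "inverted",
    "support",
    "ambiguous",
]


def junctions_to_frame(junctions: list[Junction]) -> pd.DataFrame:
    rows = [
        (
            j.chrom_left,
            j.pos_left,
            j.side_left,
            j.chrom_right,
            j.pos_right,
            j.side_right,
            j.jtype,
            j.mh_len,
            j.insertion_seq,
            bool(j.inverted),
            j.support,
            bool(j.ambiguous),
        )
        for j in junctions
    ]
    return pd.DataFrame(rows, columns=_JUNCTION_COLUMNS)


def read_junction_tsv(path) -> pd.DataFrame:
    """Read a junction table (the same schema the simulator's truth sets and
    this module's writer produce; also fits supplementary-style exports)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"type", "inverted"} - set(df.columns)
    if missing:
        raise ParameterError(f"junction table lacks columns: {sorted(missing)}")
    return df


def summarize_junctions(
    junctions: list[Junction] | pd.DataFrame,
    blocks: pd.DataFrame | None = None,
) -> dict:
    """Counts by type, inversion fraction, homology/insertion histograms and
    the duplicated vs triplicated block-size comparison.

    ``blocks`` needs columns chrom/start/end/state; sizes of state-3
    (duplicated) vs state-4 (triplicated) blocks are compared with both a
    two-sided Welch t test and a Mann-Whitney rank test.
    """
    df = junctions if isinstance(junctions, pd.DataFrame) else junctions_to_frame(junctions)
    if "ambiguous" in df.columns:
        df = df[~df.ambiguous.astype(bool)]
    out: dict = {}
    out["n_junctions"] = len(df)
    out["type_counts"] = df["type"].value_counts().to_dict()
    out["inversion_fraction"] = float(df.inverted.astype(bool).mean()) if len(df) else np.nan
    mh = df.loc[df["type"] == "microhomology", "mh_len"].astype(int)
    out["mh_length_hist"] = mh.value_counts().sort_index().to_dict()
    if "insertion_seq" in df.columns:
        ins_len = df.loc[df["type"] == "insertion", "insertion_seq"].map(
            lambda v: 0 if pd.isna(v) else len(str(v))
        )
    else:
        ins_len = pd.Series([], dtype=int)
    out["insertion_length_hist_25bp"] = (
        ((ins_len - 1) // 25 * 25 + 1).value_counts().sort_index().to_dict()
    )
    if blocks is not None:
        dup = blocks.loc[blocks.state == 3]
        tri = blocks.loc[blocks.state == 4]
        dup_sizes = (dup.end - dup.start).to_numpy(dtype=float)
        tri_sizes = (tri.end - tri.start).to_numpy(dtype=float)
        out["n_duplicated_blocks"] = len(dup_sizes)
        out["n_triplicated_blocks"] = len(tri_sizes)
        if len(dup_sizes) >= 2 and len(tri_sizes) >= 2:
            t_p = stats.ttest_ind(dup_sizes, tri_sizes, equal_var=False).pvalue
            u_p = stats.mannwhitneyu(dup_sizes, tri_sizes, alternative="two-sided").pvalue
            out["block_size_t_p"] = float(t_p)
            out["block_size_rank_p"] = float(u_p)
    return out


def _containing_gene(genes: pd.DataFrame, chrom: str, pos: int) -> str | None:
    sub = genes[(genes.chrom == chrom) & (genes.start <= pos) & (genes.end > pos)]
    if sub.empty:
        return None
    return str(sub.iloc[0].strand)


def predict_chimeric(junction: Junction, genes: pd.DataFrame) -> bool:
    """Could this junction fuse two genes into one reading orientation?

    True iff both anchors' retained sides fall inside gene bodies and there
    is a traversal of the join in which the entering gene is transcribed
    toward the junction and the leaving gene away from it.  Reading toward
    the junction at an anchor whose upstream side is retained requires a
    '+' gene (and '-' for a retained downstream side); leaving is the
    mirror image.
    """
    gl = _containing_gene(genes, junction.chrom_left, junction.pos_left)
    gr = _containing_gene(genes, junction.chrom_right, junction.pos_right)
    if gl is None or gr is None:
        return False

    def enter_req(side: str) -> str:
        return "+" if side == "upstream" else "-"

    def leave_req(side: str) -> str:
        return "+" if side == "downstream" else "-"

    fwd = gl == enter_req(junction.side_left) and gr == leave_req(junction.side_right)
    rev = gr == enter_req(junction.side_right) and gl == leave_req(junction.side_left)
    return bool(fwd or rev)


def match_junctions(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    tol: int = 1,
) -> pd.DataFrame:
    """Match truth junctions to detected ones (anchors within ``tol`` bp in
    either left/right order, same type and homology/insertion length).

    Returns the truth table with ``recovered`` and ``exact_chemistry``
    columns; used to score end-to-end recovery against a planted plan.
    """
    det = detected.reset_index(drop=True)
    used: set[int] = set()
    recovered = []
    exact = []
    for t in truth.itertuples():
        t_ins = len(getattr(t, "insertion_seq", "") or "")
        t_anchors = {
            (t.chrom_left, int(t.pos_left), t.side_left),
            (t.chrom_right, int(t.pos_right), t.side_right),
        }
        hit = None
        chem_ok = False
        for i, d in det.iterrows():
            if i in used:
                continue
            d_anchors = [
                (d.chrom_left, int(d.pos_left), d.side_left),
                (d.chrom_right, int(d.pos_right), d.side_right),
            ]
            ok = False
            for order in (d_anchors, d_anchors[::-1]):
                pairs = list(zip(sorted(t_anchors), sorted(order)))
                # anchor-wise comparison with positional tolerance
                match = all(
                    ta[0] == da[0] and abs(ta[1] - da[1]) <= tol and ta[2] == da[2]
                    for ta, da in pairs
                )
                if match:
                    ok = True
                    break
            if not ok:
                continue
            hit = i
            d_ins = len(d.insertion_seq or "") if isinstance(d.insertion_seq, str) else 0
            chem_ok = (
                d["type"] == t.type
                and int(d.mh_len) == int(t.mh_len)
                and d_ins == t_ins
            )
            if chem_ok:
                break
        if hit is not None:
            used.add(hit)
        recovered.append(hit is not None)
        exact.append(bool(hit is not None and chem_ok))
    out = truth.copy()
    out["recovered"] = recovered
    out["exact_chemistry"] = exact
    return out
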