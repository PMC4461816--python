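"""Parent-diagnostic SNP discovery and parental read assignment.

A hybrid position is diagnostic when the hybrid pileup shows exactly two
alleles at adequate depth and each parental library is effectively
homozygous for a different one of them.  Reads are then assigned to a
parent per overlapped SNP; assigned calls are pooled in genomic bins to a
percent-parent-A track, and intersected with copy-state segments to ask
which haplotype gained or lost copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParameterError, ReadSet, revcomp
from .mapping import AlignmentSet, Pileup

__all__ = [
    "SnpThresholds",
    "identify_snps",
    "assign_reads",
    "bin_parentage",
    "parent_fraction_by_state",
    "write_snp_table",
]

_BASE_BYTES = b"ACGT"


@dataclass(frozen=True)
class SnpThresholds:
    """Discovery thresholds.

    Defaults follow the hybrid-sequencing design this analysis derives
    from: >=25x hybrid depth with two alleles each at >=40% of allelic
    calls; parental homozygosity >=97% with >=6x coverage for parent A and
    >=1x for parent B.  ``noise_floor`` (5%) decides which bases count as
    alleles at all; with error-free input it is inert.
    """

    hybrid_min_depth: int = 25
    min_allele_frac: float = 0.40
    parental_homozygosity: float = 0.97
    parent_a_min_depth: int = 6
    parent_b_min_depth: int = 1
    noise_floor: float = 0.05


def identify_snps(
    hybrid: Pileup,
    parent_a: Pileup,
    parent_b: Pileup,
    thresholds: SnpThresholds | None = None,
) -> pd.DataFrame:
    """Scan pileups for parent-diagnostic positions.

    Returns a frame with columns ``chrom, pos`` (0-based), ``allele_a,
    allele_b``, sorted by position within chromosome.
    """
    t = thresholds or SnpThresholds()
    records = []
    for chrom, H in hybrid.counts.items():
        if chrom not in parent_a.counts or chrom not in parent_b.counts:
            continue
        depth = H.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, H / np.maximum(depth, 1), 0.0)
        is_allele = (H > 0) & (frac >= t.noise_floor)
        n_alleles = is_allele.sum(axis=0)
        second_frac = np.sort(frac, axis=0)[-2]
        cand = (
            (depth >= t.hybrid_min_depth)
            & (n_alleles == 2)
            & (second_frac >= t.min_allele_frac)
        )

        def parent_call(P, min_depth):
            pd_ = P.sum(axis=0)
            top = P.max(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                homo = np.where(pd_ > 0, top / np.maximum(pd_, 1), 0.0)
            allele = P.argmax(axis=0)
            ok = (pd_ >= min_depth) & (homo >= t.parental_homozygosity)
            return allele, ok

        a_allele, a_ok = parent_call(parent_a.counts[chrom], t.parent_a_min_depth)
        b_allele, b_ok = parent_call(parent_b.counts[chrom], t.parent_b_min_depth)
        cols = np.arange(H.shape[1])
        keep = (
            cand
            & a_ok
            & b_ok
            & (a_allele != b_allele)
            & is_allele[a_allele, cols]
            & is_allele[b_allele, cols]
        )
        for p in np.flatnonzero(keep):
            records.append(
                (
                    chrom,
                    int(p),
                    chr(_BASE_BYTES[a_allele[p]]),
                    chr(_BASE_BYTES[b_allele[p]]),
                )
            )
    return pd.DataFrame(records, columns=["chrom", "pos", "allele_a", "allele_b"])


def write_snp_table(snps: pd.DataFrame, path) -> None:
    out = snps.copy()
    out["pos1"] = out["pos"] + 1
    out[["chrom", "pos1", "allele_a", "allele_b"]].to_csv(path, sep="\t", index=False)


def assign_reads(
    alignments: AlignmentSet,
    reads: ReadSet,
    snps: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each SNP-overlapping read to a parent.

    One call is produced per (read, overlapped SNP).  A read base matching
    neither parental allele is 'na'; a read whose bases support different
    parents at different SNPs is conservatively 'na' at all of them
    (possible chimeric artifact).
    """
    if snps.empty:
        raise ParameterError("SNP table is empty")
    out_chrom: list[str] = []
    out_pos: list[int] = []
    out_read: list[int] = []
    out_call: list[str] = []
    for cid, chrom in enumerate(alignments.chrom_names):
        sub = snps[snps.chrom == chrom]
        if sub.empty:
            continue
        P = sub.pos.to_numpy(dtype=np.int64)
        order = np.argsort(P)
        P = P[order]
        aA = sub.allele_a.to_numpy()[order]
        aB = sub.allele_b.to_numpy()[order]
        aA_b = np.array([ord(x) for x in aA], dtype=np.uint8)
        aB_b = np.array([ord(x) for x in aB], dtype=np.uint8)
        rows = np.flatnonzero(alignments.chrom_id == cid)
        starts = alignments.start[rows]
        ends = starts + alignments.length[rows]
        lo = np.searchsorted(P, starts, side="left")
        hi = np.searchsorted(P, ends, side="left")
        hits = np.flatnonzero(hi > lo)
        for h in hits:
            r = rows[h]
            ri = int(alignments.read_index[r])
            seq = reads.sequences[ri]
            if alignments.strand[r]:
                seq = revcomp(seq)
            s = int(starts[h])
            calls = []
            for j in range(lo[h], hi[h]):
                base = seq[P[j] - s]
                if base == aA_b[j]:
                    calls.append("parentA")
                elif base == aB_b[j]:
                    calls.append("parentB")
                else:
                    calls.append("na")
            assigned = {c for c in calls if c != "na"}
            if len(assigned) > 1:
                calls = ["na"] * len(calls)
            for j, c in zip(range(lo[h], hi[h]), calls):
                out_chrom.append(chrom)
                out_pos.append(int(P[j]))
                out_read.append(ri)
                out_call.append(c)
    return pd.DataFrame(
        {"chrom": out_chrom, "pos": out_pos, "read_index": out_read, "call": out_call}
    )


def bin_parentage(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Pool parental calls in consecutive non-overlapping bins.

    ``pct_a`` is computed over assigned (non-na) calls only; bins without
    assigned calls carry NaN and are excluded from averages.
    """
    rows = []
    for chrom, clen in chrom_lengths.items():
        n_bins = (clen + bin_size - 1) // bin_size
        sub = calls[calls.chrom == chrom]
        b = (sub.pos // bin_size).to_numpy() if len(sub) else np.empty(0, int)
        for k in range(n_bins):
            in_bin = sub[b == k] if len(sub) else sub
            n_a = int((in_bin.call == "parentA").sum())
            n_b = int((in_bin.call == "parentB").sum())
            n_na = int((in_bin.call == "na").sum())
            pct = 100.0 * n_a / (n_a + n_b) if (n_a + n_b) else np.nan
            rows.append(
                (chrom, k, k * bin_size, min((k + 1) * bin_size, clen), n_a, n_b, n_na, pct)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "bin", "start", "end", "n_a", "n_b", "n_na", "pct_a"]
    )


def parent_fraction_by_state(
    calls: pd.DataFrame,
    segments: pd.DataFrame,
) -> pd.DataFrame:
    """Percent of parent-A (haploid-inducer) allele calls per copy state.

    Calls are grouped by the copy state of their containing segment.  The
    returned frame has one row per state with the pooled allele-call
    fraction plus the across-segment mean and standard error.  In a diploid
    plus extra-parent-A-copy nucleus, state-3 regions are expected near
    2/3 parent A (2 A : 1 B chromatids) and state-4 near 3/4.
    """
    per_seg = []
    for chrom in segments.chrom.unique():
        segs = segments[segments.chrom == chrom].sort_values("start")
        sub = calls[calls.chrom == chrom]
        if sub.empty:
            continue
        seg_starts = segs.start.to_numpy()
        seg_ends = segs.end.to_numpy()
        seg_states = segs.state.to_numpy()
        idx = np.searchsorted(seg_starts, sub.pos.to_numpy(), side="right") - 1
        ok = (idx >= 0) & (sub.pos.to_numpy() < seg_ends[np.clip(idx, 0, None)])
        sub = sub[ok]
        idx = idx[ok]
        for seg_i in np.unique(idx):
            seg_calls = sub[idx == seg_i]
            n_a = int((seg_calls.call == "parentA").sum())
            n_b = int((seg_calls.call == "parentB").sum())
            if n_a + n_b == 0:
                continue
            per_seg.append(
                {
                    "chrom": chrom,
                    "start": int(seg_starts[seg_i]),
                    "end": int(seg_ends[seg_i]),
                    "state": int(seg_states[seg_i]),
                    "n_a": n_a,
                    "n_b": n_b,
                    "pct_a": 100.0 * n_a / (n_a + n_b),
                }
            )
    seg_df = pd.DataFrame(per_seg)
    if seg_df.empty:
        return pd.DataFrame(
            columns=["state", "n_segments", "n_a", "n_b", "pct_a", "mean_pct_a", "se_pct_a"]
        )
    rows = []
    for state, grp in seg_df.groupby("state"):
        n_a, n_b = int(grp.n_a.sum()), int(grp.n_b.sum())
        rows.append(
            {
                "state": int(state),
                "n_segments": len(grp),
                "n_a": n_a,
                "n_b": n_b,
                "pct_a": 100.0 * n_a / (n_a + n_b),
                "mean_pct_a": float(grp.pct_a.mean()),
                "se_pct_a": float(grp.pct_a.std(ddof=1) / np.sqrt(len(grp)))
                if len(grp) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("state").reset_index(drop=True)
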