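"""Binned read-depth dosage, copy-state segmentation and karyotype calls.

Relative coverage is expressed on a scale where the diploid background
equals 2, computed per bin as ``2 * sample% / reference%`` with the
reference being either a control individual or the cohort mean.  The scale
is anchored at 2 even for haploids: class labels, not the scale, convey
ploidy.  Copy states are read off the median-smoothed profile by rounding
to the nearest integer, which automates the by-eye block definition that
dosage plots are normally read with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .core import Genome, ParameterError
from .mapping import AlignmentSet

__all__ = [
    "BinnedCounts",
    "DosageProfile",
    "KaryotypeCall",
    "bin_counts",
    "relative_dosage",
    "segment_profile",
    "classify_karyotype",
]

KARYOTYPE_CLASSES = ("euploid", "numerical", "truncated", "shattered")


@dataclass
class BinnedCounts:
    """Per-bin read counts and percentages for one sample."""

    bin_size: int
    table: pd.DataFrame  # chrom, bin, start, end, count, pct
    total_reads: int


@dataclass
class DosageProfile:
    """Per-bin relative coverage, diploid background = 2."""

    sample_id: str
    bin_size: int
    table: pd.DataFrame  # chrom, bin, start, end, rel_cov (NaN = masked)

    def chrom_values(self, chrom: str) -> np.ndarray:
        sub = self.table[self.table.chrom == chrom].sort_values("bin")
        return sub.rel_cov.to_numpy()

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "sample", self.sample_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass
class KaryotypeCall:
    """Per-chromosome alteration class."""

    chrom: str
    clazz: str  # euploid | numerical | truncated | shattered
    n_breakpoints: int
    states: tuple[int, ...]


def bin_counts(
    alignments: AlignmentSet, genome: Genome, bin_size: int
) -> BinnedCounts:
    """Count alignment starts in consecutive non-overlapping bins.

    A read belongs to the bin containing its start coordinate; percentages
    are normalized by the total mapped read count over all chromosomes.
    """
    if bin_size < 100:
        raise ParameterError("bin_size must be >= 100")
    total = len(alignments)
    if total == 0:
        raise ParameterError("no mapped reads to bin")
    rows = []
    for cid, chrom in enumerate(alignments.chrom_names):
        if chrom not in genome:
            continue
        clen = len(genome[chrom])
        n_bins = (clen + bin_size - 1) // bin_size
        sel = alignments.chrom_id == cid
        counts = np.bincount(
            alignments.start[sel] // bin_size, minlength=n_bins
        ).astype(np.int64)
        for b in range(n_bins):
            rows.append(
                (
                    chrom,
                    b,
                    b * bin_size,
                    min((b + 1) * bin_size, clen),
                    int(counts[b]),
                )
            )
    # chromosomes with no alignments still get (zero) bins
    for chrom, clen in genome.lengths.items():
        if chrom not in alignments.chrom_names:
            n_bins = (clen + bin_size - 1) // bin_size
            for b in range(n_bins):
                rows.append((chrom, b, b * bin_size, min((b + 1) * bin_size, clen), 0))
    table = pd.DataFrame(rows, columns=["chrom", "bin", "start", "end", "count"])
    table["pct"] = 100.0 * table["count"] / total
    return BinnedCounts(bin_size=bin_size, table=table, total_reads=total)


def relative_dosage(
    sample: BinnedCounts,
    reference: BinnedCounts | None = None,
    cohort: list[BinnedCounts] | None = None,
    sample_id: str = "sample",
    anchor_background: bool = True,
) -> DosageProfile:
    """Scale per-bin percentages to a diploid-background value of 2.

    Exactly one of ``reference`` (control individual) or ``cohort`` (mean
    over individuals) must be provided.  Bins where the reference percentage
    is zero are masked (NaN), not divided.

    Because percentages are normalized per sample, aneuploid samples carry
    a systematic offset (extra chromosomal material deflates every bin).
    ``anchor_background`` (default) removes it by rescaling so the
    genome-wide median bin sits exactly at 2 — the diploid background is
    *set at* 2 by construction, assuming most of the genome is euploid.
    """
    if (reference is None) == (cohort is None):
        raise ParameterError("provide exactly one of reference or cohort")
    samp = sample.table.set_index(["chrom", "bin"]).sort_index()
    if reference is not None:
        if reference.bin_size != sample.bin_size:
            raise ParameterError("sample and reference use different bin sizes")
        ref_pct = reference.table.set_index(["chrom", "bin"]).sort_index()["pct"]
    else:
        for bc in cohort:
            if bc.bin_size != sample.bin_size:
                raise ParameterError("cohort member uses a different bin size")
        ref_pct = (
            pd.concat(
                [bc.table.set_index(["chrom", "bin"])["pct"] for bc in cohort], axis=1
            )
            .mean(axis=1)
            .sort_index()
        )
    ref = ref_pct.reindex(samp.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 2.0 * samp["pct"] / ref
    rel[(ref <= 0) | ref.isna()] = np.nan
    out = samp.reset_index()[["chrom", "bin", "start", "end"]]
    out["rel_cov"] = rel.to_numpy()
    if anchor_background:
        med = _background_level(out, sample.bin_size)
        if med > 0:
            out["rel_cov"] = out["rel_cov"] * (2.0 / med)
    return DosageProfile(sample_id=sample_id, bin_size=sample.bin_size, table=out)


def _background_level(table: pd.DataFrame, bin_size: int) -> float:
    """Median relative coverage of the diploid background.

    The median is taken over ~10 kb aggregated chunk means rather than raw
    bins: per-bin noise otherwise biases the genome-wide median upward
    whenever a sizeable genome fraction sits above the background.
    """
    group = max(1, 10_000 // bin_size)
    chunks = []
    for _, sub in table.groupby("chrom", sort=False):
        vals = sub.sort_values("bin").rel_cov.to_numpy(dtype=float)
        for lo in range(0, len(vals), group):
            chunk = vals[lo : lo + group]
            if np.isfinite(chunk).any():
                chunks.append(np.nanmean(chunk))
    return float(np.nanmedian(chunks)) if chunks else float("nan")


def _fill_nan(values: np.ndarray) -> np.ndarray:
    """Nearest-neighbour fill for masked bins (NaN-free output)."""
    out = values.copy()
    bad = np.isnan(out)
    if bad.all():
        return np.full_like(out, 2.0)
    if bad.any():
        idx = np.arange(len(out))
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def segment_profile(
    profile: DosageProfile,
    min_run: int = 3,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Segment each chromosome into integer copy-state runs.

    Per-bin state is the nearest integer of the median-smoothed relative
    coverage, clamped to [0, 6]; runs shorter than ``min_run`` bins are
    merged into the flanking state whose mean is closer.  Returns a frame
    with columns chrom, start_bin, end_bin, start, end, state, mean_cov.
    """
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    if smooth_window % 2 == 0:
        raise ParameterError("smooth_window must be odd")
    rows = []
    for chrom in profile.table.chrom.unique():
        sub = profile.table[profile.table.chrom == chrom].sort_values("bin")
        values = _fill_nan(sub.rel_cov.to_numpy(dtype=float))
        if smooth_window > 1 and len(values) > 1:
            smooth = median_filter(values, size=min(smooth_window, len(values)), mode="nearest")
        else:
            smooth = values
        states = np.clip(np.rint(smooth), 0, 6).astype(int)
        runs = _run_lengths(states)
        runs = _merge_short_runs(runs, values, min_run)
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        for s_bin, e_bin, state in runs:
            rows.append(
                (
                    chrom,
                    s_bin,
                    e_bin,
                    int(starts[s_bin]),
                    int(ends[e_bin - 1]),
                    int(state),
                    float(values[s_bin:e_bin].mean()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_bin", "end_bin", "start", "end", "state", "mean_cov"],
    )


def _run_lengths(states: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    for i, s in enumerate(states):
        if runs and runs[-1][2] == s:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1, int(s)])
    return runs


def _merge_short_runs(
    runs: list[list[int]], values: np.ndarray, min_run: int
) -> list[list[int]]:
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [r[1] - r[0] for r in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_run:
            break
        s, e, _ = runs[shortest]
        mean = values[s:e].mean()
        neighbours = []
        if shortest > 0:
            neighbours.append((shortest - 1, runs[shortest - 1][2]))
        if shortest < len(runs) - 1:
            neighbours.append((shortest + 1, runs[shortest + 1][2]))
        target = min(neighbours, key=lambda nb: abs(mean - nb[1]))[0]
        lo, hi = min(shortest, target), max(shortest, target)
        runs[lo] = [runs[lo][0], runs[hi][1], runs[target][2]]
        del runs[hi]
        # re-merge adjacent equal states
        merged: list[list[int]] = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    return runs


def classify_karyotype(
    segments: pd.DataFrame,
    shatter_min: int = 5,
) -> dict[str, KaryotypeCall]:
    """Classify each chromosome from its copy-state segments.

    euploid: one segment at state 2.  numerical: one segment at another
    state (whole-chromosome gain/loss).  truncated: at most two breakpoints
    with exactly one non-background state (simple truncation events).
    shattered: at least ``shatter_min`` state transitions or three or more
    distinct states (oscillating copy number).  Chromosomes with 3-4
    transitions between just two states fall through to shattered as the
    nearest class.
    """
    if segments.empty:
        raise ParameterError("empty segmentation")
    calls: dict[str, KaryotypeCall] = {}
    for chrom in segments.chrom.unique():
        sub = segments[segments.chrom == chrom].sort_values("start_bin")
        states = tuple(int(s) for s in sub.state)
        transitions = len(states) - 1
        distinct = set(states)
        if len(states) == 1:
            clazz = "euploid" if states[0] == 2 else "numerical"
        elif transitions >= shatter_min or len(distinct) >= 3:
            clazz = "shattered"
        elif transitions <= 2 and len(distinct - {2}) == 1 and 2 in distinct:
            clazz = "truncated"
        else:
            clazz = "shattered"
        calls[chrom] = KaryotypeCall(
            chrom=chrom, clazz=clazz, n_breakpoints=transitions, states=states
        )
    return calls
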