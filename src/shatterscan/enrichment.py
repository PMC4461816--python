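"""Feature occupancy around breakpoints and permutation-based enrichment.

Windows (1000 or 10,000 bp by default) are centered on each breakpoint,
clipped to the chromosome and unioned before summing, so clustered
breakpoints are not double counted.  Occupancy inside the window union is
compared to occupancy over the remainder of the same (aneuploid)
chromosome; the enrichment ratio's significance is assessed by re-drawing
the breakpoint locations uniformly over that chromosome and ranking the
observed ratio among the shuffled ones with the (r+1)/(n+1) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FormatError, ParameterError

__all__ = [
    "FeatureSet",
    "EnrichmentResult",
    "load_features",
    "merge_intervals",
    "window_union",
    "window_occupancy",
    "enrichment_ratio",
    "permutation_p",
]

FeatureIntervals = dict[str, np.ndarray]  # chrom -> (n, 2) 0-based half-open


@dataclass
class FeatureSet:
    """Merged interval tracks per feature class."""

    classes: dict[str, FeatureIntervals]

    def __getitem__(self, name: str) -> FeatureIntervals:
        return self.classes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    @property
    def names(self) -> list[str]:
        return list(self.classes)


@dataclass
class EnrichmentResult:
    feature_class: str
    breakpoint_class: str  # e.g. 'duplicated' | 'triplicated'
    window: int
    occ_in_pct: float
    occ_else_pct: float
    ratio: float  # NaN when occ_else is 0 (flagged undefined)
    p_enrich: float
    p_deplete: float
    n_shuffles: int
    seed: int

    def to_row(self) -> dict:
        return self.__dict__.copy()


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of possibly overlapping [start, end) intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    ivs = np.asarray(intervals, dtype=np.int64)
    ivs = ivs[np.argsort(ivs[:, 0])]
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def _parse_gff3(path: Path, feature_type: str | None) -> dict[str, list]:
    per_chrom: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}: malformed GFF3 line {lineno}")
            chrom, _src, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            if feature_type is not None and ftype != feature_type:
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}: non-numeric coordinates on line {lineno}")
            if s1 < 1 or e1 < s1:
                raise FormatError(f"{path}: bad interval on line {lineno}")
            per_chrom.setdefault(chrom, []).append((s1 - 1, e1))  # to 0-based half-open
    return per_chrom


def _parse_bed(path: Path) -> dict[str, list]:
    per_chrom: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: malformed BED line {lineno}")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}: non-numeric coordinates on line {lineno}")
            if s < 0 or e < s:
                raise FormatError(f"{path}: bad interval on line {lineno}")
            per_chrom.setdefault(parts[0], []).append((s, e))
    return per_chrom


def load_features(
    paths: dict[str, str | Path],
    feature_types: dict[str, str] | None = None,
) -> FeatureSet:
    """Load one GFF3/BED file per feature class and merge intervals.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; overlapping intervals within a class are
    unioned.  ``feature_types`` optionally restricts GFF3 parsing to one
    feature type per class.
    """
    classes: dict[str, FeatureIntervals] = {}
    for cls, p in paths.items():
        p = Path(p)
        if p.suffix.lower() in (".gff", ".gff3"):
            raw = _parse_gff3(p, (feature_types or {}).get(cls))
        elif p.suffix.lower() == ".bed":
            raw = _parse_bed(p)
        else:
            raise FormatError(f"{p}: unknown annotation format (need .gff3/.gff/.bed)")
        classes[cls] = {
            chrom: merge_intervals(np.array(ivs, dtype=np.int64))
            for chrom, ivs in raw.items()
        }
    return FeatureSet(classes)


def window_union(
    breakpoints: np.ndarray, window: int, chrom_len: int
) -> np.ndarray:
    """Merged windows of ``window`` bp centered on each breakpoint, clipped
    to [0, chrom_len)."""
    bp = np.asarray(breakpoints, dtype=np.int64)
    half = window // 2
    ivs = np.stack(
        [np.clip(bp - half, 0, chrom_len), np.clip(bp + window - half, 0, chrom_len)],
        axis=1,
    )
    return merge_intervals(ivs)


def _coverage_cumsum(intervals: np.ndarray, chrom_len: int) -> np.ndarray:
    """cum[i] = feature bp in [0, i); O(1) occupancy queries afterwards."""
    delta = np.zeros(chrom_len + 1, dtype=np.int64)
    for s, e in intervals:
        delta[min(s, chrom_len)] += 1
        delta[min(e, chrom_len)] -= 1
    return np.concatenate([[0], np.cumsum(np.cumsum(delta)[:-1])])


def _occupied_bp(cum: np.ndarray, windows: np.ndarray) -> int:
    if len(windows) == 0:
        return 0
    return int((cum[windows[:, 1]] - cum[windows[:, 0]]).sum())


def window_occupancy(
    breakpoints: np.ndarray,
    feature_intervals: np.ndarray,
    window: int,
    chrom_len: int,
    cum: np.ndarray | None = None,
) -> tuple[float, float]:
    """Percent of window-union bases vs remaining-chromosome bases covered
    by the feature.  Windows are unioned before summing."""
    if len(breakpoints) == 0:
        raise ParameterError("no breakpoints supplied")
    if cum is None:
        cum = _coverage_cumsum(merge_intervals(feature_intervals), chrom_len)
    wins = window_union(breakpoints, window, chrom_len)
    in_bp = int((wins[:, 1] - wins[:, 0]).sum())
    else_bp = chrom_len - in_bp
    feat_in = _occupied_bp(cum, wins)
    feat_total = int(cum[chrom_len])
    feat_else = feat_total - feat_in
    occ_in = 100.0 * feat_in / in_bp if in_bp else np.nan
    occ_else = 100.0 * feat_else / else_bp if else_bp else np.nan
    return occ_in, occ_else


def enrichment_ratio(occ_in_pct: float, occ_else_pct: float) -> float:
    """Occupancy-in over occupancy-elsewhere; NaN when elsewhere is zero."""
    if occ_else_pct == 0 or np.isnan(occ_else_pct):
        return float("nan")
    return occ_in_pct / occ_else_pct


def permutation_p(
    breakpoints: np.ndarray,
    feature_intervals: np.ndarray,
    window: int,
    chrom_len: int,
    n_shuffles: int = 1000,
    seed: int = 0,
    feature_class: str = "feature",
    breakpoint_class: str = "all",
) -> EnrichmentResult:
    """Empirical enrichment/depletion p-values by breakpoint shuffling.

    Shuffled breakpoint sets are drawn uniformly over the chromosome,
    preserving the breakpoint count; p_enrich = (1 + #{shuffled ratio >=
    observed}) / (1 + n) and p_deplete is the mirror image.  Fixed seed,
    fixed result.
    """
    if n_shuffles < 100:
        raise ParameterError("n_shuffles must be >= 100")
    bp = np.asarray(breakpoints, dtype=np.int64)
    merged = merge_intervals(feature_intervals)
    cum = _coverage_cumsum(merged, chrom_len)
    occ_in, occ_else = window_occupancy(bp, merged, window, chrom_len, cum=cum)
    obs = enrichment_ratio(occ_in, occ_else)
    rng = np.random.default_rng(seed)
    n_ge = 0
    n_le = 0
    for _ in range(n_shuffles):
        fake = rng.integers(0, chrom_len, len(bp))
        o_in, o_else = window_occupancy(fake, merged, window, chrom_len, cum=cum)
        r = enrichment_ratio(o_in, o_else)
        if np.isnan(obs) or np.isnan(r):
            n_ge += 1
            n_le += 1
            continue
        if r >= obs:
            n_ge += 1
        if r <= obs:
            n_le += 1
    return EnrichmentResult(
        feature_class=feature_class,
        breakpoint_class=breakpoint_class,
        window=window,
        occ_in_pct=float(occ_in),
        occ_else_pct=float(occ_else),
        ratio=float(obs),
        p_enrich=(1 + n_ge) / (1 + n_shuffles),
        p_deplete=(1 + n_le) / (1 + n_shuffles),
        n_shuffles=n_shuffles,
        seed=seed,
    )
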