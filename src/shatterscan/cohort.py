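"""Cohort tallies and contingency statistics for cross outcomes.

Genome-elimination crosses yield haploid, diploid and aneuploid progeny;
comparisons of those proportions between crosses are made on 2x2 count
tables with Fisher's exact test (a chi-square with continuity correction
is reported alongside).  Where a source table prints totals and
percentages rather than raw counts, counts are reconstructed by
nearest-integer rounding and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParameterError
from .dosage import KaryotypeCall

__all__ = [
    "ContingencyResult",
    "contingency_test",
    "reconstruct_counts",
    "sample_outcome",
    "tally_cohort",
    "LIG4_CROSS_TABLE",
    "MICRONUCLEI_COUNTS",
]

# Haploid-induction outcomes per cross: (total, %aneuploid, %diploid, %haploid),
# printed as percentages of the stated total.  Raw counts are reconstructed by
# nearest-integer rounding (see reconstruct_counts).
LIG4_CROSS_TABLE = pd.DataFrame(
    [
        ("GFP-tailswap", "Ler gl1", 606, 33, 28, 39),
        ("GFP-tailswap", "lig4-2", 148, 8, 9, 83),
        ("lig4-2 GFP-tailswap", "Ler gl1", 173, 29, 31, 40),
        ("lig4-2 GFP-tailswap", "lig4-2", 159, 14, 5, 81),
    ],
    columns=["seed_parent", "pollen_parent", "total", "pct_aneuploid", "pct_diploid", "pct_haploid"],
)

# Embryos with >=1 micronucleus: 81% of 110 in genome-elimination crosses,
# 0 of 21 in control crosses.
MICRONUCLEI_COUNTS = {
    "elimination_total": 110,
    "elimination_pct_with": 81,
    "control_total": 21,
    "control_with": 0,
}


@dataclass
class ContingencyResult:
    table: np.ndarray
    p_fisher: float
    odds_ratio: float
    p_chi2: float
    haldane_corrected: bool

    def __str__(self) -> str:
        return (
            f"2x2 table {self.table.tolist()}: Fisher p = {self.p_fisher:.3g}, "
            f"OR = {self.odds_ratio:.3g}"
            + (" (Haldane-corrected)" if self.haldane_corrected else "")
            + f", chi2 p = {self.p_chi2:.3g}"
        )


def reconstruct_counts(total: int, percentages: list[float]) -> list[int]:
    """Nearest-integer counts from a printed total and percentages.

    The reconstruction is approximate whenever the percentages were
    themselves rounded; the final category absorbs the rounding remainder
    so that counts sum to the total.
    """
    counts = [int(round(total * p / 100.0)) for p in percentages[:-1]]
    counts.append(total - sum(counts))
    if min(counts) < 0:
        raise ParameterError("percentages inconsistent with the stated total")
    return counts


def contingency_test(table) -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The odds ratio uses the Haldane +0.5 correction when a zero cell is
    present; a chi-square with Yates continuity correction is reported
    alongside (degenerate margins give chi-square p = NaN).
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2):
        raise ParameterError("contingency_test expects a 2x2 table")
    if (tab < 0).any():
        raise ParameterError("counts must be nonnegative")
    if tab.sum() == 0:
        raise ParameterError("table is all zero")
    _, p_fisher = stats.fisher_exact(tab, alternative="two-sided")
    a, b, c, d = tab.ravel().astype(float)
    haldane = bool((tab == 0).any())
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    try:
        p_chi2 = float(stats.chi2_contingency(tab, correction=True)[1])
    except ValueError:
        p_chi2 = float("nan")
    return ContingencyResult(
        table=tab, p_fisher=float(p_fisher), odds_ratio=float(odds),
        p_chi2=p_chi2, haldane_corrected=haldane,
    )


def sample_outcome(
    calls: dict[str, KaryotypeCall],
    genome_pct_parent_a: float | None = None,
) -> str:
    """Ploidy outcome of one sample: aneuploid, haploid or diploid.

    Dosage alone cannot separate haploids from diploids (relative coverage
    is anchored at 2 either way), so euploid-dosage samples are called
    haploid when the genome-wide parent-A allele percentage shows a single
    haplotype (<10% or >90%), diploid otherwise.
    """
    if any(c.clazz != "euploid" for c in calls.values()):
        return "aneuploid"
    if genome_pct_parent_a is not None and (
        genome_pct_parent_a < 10 or genome_pct_parent_a > 90
    ):
        return "haploid"
    return "diploid"


def _sample_class(calls: dict[str, KaryotypeCall]) -> str:
    """Aneuploidy class label; combinations are their own category."""
    present = sorted({c.clazz for c in calls.values() if c.clazz != "euploid"})
    if not present:
        return "euploid"
    if present == ["numerical"]:
        n = sum(1 for c in calls.values() if c.clazz == "numerical")
        names = {1: "single", 2: "double", 3: "triple", 4: "quadruple"}
        return f"numerical_{names.get(n, str(n) + 'x')}"
    if len(present) == 1:
        return present[0]
    return "+".join(present)


def tally_cohort(
    cohort_calls: dict[str, dict[str, KaryotypeCall]],
    parent_a_pct: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally ploidy outcomes and aneuploidy classes over a cohort.

    Returns ``(outcomes, classes)``: outcome counts (aneuploid / diploid /
    haploid) with percentages, and the per-class breakdown of the aneuploid
    samples (numerical single/double/..., truncated, shattered and
    combination categories, each sample counted once) with the aneuploid
    denominator reported.
    """
    if not cohort_calls:
        raise ParameterError("empty cohort")
    outcomes: dict[str, int] = {}
    classes: dict[str, int] = {}
    for sample, calls in cohort_calls.items():
        pct = (parent_a_pct or {}).get(sample)
        outcome = sample_outcome(calls, pct)
        outcomes[outcome] = outcomes.get(outcome, 0) + 1
        if outcome == "aneuploid":
            cls = _sample_class(calls)
            classes[cls] = classes.get(cls, 0) + 1
    total = sum(outcomes.values())
    out_df = pd.DataFrame(
        [
            {"outcome": k, "count": v, "pct": 100.0 * v / total, "denominator": total}
            for k, v in sorted(outcomes.items())
        ]
    )
    n_aneu = sum(classes.values())
    cls_df = pd.DataFrame(
        [
            {
                "class": k,
                "count": v,
                "pct": 100.0 * v / n_aneu if n_aneu else np.nan,
                "denominator": n_aneu,
            }
            for k, v in sorted(classes.items())
        ]
    )
    return out_df, cls_df


def micronuclei_table() -> np.ndarray:
    """2x2 embryo counts (with vs without micronuclei, elimination vs
    control cross), reconstructed from the printed percentages."""
    m = MICRONUCLEI_COUNTS
    with_mn = int(round(m["elimination_total"] * m["elimination_pct_with"] / 100.0))
    return np.array(
        [
            [with_mn, m["elimination_total"] - with_mn],
            [m["control_with"], m["control_total"] - m["control_with"]],
        ]
    )


def lig4_haploid_table(rows: tuple[int, int] = (0, 1)) -> np.ndarray:
    """2x2 haploid vs non-haploid counts for two crosses of the
    haploid-induction table (default: wild-type vs lig4-2 pollen)."""
    t = LIG4_CROSS_TABLE
    out = []
    for r in rows:
        total = int(t.loc[r, "total"])
        hap = int(round(total * t.loc[r, "pct_haploid"] / 100.0))
        out.append([hap, total - hap])
    return np.array(out)
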