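"""SNP discovery thresholds, read assignment and parentage summaries."""

import numpy as np
import pandas as pd
import pytest

from shatterscan import snp as snpmod
from shatterscan.core import Genome, ParameterError, ReadSet
from shatterscan.mapping import AlignmentSet, Pileup


def _pileup(length=10, columns=None):
    """Pileup on one 'c' chromosome; columns maps pos -> (A, C, G, T)."""
    mat = np.zeros((4, length), dtype=np.uint32)
    for pos, counts in (columns or {}).items():
        mat[:, pos] = counts
    return Pileup({"c": mat})


class TestIdentifySnps:
    def test_passing_position_retained_with_parental_alleles(self):
        hybrid = _pileup(5, {2: (15, 0, 15, 0)})  # depth 30, A/G 50:50
        pa = _pileup(5, {2: (0, 0, 10, 0)})  # 10x G
        pb = _pileup(5, {2: (3, 0, 0, 0)})  # 3x A
        out = snpmod.identify_snps(hybrid, pa, pb)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.pos, row.allele_a, row.allele_b) == (2, "G", "A")

    @pytest.mark.parametrize(
        "hybrid_counts, pa_counts, pb_counts",
        [
            # hybrid depth 24 < 25
            ((12, 0, 12, 0), (0, 0, 10, 0), (3, 0, 0, 0)),
            # minor allele below 40% (10/30)
            ((10, 0, 20, 0), (0, 0, 10, 0), (3, 0, 0, 0)),
            # parent A only 96% homozygous (24/25)
            ((15, 0, 15, 0), (1, 0, 24, 0), (3, 0, 0, 0)),
            # parent A depth 5 < 6
            ((15, 0, 15, 0), (0, 0, 5, 0), (3, 0, 0, 0)),
            # parent B uncovered
            ((15, 0, 15, 0), (0, 0, 10, 0), (0, 0, 0, 0)),
            # parents share the same allele
            ((15, 0, 15, 0), (0, 0, 10, 0), (0, 0, 4, 0)),
            # three alleles above the noise floor
            ((12, 6, 12, 0), (0, 0, 10, 0), (3, 0, 0, 0)),
        ],
    )
    def test_threshold_violations_rejected(self, hybrid_counts, pa_counts, pb_counts):
        hybrid = _pileup(5, {2: hybrid_counts})
        pa = _pileup(5, {2: pa_counts})
        pb = _pileup(5, {2: pb_counts})
        assert len(snpmod.identify_snps(hybrid, pa, pb)) == 0

    def test_raising_hybrid_depth_never_adds_snps(self, small_study):
        """Monotonicity of the discovery filter in the depth threshold."""
        study = small_study
        base = snpmod.identify_snps(
            study.pileups["hybrid"], study.pileups["parent_a"], study.pileups["parent_b"]
        )
        found = set(zip(base.chrom, base.pos))
        for depth in (30, 40, 60):
            t = snpmod.SnpThresholds(hybrid_min_depth=depth)
            stricter = snpmod.identify_snps(
                study.pileups["hybrid"],
                study.pileups["parent_a"],
                study.pileups["parent_b"],
                t,
            )
            assert set(zip(stricter.chrom, stricter.pos)) <= found
            found = set(zip(stricter.chrom, stricter.pos))

    def test_discovery_equals_naive_threshold_filter(self, small_study):
        """Oracle: a direct per-position reimplementation of the filter on
        the planted SNP positions yields exactly the discovered table."""
        study = small_study
        t = snpmod.SnpThresholds()
        naive = set()
        for s in study.plant.snps.itertuples():
            h = study.pileups["hybrid"].counts[s.chrom][:, s.pos]
            a = study.pileups["parent_a"].counts[s.chrom][:, s.pos]
            b = study.pileups["parent_b"].counts[s.chrom][:, s.pos]
            dh, da, db = int(h.sum()), int(a.sum()), int(b.sum())
            if dh < t.hybrid_min_depth or da < t.parent_a_min_depth or db < t.parent_b_min_depth:
                continue
            alleles = [i for i in range(4) if h[i] > 0 and h[i] / dh >= t.noise_floor]
            if len(alleles) != 2 or min(h[i] / dh for i in alleles) < t.min_allele_frac:
                continue
            if a.max() / da < t.parental_homozygosity or b.max() / db < t.parental_homozygosity:
                continue
            ia, ib = int(a.argmax()), int(b.argmax())
            if ia == ib or ia not in alleles or ib not in alleles:
                continue
            naive.add((s.chrom, s.pos))
        assert naive == set(zip(study.snps_found.chrom, study.snps_found.pos))


def _tiny_alignments(genome, reads):
    """Place each read at its exact forward match (test scaffolding)."""
    starts, cids = [], []
    for r in reads.sequences:
        p = genome["c"].find(r)
        assert p != -1
        starts.append(p)
        cids.append(0)
    n = len(reads)
    return AlignmentSet(
        chrom_names=["c"],
        read_index=np.arange(n),
        chrom_id=np.array(cids, np.int32),
        start=np.array(starts, np.int64),
        strand=np.zeros(n, np.int8),
        length=np.array([len(r) for r in reads.sequences], np.int32),
        n_reads=n,
    )


class TestAssignReads:
    @pytest.fixture()
    def scene(self):
        rng = np.random.default_rng(17)
        seq = bytearray(bytes(b"ACGT"[c] for c in rng.integers(0, 4, 100)))
        genome = Genome({"c": bytes(seq)})
        snps = pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "pos": [10, 40],
                "allele_a": [chr(seq[10]), chr(seq[40])],
                "allele_b": ["T" if seq[10] != ord("T") else "A"] * 1
                + ["T" if seq[40] != ord("T") else "A"],
            }
        )
        return genome, snps

    def test_read_with_parent_a_allele(self, scene):
        genome, snps = scene
        reads = ReadSet([genome["c"][5:25]])
        calls = snpmod.assign_reads(_tiny_alignments(genome, reads), reads, snps)
        assert list(calls.call) == ["parentA"]

    def test_read_with_parent_b_allele(self, scene):
        genome, snps = scene
        seq = bytearray(genome["c"][5:25])
        seq[5] = ord(snps.allele_b[0])  # SNP at chrom pos 10 = read offset 5
        reads = ReadSet([bytes(seq)])
        aln = _tiny_alignments(genome, ReadSet([genome["c"][5:25]]))
        calls = snpmod.assign_reads(aln, reads, snps)
        assert list(calls.call) == ["parentB"]

    def test_mismatching_base_is_na(self, scene):
        genome, snps = scene
        seq = bytearray(genome["c"][5:25])
        current = {seq[5], ord(snps.allele_b[0])}
        seq[5] = next(b for b in b"ACGT" if b not in current)
        reads = ReadSet([bytes(seq)])
        aln = _tiny_alignments(genome, ReadSet([genome["c"][5:25]]))
        calls = snpmod.assign_reads(aln, reads, snps)
        assert list(calls.call) == ["na"]

    def test_conflicting_parents_in_one_read_all_na(self, scene):
        genome, snps = scene
        seq = bytearray(genome["c"][5:45])  # spans SNPs at 10 (A allele) and 40
        seq[35] = ord(snps.allele_b[1])  # second SNP carries the B allele
        reads = ReadSet([bytes(seq)])
        aln = _tiny_alignments(genome, ReadSet([genome["c"][5:45]]))
        calls = snpmod.assign_reads(aln, reads, snps)
        assert list(calls.call) == ["na", "na"]

    def test_empty_snp_table_rejected(self, scene):
        genome, _ = scene
        reads = ReadSet([genome["c"][5:25]])
        with pytest.raises(ParameterError):
            snpmod.assign_reads(
                _tiny_alignments(genome, reads), reads,
                pd.DataFrame(columns=["chrom", "pos", "allele_a", "allele_b"]),
            )


class TestParentageBinsAndStates:
    def test_balanced_hybrid_bins_near_fifty_percent(self, small_study):
        study = small_study
        calls = snpmod.assign_reads(
            study.aln["control"], study.reads["control"], study.snps_found
        )
        bins = snpmod.bin_parentage(calls, study.reference.lengths, 50_000)
        ok = 0
        for b in bins.itertuples():
            n = b.n_a + b.n_b
            if n == 0:
                continue
            sigma = 100.0 * np.sqrt(0.25 / n)
            ok += abs(b.pct_a - 50.0) < 3 * sigma
        assert ok / len(bins) >= 0.95

    def test_empty_bin_flagged_missing(self):
        calls = pd.DataFrame({"chrom": ["c"], "pos": [10], "read_index": [0], "call": ["parentA"]})
        bins = snpmod.bin_parentage(calls, {"c": 3_000_000}, 1_000_000)
        assert len(bins) == 3
        assert np.isnan(bins.pct_a.iloc[1]) and np.isnan(bins.pct_a.iloc[2])
        assert bins.pct_a.iloc[0] == 100.0

    def test_fraction_by_state_expectations(self, small_study):
        """State 1 carries parent-B alleles (LOH); state 2 is balanced;
        extra copies in states 3/4 come from parent A (2:1 and 3:1)."""
        study = small_study
        calls = snpmod.assign_reads(
            study.aln["shattered"], study.reads["shattered"], study.snps_found
        )
        by_state = snpmod.parent_fraction_by_state(calls, study.segments).set_index("state")
        assert by_state.loc[1, "pct_a"] < 15
        assert abs(by_state.loc[2, "pct_a"] - 50) < 5
        assert by_state.loc[3, "pct_a"] > 60
        if 4 in by_state.index:
            assert by_state.loc[4, "pct_a"] > by_state.loc[3, "pct_a"] - 5
        assert by_state.pct_a.idxmax() in (3, 4)
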