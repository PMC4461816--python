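"""Breakpoint detection, local assembly, split alignment, junction typing."""

import numpy as np
import pandas as pd
import pytest

from shatterscan import dosage as dos
from shatterscan import junctions as jnc
from shatterscan import simulate as sim
from shatterscan.core import Genome, revcomp


def _rand_genome(seed=0, length=6_000, name="c"):
    rng = np.random.default_rng(seed)
    return Genome({name: bytes(bytearray(b"ACGT"[c] for c in rng.integers(0, 4, length)))})


def _segments(runs, chrom="chr1", bin_size=500):
    rows, pos = [], 0
    for state, nbins in runs:
        rows.append(
            (chrom, pos, pos + nbins, pos * bin_size, (pos + nbins) * bin_size, state, float(state))
        )
        pos += nbins
    return pd.DataFrame(
        rows, columns=["chrom", "start_bin", "end_bin", "start", "end", "state", "mean_cov"]
    )


class TestDetectBreakpoints:
    def test_flat_chromosome_has_none(self):
        assert len(jnc.detect_breakpoints(_segments([(2, 100)]))) == 0

    def test_one_block_gives_two_breakpoints_at_segment_edges(self):
        bps = jnc.detect_breakpoints(_segments([(2, 30), (3, 40), (2, 30)]))
        assert list(bps.pos) == [15_000, 35_000]
        assert list(bps.left_state) == [2, 3]
        assert list(bps.right_state) == [3, 2]

    def test_23_duplicated_blocks_give_46_duplicated_breakpoints(self):
        runs = []
        for _ in range(23):
            runs += [(2, 10), (3, 10)]
        runs += [(2, 10)]
        bps = jnc.detect_breakpoints(_segments(runs))
        dup = bps[(bps.left_state == 3) | (bps.right_state == 3)]
        assert len(dup) == 46


class TestAssembleLocal:
    def test_tiled_error_free_reads_reassemble_region(self):
        region = _rand_genome(5, 600)["c"]
        reads = [region[i : i + 100] for i in range(0, 500, 20)] + [region[500:600]]
        contigs = jnc.assemble_local(reads, min_overlap=31, min_reads=3)
        assert len(contigs) == 1
        contig, support = contigs[0]
        assert contig == region or contig == revcomp(region)
        assert support == len(reads)

    def test_overlap_below_threshold_not_merged(self):
        region = _rand_genome(6, 300)["c"]
        # two 100-mers overlapping by exactly min_overlap - 1
        a, b = region[:100], region[70:170]
        contigs = jnc.assemble_local([a, b], min_overlap=31, min_reads=1, min_contig_len=10)
        assert sorted(len(c) for c, _ in contigs) == [100, 100]
        merged = jnc.assemble_local([a, b], min_overlap=30, min_reads=1, min_contig_len=10)
        assert [len(c) for c, _ in merged] == [170]

    def test_reverse_complement_reads_give_same_contig_up_to_orientation(self):
        region = _rand_genome(7, 600)["c"]
        reads = [region[i : i + 100] for i in range(0, 501, 20)]
        rc_reads = [revcomp(r) for r in reads]
        c1 = jnc.assemble_local(reads, min_reads=3)[0][0]
        c2 = jnc.assemble_local(rc_reads, min_reads=3)[0][0]
        assert c1 in (c2, revcomp(c2))

    def test_low_support_contig_discarded(self):
        region = _rand_genome(8, 400)["c"]
        contigs = jnc.assemble_local([region[:100], region[60:160]], min_reads=3)
        assert contigs == []


def _planted_split(jtype, seed=11, **spec_kwargs):
    """Build a two-block junction on a random genome and split-align the
    contig read off the derived sequence around the join."""
    g = _rand_genome(seed, 6_000)
    plan = sim.BlockPlan(
        entries=[
            sim.Block("c", 200, 1_200, "+", 2),
            sim.Block("c", 3_000, 4_000, spec_kwargs.pop("orient2", "+"), 2),
        ],
        junctions=[sim.JunctionSpec(jtype, **spec_kwargs)],
    )
    derived, truth = sim.build_shattered_chromosome(g, "c", plan, seed=seed)
    edited = sim.apply_edits(g, truth.edits)
    j = truth.junctions.iloc[0]
    mid = int(j.derived_pos)
    right = 150 + len(j.insertion_seq)  # keep >= anchor length past any insertion
    contig = derived[mid - 150 : mid + right]
    split = jnc.split_align(contig, edited, min_anchor=30)
    return split, truth, edited


class TestSplitAlignAndClassify:
    def test_blunt_junction_anchors_abut(self):
        split, truth, _ = _planted_split("blunt")
        assert split is not None
        assert split.overlap == 0 and split.gap == 0
        j = jnc.classify_junction(split)
        t = truth.junctions.iloc[0]
        assert j.jtype == "blunt"
        assert {j.pos_left, j.pos_right} == {t.pos_left, t.pos_right}

    @pytest.mark.parametrize("k", [2, 4, 9, 15])
    def test_microhomology_overlap_equals_planted_k(self, k):
        split, truth, _ = _planted_split("microhomology", mh_len=k)
        assert split.overlap == k
        j = jnc.classify_junction(split)
        assert j.jtype == "microhomology" and j.mh_len == k

    @pytest.mark.parametrize("n", [1, 30, 125])
    def test_insertion_middle_unaligned(self, n):
        split, truth, _ = _planted_split("insertion", ins_len=n)
        assert split.gap == n
        j = jnc.classify_junction(split)
        assert j.jtype == "insertion"
        assert j.insertion_seq == truth.junctions.iloc[0].insertion_seq

    def test_inverted_join_detected_from_strand_discordance(self):
        split, truth, _ = _planted_split("blunt", orient2="-")
        j = jnc.classify_junction(split)
        assert j.inverted
        assert j.side_left == j.side_right  # head-to-head or tail-to-tail

    def test_classification_invariant_under_contig_reverse_complement(self):
        for jtype, kw in [("blunt", {}), ("microhomology", {"mh_len": 7}), ("insertion", {"ins_len": 12})]:
            split, truth, edited = _planted_split(jtype, seed=23, **kw)
            rc = jnc.split_align(revcomp(split.contig), edited, min_anchor=30)
            a = jnc.classify_junction(split)
            b = jnc.classify_junction(rc)
            assert a.key() == b.key()
            assert a.inverted == b.inverted

    def test_short_anchor_rejected(self):
        g = _rand_genome(31, 2_000)
        rng = np.random.default_rng(0)
        novel = bytes(bytearray(b"ACGT"[c] for c in rng.integers(0, 4, 80)))
        contig = novel + g["c"][500:640]  # prefix matches nowhere
        split = jnc.split_align(contig, g, min_anchor=30)
        assert split is None


class TestSummaries:
    def _truth_frame(self, n_mh=10, n_blunt=5, n_ins=5, inverted=0):
        rows = []
        rng = np.random.default_rng(2)
        for i in range(n_mh + n_blunt + n_ins):
            if i < n_mh:
                jtype, mh, ins = "microhomology", int(rng.integers(2, 16)), ""
            elif i < n_mh + n_blunt:
                jtype, mh, ins = "blunt", 0, ""
            else:
                jtype, mh, ins = "insertion", 0, "A" * int(rng.integers(1, 126))
            rows.append(
                ("chr1", 1000 * i, "upstream", "chr1", 1000 * i + 500,
                 "downstream", jtype, mh, ins, i < inverted, 5, False)
            )
        return pd.DataFrame(rows, columns=jnc._JUNCTION_COLUMNS)

    def test_planted_type_mix_recovered_exactly(self):
        out = jnc.summarize_junctions(self._truth_frame(10, 5, 5))
        assert out["type_counts"] == {"microhomology": 10, "blunt": 5, "insertion": 5}
        assert sum(out["mh_length_hist"].values()) == 10
        assert sum(out["insertion_length_hist_25bp"].values()) == 5

    def test_all_forward_joins_have_zero_inversion_fraction(self):
        out = jnc.summarize_junctions(self._truth_frame(inverted=0))
        assert out["inversion_fraction"] == 0.0

    def test_inversion_fraction_counts_inverted_rows(self):
        out = jnc.summarize_junctions(self._truth_frame(inverted=10))
        assert out["inversion_fraction"] == pytest.approx(0.5)

    def test_block_size_comparison_significant_at_n23(self):
        """Duplicated blocks drawn 10x larger than triplicated at n=23/23."""
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(23):
            rows.append(("chr1", 0, int(rng.normal(200_000, 40_000)), 3))
        for _ in range(23):
            rows.append(("chr1", 0, int(rng.normal(20_000, 4_000)), 4))
        blocks = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        out = jnc.summarize_junctions(self._truth_frame(), blocks=blocks)
        assert out["n_duplicated_blocks"] == 23
        assert out["n_triplicated_blocks"] == 23
        assert out["block_size_t_p"] < 0.01
        assert out["block_size_rank_p"] < 0.01


class TestChimericPrediction:
    GENES = pd.DataFrame(
        {
            "chrom": ["c", "c"],
            "start": [100, 5_000],
            "end": [1_000, 6_000],
            "strand": ["+", "+"],
        }
    )

    def _junction(self, pos_left, side_left, pos_right, side_right):
        return jnc.Junction(
            chrom_left="c", pos_left=pos_left, side_left=side_left,
            chrom_right="c", pos_right=pos_right, side_right=side_right,
            jtype="blunt", mh_len=0, insertion_seq="",
            inverted=side_left == side_right,
        )

    def test_forward_join_of_two_same_strand_genes(self):
        j = self._junction(500, "upstream", 5_500, "downstream")
        assert jnc.predict_chimeric(j, self.GENES)

    def test_intergenic_anchors_false(self):
        j = self._junction(2_000, "upstream", 3_000, "downstream")
        assert not jnc.predict_chimeric(j, self.GENES)

    def test_one_genic_anchor_false(self):
        j = self._junction(500, "upstream", 3_000, "downstream")
        assert not jnc.predict_chimeric(j, self.GENES)

    def test_inverted_join_of_same_strand_genes_false(self):
        # both retained-upstream: the second gene would read backwards
        j = self._junction(500, "upstream", 5_500, "upstream")
        assert not jnc.predict_chimeric(j, self.GENES)

    def test_inverted_join_of_opposite_strand_genes_true(self):
        genes = self.GENES.copy()
        genes.loc[1, "strand"] = "-"
        j = self._junction(500, "upstream", 5_500, "upstream")
        assert jnc.predict_chimeric(j, genes)


class TestEndToEndRecovery:
    def test_planted_junctions_recovered_with_exact_chemistry(self, small_study):
        """All 8 planted junctions of the small study are reassembled with
        the right type, homology length and +-1 bp anchors."""
        study = small_study
        bps = jnc.detect_breakpoints(study.segments)
        bps = bps[bps.chrom == "chr1"]
        juncs = jnc.junctions_from_breakpoints(
            study.aln["shattered"], study.reads["shattered"], study.reference,
            bps, insert_mean=300, insert_sd=50,
        )
        match = jnc.match_junctions(
            jnc.junctions_to_frame(juncs), study.plant.truth.junctions
        )
        assert match.recovered.all()
        assert match.exact_chemistry.all()

    def test_no_junctions_called_on_diploid_control(self, small_study):
        study = small_study
        control_bins = dos.bin_counts(study.aln["control"], study.reference, 500)
        profile = dos.relative_dosage(control_bins, reference=control_bins)
        segs = dos.segment_profile(profile, min_run=4, smooth_window=7)
        bps = jnc.detect_breakpoints(segs)
        assert len(bps) == 0
        juncs = jnc.junctions_from_breakpoints(
            study.aln["control"], study.reads["control"], study.reference,
            bps, insert_mean=300, insert_sd=50,
        )
        assert juncs == []
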