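"""Generator invariants: planted SNPs, junction chemistry, read depths."""

import numpy as np
import pytest

from shatterscan import simulate as sim
from shatterscan.core import Genome, ParameterError, revcomp


def _seq_diff_positions(a: Genome, b: Genome):
    out = set()
    for chrom in a.names:
        xa, xb = a.array(chrom), b.array(chrom)
        for p in np.flatnonzero(xa != xb):
            out.add((chrom, int(p)))
    return out


class TestParentalGenomes:
    def test_snp_count_within_3_sigma_of_binomial(self):
        _, _, snps = sim.make_parental_genomes(2, 100_000, 1e-3, seed=7)
        mean, sd = 200_000 * 1e-3, np.sqrt(200_000 * 1e-3 * 0.999)
        assert abs(len(snps) - mean) < 3 * sd

    def test_same_seed_reproduces_genomes_and_table(self):
        a1, b1, s1 = sim.make_parental_genomes(2, 20_000, 1e-3, seed=42)
        a2, b2, s2 = sim.make_parental_genomes(2, 20_000, 1e-3, seed=42)
        assert a1.sequences == a2.sequences and b1.sequences == b2.sequences
        assert s1.equals(s2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"snp_rate": 0.0},
            {"snp_rate": 0.06},
            {"chrom_len": 5_000},
            {"n_chrom": 0},
        ],
    )
    def test_degenerate_parameters_rejected(self, kwargs):
        args = {"n_chrom": 1, "chrom_len": 20_000, "snp_rate": 1e-3, "seed": 0}
        args.update(kwargs)
        with pytest.raises(ParameterError):
            sim.make_parental_genomes(**args)

    def test_every_planted_snp_recoverable_no_off_plan_differences(self):
        pa, pb, snps = sim.make_parental_genomes(2, 50_000, 2e-3, seed=9)
        assert _seq_diff_positions(pa, pb) == set(zip(snps.chrom, snps.pos))
        assert snps.groupby("chrom").pos.apply(lambda s: s.is_monotonic_increasing).all()


def _toy_genome(seed=0, length=4_000):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, length)
    return Genome({"c": bytes(bytearray(b"ACGT"[c] for c in codes))})


def _two_block_plan(l1, l2, spec, orient2="+"):
    return sim.BlockPlan(
        entries=[
            sim.Block("c", 100, 100 + l1, "+", 2),
            sim.Block("c", 2000, 2000 + l2, orient2, 2),
        ],
        junctions=[spec],
    )


class TestShatteredConstruction:
    def test_blunt_junction_length_additive(self):
        g = _toy_genome()
        plan = _two_block_plan(300, 400, sim.JunctionSpec("blunt"))
        derived, truth = sim.build_shattered_chromosome(g, "c", plan, seed=1)
        assert len(derived) == 700
        assert truth.junctions.iloc[0]["type"] == "blunt"

    @pytest.mark.parametrize("k", [2, 4, 15])
    def test_microhomology_shortens_by_k(self, k):
        g = _toy_genome()
        plan = _two_block_plan(300, 400, sim.JunctionSpec("microhomology", mh_len=k))
        derived, truth = sim.build_shattered_chromosome(g, "c", plan, seed=1)
        assert len(derived) == 700 - k
        j = truth.junctions.iloc[0]
        assert j["type"] == "microhomology" and j.mh_len == k

    def test_insertion_lengthens_by_insert(self):
        g = _toy_genome()
        plan = _two_block_plan(300, 400, sim.JunctionSpec("insertion", ins_len=30))
        derived, truth = sim.build_shattered_chromosome(g, "c", plan, seed=1)
        assert len(derived) == 730
        assert len(truth.junctions.iloc[0].insertion_seq) == 30

    def test_reverse_block_marked_inversion_type(self):
        g = _toy_genome()
        plan = _two_block_plan(300, 400, sim.JunctionSpec("blunt"), orient2="-")
        _, truth = sim.build_shattered_chromosome(g, "c", plan, seed=1)
        j = truth.junctions.iloc[0]
        # head-to-head join: both anchors retain their upstream side
        assert bool(j.inverted)
        assert j.side_left == j.side_right

    def test_guards_make_realized_chemistry_equal_recorded(self, small_plant):
        """Guard bases pin the realized maximal overlap/gap to the recorded
        chemistry (no chance flank extensions); junctions whose flank edits
        conflicted are downgraded to insertions and flagged as such."""
        j = small_plant.truth.junctions
        assert (j.f_ext == 0).all() and (j.r_ext == 0).all()
        assert (j.loc[j.downgraded, "type"] == "insertion").all()

    def test_reconstruction_oracle_rebuilds_derived_exactly(self, small_plant):
        plant = small_plant
        ref = plant.parent_a["chr1"]
        parts = []
        for i, e in plant.truth.entries.iterrows():
            seg = ref[e.start : e.end]
            if e.orientation == "-":
                seg = revcomp(seg)
            if i > 0:
                spec = plant.truth.junctions.iloc[i - 1]
                if spec["type"] == "microhomology":
                    seg = seg[int(spec.mh_len) :]
                elif spec["type"] == "insertion":
                    parts.append(spec.insertion_seq.encode())
            parts.append(seg)
        assert b"".join(parts) == plant.derived

    def test_flank_edits_keep_snp_table_exact(self, small_plant):
        plant = small_plant
        assert len(plant.truth.edits) > 0  # microhomology planting edits flanks
        diffs = _seq_diff_positions(plant.parent_a, plant.parent_b)
        assert diffs == set(zip(plant.snps.chrom, plant.snps.pos))

    def test_block_outside_chromosome_rejected(self):
        g = _toy_genome()
        plan = sim.BlockPlan(
            entries=[sim.Block("c", 100, 5_000, "+", 2)], junctions=[]
        )
        with pytest.raises(ParameterError):
            sim.build_shattered_chromosome(g, "c", plan)

    def test_random_plan_copy_states_consistent(self):
        pa, _, _ = sim.make_parental_genomes(1, 150_000, 1e-3, seed=2)
        plan = sim.random_plan(pa, "chr1", n_junctions=10, seed=4)
        assert len(plan.entries) == 11
        assert len(plan.junctions) == 10
        occ = {}
        for e in plan.entries:
            occ[(e.start, e.end)] = occ.get((e.start, e.end), 0) + 1
        for iv in plan.intervals:
            assert occ.get((iv.start, iv.end), 0) == iv.state - 1
        # intervals are disjoint in the source
        ivs = sorted((iv.start, iv.end) for iv in plan.intervals)
        assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))


class TestReadSimulation:
    @staticmethod
    def _depth_profile(reads, genome, chrom, read_len):
        """Depth from exact read placement (error-free reads, both strands)."""
        seq = genome[chrom]
        depth = np.zeros(len(seq) + 1, dtype=np.int64)
        for s in reads.sequences:
            p = seq.find(s)
            if p == -1:
                p = seq.find(revcomp(s))
            if p != -1:
                depth[p] += 1
                depth[p + read_len] -= 1
        return np.cumsum(depth)[:-1]

    def test_diploid_nucleus_depth_near_requested_coverage(self):
        pa, _, _ = sim.make_parental_genomes(1, 20_000, 1e-3, seed=5)
        reads = sim.simulate_reads(
            [(pa, 2)], coverage=50, read_len=50, paired=False, seed=8
        )
        depth = self._depth_profile(reads, pa, "chr1", 50)
        interior = depth[100:-100]
        assert abs(interior.mean() - 50) < 1.0

    def test_copy3_block_depth_ratio(self):
        pa, _, _ = sim.make_parental_genomes(1, 30_000, 1e-3, seed=5)
        frag = {"chr1_frag": pa["chr1"][10_000:20_000]}
        reads = sim.simulate_reads(
            [(pa, 2), (frag, 1)], coverage=60, read_len=50, paired=False, seed=8
        )
        depth = self._depth_profile(reads, pa, "chr1", 50)
        background = np.concatenate([depth[500:9_500], depth[20_500:29_500]]).mean()
        block = depth[10_500:19_500].mean()
        assert block / background == pytest.approx(1.5, rel=0.05)

    def test_fixed_seed_byte_identical_fastq(self, tmp_path):
        pa, pb, _ = sim.make_parental_genomes(1, 15_000, 1e-3, seed=5)
        paths = []
        for k in range(2):
            r = sim.simulate_reads([(pa, 1), (pb, 1)], 10, read_len=50, paired=True,
                                   insert_mean=200, insert_sd=20, seed=33)
            p = tmp_path / f"r{k}.fastq"
            r.to_fastq(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_read_longer_than_sequence_rejected(self):
        g = Genome({"c": b"ACGT" * 20})
        with pytest.raises(ParameterError):
            sim.simulate_reads([(g, 1)], 10, read_len=100, paired=False)

    def test_depth_linear_in_copy_state(self, small_study):
        """Mean mapped depth per truth block is proportional to copy state."""
        study = small_study
        aln = study.aln["shattered"]
        cid = aln.chrom_names.index("chr1")
        starts = np.sort(aln.start[aln.chrom_id == cid])
        xs, ys = [], []
        for b in study.plant.truth.dosage_truth(100_000).itertuples():
            if b.end - b.start < 3_000:
                continue
            # interior only, away from block-edge effects
            lo, hi = b.start + 500, b.end - 500
            n = np.searchsorted(starts, hi) - np.searchsorted(starts, lo)
            xs.append(b.state)
            ys.append(n / (hi - lo))
        xs, ys = np.array(xs, float), np.array(ys)
        slope = (xs * ys).sum() / (xs * xs).sum()
        r2 = 1 - ((ys - slope * xs) ** 2).sum() / ((ys - ys.mean()) ** 2).sum()
        assert r2 > 0.99


class TestAnnotations:
    def test_chromatin_states_partition_genome(self):
        g = Genome({"c": b"ACGT" * 25_000})
        features, genes = sim.simulate_annotations(g, seed=3)
        total = 0
        covered = np.zeros(100_000, dtype=int)
        for st in range(1, 10):
            for s, e in features[f"chromatin_state_{st}"]["c"]:
                covered[s:e] += 1
                total += e - s
        assert total == 100_000
        assert covered.min() == 1 and covered.max() == 1

    def test_gene_track_strands_and_coverage(self):
        g = Genome({"c": b"ACGT" * 25_000})
        features, genes = sim.simulate_annotations(g, seed=3)
        ivs = features["gene"]["c"]
        frac = (ivs[:, 1] - ivs[:, 0]).sum() / 100_000
        assert 0.3 < frac < 0.7
        assert set(genes.strand) <= {"+", "-"}
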