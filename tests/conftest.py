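"""Shared fixtures: a small simulated hybrid study reused across modules.

Everything is generated at test time from fixed seeds; no data files ship
with the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from shatterscan import dosage as dos
from shatterscan import mapping as mp
from shatterscan import simulate as sim
from shatterscan import snp as snpmod


@dataclass
class SmallStudy:
    """A 2-chromosome, 100 kb hybrid with one shattered chr1 (8 junctions)."""

    plant: sim.ShatteredPlant
    reference: "object"
    index: mp.GenomeIndex
    reads: dict[str, object]
    aln: dict[str, mp.AlignmentSet]
    pileups: dict[str, mp.Pileup]
    snps_found: "object"
    segments: "object"  # 500 bp segmentation of the shattered sample


@pytest.fixture(scope="session")
def small_parents():
    return sim.make_parental_genomes(2, 100_000, 1e-3, seed=7)


@pytest.fixture(scope="session")
def small_plant(small_parents):
    pa, pb, snps = small_parents
    plan = sim.random_plan(pa, "chr1", n_junctions=8, seed=3)
    return sim.plant_shattered(pa, pb, snps, "chr1", plan, seed=5)


@pytest.fixture(scope="session")
def small_study(small_plant) -> SmallStudy:
    plant = small_plant
    pa, pb = plant.parent_a, plant.parent_b
    index = mp.GenomeIndex(pa, 20)
    nuclei = {
        "control": (sim.hybrid_nucleus(pa, pb), 50.0),
        "shattered": (sim.shattered_nucleus(plant), 50.0),
        "parent_a": ([(pa, 2)], 15.0),
        "parent_b": ([(pb, 2)], 8.0),
    }
    reads, aln = {}, {}
    for k, (name, (nucleus, cov)) in enumerate(nuclei.items()):
        r = sim.simulate_reads(
            nucleus, cov, read_len=100, paired=True,
            insert_mean=300, insert_sd=50, seed=11 + k,
        )
        reads[name] = r
        aln[name] = mp.map_reads(index, r, max_mismatches=5)
    pileups = {
        "hybrid": mp.build_pileup(aln["control"], reads["control"], pa),
        "parent_a": mp.build_pileup(aln["parent_a"], reads["parent_a"], pa),
        "parent_b": mp.build_pileup(aln["parent_b"], reads["parent_b"], pa),
    }
    snps_found = snpmod.identify_snps(
        pileups["hybrid"], pileups["parent_a"], pileups["parent_b"]
    )
    sample_bins = dos.bin_counts(aln["shattered"], pa, 500)
    control_bins = dos.bin_counts(aln["control"], pa, 500)
    profile = dos.relative_dosage(sample_bins, reference=control_bins, sample_id="shattered")
    segments = dos.segment_profile(profile, min_run=4, smooth_window=7)
    return SmallStudy(
        plant=plant,
        reference=pa,
        index=index,
        reads=reads,
        aln=aln,
        pileups=pileups,
        snps_found=snps_found,
        segments=segments,
    )
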