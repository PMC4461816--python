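"""End-to-end orchestration: simulate -> map -> dosage -> SNP -> junctions ->
enrichment -> cohort stats, as one reproducible, seeded run.

The run simulates a small genome-elimination study: a diploid hybrid control,
parental libraries, one individual carrying a planted shattered chromosome
(replacement model) and optionally a primary trisomic and a truncated
trisomic.  Every stage derives its random seed from the single run seed, so
rerunning a config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dosage as dos
from . import enrichment as enr
from . import junctions as jnc
from . import mapping as mp
from . import simulate as sim
from . import snp as snpmod
from .cohort import (
    contingency_test,
    lig4_haploid_table,
    micronuclei_table,
    tally_cohort,
)
from .core import Genome, ParameterError
from .snp import SnpThresholds

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

log = logging.getLogger("shatterscan")


@dataclass
class RunConfig:
    """All pipeline parameters in one flat, serializable record.

    Analysis constants default to the published protocol: 100,000 bp dosage
    bins with the diploid background set at 2; SNP thresholds of >=25x
    hybrid depth, >=40% allele fraction, >=97% parental homozygosity,
    >=6x/>=1x parental depth; 1 Mb parentage bins; 500 bp breakpoint bins;
    2000 bp read-extraction radius; the 2-15 bp microhomology band; 1000 bp
    and 10,000 bp enrichment windows with 1000 shuffles.
    """

    seed: int = 1
    # synthetic genome
    n_chrom: int = 5
    chrom_len: int = 300_000
    snp_rate: float = 1e-3
    source_chrom: str = "chr3"
    n_junctions: int = 20
    min_block: int = 6_000
    max_block: int = 15_000
    gap_min: int = 3_500
    # reads
    coverage: float = 50.0
    extra_coverage: float = 30.0
    parent_a_coverage: float = 15.0
    parent_b_coverage: float = 8.0
    read_len: int = 100
    paired: bool = True
    insert_mean: int = 300
    insert_sd: int = 50
    error_rate: float = 0.0
    include_numerical: bool = True
    include_truncated: bool = True
    numerical_chrom: str = "chr2"
    truncated_chrom: str = "chr4"
    truncated_break_frac: float = 0.6
    # read processing / mapping
    quality_threshold: int = 20
    min_read_len: int = 30
    seed_len: int = 20
    max_mismatches: int = 5
    # dosage
    dosage_bin: int = 100_000
    breakpoint_bin: int = 500
    min_run: int = 4
    smooth_window: int = 11
    shatter_min: int = 5
    # SNP analysis
    hybrid_min_depth: int = 25
    min_allele_frac: float = 0.40
    parental_homozygosity: float = 0.97
    parent_a_min_depth: int = 6
    parent_b_min_depth: int = 1
    parentage_bin: int = 1_000_000
    # junctions
    radius: int = 2_000
    min_overlap: int = 31
    min_reads: int = 3
    min_anchor: int = 30
    mh_min: int = 2
    # enrichment
    windows: tuple[int, ...] = (1_000, 10_000)
    n_shuffles: int = 1_000
    # diagnostics
    keep_pileups: bool = False

    def validate(self) -> None:
        if self.n_shuffles < 100:
            raise ParameterError("n_shuffles must be >= 100")
        if self.coverage <= 0 or self.extra_coverage <= 0:
            raise ParameterError("coverage must be positive")
        if not 0 < self.snp_rate <= 0.05:
            raise ParameterError("snp_rate must lie in (0, 0.05]")
        if self.smooth_window % 2 == 0:
            raise ParameterError("smooth_window must be odd")
        if self.paired and self.insert_mean <= 2 * self.read_len:
            raise ParameterError("insert_mean must exceed 2 * read_len")
        if not 1 <= self.source_chrom_index + 1 <= self.n_chrom:
            raise ParameterError("source_chrom outside the simulated genome")

    @property
    def source_chrom_index(self) -> int:
        return int(self.source_chrom.removeprefix("chr")) - 1

    def snp_thresholds(self) -> SnpThresholds:
        return SnpThresholds(
            hybrid_min_depth=self.hybrid_min_depth,
            min_allele_frac=self.min_allele_frac,
            parental_homozygosity=self.parental_homozygosity,
            parent_a_min_depth=self.parent_a_min_depth,
            parent_b_min_depth=self.parent_b_min_depth,
        )

    def stage_seed(self, k: int) -> int:
        return (self.seed * 1_000_003 + k) % (2**31 - 1)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["windows"] = list(self.windows)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "windows" in data:
            data["windows"] = tuple(data["windows"])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(
            {**asdict(self), "windows": list(self.windows)}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    truth: sim.TruthSet
    snps_planted: pd.DataFrame
    snps_found: pd.DataFrame
    karyotype_calls: dict[str, dict]
    karyotype_truth: dict[str, dict[str, str]]
    segments_500: dict[str, pd.DataFrame]
    parentage: pd.DataFrame
    fraction_by_state: pd.DataFrame
    junctions: list
    junction_match: pd.DataFrame
    breakpoints: pd.DataFrame
    enrichment: pd.DataFrame
    cohort_outcomes: pd.DataFrame
    cohort_classes: pd.DataFrame
    printed_stats: dict
    out_dir: Path | None = None
    pileups: dict | None = None  # hybrid/parent_a/parent_b, when kept

    def karyotype_accuracy(self) -> float:
        total = correct = 0
        for sample, truth in self.karyotype_truth.items():
            calls = self.karyotype_calls[sample]
            for chrom, cls in truth.items():
                total += 1
                correct += int(calls[chrom].clazz == cls)
        return 100.0 * correct / total

    def junction_recovery(self) -> dict[str, float]:
        m = self.junction_match
        return {
            "n_truth": int(len(m)),
            "n_detected": int(len(self.junctions)),
            "recovered_pct": 100.0 * float(m.recovered.mean()),
            "exact_chemistry_pct": 100.0 * float(m.exact_chemistry.mean()),
        }

    def summary(self) -> dict:
        state2 = self.fraction_by_state[self.fraction_by_state.state == 2]
        return {
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "n_snps_planted": int(len(self.snps_planted)),
            "n_snps_found": int(len(self.snps_found)),
            "karyotype_accuracy_pct": self.karyotype_accuracy(),
            **{f"junction_{k}": v for k, v in self.junction_recovery().items()},
            "state2_pct_parent_a": float(state2.pct_a.iloc[0]) if len(state2) else np.nan,
            "micronuclei_fisher_p": self.printed_stats["micronuclei"].p_fisher,
            "lig4_fisher_p": self.printed_stats["lig4"].p_fisher,
        }


def _simulate_samples(cfg: RunConfig):
    """Plant the study: parents, SNPs, shattered plan, per-sample nuclei."""
    pa, pb, snps = sim.make_parental_genomes(
        cfg.n_chrom, cfg.chrom_len, cfg.snp_rate, cfg.stage_seed(1)
    )
    plan = sim.random_plan(
        pa,
        cfg.source_chrom,
        cfg.n_junctions,
        cfg.stage_seed(2),
        min_block=cfg.min_block,
        max_block=cfg.max_block,
        gap_min=cfg.gap_min,
        mh_range=(cfg.mh_min, 15),
    )
    plant = sim.plant_shattered(pa, pb, snps, cfg.source_chrom, plan, cfg.stage_seed(3))
    pa, pb, snps = plant.parent_a, plant.parent_b, plant.snps

    nuclei: dict[str, tuple[list, float]] = {
        "control": (sim.hybrid_nucleus(pa, pb), cfg.coverage),
        "shattered": (sim.shattered_nucleus(plant), cfg.coverage),
        "parent_a": ([(pa, 2)], cfg.parent_a_coverage),
        "parent_b": ([(pb, 2)], cfg.parent_b_coverage),
    }
    truth_classes: dict[str, dict[str, str]] = {
        "control": {c: "euploid" for c in pa.names},
        "shattered": dict(plant.truth.chrom_classes),
    }
    if cfg.include_numerical:
        nuclei["numerical"] = (
            sim.trisomic_nucleus(pa, pb, cfg.numerical_chrom),
            cfg.extra_coverage,
        )
        truth_classes["numerical"] = {
            c: ("numerical" if c == cfg.numerical_chrom else "euploid")
            for c in pa.names
        }
    if cfg.include_truncated:
        break_pos = int(cfg.truncated_break_frac * cfg.chrom_len)
        nuclei["truncated"] = (
            sim.truncated_nucleus(pa, pb, cfg.truncated_chrom, break_pos),
            cfg.extra_coverage,
        )
        truth_classes["truncated"] = {
            c: ("truncated" if c == cfg.truncated_chrom else "euploid")
            for c in pa.names
        }
    return pa, pb, snps, plant, nuclei, truth_classes


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute every stage on a fully simulated study; see class docs."""
    cfg.validate()
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    def stage(name: str) -> None:
        log.info("[%7.1fs] %s", time.time() - t0, name)

    stage("simulate genomes and samples")
    pa, pb, snps, plant, nuclei, truth_classes = _simulate_samples(cfg)
    reference = pa  # parent A is the haploid inducer and the mapping reference

    stage("map reads")
    index = mp.GenomeIndex(reference, cfg.seed_len)
    sample_reads: dict[str, object] = {}
    sample_aln: dict[str, mp.AlignmentSet] = {}
    for si, (name, (nucleus, coverage)) in enumerate(nuclei.items()):
        reads = sim.simulate_reads(
            nucleus,
            coverage,
            read_len=cfg.read_len,
            paired=cfg.paired,
            insert_mean=cfg.insert_mean,
            insert_sd=cfg.insert_sd,
            error_rate=cfg.error_rate,
            seed=cfg.stage_seed(10 + si),
        )
        reads = mp.filter_reads(reads, cfg.quality_threshold, cfg.min_read_len)
        sample_reads[name] = reads
        sample_aln[name] = mp.map_reads(
            index, reads, cfg.seed_len, max_mismatches=cfg.max_mismatches
        )
        log.info(
            "  %s: %d reads, %d uniquely mapped",
            name,
            len(reads),
            len(sample_aln[name]),
        )

    stage("SNP discovery")
    pile_hybrid = mp.build_pileup(sample_aln["control"], sample_reads["control"], reference)
    pile_a = mp.build_pileup(sample_aln["parent_a"], sample_reads["parent_a"], reference)
    pile_b = mp.build_pileup(sample_aln["parent_b"], sample_reads["parent_b"], reference)
    snps_found = snpmod.identify_snps(pile_hybrid, pile_a, pile_b, cfg.snp_thresholds())

    stage("dosage, segmentation and karyotypes")
    control_100k = dos.bin_counts(sample_aln["control"], reference, cfg.dosage_bin)
    control_500 = dos.bin_counts(sample_aln["control"], reference, cfg.breakpoint_bin)
    karyotype_calls: dict[str, dict] = {}
    segments_500: dict[str, pd.DataFrame] = {}
    analysis_samples = [s for s in nuclei if not s.startswith("parent_")]
    for name in analysis_samples:
        prof_100k = dos.relative_dosage(
            dos.bin_counts(sample_aln[name], reference, cfg.dosage_bin),
            reference=control_100k,
            sample_id=name,
        )
        prof_500 = dos.relative_dosage(
            dos.bin_counts(sample_aln[name], reference, cfg.breakpoint_bin),
            reference=control_500,
            sample_id=name,
        )
        segments_500[name] = dos.segment_profile(
            prof_500, min_run=cfg.min_run, smooth_window=cfg.smooth_window
        )
        karyotype_calls[name] = dos.classify_karyotype(
            segments_500[name], shatter_min=cfg.shatter_min
        )
        if out is not None:
            prof_100k.write_tsv(out / f"dosage_{cfg.dosage_bin}_{name}.tsv")
            segments_500[name].to_csv(
                out / f"segments_{name}.tsv", sep="\t", index=False
            )

    stage("parental assignment")
    calls = snpmod.assign_reads(
        sample_aln["shattered"], sample_reads["shattered"], snps_found
    )
    parentage = snpmod.bin_parentage(calls, reference.lengths, cfg.parentage_bin)
    by_state = snpmod.parent_fraction_by_state(calls, segments_500["shattered"])
    control_calls = snpmod.assign_reads(
        sample_aln["control"], sample_reads["control"], snps_found
    )
    control_parentage = snpmod.bin_parentage(
        control_calls, reference.lengths, cfg.parentage_bin
    )

    stage("junction assembly")
    breakpoints = jnc.detect_breakpoints(segments_500["shattered"])
    source_bp = breakpoints[breakpoints.chrom == cfg.source_chrom]
    junctions = jnc.junctions_from_breakpoints(
        sample_aln["shattered"],
        sample_reads["shattered"],
        reference,
        source_bp,
        radius=cfg.radius,
        insert_mean=cfg.insert_mean,
        insert_sd=cfg.insert_sd,
        min_overlap=cfg.min_overlap,
        min_reads=cfg.min_reads,
        min_anchor=cfg.min_anchor,
    )
    junction_match = jnc.match_junctions(
        jnc.junctions_to_frame(junctions), plant.truth.junctions
    )

    stage("feature enrichment")
    features, genes = sim.simulate_annotations(reference, cfg.stage_seed(40))
    chrom_len = len(reference[cfg.source_chrom])
    enr_rows = []
    bp_classes = {
        "duplicated": source_bp[
            (source_bp.left_state == 3) | (source_bp.right_state == 3)
        ].pos.to_numpy(),
        "triplicated": source_bp[
            (source_bp.left_state == 4) | (source_bp.right_state == 4)
        ].pos.to_numpy(),
    }
    for cls_name in ("gene", "transposon", "satellite", "replication_origin", "dhs"):
        ivs = features[cls_name].get(cfg.source_chrom, np.empty((0, 2), dtype=np.int64))
        for bp_cls, bp_pos in bp_classes.items():
            if len(bp_pos) == 0:
                continue
            for k, window in enumerate(cfg.windows):
                res = enr.permutation_p(
                    bp_pos,
                    ivs,
                    window,
                    chrom_len,
                    n_shuffles=cfg.n_shuffles,
                    seed=cfg.stage_seed(50 + k),
                    feature_class=cls_name,
                    breakpoint_class=bp_cls,
                )
                enr_rows.append(res.to_row())
    enrichment = pd.DataFrame(enr_rows)

    stage("cohort statistics")
    genome_pct = {
        name: float(
            100.0
            * (c := (parentage if name == "shattered" else control_parentage)).n_a.sum()
            / max(c.n_a.sum() + c.n_b.sum(), 1)
        )
        for name in ("shattered", "control")
    }
    outcomes, classes = tally_cohort(
        karyotype_calls,
        {name: genome_pct.get(name, 50.0) for name in karyotype_calls},
    )
    printed_stats = {
        "micronuclei": contingency_test(micronuclei_table()),
        "lig4": contingency_test(lig4_haploid_table()),
    }

    result = RunResult(
        config=cfg,
        truth=plant.truth,
        snps_planted=snps,
        snps_found=snps_found,
        karyotype_calls=karyotype_calls,
        karyotype_truth=truth_classes,
        segments_500=segments_500,
        parentage=parentage,
        fraction_by_state=by_state,
        junctions=junctions,
        junction_match=junction_match,
        breakpoints=breakpoints,
        enrichment=enrichment,
        cohort_outcomes=outcomes,
        cohort_classes=classes,
        printed_stats=printed_stats,
        out_dir=out,
        pileups=(
            {"hybrid": pile_hybrid, "parent_a": pile_a, "parent_b": pile_b}
            if cfg.keep_pileups
            else None
        ),
    )
    if out is not None:
        stage("write outputs")
        plant.truth.write(out)
        snpmod.write_snp_table(snps_found, out / "snps_found.tsv")
        parentage.to_csv(out / "parentage_1mb.tsv", sep="\t", index=False)
        by_state.to_csv(out / "parent_fraction_by_state.tsv", sep="\t", index=False)
        jnc.junctions_to_frame(junctions).to_csv(
            out / "junctions.tsv", sep="\t", index=False
        )
        breakpoints.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        outcomes.to_csv(out / "cohort_outcomes.tsv", sep="\t", index=False)
        classes.to_csv(out / "cohort_classes.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(result.summary(), fh, indent=2, default=float)
    stage("done")
    return result
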