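"""End-to-end orchestration of the synthetic parentage study.

``run_scenario`` reproduces the whole design from one config and seed:
simulate the open-pollinated population, screen the candidate-parent VCF
for focal-father-specific SNPs, build the marker panel and
mini-reference, simulate pooled barcoded amplicon reads, demultiplex /
align / call, assign parentage by the presence rule, and validate the
assignments genome-wide with method-of-moments IBD.  Every stage writes
its artifact in a standard text format, and a truth-comparison summary
scores the result against the simulator's pedigree.

A single global seed is fanned out to per-stage seeds by a fixed
derivation, so each stage is independently reproducible and the whole
run is byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import amplicon, ibd, io_utils, parentage, popsim, snp_select
from .genotypes import HET, GenotypeMatrix, PedigreeTruth

logger = logging.getLogger("sibtrace")


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class ScenarioConfig:
    """All tunable parameters of the synthetic study, serialisable to YAML.

    Defaults mirror the emulated design: 1 mother, 150 candidate
    fathers, 332 open-pollinated offspring, a 10-site one-per-chromosome
    panel excluding chr1/chr7, Q30 paired 150 bp reads at ~2300x mean
    depth per site.
    """

    seed: int = 0
    # population
    n_fathers: int = 150
    n_offspring: int = 332
    chrom_names: list[str] = field(default_factory=lambda: [f"chr{i}" for i in range(1, 13)])
    chrom_length: int = 60000
    sites_per_chrom: int = 420
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    focal_father: str = "father_039"
    focal_father_weight: float = 0.37
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    # panel
    n_panel_sites: int = 10
    excluded_chroms: list[str] = field(default_factory=lambda: ["chr1", "chr7"])
    select_mode: str = "strict"
    # sequencing
    depth_mean: float = 2300.0
    read_length: int = 150
    quality_q: float | None = 30.0
    compress_reads: bool = True
    # calling / assignment thresholds
    min_depth: int = 100
    het_band: tuple[float, float] = (0.2, 0.8)
    min_het_sites: int = 1
    # IBD validation
    ibd_low: float = ibd.FIRST_DEGREE_LOW
    ibd_high: float = ibd.FIRST_DEGREE_HIGH
    ibd_min_sites: int = 200
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        self.allele_freq_range = tuple(self.allele_freq_range)  # type: ignore[assignment]
        self.het_band = tuple(self.het_band)  # type: ignore[assignment]
        if self.n_offspring < 0 or self.n_panel_sites < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_fathers < 2:
            raise ValueError("n_fathers must be >= 2")
        if not (0 <= self.focal_father_weight <= 1):
            raise ValueError("focal_father_weight must be in [0, 1]")
        if self.select_mode not in ("strict", "literal", "paper_literal"):
            raise ValueError(f"unknown select_mode {self.select_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["allele_freq_range"] = list(self.allele_freq_range)
        data["het_band"] = list(self.het_band)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    outdir: Path
    paths: dict[str, Path]
    truth: PedigreeTruth
    panel: snp_select.Panel
    summary: dict[str, Any]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _father_weights(config: ScenarioConfig, fathers: list[str]) -> dict[str, float]:
    others = [f for f in fathers if f != config.focal_father]
    w = config.focal_father_weight
    rest = (1.0 - w) / len(others) if others else 0.0
    weights = {f: rest for f in others}
    weights[config.focal_father] = w
    return weights


def run_scenario(config: ScenarioConfig, outdir: str | Path) -> ScenarioResult:
    """Run every stage end to end; see the module docstring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "config"
    try:
        paths["config"] = outdir / "scenario.yaml"
        config.to_yaml(paths["config"])

        # -- population simulation -------------------------------------
        stage = "simulate"
        genome = popsim.simulate_genome(
            config.chrom_names, config.chrom_length, seed=stage_seed(config.seed, 0)
        )
        founders, freq_table = popsim.simulate_founders(
            config.n_fathers,
            config.chrom_names,
            config.sites_per_chrom,
            allele_freq_range=config.allele_freq_range,
            seed=stage_seed(config.seed, 1),
            genome=genome,
        )
        founders, truth = popsim.plant_specific_sites(
            founders,
            config.focal_father,
            config.n_panel_sites,
            excluded_chroms=config.excluded_chroms,
            seed=stage_seed(config.seed, 2),
            genome=genome,
            mother=founders.samples[0],
        )
        mother = truth.mother or founders.samples[0]
        fathers = [s for s in founders.samples if s != mother]
        offspring, off_truth = popsim.simulate_offspring(
            founders,
            mother,
            _father_weights(config, fathers),
            config.n_offspring,
            seed=stage_seed(config.seed, 3),
        )
        truth = truth.merged_with(off_truth)
        truth.focal_father = config.focal_father

        # the "resequencing" view of the offspring: truth plus optional
        # genotyping error and missingness
        reseq = popsim.apply_genotyping_error(
            offspring, config.genotyping_error_rate, seed=stage_seed(config.seed, 4)
        )
        reseq = popsim.apply_missingness(
            reseq, config.missing_rate, seed=stage_seed(config.seed, 5)
        )

        # candidate-parent VCF carries the focal father as two replicates
        replicates = [f"{config.focal_father}A", f"{config.focal_father}B"]
        selection_matrix = founders.with_replicates(config.focal_father, replicates)

        paths["genome"] = outdir / "genome.fasta"
        io_utils.write_fasta(genome, paths["genome"])
        paths["founders_vcf"] = outdir / "founders.vcf"
        io_utils.write_vcf(selection_matrix, paths["founders_vcf"])
        paths["offspring_vcf"] = outdir / "offspring.vcf"
        io_utils.write_vcf(reseq, paths["offspring_vcf"])
        paths["truth"] = outdir / "truth.tsv"
        popsim.write_truth(truth, paths["truth"])
        paths["freqs"] = outdir / "founder_freqs.tsv"
        freq_table.to_csv(paths["freqs"], sep="\t", index=False, float_format="%.6f")

        # -- marker selection -------------------------------------------
        stage = "select"
        candidates = snp_select.select_specific_sites(
            selection_matrix, replicates, mode=config.select_mode
        )
        panel = snp_select.build_panel(
            candidates,
            config.n_panel_sites,
            per_chrom_limit=1,
            excluded_chroms=config.excluded_chroms,
            target_label=config.focal_father,
        ) if config.n_panel_sites else snp_select.Panel([], config.focal_father)
        paths["panel"] = outdir / "panel.tsv"
        paths["panel_meta"] = outdir / "panel.yaml"
        snp_select.write_panel(panel, paths["panel"], paths["panel_meta"])
        logger.info(
            "select: mode=%s candidates=%d panel=%d", config.select_mode,
            len(candidates), len(panel),
        )

        # -- mini-reference ---------------------------------------------
        stage = "mkref"
        miniref = amplicon.build_mini_reference(genome, panel)
        paths["miniref"] = outdir / "miniref.fasta"
        paths["miniref_map"] = outdir / "miniref_map.tsv"
        miniref.write(paths["miniref"], paths["miniref_map"])

        # -- read simulation --------------------------------------------
        stage = "simreads"
        scheme = amplicon.BarcodeScheme.combinatorial(offspring.samples)
        paths["scheme"] = outdir / "barcode_scheme.tsv"
        scheme.write_tsv(paths["scheme"])
        ext = ".fastq.gz" if config.compress_reads else ".fastq"
        paths["r1"] = outdir / f"reads_R1{ext}"
        paths["r2"] = outdir / f"reads_R2{ext}"
        panel_truth = offspring.restrict_to_sites(panel.sites) if len(panel) else None
        if panel_truth is not None and offspring.n_samples:
            reads = amplicon.generate_reads(
                genome,
                panel,
                scheme,
                panel_truth,
                depth_mean=config.depth_mean,
                read_length=config.read_length,
                quality_q=config.quality_q,
                seed=stage_seed(config.seed, 6),
            )
            n_pairs = io_utils.write_fastq_pair(reads, paths["r1"], paths["r2"])
        else:
            n_pairs = io_utils.write_fastq_pair([], paths["r1"], paths["r2"])

        # -- demultiplex + align + call (streamed) ----------------------
        stage = "call"
        demux_counts: dict[str, int] = {s: 0 for s in scheme.samples}
        n_unassigned = 0

        def _counted():
            nonlocal n_unassigned
            pair_iter = io_utils.read_fastq_pair(paths["r1"], paths["r2"])
            for sample, pair in amplicon.iter_demultiplex(pair_iter, scheme):
                if sample is None:
                    n_unassigned += 1
                else:
                    demux_counts[sample] += 1
                yield sample, pair

        pileups, n_discarded = amplicon.trim_and_align(_counted(), miniref)
        paths["demux_counts"] = outdir / "demux_counts.tsv"
        with open(paths["demux_counts"], "w") as fh:
            fh.write("sample\tn_pairs\n")
            for s in scheme.samples:
                fh.write(f"{s}\t{demux_counts[s]}\n")
            fh.write(f"__unassigned__\t{n_unassigned}\n")

        calls = amplicon.call_all_genotypes(
            pileups, miniref, offspring.samples,
            min_depth=config.min_depth, het_band=config.het_band,
        )
        paths["calls"] = outdir / "calls.tsv"
        amplicon.write_calls_tsv(calls, paths["calls"])
        logger.info(
            "call: pairs=%d unassigned=%d discarded_reads=%d min_depth=%d het_band=%s",
            n_pairs, n_unassigned, n_discarded, config.min_depth, config.het_band,
        )

        # -- parentage ---------------------------------------------------
        stage = "assign"
        panel_calls = parentage.panel_calls_from_genotype_calls(calls)
        for s in offspring.samples:
            panel_calls.setdefault(s, {})
        assignments = parentage.assign_parentage(
            panel_calls, panel, min_het_sites=config.min_het_sites
        ) if len(panel) else []
        paths["parentage"] = outdir / "parentage.tsv"
        parentage.write_parentage_tsv(assignments, paths["parentage"])

        # -- IBD validation (on the resequencing genotypes) --------------
        stage = "ibd"
        founder_freqs = ibd.allele_frequencies(founders)
        combined = GenotypeMatrix(
            founders.samples + reseq.samples,
            founders.sites,
            np.concatenate([founders.calls, reseq.calls], axis=0)
            if reseq.n_samples
            else founders.calls,
        )
        pairs = [(o, config.focal_father) for o in reseq.samples]
        ibd_table = ibd.pairwise_ibd(
            combined, pairs, founder_freqs,
            min_maf=config.min_maf, min_sites=config.ibd_min_sites,
            low=config.ibd_low, high=config.ibd_high,
        )
        paths["ibd"] = outdir / "ibd.tsv"
        ibd.write_ibd_tsv(ibd_table, paths["ibd"])

        # -- truth comparison --------------------------------------------
        stage = "summary"
        summary = _summarise(config, truth, offspring, panel, assignments, ibd_table)
        summary["n_read_pairs"] = n_pairs
        summary["n_unassigned_pairs"] = n_unassigned
        summary["n_discarded_reads"] = n_discarded
        summary["thresholds"] = {
            "select_mode": config.select_mode,
            "min_depth": config.min_depth,
            "het_band": list(config.het_band),
            "min_het_sites": config.min_het_sites,
            "ibd_window": [config.ibd_low, config.ibd_high],
        }
        paths["summary"] = outdir / "summary.json"
        with open(paths["summary"], "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    return ScenarioResult(config, outdir, paths, truth, panel, summary)


def _summarise(
    config: ScenarioConfig,
    truth: PedigreeTruth,
    offspring: GenotypeMatrix,
    panel: snp_select.Panel,
    assignments: list[parentage.ParentageCall],
    ibd_table,
) -> dict[str, Any]:
    true_focal = truth.true_focal_offspring()
    # offspring that actually inherited >= min_het_sites private alleles
    # (pre-error truth): the detectable subset under the presence rule
    detectable: set[str] = set()
    if len(panel) and offspring.n_samples:
        panel_truth = offspring.restrict_to_sites(panel.sites)
        n_het = (panel_truth.calls == HET).sum(axis=1)
        detectable = {
            s for s, n in zip(panel_truth.samples, n_het)
            if s in true_focal and n >= config.min_het_sites
        }
    assigned = {a.sample for a in assignments if a.is_focal_offspring}
    indeterminate = {a.sample for a in assignments if a.indeterminate}
    non_focal = set(offspring.samples) - true_focal

    tp = len(assigned & true_focal)
    fp = len(assigned & non_focal)
    fn_detectable = len(detectable - assigned)
    sensitivity = tp / len(true_focal) if true_focal else float("nan")
    sensitivity_detectable = (
        len(assigned & detectable) / len(detectable) if detectable else float("nan")
    )
    specificity = (
        1.0 - fp / len(non_focal) if non_focal else float("nan")
    )

    concordant = float("nan")
    if len(ibd_table) and assigned:
        sub = ibd_table[ibd_table["sample_a"].isin(assigned)]
        if len(sub):
            concordant = float(sub["first_degree"].mean())

    return {
        "panel_size": len(panel),
        "n_offspring": offspring.n_samples,
        "n_true_focal": len(true_focal),
        "n_detectable_focal": len(detectable),
        "n_assigned_focal": len(assigned),
        "n_indeterminate": len(indeterminate),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives_detectable": fn_detectable,
        "sensitivity": sensitivity,
        "sensitivity_detectable": sensitivity_detectable,
        "specificity": specificity,
        "ibd_first_degree_concordance": concordant,
        "detection_power_closed_form": parentage.detection_power(
            len(panel), 0.5, 0.0, config.min_het_sites
        ),
    }
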