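"""End-to-end pipeline orchestration with one declarative configuration.

Stages run in workflow order — simulate → filter → design → diversity →
map — and every stage's inputs and outputs are files in standard formats
(VCF, FASTA, BED, TSV, Newick), so any stage can be toggled off and rerun
later against the files already on disk.  Identical configuration and seed
produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from indelmark import io as iio
from indelmark import report as rpt
from indelmark.diversity import PanelDiversity
from indelmark.filtering import FilterCriteria, filter_indels, filter_snps, read_variants, summarize_genome
from indelmark.mapping import F2LinkageModel, detect_deletion
from indelmark.markers import (
    IndelMarker,
    PrimerConstraints,
    design_marker,
    markers_table,
    select_anchor_set,
    select_candidates,
)
from indelmark.simulate import (
    F2SimSpec,
    GenomeModel,
    SimulationConfig,
    inject_deletion,
    simulate_f2,
    simulate_panel,
    simulate_reference,
    simulate_variant_calls,
)

log = logging.getLogger("indelmark")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "indelmark_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_filter: bool = True
    run_design: bool = True
    run_diversity: bool = True
    run_map: bool = True
    render_report: bool = True
    # genome / simulation
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    gc: float = 0.35
    indel_rate: float = 5.2e-5
    snp_rate: float = 2.55e-4
    het_fraction: float = 43 / 49276
    unanchored_fraction: float = 620 / 49276
    # filtering
    min_depth: int = 5
    min_mapping_quality: float = 20.0
    min_indel_length: int = 5
    # marker design
    candidate_min_len: int = 5
    candidate_max_len: int = 50
    anchor_count: int = 30
    # panel
    n_cultivars: int = 14
    third_allele_rate: float = 14 / 165
    panel_missing_rate: float = 0.02
    # F2 mapping
    f2_plants: int = 511
    cm_per_mb: float = 2.5
    causal_chrom: str = "chr01"
    causal_fraction: float = 0.4  # causal position as a fraction of the chromosome
    deletion_length: int = 253_187

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def genome_model(self) -> GenomeModel:
        return GenomeModel.demo(self.n_chromosomes, self.chrom_length, gc=self.gc)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            indel_rate=self.indel_rate, snp_rate=self.snp_rate,
            het_fraction=self.het_fraction, unanchored_fraction=self.unanchored_fraction,
            seed=self.seed,
        )

    def filter_criteria(self) -> FilterCriteria:
        return FilterCriteria(
            min_depth=self.min_depth,
            min_mapping_quality=self.min_mapping_quality,
            min_indel_length=self.min_indel_length,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of stage results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = config.genome_model()
    results: dict = {"config": config}

    # --- simulate -----------------------------------------------------------
    if config.run_simulate:
        log.info("simulate: genome of %d chromosomes x %d bp", config.n_chromosomes, config.chrom_length)
        reference = simulate_reference(genome, seed=config.seed)
        sim = simulate_variant_calls(reference, config.simulation_config())
        iio.write_fasta(reference, out / "reference.fasta")
        iio.write_vcf(sim.calls, out / "variants.vcf", contig_lengths=genome.lengths)
        iio.write_bed(
            [(c, s, e) for c, (s, e) in genome.pericentromere.items()],
            out / "pericentromere.bed",
        )
        sim.ledger.to_csv(out / "ground_truth_ledger.tsv", sep="\t", index=False)
        log.info("simulate: %d calls emitted", len(sim.calls))

    # --- filter -------------------------------------------------------------
    filter_summary = None
    if config.run_filter:
        calls = read_variants(str(out / "variants.vcf"))
        peri = iio.read_bed(out / "pericentromere.bed")
        genome.pericentromere.update(peri)
        retained, filter_summary = filter_indels(calls, config.filter_criteria())
        snps = filter_snps(calls, config.filter_criteria())
        summarize_genome(retained, genome, filter_summary)
        iio.write_vcf(retained, out / "retained_indels.vcf", contig_lengths=genome.lengths)
        filter_summary.as_series().to_csv(out / "filter_summary.tsv", sep="\t", header=["value"])
        pd.Series(filter_summary.size_histogram, name="count").rename_axis("length").to_csv(
            out / "size_histogram.tsv", sep="\t"
        )
        filter_summary.window_counts.to_csv(out / "window_counts.tsv", sep="\t", index=False)
        log.info(
            "filter: %d detected -> %d retained INDELs, %d retained SNPs",
            filter_summary.total_detected, filter_summary.retained, len(snps),
        )
        results["filter_summary"] = filter_summary
        results["retained"] = retained
        results["snps"] = snps

    # --- design -------------------------------------------------------------
    anchors = []
    marker_df = None
    if config.run_design:
        reference = iio.read_fasta(out / "reference.fasta")
        retained = results.get("retained") or read_variants(str(out / "retained_indels.vcf"))
        candidates = select_candidates(retained, config.candidate_min_len, config.candidate_max_len)
        designed = []
        for i, call in enumerate(candidates, start=1):
            marker = design_marker(f"MK{i:04d}", reference[call.chrom], call)
            if isinstance(marker, IndelMarker):
                designed.append(marker)
        anchors = select_anchor_set(designed, genome, config.anchor_count)
        marker_df = markers_table(anchors)
        marker_df.to_csv(out / "markers.tsv", sep="\t", index=False)
        markers_table(designed).to_csv(out / "designed_markers.tsv", sep="\t", index=False)
        log.info("design: %d candidates -> %d designable -> %d anchors",
                 len(candidates), len(designed), len(anchors))
        results["markers"] = anchors
        results["designed_markers"] = designed

    # --- diversity ----------------------------------------------------------
    diversity_results = None
    if config.run_diversity:
        marker_df = marker_df if marker_df is not None else pd.read_csv(out / "markers.tsv", sep="\t")
        panel = simulate_panel(
            marker_df, n_cultivars=config.n_cultivars,
            third_allele_rate=config.third_allele_rate,
            missing_rate=config.panel_missing_rate, seed=config.seed,
        )
        iio.write_tsv(panel.genotypes, out / "panel_genotypes.tsv")
        diversity_results = PanelDiversity(panel.genotypes).fit()
        iio.write_tsv(diversity_results.polymorphism.to_table_layout(), out / "panel_pairwise.tsv")
        (out / "panel_upgma.nwk").write_text(diversity_results.dendrogram.newick() + "\n")
        log.info("diversity: %d markers x %d cultivars scored",
                 len(panel.genotypes), config.n_cultivars)
        results["diversity"] = diversity_results

    # --- map ----------------------------------------------------------------
    linkage_results = None
    deletion = None
    if config.run_map:
        marker_df = marker_df if marker_df is not None else pd.read_csv(out / "markers.tsv", sep="\t")
        designed_path = out / "designed_markers.tsv"
        designed_df = (
            markers_table(results["designed_markers"]) if "designed_markers" in results
            else (pd.read_csv(designed_path, sep="\t") if designed_path.exists() else marker_df)
        )
        causal_pos = int(genome.lengths[config.causal_chrom] * config.causal_fraction)
        # the mutant line carries a deletion spanning the causal locus
        del_start = max(1, causal_pos - config.deletion_length // 2)
        del_end = del_start + config.deletion_length

        def genotype_mutants(markers: pd.DataFrame, seed: int):
            spec = F2SimSpec(
                marker_map=markers[["marker_id", "chrom", "pos"]],
                causal_chrom=config.causal_chrom, causal_pos=causal_pos,
                chrom_lengths=dict(genome.lengths), cm_per_mb=config.cm_per_mb,
                n_plants=config.f2_plants, seed=seed,
            )
            scenario = simulate_f2(spec)
            scenario, _ = inject_deletion(scenario, config.causal_chrom, del_start, del_end)
            return scenario

        # pass 1: preliminary scan with the genome-wide anchor set
        scenario = genotype_mutants(marker_df, config.seed)
        iio.write_tsv(scenario.table(), out / "f2_population.tsv")
        marker_df[["marker_id", "chrom", "pos"]].to_csv(out / "f2_marker_map.tsv", sep="\t", index=False)
        preliminary = F2LinkageModel(scenario.table(), scenario.marker_map).fit()
        interval0 = preliminary.interval
        log.info("map: preliminary interval %s", interval0.summary())

        # pass 2: densify the preliminary interval with fine-scale markers
        lo = interval0.left_pos if not interval0.open_left else 1
        hi = interval0.right_pos if not interval0.open_right else genome.lengths[config.causal_chrom]
        on_chrom = designed_df[designed_df["chrom"] == config.causal_chrom]
        fine = on_chrom[(on_chrom["pos"] >= lo) & (on_chrom["pos"] <= hi)]
        marker_map2 = (
            pd.concat([marker_df, fine])[["marker_id", "chrom", "pos", "footprint_start", "footprint_end"]]
            .drop_duplicates("marker_id")
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )
        scenario2 = genotype_mutants(marker_map2, config.seed + 1)
        linkage_results = F2LinkageModel(scenario2.table(), scenario2.marker_map).fit()
        iio.write_tsv(scenario2.table(), out / "f2_population_fine.tsv")

        # amplification-failure pattern over the mutant class -> deletion candidate
        mutants = scenario2.table().query("phenotype == 'mutant'")
        scan_chrom = linkage_results.scan[linkage_results.scan["chrom"] == config.causal_chrom]
        fail_df = scan_chrom[["marker_id", "chrom", "pos"]].copy()
        fail_df["failed"] = [bool(mutants[m].isna().all()) for m in fail_df["marker_id"]]
        fail_df.to_csv(out / "amplification_failures.tsv", sep="\t", index=False)
        deletion = detect_deletion(fail_df, boundaries=(del_start, del_end))
        (out / "mapping_report.txt").write_text(
            "Preliminary (anchor) interval: " + interval0.summary() + "\n\n"
            + linkage_results.summary()
            + "\n\n"
            + (deletion.summary() if deletion is not None else "no deletion candidate")
            + "\n"
        )
        linkage_results.scan.to_csv(out / "linkage_scan.tsv", sep="\t", index=False)
        log.info("map: fine interval %s", linkage_results.interval.summary())
        results["preliminary_interval"] = interval0
        results["linkage"] = linkage_results
        results["deletion"] = deletion
        results["true_locus"] = (config.causal_chrom, causal_pos)

    # --- report -------------------------------------------------------------
    if config.render_report:
        if filter_summary is not None and filter_summary.window_counts is not None:
            rpt.plot_window_counts(filter_summary.window_counts, out / "fig_window_counts.png")
            rpt.plot_size_histogram(filter_summary.size_histogram, out / "fig_size_histogram.png")
        if diversity_results is not None:
            rpt.plot_dendrogram(diversity_results, out / "fig_dendrogram.png")
        if linkage_results is not None:
            rpt.plot_mapping(linkage_results, out / "fig_mapping.png")
        results["report"] = rpt.render_text_report(
            out, filter_summary=filter_summary,
            diversity_results=diversity_results, linkage_results=linkage_results,
        )
    return results
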