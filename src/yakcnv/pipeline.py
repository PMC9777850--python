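"""End-to-end pipeline: simulate -> call -> merge -> annotate -> compare ->
enrich -> qPCR-validate, with every stage's before/after counts logged.

The pipeline operates per group: each group's calls are merged into CNVRs
and frequency-filtered independently, the two retained gene sets are
compared, and the differential set is tested for term enrichment.  A qPCR
validation round re-estimates copy numbers at a panel of regions from
simulated Ct tables and reports concordance with the sequencing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io
from .annotation import AnnotatedCNVR, gene_set, overlap_genes, write_gff3
from .cnvr import CNVR, frequency_filter, merge_cnvrs
from .config import PipelineConfig
from .enrichment import EnrichmentRow, enrich, enrichment_table
from .group_compare import (
    DiffResult,
    GroupSummary,
    cnvr_density,
    combine_summaries,
    differential_genes,
    summarize_group,
    summary_table,
)
from .qpcr import concordance, delta_delta_ct, estimates_table
from .rd_caller import CNVCall, call_sample
from .synthetic import (
    SyntheticCohort,
    make_term_map,
    simulate_cohort,
    simulate_qpcr,
)

logger = logging.getLogger(__name__)

GROUP_A = "long_haired"
GROUP_B = "normal_haired"

@dataclass
class PipelineReport:
    """Everything the pipeline computed, plus where it was written."""

    config: PipelineConfig
    calls: dict[str, list[CNVCall]]  # group -> calls
    cnvrs: dict[str, list[CNVR]]  # group -> retained CNVRs
    annotated: dict[str, list[AnnotatedCNVR]]
    gene_sets: dict[str, set[str]]
    summaries: list[GroupSummary]
    diff: DiffResult
    enrichment: list[EnrichmentRow]
    qpcr: dict[str, object] | None
    stage_counts: dict[str, int] = field(default_factory=dict)
    out_dir: Path | None = None

def _sequencing_cn(
    calls: Sequence[CNVCall], sample_id: str, chrom: str, start: int, end: int
) -> int:
    """Sequencing-derived CN at a region for one sample (2 if no call)."""
    for c in calls:
        if (
            c.sample_id == sample_id
            and c.chrom == chrom
            and min(c.end, end) > max(c.start, start)
        ):
            return c.copy_number
    return 2

def run_pipeline(
    config: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> PipelineReport:
    """Run the whole analysis on a seeded synthetic cohort.

    Fixed seed implies a bit-identical report bundle.  Stage failures
    propagate with the stage named in the log.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: seed=%d", cfg.seed)
    cohort = simulate_cohort(
        seed=cfg.seed,
        n_per_group=cfg.n_per_group,
        n_chrom=cfg.n_chrom,
        chrom_length=cfg.chrom_length,
        n_genes=cfg.n_genes,
        n_shared=cfg.n_shared,
        n_group_a_only=cfg.n_group_a_only,
        n_intronic=cfg.n_intronic,
        n_intergenic=cfg.n_intergenic,
        mean_coverage=cfg.mean_coverage,
        bin_size=cfg.bin_size,
        gc_bias_strength=cfg.gc_bias_strength,
        dispersion=cfg.dispersion,
    )
    groups = {GROUP_A: cohort.truth.group_a, GROUP_B: cohort.truth.group_b}
    counts: dict[str, int] = {}

    # --- per-sample calling -------------------------------------------------
    params = cfg.caller_params()
    calls_by_group: dict[str, list[CNVCall]] = {}
    for gname, samples in groups.items():
        gcalls: list[CNVCall] = []
        for s in samples:
            gcalls.extend(call_sample(cohort.profiles[s], params))
        calls_by_group[gname] = gcalls
        counts[f"calls_{gname}"] = len(gcalls)
        logger.info("stage call [%s]: %d calls from %d samples",
                    gname, len(gcalls), len(samples))

    # --- CNVR merge + frequency filter (per group by default) ---------------
    cnvrs_by_group: dict[str, list[CNVR]] = {}
    if cfg.merge_across_groups:
        merged = merge_cnvrs([c for g in calls_by_group.values() for c in g])
        retained = frequency_filter(merged, cfg.min_samples)
        for gname in groups:
            cnvrs_by_group[gname] = [
                r for r in retained
                if any(s in groups[gname] for s in r.supporting_samples)
            ]
        counts["cnvrs_merged"] = len(merged)
        counts["cnvrs_retained"] = len(retained)
    else:
        for gname, gcalls in calls_by_group.items():
            merged = merge_cnvrs(gcalls)
            retained = frequency_filter(merged, cfg.min_samples)
            cnvrs_by_group[gname] = retained
            counts[f"cnvrs_{gname}"] = len(merged)
            counts[f"cnvrs_retained_{gname}"] = len(retained)
            logger.info("stage merge [%s]: %d CNVRs -> %d after >=%d-sample filter",
                        gname, len(merged), len(retained), cfg.min_samples)

    # --- gene annotation, intronic removal ----------------------------------
    annotated_by_group = {
        g: overlap_genes(rs, cohort.genes) for g, rs in cnvrs_by_group.items()
    }
    gene_sets = {
        g: gene_set(ann, retained_only=not cfg.keep_intronic)
        for g, ann in annotated_by_group.items()
    }
    for g, gs in gene_sets.items():
        counts[f"genes_{g}"] = len(gs)
        logger.info("stage annotate [%s]: %d genes after intronic removal", g, len(gs))

    # --- two-group comparison ------------------------------------------------
    summaries = [
        summarize_group(calls_by_group[g], len(groups[g]), g) for g in groups
    ]
    summaries.append(combine_summaries(summaries))
    diff = differential_genes(gene_sets[GROUP_A], gene_sets[GROUP_B])
    counts["differential_genes"] = len(diff.differential)
    logger.info("stage compare: %d differential genes (nested=%s)",
                len(diff.differential), diff.b_subset_of_a)

    # --- enrichment of the differential set ---------------------------------
    population = {g.gene_id for g in cohort.genes.genes}
    term_map = make_term_map(
        population,
        seed=np.random.SeedSequence([cfg.seed, 101]),
        enriched_genes=diff.differential or None,
    )
    enr = enrich(diff.differential, term_map, population, alpha=cfg.alpha)
    counts["enriched_terms"] = sum(r.adjusted_p <= cfg.alpha for r in enr)

    # --- qPCR validation round ----------------------------------------------
    qpcr_report: dict[str, object] | None = None
    exonic_regions = [r for r in cohort.truth.regions if r.placement == "exonic"]
    targets = exonic_regions[: cfg.qpcr_targets]
    if targets:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
        val_samples = [
            s
            for grp in (cohort.truth.group_a, cohort.truth.group_b)
            for s in rng.choice(
                grp, size=min(cfg.qpcr_samples_per_group, len(grp)), replace=False
            )
        ]
        truth_cns = {
            (s, r.region_id): cohort.truth.carriers[r.region_id].get(s, 2)
            for s in val_samples
            for r in targets
        }
        # calibrators: validation samples diploid at every target (fall back
        # to a synthetic diploid control if the cohort has none)
        calibrators = [
            s
            for s in val_samples
            if all(truth_cns[(s, r.region_id)] == 2 for r in targets)
        ]
        if not calibrators:
            for r in targets:
                truth_cns[("CTRL", r.region_id)] = 2
            calibrators = ["CTRL"]
        table = simulate_qpcr(
            truth_cns,
            ct_noise_sd=cfg.qpcr_ct_noise_sd,
            seed=np.random.SeedSequence([cfg.seed, 303]),
        )
        estimates = delta_delta_ct(table, calibrators)
        all_calls = [c for g in calls_by_group.values() for c in g]
        seq_cns = {
            (s, r.region_id): _sequencing_cn(all_calls, s, r.chrom, r.start, r.end)
            for s in val_samples
            for r in targets
        }
        qpcr_report = concordance(
            [e for e in estimates if e.sample_id != "CTRL"], seq_cns
        )
        qpcr_report["estimates"] = estimates_table(estimates)
        counts["qpcr_pairs"] = int(qpcr_report["n_pairs"])  # type: ignore[arg-type]
        logger.info(
            "stage qpcr: %s/%s pairs direction-concordant",
            qpcr_report["n_direction_concordant"], qpcr_report["n_pairs"],
        )

    report = PipelineReport(
        config=cfg,
        calls=calls_by_group,
        cnvrs=cnvrs_by_group,
        annotated=annotated_by_group,
        gene_sets=gene_sets,
        summaries=summaries,
        diff=diff,
        enrichment=enr,
        qpcr=qpcr_report,
        stage_counts=counts,
        out_dir=out,
    )
    if out is not None:
        _write_bundle(report, cohort, out)
    return report

def _write_bundle(report: PipelineReport, cohort: SyntheticCohort, out: Path) -> None:
    cfg = report.config
    chrom_lengths = dict(zip(cohort.genome.chrom_names, cohort.genome.chrom_lengths))
    cfg.to_yaml(out / "config.yaml")
    write_gff3(cohort.genes, out / "genes.gff3")
    io.write_table(cohort.truth.to_frame(), out / "truth.tsv")
    for g, calls in report.calls.items():
        io.write_calls_bed(calls, out / f"calls_{g}.bed")
        io.write_calls_vcf(calls, out / f"calls_{g}.vcf", chrom_lengths)
    for g, rs in report.cnvrs.items():
        io.write_cnvr_bed(rs, out / f"cnvr_{g}.bed")
        io.write_cnvr_vcf(rs, out / f"cnvr_{g}.vcf", chrom_lengths)
        io.write_table(
            cnvr_density(rs, chrom_lengths), out / f"cnvr_density_{g}.tsv"
        )
    for g, gs in report.gene_sets.items():
        io.write_gene_list(gs, out / f"genes_{g}.txt")
    io.write_gene_list(report.diff.differential, out / "genes_differential.txt")
    io.write_table(summary_table(report.summaries), out / "summary.tsv")
    io.write_table(
        enrichment_table(report.enrichment, alpha=cfg.alpha), out / "enrichment.tsv"
    )
    if report.qpcr is not None:
        report.qpcr["estimates"].to_csv(out / "qpcr_estimates.csv", index=False)  # type: ignore[union-attr]
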