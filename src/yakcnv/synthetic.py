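"""Synthetic cohorts with known CNV truth.

This module generates everything the analysis consumes — a small genome
with a GC landscape, a gene model, planted per-sample CNV genotypes, binned
depth profiles, and qPCR Ct tables — so the whole pipeline can be exercised
and scored against ground truth without any sequencing data.

The generator mirrors the statistical structure of a two-group livestock
resequencing design: two closely related groups of diploid individuals
(default 10 + 10), ~7.5x mean coverage, negative-binomial count noise with
a multiplicative unimodal GC bias, CNVs from 0.6 kb upward, and a *nested*
gene-set structure in which every gene hit in group B is also hit in group
A (shared variants segregate in both groups; a second class of variants
segregates only in group A).  Depth is simulated directly at the bin level;
no reads are generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import Gene, GeneModel
from .rd_caller import DEL, DUP, CNVCall, DepthProfile, reciprocal_overlap

GC_PEAK = 0.45  # GC fraction at which simulated capture efficiency peaks


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass
class GenomeModel:
    """Chromosome sizes plus a GC fraction per fixed-width window."""

    chrom_names: list[str]
    chrom_lengths: list[int]
    gc_window: int
    gc: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths lengths differ")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.gc_window <= 0:
            raise ValueError("gc_window must be positive")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            lw = self.gc[name]
            expect = math.ceil(length / self.gc_window)
            if len(lw) != expect:
                raise ValueError(
                    f"{name}: {len(lw)} GC windows, expected {expect}"
                )
            if np.any((lw < 0) | (lw > 1)):
                raise ValueError(f"{name}: GC outside [0,1]")

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def bin_gc(self, chrom: str, bin_size: int) -> np.ndarray:
        """GC fraction per depth bin (window containing the bin midpoint)."""
        length = self.chrom_length(chrom)
        n_bins = math.ceil(length / bin_size)
        mids = np.minimum(
            np.arange(n_bins) * bin_size + bin_size // 2, length - 1
        )
        idx = np.minimum(mids // self.gc_window, len(self.gc[chrom]) - 1)
        return self.gc[chrom][idx]


def make_genome(
    n_chrom: int,
    chrom_length: int,
    gc_window: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> GenomeModel:
    """Generate a genome with a smooth, bounded GC landscape.

    The GC track per chromosome is moving-average-smoothed white noise
    rescaled around 0.45 and clipped to [0.25, 0.65] — smooth enough that
    neighbouring bins share GC strata, variable enough that the GC
    correction stage has something to undo.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if gc_window <= 0 or chrom_length <= 0:
        raise ValueError("sizes must be positive")
    if chrom_length < 10 * gc_window:
        raise ValueError("chrom_length must be at least 10 x gc_window")

    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    gc: dict[str, np.ndarray] = {}
    for name in names:
        n_win = math.ceil(chrom_length / gc_window)
        noise = rng.normal(0.0, 1.0, n_win + 40)
        kernel = np.ones(21) / 21
        smooth = np.convolve(noise, kernel, mode="valid")[:n_win]
        smooth = smooth / max(smooth.std(), 1e-9) * 0.06
        gc[name] = np.clip(GC_PEAK + smooth, 0.25, 0.65)
    return GenomeModel(
        chrom_names=names,
        chrom_lengths=[chrom_length] * n_chrom,
        gc_window=gc_window,
        gc=gc,
    )


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------


def make_genes(
    genome: GenomeModel,
    n_genes: int,
    exons_per_gene: int = 3,
    seed: int | np.random.SeedSequence = 0,
    gene_length_range: tuple[int, int] = (10_000, 30_000),
    exon_length_range: tuple[int, int] = (150, 400),
    min_gap: int = 5_000,
) -> GeneModel:
    """Place non-overlapping genes with exons strictly inside each span.

    Genes are laid down left to right with random gaps, spread over the
    chromosomes in proportion to a per-chromosome quota; each gene gets
    ``exons_per_gene`` exons, one per equal-width slot of the gene body, so
    exons are ordered and separated by introns.  Raises if the genome
    cannot hold ``n_genes`` at these sizes.
    """
    if n_genes < 0 or exons_per_gene < 1:
        raise ValueError("n_genes must be >= 0 and exons_per_gene >= 1")
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    placed = 0
    n_chrom = len(genome.chrom_names)
    for ci, (chrom, length) in enumerate(
        zip(genome.chrom_names, genome.chrom_lengths)
    ):
        quota = n_genes if ci == n_chrom - 1 else min(
            n_genes, placed + -(-n_genes // n_chrom)
        )
        pos = int(rng.integers(min_gap, 2 * min_gap))
        while placed < quota:
            glen = int(rng.integers(*gene_length_range))
            if pos + glen + min_gap > length:
                break
            gid = f"gene{placed + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(gene_id=gid, name=gid.upper(), chrom=chrom,
                     start=pos, end=pos + glen, strand=strand)
            )
            slot = glen // exons_per_gene
            ivs: list[tuple[int, int]] = []
            for k in range(exons_per_gene):
                elen = int(rng.integers(*exon_length_range))
                lo = pos + k * slot + 100
                hi = pos + (k + 1) * slot - elen - 100
                es = int(rng.integers(lo, max(lo + 1, hi)))
                ivs.append((es, es + elen))
            exons[gid] = ivs
            placed += 1
            pos += glen + int(rng.integers(min_gap, 3 * min_gap))
    if placed < n_genes:
        raise ValueError(
            f"cannot pack {n_genes} genes of {gene_length_range} bp into this genome "
            f"(placed {placed})"
        )
    return GeneModel(genes=genes, exons=exons)


# ---------------------------------------------------------------------------
# planted CNVs and cohort truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCNV:
    """One true CNV genotype: sample, interval, integer copy number."""

    sample_id: str
    chrom: str
    start: int
    end: int
    true_copy_number: int

    def __post_init__(self) -> None:
        if self.end - self.start < 600:
            raise ValueError("planted CNVs must be >= 600 bp")
        if self.true_copy_number < 0:
            raise ValueError("copy number must be >= 0")


@dataclass(frozen=True)
class PlantedRegion:
    """A planted locus shared by its carriers (before per-sample genotypes)."""

    region_id: str
    chrom: str
    start: int
    end: int
    svtype: str  # DEL or DUP
    scope: str  # "shared" (both groups) or "group_a" (group A only)
    placement: str  # "exonic" | "intronic" | "intergenic"
    genes: tuple[str, ...]  # exon-affecting gene overlaps (the meaningful ones)


@dataclass
class CohortTruth:
    """Ground truth for a planted cohort; the oracle every stage is scored on."""

    regions: list[PlantedRegion]
    carriers: dict[str, dict[str, int]]  # region_id -> sample_id -> CN
    group_a: list[str]
    group_b: list[str]

    def sample_cnvs(self, sample_id: str) -> list[PlantedCNV]:
        out = [
            PlantedCNV(sample_id, r.chrom, r.start, r.end, cn)
            for r in self.regions
            for s, cn in self.carriers[r.region_id].items()
            if s == sample_id
        ]
        out.sort(key=lambda p: (p.chrom, p.start))
        return out

    def gene_set(self, group: str) -> set[str]:
        """Exon-affecting genes carried by the group ('a' or 'b')."""
        genes: set[str] = set()
        for r in self.regions:
            if group == "a" or r.scope == "shared":
                genes.update(r.genes)
        return genes

    def differential_genes(self) -> set[str]:
        return self.gene_set("a") - self.gene_set("b")

    def truth_pairs(self) -> list[PlantedCNV]:
        """All (sample, interval, CN) truths, over every carrier."""
        return [p for s in self.group_a + self.group_b for p in self.sample_cnvs(s)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            for s, cn in sorted(self.carriers[r.region_id].items()):
                rows.append(
                    {
                        "region_id": r.region_id,
                        "chrom": r.chrom,
                        "start": r.start,
                        "end": r.end,
                        "svtype": r.svtype,
                        "scope": r.scope,
                        "placement": r.placement,
                        "genes": ",".join(r.genes),
                        "sample_id": s,
                        "copy_number": cn,
                    }
                )
        return pd.DataFrame(rows)


def _exon_gene_overlaps(
    model: GeneModel, chrom: str, start: int, end: int
) -> tuple[str, ...]:
    """Brute-force: genes whose exons the interval touches, or that it contains."""
    hit: list[str] = []
    for g in model.genes:
        if g.chrom != chrom or min(end, g.end) <= max(start, g.start):
            continue
        if start <= g.start and end >= g.end:
            hit.append(g.gene_id)
        elif any(min(end, e) > max(start, s) for s, e in model.exons[g.gene_id]):
            hit.append(g.gene_id)
    return tuple(sorted(hit))


def plant_cohort_cnvs(
    genome: GenomeModel,
    genes: GeneModel,
    n_per_group: int = 10,
    n_shared: int = 4,
    n_group_a_only: int = 3,
    size_range: tuple[int, int] = (5_000, 30_000),
    seed: int | np.random.SeedSequence = 0,
    n_intronic: int = 0,
    n_intergenic: int = 0,
    cn_choices_del: Sequence[int] = (0, 1),
    cn_choices_dup: Sequence[int] = (3, 4),
    min_carriers: int | None = None,
    margin: int = 5_000,
    intronic_margin: int = 3_000,
) -> tuple[list[PlantedCNV], CohortTruth]:
    """Plant CNV loci across a two-group cohort and record the truth table.

    ``n_shared`` exon-overlapping loci segregate in >= ``min_carriers``
    samples of BOTH groups; ``n_group_a_only`` segregate only in group A —
    this builds the nested structure where group B's gene set is a subset
    of group A's, so the truth differential gene set is exactly the genes
    of the A-only loci.  ``n_intronic`` loci sit strictly inside an intron
    (they exercise intronic removal and contribute no genes to the truth
    sets) and ``n_intergenic`` loci avoid genes entirely.

    ``min_carriers`` defaults to max(4, n_per_group // 2): common variants,
    comfortably above the 4-sample frequency filter.  Loci are mutually
    separated by ``margin`` bp and never touch a non-anchor gene, so merged
    regions stay distinct downstream.  Intronic loci keep
    ``intronic_margin`` bp clear of the flanking exons so that the modest
    boundary overshoot of read-depth calls cannot spill onto an exon.
    """
    if n_per_group < 4:
        raise ValueError("n_per_group must be >= 4 to exercise the frequency filter")
    if size_range[0] < 600:
        raise ValueError("size_range minimum must be >= 600 bp")
    if min_carriers is None:
        min_carriers = max(4, n_per_group // 2)
    if not 4 <= min_carriers <= n_per_group:
        raise ValueError("min_carriers must be in [4, n_per_group]")

    rng = np.random.default_rng(seed)
    group_a = [f"LH{i + 1:02d}" for i in range(n_per_group)]
    group_b = [f"NH{i + 1:02d}" for i in range(n_per_group)]

    # occupied space: every gene span plus clearance, growing as loci are
    # placed; the margin keeps call-boundary jitter from reaching a
    # neighbouring gene downstream
    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in genome.chrom_names}
    for g in genes.genes:
        occupied[g.chrom].addi(max(0, g.start - margin), g.end + margin, g.gene_id)

    free_genes = list(genes.genes)
    rng.shuffle(free_genes)

    def reserve(chrom: str, start: int, end: int) -> None:
        occupied[chrom].addi(max(0, start - margin), end + margin, None)

    def conflicts(chrom: str, start: int, end: int, ignore: Gene | None) -> bool:
        for iv in occupied[chrom].overlap(start, end):
            if ignore is not None and iv.data == ignore.gene_id:
                continue
            return True
        return False

    regions: list[PlantedRegion] = []

    def place_exonic(scope: str, idx: int) -> PlantedRegion:
        while free_genes:
            g = free_genes.pop()
            exon_ivs = list(genes.exons[g.gene_id])
            rng.shuffle(exon_ivs)
            for es, ee in exon_ivs:
                length = int(rng.integers(size_range[0], size_range[1] + 1))
                mid = (es + ee) // 2
                start = max(0, mid - length // 2)
                end = min(genome.chrom_length(g.chrom), start + length)
                start = max(0, end - length)
                if end - start < size_range[0]:
                    continue
                if conflicts(g.chrom, start, end, ignore=g):
                    continue
                reserve(g.chrom, start, end)
                svtype = DEL if rng.random() < 0.5 else DUP
                return PlantedRegion(
                    region_id=f"cnv{idx:03d}",
                    chrom=g.chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    scope=scope,
                    placement="exonic",
                    genes=_exon_gene_overlaps(genes, g.chrom, start, end),
                )
        raise ValueError("ran out of genes while placing exon-overlapping CNVs")

    def place_intronic(idx: int) -> PlantedRegion:
        while free_genes:
            g = free_genes.pop()
            ivs = genes.exons[g.gene_id]
            introns = [
                (ivs[i][1] + intronic_margin, ivs[i + 1][0] - intronic_margin)
                for i in range(len(ivs) - 1)
            ]
            rng.shuffle(introns)
            for lo, hi in introns:
                room = hi - lo
                if room < 700:
                    continue
                length = int(
                    rng.integers(600, min(size_range[1], room - 100) + 1)
                )
                start = int(rng.integers(lo, hi - length + 1))
                end = start + length
                if conflicts(g.chrom, start, end, ignore=g):
                    continue
                reserve(g.chrom, start, end)
                svtype = DEL if rng.random() < 0.5 else DUP
                return PlantedRegion(
                    region_id=f"cnv{idx:03d}",
                    chrom=g.chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    scope="shared",
                    placement="intronic",
                    genes=(),  # intronic-only: removed downstream, no truth genes
                )
        raise ValueError("ran out of genes while placing intronic CNVs")

    def place_intergenic(idx: int) -> PlantedRegion:
        for _ in range(200):
            chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
            clen = genome.chrom_length(chrom)
            length = int(rng.integers(size_range[0], size_range[1] + 1))
            if clen <= length + 2:
                continue
            start = int(rng.integers(0, clen - length))
            end = start + length
            if conflicts(chrom, start, end, ignore=None):
                continue
            reserve(chrom, start, end)
            svtype = DEL if rng.random() < 0.5 else DUP
            return PlantedRegion(
                region_id=f"cnv{idx:03d}",
                chrom=chrom,
                start=start,
                end=end,
                svtype=svtype,
                scope="shared",
                placement="intergenic",
                genes=(),
            )
        raise ValueError("could not place an intergenic CNV; genome too crowded")

    idx = 1
    for _ in range(n_shared):
        regions.append(place_exonic("shared", idx)); idx += 1
    for _ in range(n_group_a_only):
        regions.append(place_exonic("group_a", idx)); idx += 1
    for _ in range(n_intronic):
        regions.append(place_intronic(idx)); idx += 1
    for _ in range(n_intergenic):
        regions.append(place_intergenic(idx)); idx += 1

    carriers: dict[str, dict[str, int]] = {}
    for r in regions:
        cn_pool = list(cn_choices_del if r.svtype == DEL else cn_choices_dup)
        geno: dict[str, int] = {}
        groups = [group_a] if r.scope == "group_a" else [group_a, group_b]
        for grp in groups:
            k = int(rng.integers(min_carriers, n_per_group + 1))
            chosen = rng.choice(grp, size=k, replace=False)
            for s in chosen:
                geno[str(s)] = int(cn_pool[int(rng.integers(len(cn_pool)))])
        carriers[r.region_id] = geno

    truth = CohortTruth(
        regions=regions, carriers=carriers, group_a=group_a, group_b=group_b
    )
    return truth.truth_pairs(), truth


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------


def gc_factor(gc: np.ndarray | float, strength: float) -> np.ndarray | float:
    """Unimodal multiplicative GC efficiency, peaking at GC 0.45.

    ``exp(-strength * (gc - 0.45)^2)``; strength 0 disables the bias.
    """
    return np.exp(-strength * (np.asarray(gc, dtype=float) - GC_PEAK) ** 2)


def simulate_depth(
    genome: GenomeModel,
    planted: Sequence[PlantedCNV],
    sample_id: str,
    mean_coverage: float = 7.5,
    bin_size: int = 500,
    gc_bias_strength: float = 4.0,
    dispersion: float = 0.02,
    read_length: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> list[DepthProfile]:
    """Simulate binned read counts for one sample (one profile per chromosome).

    Each bin's expected count is
    ``(CN/2) * mean_coverage * bin_width / read_length * gc_factor(GC)``
    with CN the copy number averaged over the bin (planted CNVs contribute
    fractionally to partially overlapped bins).  Counts are negative
    binomial with variance ``mu + dispersion * mu^2``; dispersion 0 gives
    Poisson.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if dispersion < 0 or gc_bias_strength < 0:
        raise ValueError("dispersion and gc_bias_strength must be >= 0")
    for p in planted:
        if p.sample_id != sample_id:
            raise ValueError(f"planted CNV for {p.sample_id} passed to {sample_id}")

    rng = np.random.default_rng(seed)
    profiles: list[DepthProfile] = []
    for chrom, clen in zip(genome.chrom_names, genome.chrom_lengths):
        n_bins = math.ceil(clen / bin_size)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        widths = np.minimum(starts + bin_size, clen) - starts
        cn = np.full(n_bins, 2.0)
        for p in planted:
            if p.chrom != chrom:
                continue
            b0 = p.start // bin_size
            b1 = (p.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                ov = min(p.end, (b + 1) * bin_size) - max(p.start, b * bin_size)
                cn[b] += (p.true_copy_number - 2) * ov / widths[b]
        gc = genome.bin_gc(chrom, bin_size)
        mu = (
            (np.maximum(cn, 0.0) / 2.0)
            * mean_coverage
            * widths
            / read_length
            * gc_factor(gc, gc_bias_strength)
        )
        counts = np.zeros(n_bins, dtype=np.int64)
        pos = mu > 0
        if dispersion > 0:
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mu[pos])
            counts[pos] = rng.negative_binomial(n_param, p_param)
        else:
            counts[pos] = rng.poisson(mu[pos])
        profiles.append(
            DepthProfile(
                sample_id=sample_id,
                chrom=chrom,
                bin_size=bin_size,
                counts=counts.astype(float),
                gc=gc,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_qpcr(
    truth_cns: Mapping[tuple[str, str], int],
    ct_noise_sd: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    reference_ct_baseline: float = 20.0,
    ct_ceiling: float = 40.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Ct tables from true copy numbers (the inverse of ddCT quantification).

    For each (sample, target) with copy number CN, the target well reads
    ``baseline - log2(CN/2) + noise`` so a diploid sample has dCt 0 against
    the reference well (``baseline + noise``).  CN 0 cannot amplify and is
    encoded by the Ct ceiling (default 40 cycles).  Three technical
    replicates per well, independent Gaussian noise per well.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for (sample_id, target_id), cn in truth_cns.items():
        if cn < 0:
            raise ValueError("copy numbers must be >= 0")
        for rep in range(1, n_replicates + 1):
            if cn == 0:
                t_ct = ct_ceiling
            else:
                t_ct = (
                    reference_ct_baseline
                    - math.log2(cn / 2)
                    + rng.normal(0.0, ct_noise_sd)
                )
            r_ct = reference_ct_baseline + rng.normal(0.0, ct_noise_sd)
            rows.append(
                {
                    "sample_id": sample_id,
                    "target_region_id": target_id,
                    "replicate_index": rep,
                    "target_ct": t_ct,
                    "reference_ct": r_ct,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# term map (for the enrichment demo) and truth-based scoring
# ---------------------------------------------------------------------------


def make_term_map(
    population: Iterable[str],
    n_terms: int = 20,
    seed: int | np.random.SeedSequence = 0,
    term_size_range: tuple[int, int] = (3, 12),
    enriched_genes: Iterable[str] | None = None,
):
    """A flat synthetic term->genes map over the population.

    Random terms of modest size, plus (optionally) one term concentrated on
    ``enriched_genes`` so a planted enrichment signal exists.  Categories
    cycle through the three GO namespaces.
    """
    from .enrichment import TermMap

    rng = np.random.default_rng(seed)
    pop = sorted(population)
    cats = ["biological process", "cellular component", "molecular function"]
    terms: dict[str, set[str]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for i in range(n_terms):
        k = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        k = min(k, len(pop))
        tid = f"TERM:{i + 1:04d}"
        terms[tid] = set(rng.choice(pop, size=k, replace=False).tolist())
        meta[tid] = (f"synthetic term {i + 1}", cats[i % 3])
    if enriched_genes is not None:
        eg = set(enriched_genes) & set(pop)
        if eg:
            terms["TERM:PLANTED"] = eg
            meta["TERM:PLANTED"] = ("planted enriched term", cats[0])
    return TermMap(terms=terms, meta=meta)


def evaluate_calls(
    calls: Sequence[CNVCall],
    truth: CohortTruth,
    min_reciprocal_overlap: float = 0.5,
) -> dict[str, float]:
    """Recall/precision of per-sample calls against the planted truth.

    A truth genotype (sample, interval, CN) counts as recovered when a call
    from the same sample overlaps it reciprocally by at least
    ``min_reciprocal_overlap`` with the right direction (DEL for CN < 2).
    A call not matching any truth genotype is a false positive.
    """
    pairs = truth.truth_pairs()
    by_sample: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    tp = 0
    matched_calls: set[int] = set()
    for p in pairs:
        want = DEL if p.true_copy_number < 2 else DUP
        for c in by_sample.get(p.sample_id, []):
            if (
                c.chrom == p.chrom
                and c.svtype == want
                and reciprocal_overlap((c.start, c.end), (p.start, p.end))
                >= min_reciprocal_overlap
            ):
                tp += 1
                matched_calls.add(id(c))
                break
    fp = sum(1 for c in calls if id(c) not in matched_calls)
    fn = len(pairs) - tp
    recall = tp / len(pairs) if pairs else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_truth": len(pairs),
        "n_calls": len(calls),
    }


# ---------------------------------------------------------------------------
# whole-cohort convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    genome: GenomeModel
    genes: GeneModel
    truth: CohortTruth
    profiles: dict[str, list[DepthProfile]]  # sample -> per-chromosome profiles
    bin_size: int


def simulate_cohort(
    seed: int = 0,
    n_per_group: int = 10,
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 30,
    n_shared: int = 4,
    n_group_a_only: int = 3,
    n_intronic: int = 2,
    n_intergenic: int = 1,
    size_range: tuple[int, int] = (5_000, 30_000),
    mean_coverage: float = 7.5,
    bin_size: int = 500,
    gc_bias_strength: float = 4.0,
    dispersion: float = 0.02,
    cn_choices_del: Sequence[int] = (0, 1),
    cn_choices_dup: Sequence[int] = (3, 4),
) -> SyntheticCohort:
    """Generate a complete two-group cohort: genome, genes, truth, depth.

    Defaults emulate the study design this package targets: 2 x 10 diploid
    samples at 7.5x coverage with GC bias and overdispersed counts, shared
    and group-A-private exon-overlapping CNVs (nested gene sets), a couple
    of intronic loci, and one intergenic locus.  All randomness descends
    from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_genes, s_plant, s_depth = ss.spawn(4)
    genome = make_genome(n_chrom, chrom_length, seed=s_genome)
    genes = make_genes(genome, n_genes, seed=s_genes)
    _, truth = plant_cohort_cnvs(
        genome,
        genes,
        n_per_group=n_per_group,
        n_shared=n_shared,
        n_group_a_only=n_group_a_only,
        size_range=size_range,
        seed=s_plant,
        n_intronic=n_intronic,
        n_intergenic=n_intergenic,
        cn_choices_del=cn_choices_del,
        cn_choices_dup=cn_choices_dup,
    )
    samples = truth.group_a + truth.group_b
    depth_seeds = s_depth.spawn(len(samples))
    profiles = {
        s: simulate_depth(
            genome,
            truth.sample_cnvs(s),
            s,
            mean_coverage=mean_coverage,
            bin_size=bin_size,
            gc_bias_strength=gc_bias_strength,
            dispersion=dispersion,
            seed=ds,
        )
        for s, ds in zip(samples, depth_seeds)
    }
    return SyntheticCohort(
        genome=genome, genes=genes, truth=truth, profiles=profiles, bin_size=bin_size
    )
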