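"""Generator correctness: determinism, truth-table consistency, depth model."""

from __future__ import annotations

import numpy as np
import pytest

from yakcnv.annotation import read_gff3, write_gff3
from yakcnv.synthetic import (
    make_genes,
    make_genome,
    plant_cohort_cnvs,
    simulate_depth,
    simulate_qpcr,
)


class TestMakeGenome:
    def test_window_count_and_bounds(self):
        g = make_genome(n_chrom=1, chrom_length=1_000_000, gc_window=500, seed=0)
        assert len(g.gc["chr1"]) == 2000
        g2 = make_genome(n_chrom=2, chrom_length=100_000, seed=3)
        assert g2.chrom_names == ["chr1", "chr2"]
        for c in g2.chrom_names:
            assert np.all((g2.gc[c] >= 0.25) & (g2.gc[c] <= 0.65))

    def test_deterministic_under_fixed_seed(self):
        a = make_genome(2, 100_000, seed=42)
        b = make_genome(2, 100_000, seed=42)
        assert a.chrom_lengths == b.chrom_lengths
        for c in a.chrom_names:
            np.testing.assert_array_equal(a.gc[c], b.gc[c])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chrom=0, chrom_length=100_000),
            dict(n_chrom=1, chrom_length=-5),
            dict(n_chrom=1, chrom_length=100_000, gc_window=0),
            dict(n_chrom=1, chrom_length=4_000, gc_window=500),  # < 10 windows
        ],
    )
    def test_rejects_bad_sizes(self, kwargs):
        with pytest.raises(ValueError):
            make_genome(seed=0, **kwargs)


class TestMakeGenes:
    def test_counts_and_structure(self, genome):
        gm = make_genes(genome, n_genes=10, exons_per_gene=3, seed=5)
        assert len(gm.genes) == 10
        assert sum(len(v) for v in gm.exons.values()) == 30
        for g in gm.genes:  # exons strictly inside the gene span
            for s, e in gm.exons[g.gene_id]:
                assert g.start < s < e < g.end

    def test_empty_model(self, genome, tmp_path):
        gm = make_genes(genome, n_genes=0, seed=1)
        assert len(gm.genes) == 0
        p = tmp_path / "empty.gff3"
        write_gff3(gm, p)
        assert len(read_gff3(p)) == 0

    def test_gff3_round_trip(self, gene_model, tmp_path):
        p = tmp_path / "genes.gff3"
        write_gff3(gene_model, p)
        back = read_gff3(p)
        orig = {(g.gene_id, g.chrom, g.start, g.end) for g in gene_model.genes}
        assert {(g.gene_id, g.chrom, g.start, g.end) for g in back.genes} == orig
        for gid, ivs in gene_model.exons.items():
            assert back.exons[gid] == ivs

    def test_infeasible_packing_reported(self, genome):
        with pytest.raises(ValueError, match="cannot pack"):
            make_genes(genome, n_genes=100, gene_length_range=(40_000, 50_000), seed=0)


class TestPlantCohort:
    def test_empty_truth(self, genome, gene_model):
        planted, truth = plant_cohort_cnvs(
            genome, gene_model, n_shared=0, n_group_a_only=0, seed=0
        )
        assert planted == [] and truth.regions == []

    def test_truth_table_consistency(self, genome, gene_model):
        """Carriers exist, >= 4 per designated group, genes verified by brute force."""
        _, truth = plant_cohort_cnvs(
            genome, gene_model, n_per_group=6, n_shared=2, n_group_a_only=2,
            size_range=(2_000, 6_000), seed=7,
        )
        samples = set(truth.group_a + truth.group_b)
        gene_spans = {g.gene_id: (g.chrom, g.start, g.end) for g in gene_model.genes}
        for r in truth.regions:
            carriers = truth.carriers[r.region_id]
            assert set(carriers) <= samples
            in_a = sum(1 for s in carriers if s in truth.group_a)
            in_b = sum(1 for s in carriers if s in truth.group_b)
            assert in_a >= 4
            if r.scope == "group_a":
                assert in_b == 0
            else:
                assert in_b >= 4
            # every listed gene really intersects the interval (exon or full span)
            for gid in r.genes:
                chrom, gs, ge = gene_spans[gid]
                assert chrom == r.chrom
                spanned = r.start <= gs and r.end >= ge
                exonic = any(
                    min(r.end, e) > max(r.start, s)
                    for s, e in gene_model.exons[gid]
                )
                assert spanned or exonic

    def test_differential_is_group_a_only_genes(self, genome, gene_model):
        _, truth = plant_cohort_cnvs(
            genome, gene_model, n_per_group=5, n_shared=3, n_group_a_only=2,
            size_range=(2_000, 6_000), seed=3,
        )
        a_only_genes = {
            g for r in truth.regions if r.scope == "group_a" for g in r.genes
        }
        shared_genes = {
            g for r in truth.regions if r.scope == "shared" for g in r.genes
        }
        assert truth.differential_genes() == a_only_genes - shared_genes

    def test_per_sample_intervals_do_not_overlap(self, genome, gene_model):
        _, truth = plant_cohort_cnvs(
            genome, gene_model, n_shared=3, n_group_a_only=2,
            size_range=(2_000, 8_000), seed=9,
        )
        for s in truth.group_a + truth.group_b:
            ivs = sorted((p.start, p.end, p.chrom) for p in truth.sample_cnvs(s))
            for (s1, e1, c1), (s2, e2, c2) in zip(ivs, ivs[1:]):
                assert c1 != c2 or s2 >= e1

    def test_size_floor_enforced(self, genome, gene_model):
        with pytest.raises(ValueError, match="600"):
            plant_cohort_cnvs(genome, gene_model, size_range=(100, 5_000), seed=0)


class TestSimulateDepth:
    def test_flat_diploid_mean_matches_expectation(self, genome):
        """No GC bias, CN 2 everywhere: mean depth within 3 SE of coverage model."""
        profs = simulate_depth(
            genome, [], "s1", mean_coverage=7.5, bin_size=500,
            gc_bias_strength=0.0, dispersion=0.02, seed=1,
        )
        counts = np.concatenate([p.counts for p in profs])
        mu = 7.5 * 500 / 100  # coverage * bin / read-length equivalent
        se = np.sqrt(mu + 0.02 * mu**2) / np.sqrt(len(counts))
        assert abs(counts.mean() - mu) < 3 * se

    def test_homozygous_deletion_is_empty(self, genome):
        from yakcnv.synthetic import PlantedCNV

        cnv = PlantedCNV("s1", "chr1", 10_000, 20_000, 0)
        profs = simulate_depth(genome, [cnv], "s1", dispersion=0.0, seed=2)
        c = profs[0]
        assert c.counts[10_000 // 500 + 1 : 20_000 // 500 - 1].sum() == 0

    def test_duplication_doubles_regional_depth(self, genome):
        from yakcnv.synthetic import PlantedCNV

        cnv = PlantedCNV("s1", "chr1", 50_000, 70_000, 4)
        profs = simulate_depth(
            genome, [cnv], "s1", gc_bias_strength=0.0, dispersion=0.01, seed=3
        )
        c = profs[0].counts
        inside = c[50_000 // 500 : 70_000 // 500].mean()
        flank = np.concatenate([c[: 50_000 // 500], c[70_000 // 500 :]]).mean()
        assert inside / flank == pytest.approx(2.0, rel=0.06)

    def test_depth_scales_linearly_in_copy_number(self, genome):
        """Regression of region mean depth on CN has slope ~ coverage/2."""
        from yakcnv.synthetic import PlantedCNV

        cns = [0, 1, 2, 3, 4]
        regions = [(20_000 + 30_000 * i, 40_000 + 30_000 * i) for i in range(len(cns))]
        planted = [
            PlantedCNV("s1", "chr1", s, e, cn)
            for (s, e), cn in zip(regions, cns) if cn != 2
        ]
        profs = simulate_depth(
            genome, planted, "s1", gc_bias_strength=0.0, dispersion=0.01, seed=4
        )
        c = profs[0].counts
        means = [c[s // 500 : e // 500].mean() for s, e in regions]
        slope = np.polyfit(cns, means, 1)[0]
        per_cn = 7.5 * 500 / 100 / 2
        assert slope == pytest.approx(per_cn, rel=0.05)

    def test_rejects_mismatched_sample(self, genome):
        from yakcnv.synthetic import PlantedCNV

        cnv = PlantedCNV("other", "chr1", 0, 5_000, 0)
        with pytest.raises(ValueError, match="other"):
            simulate_depth(genome, [cnv], "s1", seed=0)

    def test_rejects_negative_dispersion(self, genome):
        with pytest.raises(ValueError):
            simulate_depth(genome, [], "s1", dispersion=-0.1, seed=0)


class TestSimulateQpcr:
    def test_noise_free_ct_spacing(self):
        """CN 4 amplifies exactly one cycle earlier than CN 2."""
        table = simulate_qpcr(
            {("s1", "r1"): 2, ("s2", "r1"): 4}, ct_noise_sd=0.0, seed=0
        )
        ct = table.groupby("sample_id")["target_ct"].mean()
        assert ct["s1"] - ct["s2"] == pytest.approx(1.0)
        assert (table.groupby(["sample_id", "target_region_id"]).size() == 3).all()

    def test_zero_copy_hits_ceiling(self):
        table = simulate_qpcr({("s1", "r1"): 0}, ct_noise_sd=0.0, seed=0)
        assert (table["target_ct"] == 40.0).all()

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            simulate_qpcr({("s1", "r1"): 2}, ct_noise_sd=-1.0, seed=0)
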