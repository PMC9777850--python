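# Methods

`yakcnv` implements the standard read-depth (RD) workflow for detecting
copy-number variation (CNV) in small two-group resequencing cohorts, the
cross-sample construction of CNV regions (CNVRs), gene-level comparison of
the two groups, term enrichment, and qPCR-based validation. This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Depth model and simulation

The unit of analysis is the binned read count. For bin width *w* (default
500 bp), fold coverage *c* (default 7.5×) and an effective read length *L*
(100 bp), a diploid bin is expected to hold

    mu = c · w / L ≈ 37.5 reads,

scaled by CN/2 inside a CNV of copy number CN and by a multiplicative GC
efficiency `exp(−s·(g − 0.45)²)` with strength *s* (default 4; *s* = 0
disables the bias — this keeps the GC-correction stage falsifiable).
Counts are negative binomial with variance `mu + α·mu²`; the dispersion
α = 0.02 gives a per-bin coefficient of variation of ≈ 0.22 at 7.5×, a
moderately overdispersed regime typical of short-read depth. α = 0 reduces
to Poisson.

The synthetic cohort mirrors the targeted study design: two groups of 10
diploid individuals, genomes of 2 × 1 Mb with a smooth GC landscape in
[0.25, 0.65], ~30 non-overlapping genes with 3 exons each, and planted CNV
loci of 5–30 kb. Loci come in two scopes — *shared* (segregating in ≥ 4
samples of both groups) and *group-A-only* — which produces the nested
gene-set structure (every gene hit in group B also hit in group A) whose
set difference is the differential gene set. Additional intronic-only and
intergenic loci exercise the annotation filter without contributing truth
genes. Carrier counts per locus are uniform on
[max(4, n/2), n]: common variants, deliberately above the 4-sample
frequency floor so that the filter's behaviour, not detection at the
margin, determines retention. Carriers draw genotypes from {0, 1} (losses)
or {3, 4} (gains), so both homozygous and heterozygous states and the
copy-number rounding path are exercised.

Placement margins are identifiability conditions, not tuning: planted loci
keep 5 kb clearance from non-anchor genes and from each other, and
intronic loci keep 3 kb from the flanking exons. Call boundaries on noisy
data jitter by roughly a bin; without clearance, a locus's truth
annotation class (exonic/intronic/intergenic) would be ill-defined at the
scale of that jitter.

What the generator does **not** emulate: mappability structure, reference
gaps, segmental duplications, multi-allelic or overlapping CNVs within one
sample, batch effects between samples, and GC bias shapes other than a
single smooth unimodal factor. Passing tests therefore demonstrate
correctness of the pipeline's logic and its statistical behaviour under a
clean NB depth model — not performance on real alignments.

## CNV calling

Per sample: GC correction → normalisation → segmentation.

**GC correction.** Bins are stratified by rounded GC percent, adjacent
percents pooled until every stratum holds at least max(5, 4% of the
sample's bins), with bins pooled across chromosomes. Each bin is rescaled
by `global median / stratum median`. The 4% floor exists because a rare-GC
stratum can otherwise be majority-occupied by a single CNV, in which case
the stratum median absorbs exactly the signal the caller needs — a failure
mode we observed directly on synthetic cohorts. With noise-free input and
well-populated strata the correction inverts a planted multiplicative
bias exactly (tested).

**Normalisation.** The diploid baseline is the *median* corrected bin
depth over the whole sample — robust against the CNVs themselves, unlike
the mean. rd_ratio = corrected depth / baseline; copy number =
round-half-away-from-zero of 2 × rd_ratio, floored at 0.

**Segmentation.** Maximal runs of bins with ratio < 0.75 (deletion) or
> 1.25 (duplication), bridging single-bin interior gaps. Three refinements
control the behaviour of this rule under noise:

1. *Threshold-null z-test.* Every candidate's mean ratio is tested
   one-sided against the calling threshold itself — null hypothesis: the
   segment's true ratio *equals* the threshold. The null noise scale uses
   the NB mean–variance relation: the dispersion is backed out of the
   measured diploid coefficient of variation and the diploid baseline,
   then re-evaluated at the threshold ratio (counts at ratio 0.75 are less
   noisy than diploid counts; at 1.25 slightly noisier). Candidates with
   p > `max_segment_p` (default 2.5 × 10⁻³) are dropped. Chance runs of
   borderline bins sit just past the threshold and fail; real segments
   with means near 0.5, 1.5 or 2.0 pass.
2. *Boundary trimming.* Terminal bins within one null-sd of the threshold
   are trimmed. Noise bins adjacent to a true segment qualify only
   barely, so trimming stops boundary creep (which otherwise accumulates
   across the min/max span of many carriers at the CNVR level) at the
   cost of, at worst, a partially-overlapped edge bin.
3. *Stitching.* Same-direction runs separated by ≤ 3 non-qualifying bins
   are rejoined when the gap bins lean to the same side of 1 and the
   combined mean still clears the threshold. Heterozygous events sit
   close enough to the threshold that noise occasionally splits them;
   the fragments alone can lack the evidence the whole segment carries.

Finally, segments not longer than 500 bp are discarded (the "> 0.5 kb"
retention rule; strictly greater, so a single 500-bp bin never survives).
Calls are scale-invariant (ratios only) and deterministic for fixed input.

Measured per-carrier detection at 7.5×/500 bp (120 replicates per cell):
CN = 0 and CN = 4 ≈ 1.00 at ≥ 5 kb; CN = 1 ≈ 0.97–1.00 at 5.5 kb;
CN = 3 ≈ 0.78 at 5.5 kb rising to ≈ 0.92 at 8 kb. Heterozygous
duplications near the size floor are the intrinsically weakest class (an
effect of +0.25 against the noisiest count regime) and the main residual
limitation: in a few percent of cohort seeds a small all-CN3 locus falls
below the 4-sample frequency floor in one group.

## CNVR construction and filtering

Calls from different samples overlapping by **≥ 1 bp** on the same
chromosome merge transitively (single-linkage), the region extending to
the union span. Half-open abutting intervals share no base and never
merge. A sample contributing several calls to one region counts **once**
toward the region's frequency ("present in N samples" counts samples, not
calls); a sample contributing both directions is recorded as `both` and
makes the region `mixed` (otherwise `gain`/`loss`). Regions with frequency
< 4 are discarded. Merging is per group by default (each group's samples
are combined separately); a cross-cohort mode exists but is off by
default, matching the per-phenotype construction the workflow targets.
The merge is tested for exact agreement with a brute-force per-base
union-find oracle, plus idempotence, order-invariance and conservation.

## Annotation and group comparison

CNVRs are intersected with a GFF3 gene model (1-based inclusive on disk,
0-based half-open internally; conversion only at I/O boundaries).
Per CNVR/gene pair: `spanning` (region contains the gene), `exonic`
(≥ 1 bp on an exon), else `intronic`. Intronic-only hits are dropped from
gene-level outputs — purely intronic copy changes do not alter coding
dosage — and a CNVR whose hits are all intronic is not retained. The
intronic filter is applied per hit: a CNVR hitting gene X's exon and gene
Y's intron keeps X and drops Y.

Group summaries report call counts, the duplication/deletion split, size
statistics in kb, and the per-individual mean rounded half-away-from-zero
to an integer; a combined row sums counts and recomputes the mean.
The differential gene set is the symmetric difference of the two groups'
retained gene sets, with the nested case (B ⊆ A) flagged explicitly
because the symmetric difference then reduces to A-private genes.
Chromosome density tracks count CNVR midpoints per window (conserving the
total), and size histograms bin call lengths in kb.

## Enrichment

One-sided hypergeometric upper tail per term (`scipy`), P(X ≥ k) for k
study genes in a term of K population genes, study size n, population N —
tested against exhaustive combinatorial summation for N ≤ 20.
Benjamini–Hochberg step-up (`statsmodels`) adjusts across terms, ties
broken by stable sort, values capped at 1; terms with adjusted p ≤ 0.05
are flagged. Under null simulation the rate of families with any
significant term stays within the FDR budget (tested with Monte-Carlo
slack). The EASE-style modified Fisher score of some enrichment web tools
is deliberately not replicated; a plain hypergeometric tail is stated and
tested instead. No GO DAG propagation — term maps are flat (GMT or
two-column TSV).

## qPCR quantification

Standard ΔΔCT: per sample × target, ΔCt = mean(target Ct) − mean(reference
Ct) over 3 technical replicates; ΔΔCt subtracts the mean ΔCt of calibrator
samples assumed diploid at the target; relative quantity = 2^(−ΔΔCt);
copy number = 2 × relative quantity. No amplification-efficiency (Pfaffl)
correction. A CN = 0 template cannot amplify and is encoded at a 40-cycle
ceiling by the simulator. Estimates are invariant to a global Ct shift,
and noise-free tables invert exactly for CN ∈ {1, 2, 3, 4}. Because Ct
noise is additive on the log2 scale, the linear-scale CN error grows
proportionally with CN; tolerance checks are therefore relative, not
flat. Concordance with sequencing is reported two ways — direction
agreement (gain/loss/neutral vs 2) and exact rounded-integer agreement —
since "accurate copy number" admits either reading. The validation panel
defaults to 8 target regions × 6 + 6 samples.

## Numerical and degenerate-input conventions

- Rounding of copy numbers and per-individual means: half away from zero.
- All-zero depth profiles: GC correction warns and returns input; a zero
  diploid baseline is an error (degenerate profile).
- Deterministic ratio tracks (noise estimate 0) skip the z-test and
  trimming; candidates only need their mean beyond the threshold.
- Empty inputs (no calls, empty study set, empty GFF3) produce empty
  outputs, not errors; an empty qPCR/sequencing intersection is an error
  because "fraction concordant of nothing" has no value.
- Every stage logs before/after counts (calls → CNVRs → retained → genes).
- All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning; fixed seed ⇒ bit-identical outputs.

## Problem sizes

Default desk-scale conditions — 20 samples × 2 Mb at 500 bp bins — were
chosen so a full cohort simulation plus calling runs in seconds and the
complete test suite in well under a minute, while every per-bin effect
size (≈ 37.5 reads/bin) matches the targeted coverage regime. All sizes
are configurable; nothing in the implementation assumes these defaults.
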