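"""Read-depth CNV detection from binned coverage profiles.

The caller follows the classic read-depth (RD) recipe: GC-stratified median
correction of bin counts, normalisation to an rd_ratio against the sample's
diploid baseline (the median bin, robust to the CNVs themselves), and
segmentation of the ratio track into duplication/deletion segments.

Segmentation is deliberately simple and transparent: maximal runs of bins
whose ratio crosses a deletion or duplication threshold, with a small
tolerated gap, then a one-sided z-test of each candidate's mean against
the threshold itself so that borderline noise runs are rejected while
short but clean events (a homozygous deletion spanning two bins) survive.
Candidate segments not longer than ``min_len_bp`` (default 500 bp, i.e.
events must exceed 0.5 kb) are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import stats

from ._util import round_half_away

logger = logging.getLogger(__name__)

DEL = "DEL"
DUP = "DUP"


@dataclass
class DepthProfile:
    """Binned read depth for one sample on one chromosome.

    Bins tile the chromosome left to right starting at coordinate 0;
    bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)`` (the last bin may be
    truncated by the chromosome end).  ``counts`` may be real-valued after
    GC correction.
    """

    sample_id: str
    chrom: str
    bin_size: int
    counts: np.ndarray
    gc: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        if len(self.counts) != len(self.gc):
            raise ValueError(
                f"counts ({len(self.counts)}) and gc ({len(self.gc)}) lengths differ"
            )
        if np.any(self.counts < 0):
            raise ValueError("bin counts must be non-negative")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("GC fractions must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class RatioTrack:
    """Per-bin rd_ratio for one chromosome, plus the diploid baseline used."""

    sample_id: str
    chrom: str
    bin_size: int
    ratios: np.ndarray
    diploid_mean: float


@dataclass(frozen=True)
class CNVCall:
    """A per-sample duplication or deletion interval (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    rd_ratio: float
    copy_number: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.svtype not in (DEL, DUP):
            raise ValueError(f"svtype must be DEL or DUP, got {self.svtype!r}")
        if self.svtype == DEL and not self.rd_ratio < 1:
            raise ValueError("DEL calls require rd_ratio < 1")
        if self.svtype == DUP and not self.rd_ratio > 1:
            raise ValueError("DUP calls require rd_ratio > 1")
        if self.copy_number < 0:
            object.__setattr__(
                self, "copy_number", max(0, round_half_away(2 * self.rd_ratio))
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CallerParams:
    """Tunable knobs of the RD caller; defaults suit ~7.5x coverage, 500 bp bins."""

    del_thresh: float = 0.75
    dup_thresh: float = 1.25
    max_gap_bins: int = 1
    min_len_bp: int = 500
    max_segment_p: float = 2.5e-3
    boundary_trim_sd: float = 1.0
    stitch_gap_bins: int = 3
    min_gc_stratum: int = 5

    def validate(self) -> None:
        if not (0 < self.del_thresh < 1 < self.dup_thresh):
            raise ValueError(
                "thresholds must satisfy 0 < del_thresh < 1 < dup_thresh, "
                f"got {self.del_thresh}/{self.dup_thresh}"
            )
        if self.max_gap_bins < 0 or self.min_len_bp < 0:
            raise ValueError("max_gap_bins and min_len_bp must be non-negative")


def _gc_correction_factors(
    counts: np.ndarray, gc: np.ndarray, min_stratum: int = 5
) -> np.ndarray:
    """Per-bin multiplicative correction factors from GC-stratified medians.

    Bins are stratified by rounded GC percent; adjacent percents are pooled
    until every stratum holds at least max(min_stratum, 4% of bins).  The
    4% floor keeps any single CNV a minority of its stratum, so the
    stratum median stays anchored to diploid depth and cannot absorb the
    CNV signal it is meant to preserve.  Factor = global median / stratum
    median; degenerate strata (median 0) keep factor 1.
    """
    n = len(counts)
    global_median = float(np.median(counts))
    factors = np.ones(n)
    if global_median == 0 or n == 0:
        return factors
    floor = max(min_stratum, int(round(0.04 * n)))
    gc_pct = np.rint(gc * 100).astype(int)
    pcts = np.unique(gc_pct)
    groups: list[list[int]] = []
    acc: list[int] = []
    acc_size = 0
    for pct in pcts:
        acc.append(pct)
        acc_size += int((gc_pct == pct).sum())
        if acc_size >= floor:
            groups.append(acc)
            acc, acc_size = [], 0
    if acc:  # trailing undersized group joins its neighbour
        if groups:
            groups[-1].extend(acc)
        else:
            groups.append(acc)
    for grp in groups:
        mask = np.isin(gc_pct, grp)
        if mask.sum() < min_stratum:
            continue
        stratum_median = float(np.median(counts[mask]))
        if stratum_median > 0:
            factors[mask] = global_median / stratum_median
    return factors


def gc_correct(profile: DepthProfile, min_stratum: int = 5) -> DepthProfile:
    """Remove multiplicative GC bias by GC-stratified median scaling.

    Each bin's count is rescaled by global_median / stratum_median over
    pooled GC-percent strata (see ``_gc_correction_factors``).  Strata with
    fewer than ``min_stratum`` bins keep factor 1 so sparse strata cannot
    blow up the correction.  An all-zero profile is returned unchanged
    with a warning.

    When calling a whole sample prefer ``call_sample``, which pools bins
    across chromosomes before estimating the strata.
    """
    if profile.n_bins < 100:
        warnings.warn(
            f"{profile.sample_id}/{profile.chrom}: only {profile.n_bins} bins; "
            "per-GC medians may be unstable",
            stacklevel=2,
        )
    if float(np.median(profile.counts)) == 0:
        warnings.warn(
            f"{profile.sample_id}/{profile.chrom}: all-zero (median 0) profile, "
            "GC correction skipped",
            stacklevel=2,
        )
        return replace(profile, counts=profile.counts.copy())
    factors = _gc_correction_factors(profile.counts, profile.gc, min_stratum)
    return replace(profile, counts=profile.counts * factors)


def normalize(profile: DepthProfile, diploid_mean: float | None = None) -> RatioTrack:
    """Convert corrected depth to rd_ratio against the diploid baseline.

    The baseline defaults to the median bin depth of this profile; pass a
    sample-wide value (median over all chromosomes) when calling a whole
    genome so one aberrant chromosome cannot shift its own baseline.
    """
    if diploid_mean is None:
        diploid_mean = float(np.median(profile.counts))
    if diploid_mean <= 0:
        raise ValueError(
            f"{profile.sample_id}/{profile.chrom}: diploid baseline is "
            f"{diploid_mean}; profile is degenerate"
        )
    return RatioTrack(
        sample_id=profile.sample_id,
        chrom=profile.chrom,
        bin_size=profile.bin_size,
        ratios=profile.counts / diploid_mean,
        diploid_mean=diploid_mean,
    )


def _runs_with_gaps(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal [start, end) index runs of True, bridging gaps of <= max_gap False."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    run_start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((run_start, prev + 1))
            run_start = prev = i
    runs.append((run_start, prev + 1))
    return runs


def robust_ratio_sd(ratios: np.ndarray) -> float:
    """Scale of bin-to-bin ratio noise: 1.4826 * MAD about the median."""
    med = np.median(ratios)
    return float(1.4826 * np.median(np.abs(ratios - med)))


def segment_calls(
    track: RatioTrack,
    params: CallerParams | None = None,
    noise_sd: float | None = None,
) -> list[CNVCall]:
    """Segment an rd_ratio track into DEL/DUP calls.

    Qualifying bins (ratio below ``del_thresh`` or above ``dup_thresh``) are
    grouped into maximal runs tolerating up to ``max_gap_bins`` interior
    non-qualifying bins.  Each candidate's rd_ratio is the mean bin ratio
    over its span; candidates whose mean contradicts their direction or
    whose length is <= ``min_len_bp`` are dropped.

    Because short chance excursions of noisy bins all sit just past the
    threshold, each candidate must also pass a one-sided z-test of its mean
    against the threshold itself (null: the segment's true ratio equals the
    calling threshold).  The null noise scale follows the negative-binomial
    mean-variance relation: the overdispersion is backed out of the
    measured diploid coefficient of variation and the diploid baseline,
    then re-evaluated at the threshold ratio — counts at ratio 0.75 are
    less noisy than diploid counts, counts at 1.25 slightly noisier.  Real
    CNV segments have means near 0.5, 1.5 or 2.0 and pass easily; runs of
    bins that barely cleared the threshold by chance do not.

    Runs of the same direction separated by at most ``stitch_gap_bins``
    non-qualifying bins are stitched back together when the gap bins lean
    to the same side of 1 and the combined mean still clears the
    threshold: heterozygous events sit close enough to the threshold that
    noise occasionally splits them, and the fragments alone can lack the
    evidence the whole segment carries.

    Segment boundaries are then trimmed: terminal bins whose ratio is not
    at least ``boundary_trim_sd`` noise-sds beyond the threshold are
    removed.  Noise bins adjacent to a true segment sit just past the
    threshold by construction, so trimming stops boundary creep at the
    cost of, at worst, a partially overlapped edge bin of a real event.

    ``noise_sd`` lets the caller supply a genome-wide noise estimate;
    otherwise it is estimated from this track.  A noise estimate of zero
    (deterministic tracks) keeps every candidate whose mean clears the
    threshold.
    """
    params = params or CallerParams()
    params.validate()
    ratios = track.ratios
    if ratios.size == 0:
        return []
    if noise_sd is None:
        noise_sd = robust_ratio_sd(ratios)

    # overdispersion from the diploid cv; null noise re-evaluated at the
    # threshold ratio via the NB mean-variance relation
    dip = track.diploid_mean
    alpha = max(noise_sd**2 - 1.0 / dip, 0.0) if dip > 0 else 0.0

    def null_sd(r: float) -> float:
        if noise_sd == 0 or dip <= 0:
            return 0.0
        return r * np.sqrt(1.0 / (r * dip) + alpha)

    calls: list[CNVCall] = []
    for svtype, mask in (
        (DEL, ratios < params.del_thresh),
        (DUP, ratios > params.dup_thresh),
    ):
        thresh = params.del_thresh if svtype == DEL else params.dup_thresh
        sd0 = null_sd(thresh)
        if sd0 > 0 and params.boundary_trim_sd > 0:
            pad = params.boundary_trim_sd * sd0
            if svtype == DEL:
                strong = ratios <= params.del_thresh - pad
            else:
                strong = ratios >= params.dup_thresh + pad
        else:
            strong = mask
        runs = _runs_with_gaps(mask, params.max_gap_bins)
        # stitch same-direction runs across short, same-leaning gaps
        stitched: list[tuple[int, int]] = []
        for i0, i1 in runs:
            if stitched:
                p0, p1 = stitched[-1]
                gap = ratios[p1:i0]
                gap_leans = (
                    gap.size > 0
                    and (gap.mean() < 1 if svtype == DEL else gap.mean() > 1)
                )
                combined = ratios[p0:i1].mean()
                qualifies = (
                    combined < params.del_thresh
                    if svtype == DEL
                    else combined > params.dup_thresh
                )
                if i0 - p1 <= params.stitch_gap_bins and gap_leans and qualifies:
                    stitched[-1] = (p0, i1)
                    continue
            stitched.append((i0, i1))
        for i0, i1 in stitched:
            while i1 > i0 and not strong[i1 - 1]:
                i1 -= 1
            while i1 > i0 and not strong[i0]:
                i0 += 1
            if i1 <= i0:
                continue
            seg = ratios[i0:i1]
            mean = float(seg.mean())
            if svtype == DEL and not mean < 1:
                continue
            if svtype == DUP and not mean > 1:
                continue
            start = i0 * track.bin_size
            end = i1 * track.bin_size
            if end - start <= params.min_len_bp:
                continue
            excess = thresh - mean if svtype == DEL else mean - thresh
            if sd0 > 0:
                z = excess * np.sqrt(i1 - i0) / sd0
                if stats.norm.sf(z) > params.max_segment_p:
                    continue
            elif excess <= 0:
                continue
            calls.append(
                CNVCall(
                    sample_id=track.sample_id,
                    chrom=track.chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    rd_ratio=mean,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def call_sample(
    profiles: Iterable[DepthProfile] | DepthProfile,
    params: CallerParams | None = None,
) -> list[CNVCall]:
    """Full per-sample pipeline: GC-correct, normalise, segment.

    Accepts one profile or one per chromosome; the diploid baseline and the
    noise scale are estimated once across all chromosomes of the sample.
    Deterministic for fixed input.
    """
    if isinstance(profiles, DepthProfile):
        profiles = [profiles]
    params = params or CallerParams()
    params.validate()

    # GC strata estimated once over the whole sample: pooling chromosomes
    # doubles the support behind every stratum median
    profiles = list(profiles)
    pooled_counts = np.concatenate([p.counts for p in profiles])
    pooled_gc = np.concatenate([p.gc for p in profiles])
    if float(np.median(pooled_counts)) == 0:
        raise ValueError("sample median depth is 0; cannot normalise")
    factors = _gc_correction_factors(
        pooled_counts, pooled_gc, min_stratum=params.min_gc_stratum
    )
    corrected = []
    offset = 0
    for p in profiles:
        f = factors[offset : offset + p.n_bins]
        corrected.append(replace(p, counts=p.counts * f))
        offset += p.n_bins
    all_counts = np.concatenate([p.counts for p in corrected])
    diploid = float(np.median(all_counts))
    if diploid <= 0:
        raise ValueError("sample diploid baseline is 0; cannot normalise")

    tracks = [normalize(p, diploid_mean=diploid) for p in corrected]
    noise_sd = robust_ratio_sd(np.concatenate([t.ratios for t in tracks]))

    calls: list[CNVCall] = []
    for track in tracks:
        calls.extend(segment_calls(track, params, noise_sd=noise_sd))
    calls.sort(key=lambda c: (c.chrom, c.start))
    logger.info(
        "%s: %d calls (%d DEL, %d DUP), diploid baseline %.2f",
        corrected[0].sample_id if corrected else "?",
        len(calls),
        sum(c.svtype == DEL for c in calls),
        sum(c.svtype == DUP for c in calls),
        diploid,
    )
    return calls


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap fraction of two half-open intervals (0 if disjoint)."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0], b[1] - b[0])
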