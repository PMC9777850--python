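"""Merging per-sample CNV calls into cross-sample CNV regions (CNVRs).

Calls from different individuals that overlap by at least 1 bp on the same
chromosome are merged transitively, the region boundary extending to the
union span.  Half-open abutting intervals share no base and are NOT merged.
A frequency filter then keeps regions supported by a minimum number of
distinct samples (default 4), which suppresses private false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .rd_caller import DEL, DUP, CNVCall

logger = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"
MIXED = "mixed"


@dataclass
class CNVR:
    """A merged cross-sample CNV region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    per_sample_svtype: dict[str, str] = field(default_factory=dict)
    members: list[CNVCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty CNVR [{self.start},{self.end})")

    @property
    def supporting_samples(self) -> set[str]:
        return set(self.per_sample_svtype)

    @property
    def frequency(self) -> int:
        """Number of distinct supporting samples (calls never count twice)."""
        return len(self.per_sample_svtype)

    @property
    def cnvr_class(self) -> str:
        return classify(self)

    @property
    def length(self) -> int:
        return self.end - self.start


def classify(cnvr: CNVR) -> str:
    """gain if every sample carries only DUP, loss if only DEL, else mixed."""
    types = set(cnvr.per_sample_svtype.values())
    if types == {DUP}:
        return GAIN
    if types == {DEL}:
        return LOSS
    return MIXED


def merge_cnvrs(calls: Iterable[CNVCall]) -> list[CNVR]:
    """Single-linkage merge of calls overlapping by >= 1 bp into CNVRs.

    The transitive closure of the 1-bp-overlap relation forms one CNVR per
    connected component, spanning min(start)..max(end) of its members.  A
    sample contributing both a DUP and a DEL to one region is recorded once
    with svtype ``both``.  Output is sorted by (chrom, start); CNVRs on one
    chromosome are pairwise disjoint by construction.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    out: list[CNVR] = []
    cur: list[CNVCall] = []

    def flush() -> None:
        if not cur:
            return
        sv: dict[str, str] = {}
        for c in cur:
            prev = sv.get(c.sample_id)
            if prev is None:
                sv[c.sample_id] = c.svtype
            elif prev != c.svtype and prev != "both":
                sv[c.sample_id] = "both"
        out.append(
            CNVR(
                chrom=cur[0].chrom,
                start=min(c.start for c in cur),
                end=max(c.end for c in cur),
                per_sample_svtype=sv,
                members=list(cur),
            )
        )

    cur_chrom: str | None = None
    cur_end = -1
    for c in ordered:
        if c.chrom != cur_chrom or c.start >= cur_end:
            flush()
            cur = [c]
            cur_chrom = c.chrom
            cur_end = c.end
        else:
            cur.append(c)
            cur_end = max(cur_end, c.end)
    flush()
    logger.info("merged %d calls into %d CNVRs", len(ordered), len(out))
    return out


def frequency_filter(cnvrs: Sequence[CNVR], min_samples: int = 4) -> list[CNVR]:
    """Keep CNVRs supported by at least ``min_samples`` distinct samples."""
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    kept = [r for r in cnvrs if r.frequency >= min_samples]
    logger.info(
        "frequency filter (>= %d samples): %d -> %d CNVRs",
        min_samples,
        len(cnvrs),
        len(kept),
    )
    return kept
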