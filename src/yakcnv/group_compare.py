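"""Two-group reporting: call summaries, size distributions, differential
gene sets, and chromosome CNVR density tracks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .cnvr import CNVR
from .rd_caller import DEL, DUP, CNVCall


@dataclass(frozen=True)
class GroupSummary:
    """Per-group CNV call statistics (one row of a cohort summary table).

    ``mean_cnvs_per_individual`` is the total call count divided by the
    sample count, rounded half away from zero to an integer, the convention
    used in cohort summary tables.  Size statistics are in kb (1 kb =
    1000 bp) and NaN when no raw sizes are available (e.g. a combined row
    built from counts only).
    """

    group_name: str
    n_samples: int
    n_dup: int
    n_del: int
    size_mean_kb: float = float("nan")
    size_median_kb: float = float("nan")
    size_min_kb: float = float("nan")
    size_max_kb: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_dup < 0 or self.n_del < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cnvs(self) -> int:
        return self.n_dup + self.n_del

    @property
    def mean_cnvs_per_individual(self) -> int:
        return round_half_away(self.n_cnvs / self.n_samples)


def summarize_group(
    calls: Sequence[CNVCall], n_samples: int, group_name: str = "group"
) -> GroupSummary:
    """Summarise one group's calls: counts, dup/del split, size stats in kb."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    sizes_kb = np.array([c.length / 1000.0 for c in calls])
    if sizes_kb.size:
        stats = dict(
            size_mean_kb=float(sizes_kb.mean()),
            size_median_kb=float(np.median(sizes_kb)),
            size_min_kb=float(sizes_kb.min()),
            size_max_kb=float(sizes_kb.max()),
        )
    else:
        stats = {}
    return GroupSummary(
        group_name=group_name,
        n_samples=n_samples,
        n_dup=sum(c.svtype == DUP for c in calls),
        n_del=sum(c.svtype == DEL for c in calls),
        **stats,
    )


def combine_summaries(
    summaries: Sequence[GroupSummary], name: str = "total"
) -> GroupSummary:
    """Overall row: counts and samples summed, per-individual mean recomputed."""
    if not summaries:
        raise ValueError("need at least one summary")
    return GroupSummary(
        group_name=name,
        n_samples=sum(s.n_samples for s in summaries),
        n_dup=sum(s.n_dup for s in summaries),
        n_del=sum(s.n_del for s in summaries),
    )


def summary_table(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = [
        {
            "group": s.group_name,
            "n_samples": s.n_samples,
            "cnvs": s.n_cnvs,
            "duplication": s.n_dup,
            "deletion": s.n_del,
            "individual_average_cnvs": s.mean_cnvs_per_individual,
            "size_mean_kb": s.size_mean_kb,
            "size_median_kb": s.size_median_kb,
            "size_min_kb": s.size_min_kb,
            "size_max_kb": s.size_max_kb,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiffResult:
    """Set algebra of two groups' gene sets.

    ``differential`` is the symmetric difference; ``b_subset_of_a`` flags
    the nested case where it reduces to the A-private genes.
    """

    genes_a: frozenset[str]
    genes_b: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.genes_a & self.genes_b

    @property
    def only_a(self) -> frozenset[str]:
        return self.genes_a - self.genes_b

    @property
    def only_b(self) -> frozenset[str]:
        return self.genes_b - self.genes_a

    @property
    def differential(self) -> frozenset[str]:
        return self.only_a | self.only_b

    @property
    def b_subset_of_a(self) -> bool:
        return self.genes_b <= self.genes_a


def differential_genes(genes_a: Iterable[str], genes_b: Iterable[str]) -> DiffResult:
    return DiffResult(genes_a=frozenset(genes_a), genes_b=frozenset(genes_b))


def cnvr_density(
    cnvrs: Sequence[CNVR],
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
) -> pd.DataFrame:
    """Windowed CNVR counts per chromosome (bedGraph-shaped frame).

    Each CNVR is assigned to the window containing its midpoint, so the
    track total always equals the CNVR count.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // window))
        counts = np.zeros(n_win, dtype=int)
        for r in cnvrs:
            if r.chrom == chrom:
                mid = (r.start + r.end) // 2
                counts[min(mid // window, n_win - 1)] += 1
        for i in range(n_win):
            rows.append(
                {
                    "chrom": chrom,
                    "start": i * window,
                    "end": min((i + 1) * window, length),
                    "count": int(counts[i]),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def size_histogram(
    calls: Sequence[CNVCall], bin_edges_kb: Sequence[float]
) -> pd.DataFrame:
    """Histogram of call sizes (kb) over [e0,e1), [e1,e2), ..., last bin closed.

    All sizes must fall inside the edges so counts conserve the call count.
    """
    edges = np.asarray(bin_edges_kb, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges_kb must be strictly increasing, length >= 2")
    sizes = np.array([c.length / 1000.0 for c in calls])
    if sizes.size and (sizes.min() < edges[0] or sizes.max() > edges[-1]):
        raise ValueError("call sizes fall outside the histogram edges")
    counts, _ = np.histogram(sizes, bins=edges)
    return pd.DataFrame(
        {"low_kb": edges[:-1], "high_kb": edges[1:], "count": counts.astype(int)}
    )
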