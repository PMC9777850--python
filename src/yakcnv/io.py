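"""File formats: depth TSV/bedGraph, BED, symbolic-allele VCF, gene lists.

Internal coordinates are universally 0-based half-open; conversions to the
1-based inclusive conventions of VCF happen only here, at the boundary.
An internal interval [start, end) becomes VCF POS = start + 1 with INFO
END = end; the mapping is its own exact inverse.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cnvr import CNVR
from .rd_caller import DEL, DUP, CNVCall, DepthProfile
from .synthetic import GenomeModel

# --------------------------------------------------------------------------
# coordinate conversions (0-based half-open <-> 1-based inclusive)
# --------------------------------------------------------------------------


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """[start, end) half-open -> (first, last) 1-based inclusive."""
    if end <= start:
        raise ValueError(f"empty interval [{start},{end})")
    return start + 1, end


def to_zero_based(first: int, last: int) -> tuple[int, int]:
    """(first, last) 1-based inclusive -> [start, end) half-open."""
    if last < first:
        raise ValueError(f"inverted interval {first}..{last}")
    return first - 1, last


# --------------------------------------------------------------------------
# depth profiles (4-column bedGraph-style TSV) + GC track
# --------------------------------------------------------------------------


def write_depth(profiles: Sequence[DepthProfile], path: str | Path) -> None:
    """One sample's binned depth as chrom/start/end/count TSV."""
    with Path(path).open("w") as fh:
        for p in profiles:
            starts = np.arange(p.n_bins, dtype=np.int64) * p.bin_size
            for s, c in zip(starts, p.counts):
                fh.write(f"{p.chrom}\t{s}\t{s + p.bin_size}\t{c:g}\n")


def write_gc_track(genome: GenomeModel, bin_size: int, path: str | Path) -> None:
    """Per-bin GC fractions for all chromosomes (pairs with write_depth)."""
    with Path(path).open("w") as fh:
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            gc = genome.bin_gc(chrom, bin_size)
            for i, g in enumerate(gc):
                s = i * bin_size
                fh.write(f"{chrom}\t{s}\t{min(s + bin_size, length)}\t{g:.6f}\n")


def read_depth(
    depth_path: str | Path, gc_path: str | Path, sample_id: str
) -> list[DepthProfile]:
    """Rebuild per-chromosome profiles from a depth TSV and its GC track."""
    depth = pd.read_csv(
        depth_path, sep="\t", names=["chrom", "start", "end", "count"]
    )
    gc = pd.read_csv(gc_path, sep="\t", names=["chrom", "start", "end", "gc"])
    profiles = []
    for chrom, sub in depth.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        gsub = gc[gc["chrom"] == chrom].sort_values("start")
        if len(gsub) != len(sub):
            raise ValueError(
                f"{chrom}: depth has {len(sub)} bins but GC track has {len(gsub)}"
            )
        bin_size = int(sub["end"].iloc[0] - sub["start"].iloc[0])
        profiles.append(
            DepthProfile(
                sample_id=sample_id,
                chrom=str(chrom),
                bin_size=bin_size,
                counts=sub["count"].to_numpy(dtype=float),
                gc=gsub["gc"].to_numpy(dtype=float),
            )
        )
    return profiles


# --------------------------------------------------------------------------
# BED (calls and CNVRs)
# --------------------------------------------------------------------------


def write_calls_bed(calls: Sequence[CNVCall], path: str | Path) -> None:
    """Per-sample calls: chrom start end svtype copy_number sample rd_ratio."""
    with Path(path).open("w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.start)):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.svtype}\t{c.copy_number}\t"
                f"{c.sample_id}\t{c.rd_ratio:.4f}\n"
            )


def read_calls_bed(path: str | Path) -> list[CNVCall]:
    calls = []
    prev: tuple[str, int] | None = None
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            svtype, cn, sample, ratio = parts[3], int(parts[4]), parts[5], float(parts[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed row ({exc})") from exc
        key = (chrom, start)
        if prev is not None and key < prev:
            raise ValueError(f"{path}:{ln}: rows not sorted by (chrom, start)")
        prev = key
        calls.append(
            CNVCall(
                sample_id=sample, chrom=chrom, start=start, end=end,
                svtype=svtype, rd_ratio=ratio, copy_number=cn,
            )
        )
    return calls


def write_cnvr_bed(cnvrs: Sequence[CNVR], path: str | Path) -> None:
    """CNVRs with frequency, class and supporting samples as extra columns."""
    with Path(path).open("w") as fh:
        for r in sorted(cnvrs, key=lambda r: (r.chrom, r.start)):
            samples = ",".join(sorted(r.supporting_samples))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.cnvr_class}\t{r.frequency}\t"
                f"{samples}\n"
            )


# --------------------------------------------------------------------------
# VCF 4.2 with symbolic <DEL>/<DUP> alleles
# --------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=yakcnv
##ALT=<ID=DEL,Description="Deletion relative to the reference">
##ALT=<ID=DUP,Description="Duplication relative to the reference">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=RDRATIO,Number=1,Type=Float,Description="Segment read-depth ratio">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Estimated copy number">
##INFO=<ID=SAMPLES,Number=.,Type=String,Description="Supporting sample ids">
"""


def _contig_lines(chrom_lengths: Mapping[str, int] | None, chroms: Iterable[str]) -> str:
    if chrom_lengths:
        return "".join(
            f"##contig=<ID={c},length={l}>\n" for c, l in chrom_lengths.items()
        )
    return "".join(f"##contig=<ID={c}>\n" for c in dict.fromkeys(chroms))


def write_calls_vcf(
    calls: Sequence[CNVCall],
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Per-sample calls as symbolic-allele VCF records."""
    with Path(path).open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(chrom_lengths, (c.chrom for c in calls)))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(sorted(calls, key=lambda c: (c.chrom, c.start)), 1):
            pos, end = to_one_based(c.start, c.end)
            svlen = c.length if c.svtype == DUP else -c.length
            fh.write(
                f"{c.chrom}\t{pos}\t{c.sample_id}_cnv{i}\tN\t<{c.svtype}>\t.\t.\t"
                f"END={end};SVLEN={svlen};SVTYPE={c.svtype};"
                f"RDRATIO={c.rd_ratio:.4f};CN={c.copy_number};SAMPLES={c.sample_id}\n"
            )


def read_calls_vcf(path: str | Path) -> list[CNVCall]:
    """Parse symbolic-allele records back into calls (INFO END is mandatory).

    The raw INFO/END value is used directly (1-based inclusive), so the
    conversion back to half-open coordinates is the exact inverse of the
    writer regardless of how a VCF library reinterprets SVLEN.
    """
    calls = []
    for rec in VCF(str(path)):
        end = rec.INFO.get("END")
        if end is None:
            raise ValueError(f"{path}: record at {rec.CHROM}:{rec.POS} lacks END")
        end = int(end)
        if end < rec.POS:
            raise ValueError(
                f"{path}: END {end} < POS {rec.POS} at {rec.CHROM}:{rec.POS}"
            )
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in (DEL, DUP):
            raise ValueError(f"{path}: unsupported SVTYPE {svtype}")
        start, stop = to_zero_based(rec.POS, end)
        samples = str(rec.INFO.get("SAMPLES") or "unknown").split(",")
        ratio = rec.INFO.get("RDRATIO")
        if ratio is None:
            ratio = 0.5 if svtype == DEL else 1.5  # CNVR records carry no ratio
        cn = rec.INFO.get("CN")
        calls.append(
            CNVCall(
                sample_id=samples[0],
                chrom=rec.CHROM,
                start=start,
                end=stop,
                svtype=svtype,
                rd_ratio=float(ratio),
                copy_number=int(cn) if cn is not None else -1,
            )
        )
    return calls


def write_cnvr_vcf(
    cnvrs: Sequence[CNVR],
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Per-group merged CNVRs as one VCF (class mapped to DEL/DUP; mixed -> DUP+DEL carriers listed)."""
    with Path(path).open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(chrom_lengths, (r.chrom for r in cnvrs)))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(sorted(cnvrs, key=lambda r: (r.chrom, r.start)), 1):
            pos, end = to_one_based(r.start, r.end)
            alt = {"gain": "DUP", "loss": "DEL"}.get(r.cnvr_class, "DUP")
            samples = ",".join(sorted(r.supporting_samples))
            fh.write(
                f"{r.chrom}\t{pos}\tcnvr{i}\tN\t<{alt}>\t.\t.\t"
                f"END={end};SVLEN={r.length if alt == 'DUP' else -r.length};"
                f"SVTYPE={alt};SAMPLES={samples}\n"
            )


# --------------------------------------------------------------------------
# gene lists / tables
# --------------------------------------------------------------------------


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> set[str]:
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
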