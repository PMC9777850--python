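"""Gene-overlap annotation of CNVRs and intronic-variant removal.

CNVRs are intersected with a GFF3 gene model.  Each CNVR/gene pair is
classified as

* ``spanning`` — the CNVR fully contains the gene span,
* ``exonic``   — the CNVR overlaps at least one exon of the gene,
* ``intronic`` — the CNVR overlaps the gene span but no exon.

Hits touching only intronic sequence are flagged non-retained: gene-level
outputs keep exon-affecting variants only, since purely intronic copy
changes do not alter coding dosage.  CNVRs with no gene overlap are
intergenic and contribute nothing to gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from intervaltree import IntervalTree

from .cnvr import CNVR

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Gene:
    """One gene with 0-based half-open coordinates (converted from GFF3)."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty span [{self.start},{self.end})")


@dataclass
class GeneModel:
    """Genes plus per-gene exon intervals, everything 0-based half-open."""

    genes: list[Gene]
    exons: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        by_id = {g.gene_id: g for g in self.genes}
        if len(by_id) != len(self.genes):
            raise ValueError("duplicate gene_ids in gene model")
        for gid, ivs in self.exons.items():
            if gid not in by_id:
                raise ValueError(f"exons reference unknown gene {gid}")
            g = by_id[gid]
            for s, e in ivs:
                if not (g.start <= s < e <= g.end):
                    raise ValueError(
                        f"exon [{s},{e}) outside gene {gid} span [{g.start},{g.end})"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        return next(g for g in self.genes if g.gene_id == gene_id)


@dataclass
class GeneHit:
    gene_id: str
    region_class: str  # exonic | intronic | spanning

    @property
    def retained(self) -> bool:
        return self.region_class != "intronic"


@dataclass
class AnnotatedCNVR:
    cnvr: CNVR
    hits: list[GeneHit] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        """True if at least one hit affects exonic sequence."""
        return any(h.retained for h in self.hits)


def read_gff3(path: str | Path) -> GeneModel:
    """Load gene and exon features from a GFF3 file.

    GFF3 1-based inclusive coordinates become 0-based half-open internally.
    Exons must name a known gene via Parent (directly or through an mRNA);
    orphan exons are an error.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return GeneModel(genes=[], exons={})
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ValueError(f"{path}: malformed GFF3 ({exc})") from exc

    genes: list[Gene] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    gene_ids: set[str] = set()
    for f in db.features_of_type("gene"):
        name = f.attributes.get("Name", [f.id])[0]
        genes.append(
            Gene(
                gene_id=f.id,
                name=name,
                chrom=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand or "+",
            )
        )
        gene_ids.add(f.id)
        exons[f.id] = []

    for f in db.features_of_type("exon"):
        parents = f.attributes.get("Parent", [])
        owner = None
        for p in parents:
            if p in gene_ids:
                owner = p
                break
            # exon -> mRNA -> gene
            try:
                pf = db[p]
            except gffutils.FeatureNotFoundError:
                continue
            for pp in pf.attributes.get("Parent", []):
                if pp in gene_ids:
                    owner = pp
                    break
        if owner is None:
            raise ValueError(
                f"{path}: exon at {f.seqid}:{f.start}-{f.end} has no gene parent"
            )
        exons[owner].append((f.start - 1, f.end))

    for gid in exons:
        exons[gid].sort()
    model = GeneModel(genes=genes, exons=exons)
    logger.info(
        "%s: %d genes, %d exons", path.name, len(genes), sum(map(len, exons.values()))
    )
    return model


def write_gff3(model: GeneModel, path: str | Path) -> None:
    """Write the gene model back out as GFF3 (gene + exon features)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(model.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tyakcnv\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.name}\n"
            )
            for i, (s, e) in enumerate(model.exons.get(g.gene_id, []), start=1):
                fh.write(
                    f"{g.chrom}\tyakcnv\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def overlap_genes(
    cnvrs: Iterable[CNVR], model: GeneModel
) -> list[AnnotatedCNVR]:
    """Annotate each CNVR with overlapping genes (>= 1 bp on the gene span)."""
    trees: dict[str, IntervalTree] = {}
    for g in model.genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    cnvrs = list(cnvrs)
    missing = {c.chrom for c in cnvrs if c.chrom not in trees}
    if missing and model.genes:
        warnings.warn(
            f"{len(missing)} CNVR chromosome(s) absent from gene model: "
            f"{sorted(missing)}",
            stacklevel=2,
        )

    out: list[AnnotatedCNVR] = []
    for c in cnvrs:
        hits: list[GeneHit] = []
        for iv in sorted(trees.get(c.chrom, IntervalTree()).overlap(c.start, c.end)):
            g: Gene = iv.data
            if c.start <= g.start and c.end >= g.end:
                cls = "spanning"
            elif any(
                min(c.end, e) > max(c.start, s) for s, e in model.exons.get(g.gene_id, [])
            ):
                cls = "exonic"
            else:
                cls = "intronic"
            hits.append(GeneHit(gene_id=g.gene_id, region_class=cls))
        out.append(AnnotatedCNVR(cnvr=c, hits=hits))
    return out


def gene_set(
    annotated: Iterable[AnnotatedCNVR], retained_only: bool = True
) -> set[str]:
    """Distinct gene ids hit by the CNVRs.

    With ``retained_only`` (default) intronic-only hits are excluded, which
    is the gene list used for comparative and enrichment analysis.
    """
    genes: set[str] = set()
    for ann in annotated:
        for h in ann.hits:
            if h.retained or not retained_only:
                genes.add(h.gene_id)
    return genes
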