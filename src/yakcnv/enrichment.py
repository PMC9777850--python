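"""Term enrichment of a study gene set: hypergeometric upper tail + BH-FDR.

Given a study set of n genes from a population of N, a term annotating K
population genes, and k study genes in the term, the enrichment p-value is
the upper-tail hypergeometric probability P(X >= k).  Benjamini–Hochberg
step-up adjustment across terms controls the FDR; terms with adjusted
p <= alpha (default 0.05) are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("biological process", "cellular component", "molecular function")


@dataclass
class TermMap:
    """Flat term -> gene-set map plus (name, category) metadata per term."""

    terms: dict[str, set[str]]
    meta: dict[str, tuple[str, str]]

    def population_check(self, population: set[str]) -> None:
        for tid, genes in self.terms.items():
            extra = genes - population
            if extra:
                raise ValueError(
                    f"term {tid} annotates genes outside the population: "
                    f"{sorted(extra)[:5]}"
                )

    @classmethod
    def from_gmt(cls, path: str | Path) -> "TermMap":
        """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
        terms: dict[str, set[str]] = {}
        meta: dict[str, tuple[str, str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            terms[parts[0]] = set(parts[2:])
            meta[parts[0]] = (parts[1], "biological process")
        return cls(terms=terms, meta=meta)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermMap":
        """Two-column TSV: term_id <tab> gene_id (one pair per line)."""
        terms: dict[str, set[str]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 2 columns, got {len(parts)}")
            terms.setdefault(parts[0], set()).add(parts[1])
        meta = {t: (t, "biological process") for t in terms}
        return cls(terms=terms, meta=meta)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    category: str
    k: int  # study genes in term
    K: int  # population genes in term
    n: int  # study size
    N: int  # population size
    p_value: float
    adjusted_p: float
    genes: tuple[str, ...]

    @property
    def significant(self) -> bool:
        return bool(self.adjusted_p <= 0.05)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for X ~ HG(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study_set: Iterable[str],
    term_map: TermMap,
    population: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Test every term with >= 1 study gene; BH-adjust; sort by adjusted p.

    Study genes must be a subset of the population (the gene universe the
    terms annotate); violations are reported by name.
    """
    study = set(study_set)
    pop = set(population)
    outside = study - pop
    if outside:
        raise ValueError(
            f"{len(outside)} study gene(s) outside the population: "
            f"{sorted(outside)[:10]}"
        )
    term_map.population_check(pop)

    n, N = len(study), len(pop)
    rows = []
    for tid in sorted(term_map.terms):
        genes = term_map.terms[tid]
        hit = study & genes
        if not hit:
            continue
        p = hypergeom_test(len(hit), len(genes), n, N)
        name, cat = term_map.meta.get(tid, (tid, "biological process"))
        rows.append((tid, name, cat, len(hit), len(genes), p, tuple(sorted(hit))))

    adj = bh_adjust([r[5] for r in rows])
    out = [
        EnrichmentRow(
            term_id=tid, name=name, category=cat, k=k, K=K, n=n, N=N,
            p_value=p, adjusted_p=float(q), genes=genes,
        )
        for (tid, name, cat, k, K, p, genes), q in zip(rows, adj)
    ]
    out.sort(key=lambda r: (r.adjusted_p, r.term_id))
    # alpha only affects the significance flag downstream; all rows returned
    return out


def enrichment_table(rows: Iterable[EnrichmentRow], alpha: float = 0.05) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "category": r.category,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "significant": r.adjusted_p <= alpha,
                "genes": ",".join(r.genes),
            }
            for r in rows
        ]
    )
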