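"""Gene assignment for DMRs and Fisher-exact functional enrichment.

A gene is associated with a region when the gap between the two
intervals is at most 5 kb (0 when they overlap or abut); strand is
ignored. Enrichment of annotation terms among DMR-associated genes is
the classic one-sided Fisher / hypergeometric over-representation test
against a gene universe; no term-hierarchy decorrelation is applied, so
p-values of related terms are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_fdr
from .io import GenomicInterval

__all__ = [
    "GeneRecord",
    "read_genes",
    "read_gene2go",
    "assign_genes_to_regions",
    "go_fisher_enrichment",
]


@dataclass
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    go_terms: set[str] = field(default_factory=set)


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read genes from BED-like TSV: chrom, start, end, gene_id[, strand]."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            strand = f[4] if len(f) > 4 else (f[5] if len(f) > 5 else ".")
            genes.append(
                GeneRecord(f[3], GenomicInterval(f[0], int(f[1]), int(f[2]), f[3], strand))
            )
    return genes


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene -> term TSV into a mapping."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, term = line.rstrip("\n").split("\t")[:2]
            mapping.setdefault(gene, set()).add(term)
    return mapping


def assign_genes_to_regions(
    regions: list,
    genes: list[GeneRecord],
    flank_bp: int = 5000,
) -> dict:
    """Map each region to the gene ids within ``flank_bp`` of it.

    Distance is the interval gap under half-open coordinates (zero for
    overlapping or abutting pairs); the gene body, not the TSS, anchors
    the measurement. Returns {region: set of gene_ids} keyed by the
    region objects in input order.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    out = {}
    for r in regions:
        riv = r if isinstance(r, GenomicInterval) else GenomicInterval(
            r.chrom, r.start, r.end, getattr(r, "name", "")
        )
        hits = {
            g.gene_id
            for g in by_chrom.get(riv.chrom, ())
            if riv.gap_to(g.interval) <= flank_bp
        }
        out[r] = hits
    return out


def go_fisher_enrichment(
    study_genes: set[str],
    universe_genes: set[str],
    gene2go: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per annotation term.

    For a term carried by K of the N universe genes and k of the n
    study genes, p = P(X >= k) with X ~ Hypergeom(N, K, n). Terms absent
    from the study set are omitted. A BH-adjusted column is included for
    convenience; the selection convention is on the raw p.
    """
    if not study_genes <= universe_genes:
        raise ValueError("study genes must be a subset of the universe")
    if not study_genes:
        return pd.DataFrame(
            columns=["term_id", "k_sig", "n_sig", "K_bg", "N_bg", "p", "bh"]
        )
    N = len(universe_genes)
    n = len(study_genes)
    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe_genes:
        for term in gene2go.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in study_genes:
                term_study[term] = term_study.get(term, 0) + 1
    rows = []
    for term, k in sorted(term_study.items()):
        K = term_universe[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k_sig": k, "n_sig": n, "K_bg": K, "N_bg": N, "p": p})
    df = pd.DataFrame(rows)
    df["bh"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values("p", kind="stable").reset_index(drop=True)
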