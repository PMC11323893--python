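"""Cohort-level statistics: SV density, gene-SV overlap, level-2
functional enrichment with Benjamini-Hochberg FDR, lifestyle
comparisons, and the phage-bacteria SV-sharing network."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exchange import GEClassification
from .model import AbundanceMatrix, GeneRecord, SVCluster, SVRecord, SVType, TaxonLineage

logger = logging.getLogger(__name__)


def sv_density(
    sv_counts: Mapping[str, int],
    genome_lengths: Mapping[str, int],
) -> dict[str, float]:
    """SVs per 1 Mb of genome, per genome."""
    out = {}
    for gid, count in sv_counts.items():
        if gid not in genome_lengths:
            raise KeyError(f"no length for genome {gid!r}")
        out[gid] = count * 1e6 / genome_lengths[gid]
    return out


def gene_sv_overlap(
    genes: Sequence[GeneRecord],
    svs: Sequence[SVRecord],
) -> dict[str, str]:
    """Label each gene "SV" or "conserved".

    A gene is in an SV region iff its half-open interval intersects a
    DEL/DUP/INV interval by at least 1 bp, or contains the breakpoint
    (start position) of an INS.
    """
    by_genome: dict[str, list[SVRecord]] = {}
    for sv in svs:
        by_genome.setdefault(sv.contig, []).append(sv)
    labels = {}
    for gene in genes:
        label = "conserved"
        for sv in by_genome.get(gene.genome_id, ()):
            if sv.svtype is SVType.INS:
                if gene.start <= sv.start < gene.end:
                    label = "SV"
                    break
            elif min(gene.end, sv.end) - max(gene.start, sv.start) > 0:
                label = "SV"
                break
        labels[gene.gene_id] = label
    return labels


@dataclass(frozen=True)
class EnrichmentRow:
    """One 2x2 enrichment table: category membership x region label."""

    category: str
    a: int   # category genes in SV regions
    b: int   # other genes in SV regions
    c: int   # category genes in conserved regions
    d: int   # other genes in conserved regions
    odds_ratio: float
    p: float
    q: float = math.nan


def _fisher_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (over-representation in SV regions) Fisher exact test."""
    odds = math.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c else math.nan
    )
    # P(X >= a), X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b)
    p = float(sps.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    return odds, min(p, 1.0)


def functional_enrichment(
    gene_labels: Mapping[str, str],
    gene_categories: Mapping[str, str],
    categories: Optional[Sequence[str]] = None,
) -> list[EnrichmentRow]:
    """Per-category over-representation of SV-region genes.

    One-sided hypergeometric p per level-2 category, Benjamini-Hochberg
    adjusted across the categories tested in this run; rows come back
    sorted by q then category name.
    """
    sv_genes = [g for g, lab in gene_labels.items() if lab == "SV"]
    cons_genes = [g for g, lab in gene_labels.items() if lab == "conserved"]
    if categories is None:
        categories = sorted({gene_categories[g] for g in gene_labels
                             if g in gene_categories})
    rows = []
    for cat in categories:
        a = sum(1 for g in sv_genes if gene_categories.get(g) == cat)
        c = sum(1 for g in cons_genes if gene_categories.get(g) == cat)
        b = len(sv_genes) - a
        d = len(cons_genes) - c
        if a == 0 and c == 0:
            rows.append(EnrichmentRow(cat, a, b, c, d, math.nan, 1.0))
        else:
            odds, p = _fisher_greater(a, b, c, d)
            rows.append(EnrichmentRow(cat, a, b, c, d, odds, p))
    if rows:
        qs = multipletests([r.p for r in rows], method="fdr_bh")[1]
        rows = [
            EnrichmentRow(r.category, r.a, r.b, r.c, r.d, r.odds_ratio, r.p, q)
            for r, q in zip(rows, qs)
        ]
    return sorted(rows, key=lambda r: (r.q, r.category))


def compare_lifestyles(
    density_a: Sequence[float],
    density_b: Sequence[float],
) -> dict:
    """Two-sided Mann-Whitney U between two density groups.

    Exact null distribution for small tie-free samples (combined
    n <= 20); normal approximation with tie correction otherwise.
    Degenerate all-tied input gives p = 1.
    """
    if not len(density_a) or not len(density_b):
        raise ValueError("both lifestyle groups must be non-empty")
    a = np.asarray(density_a, dtype=float)
    b = np.asarray(density_b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        p = 1.0
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u, p = float(res.statistic), float(res.pvalue)
    return {
        "u": u,
        "p": min(p, 1.0),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


@dataclass
class NetworkEdge:
    phage_id: str
    bacterial_taxon: str
    shared_sv_count: int
    abundance_r: Optional[float] = None


def build_sharing_network(
    classifications: Mapping[str, GEClassification],
    sv_phage: Mapping[str, str],
    lineages: Mapping[str, TaxonLineage],
    rank: str = "genus",
) -> list[NetworkEdge]:
    """Phage-bacteria edges weighted by shared GE-like SV counts.

    ``sv_phage`` maps each SV id to the phage genome carrying it;
    bacterial genomes aggregate to ``rank`` (genus by default), falling
    back to their deepest present rank with a warning.
    """
    weights: dict[tuple[str, str], int] = {}
    for sv_id, cls in classifications.items():
        if cls.label != "GE_like" or sv_id not in sv_phage:
            continue
        phage = sv_phage[sv_id]
        taxa = set()
        for genome in cls.matched_genomes:
            lin = lineages.get(genome)
            if lin is None:
                logger.warning("no lineage for matched genome %r", genome)
                continue
            taxon = lin.ranks.get(rank)
            if not taxon:
                deepest = lin.deepest_rank()
                taxon = lin.ranks.get(deepest, genome) if deepest else genome
                logger.warning(
                    "genome %r lacks rank %r; using %r", genome, rank, taxon
                )
            taxa.add(taxon)
        for taxon in taxa:
            weights[(phage, taxon)] = weights.get((phage, taxon), 0) + 1
    return [
        NetworkEdge(phage_id=p, bacterial_taxon=t, shared_sv_count=w)
        for (p, t), w in sorted(weights.items())
    ]


def abundance_correlations(
    matrix: AbundanceMatrix,
    edges: Sequence[NetworkEdge],
) -> dict:
    """Pearson r of phage vs bacterial abundance for every network edge,
    plus the overall correlation between shared-SV count and pair r."""
    if len(matrix.sample_ids) < 3:
        raise ValueError("need >= 3 samples for correlations")
    rows = {rid: i for i, rid in enumerate(matrix.row_ids)}
    values = np.asarray(matrix.values, dtype=float)
    pair_r, counts = [], []
    for edge in edges:
        if edge.phage_id not in rows or edge.bacterial_taxon not in rows:
            continue
        x = values[rows[edge.phage_id]]
        y = values[rows[edge.bacterial_taxon]]
        if np.std(x) == 0 or np.std(y) == 0:
            edge.abundance_r = None
            logger.warning(
                "zero-variance abundance for pair (%s, %s)",
                edge.phage_id, edge.bacterial_taxon,
            )
            continue
        r = float(sps.pearsonr(x, y).statistic)
        edge.abundance_r = r
        pair_r.append(r)
        counts.append(edge.shared_sv_count)
    summary_r = math.nan
    if len(pair_r) >= 3 and np.std(counts) > 0 and np.std(pair_r) > 0:
        summary_r = float(sps.pearsonr(counts, pair_r).statistic)
    return {
        "edges": list(edges),
        "mean_pair_r": float(np.mean(pair_r)) if pair_r else math.nan,
        "count_vs_r": summary_r,
    }


def edges_to_frame(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phage_id": e.phage_id,
                "bacterial_taxon": e.bacterial_taxon,
                "shared_sv_count": e.shared_sv_count,
                "abundance_r": e.abundance_r,
            }
            for e in edges
        ]
    )
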