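"""Genomic-context annotation and category enrichment.

CGI relation follows the usual 450K convention: a position inside a CpG
island is Island; within 2 kb of an island edge, Shore; within the next
2 kb, Shelf; otherwise OpenSea.  North/south flanks are collapsed to
symmetric Shore/Shelf classes.  Enrichment of differential sites per
category uses the upper-tail hypergeometric distribution with all manifest
CpGs as the background population; gene-set enrichment uses a one-sided
Fisher's exact test at gene level.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .types import (
    CGI_RELATIONS,
    REGION_LABELS,
    CpGRecord,
    EnrichmentRecord,
    GeneModel,
    GenomicInterval,
    SiteStat,
)

log = logging.getLogger(__name__)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicInterval(last.chrom, last.start, max(last.end, iv.end), last.name))
        else:
            merged.append(iv)
    return merged


def assign_cgi_relation(
    pos: int,
    chrom: str,
    cgi_intervals: list[GenomicInterval],
    shore_width: int = 2000,
    shelf_width: int = 2000,
) -> str:
    """Classify one position as Island / Shore / Shelf / OpenSea."""
    dist = _distance_to_nearest_cgi(np.array([pos]), chrom, cgi_intervals)[0]
    return _relation_from_distance(dist, shore_width, shelf_width)


def assign_cgi_relations(
    positions: np.ndarray,
    chrom: str,
    cgi_intervals: list[GenomicInterval],
    shore_width: int = 2000,
    shelf_width: int = 2000,
) -> list[str]:
    """Vectorised CGI classification for many positions on one chromosome."""
    dists = _distance_to_nearest_cgi(np.asarray(positions), chrom, cgi_intervals)
    return [_relation_from_distance(d, shore_width, shelf_width) for d in dists]


def _relation_from_distance(dist: float, shore_width: int, shelf_width: int) -> str:
    if dist == 0:
        return "Island"
    if dist <= shore_width:
        return "Shore"
    if dist <= shore_width + shelf_width:
        return "Shelf"
    return "OpenSea"


def _distance_to_nearest_cgi(
    positions: np.ndarray, chrom: str, cgi_intervals: list[GenomicInterval]
) -> np.ndarray:
    """Distance (bp) from each position to the nearest island; 0 if inside.

    For a position left of an island starting at s the distance is s - pos;
    the edge base itself (pos = end) is 1 bp outside a half-open interval.
    """
    merged = [iv for iv in merge_intervals(cgi_intervals) if iv.chrom == chrom]
    if not merged:
        return np.full(len(positions), np.inf)
    starts = np.array([iv.start for iv in merged])
    ends = np.array([iv.end for iv in merged])
    pos = np.asarray(positions)
    idx = np.searchsorted(starts, pos, side="right")
    dist_prev = np.where(idx > 0, pos - ends[np.clip(idx - 1, 0, None)] + 1, np.inf)
    dist_prev = np.where((idx > 0) & (pos < ends[np.clip(idx - 1, 0, None)]), 0, dist_prev)
    dist_next = np.where(idx < len(starts), starts[np.clip(idx, None, len(starts) - 1)] - pos, np.inf)
    return np.minimum(dist_prev, dist_next)


def assign_gene_region(
    pos: int,
    chrom: str,
    gene_models: list[GeneModel],
    tss200: int = 200,
    tss1500: int = 1500,
) -> frozenset[str]:
    """Strand-aware gene-region labels for one position.

    TSS200 is within ``tss200`` bp upstream of a TSS; TSS1500 the
    200–1500 bp band beyond it; UTR5/Exon1/UTR3 from the model bounds,
    Body for the remainder of the gene span.  A position hitting no gene
    gets {Intergenic}; multi-gene positions accumulate labels.
    """
    labels: set[str] = set()
    for gm in gene_models:
        if gm.chrom != chrom:
            continue
        upstream = gm.tss - pos if gm.strand == "+" else pos - gm.tss
        if 0 < upstream <= tss200:
            labels.add("TSS200")
            continue
        if tss200 < upstream <= tss1500:
            labels.add("TSS1500")
            continue
        if gm.span[0] <= pos < gm.span[1]:
            if gm.utr5 and gm.utr5[0] <= pos < gm.utr5[1]:
                labels.add("UTR5")
            elif gm.exon1 and gm.exon1[0] <= pos < gm.exon1[1]:
                labels.add("Exon1")
            elif gm.utr3 and gm.utr3[0] <= pos < gm.utr3[1]:
                labels.add("UTR3")
            else:
                labels.add("Body")
    return frozenset(labels) if labels else frozenset({"Intergenic"})


def hypergeometric_enrichment(
    selected: set[str],
    category_members: set[str],
    background: set[str],
    category: str = "category",
) -> EnrichmentRecord:
    """Upper-tail hypergeometric enrichment of a category in a selection.

    With N background items of which K are in the category, and n selected
    items of which k are in the category, p = P(X >= k) for X
    hypergeometric(N, K, n).  Exact computation, no normal approximation.
    """
    if not selected <= background:
        raise ValueError("selected set must be a subset of the background")
    if not category_members <= background:
        raise ValueError("category members must be a subset of the background")
    N, K, n = len(background), len(category_members), len(selected)
    k = len(selected & category_members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentRecord(category, k, n, K, N, fold, p, "hypergeometric")


def category_enrichment_profile(
    stats_list: list[SiteStat],
    manifest: list[CpGRecord],
) -> list[EnrichmentRecord]:
    """Enrichment of hyper- and hypomethylated sites per gene-region label
    and CGI-relation class, against all manifest CpGs as background.

    Returns one record per (direction, category) with the category string
    ``"<direction>:<label>"``; empty selections yield k = 0, p = 1 records.
    """
    background = {r.cpg_id for r in manifest}
    by_region: dict[str, set[str]] = {lab: set() for lab in REGION_LABELS}
    by_cgi: dict[str, set[str]] = {rel: set() for rel in CGI_RELATIONS}
    for r in manifest:
        for lab in r.region_labels:
            by_region[lab].add(r.cpg_id)
        by_cgi[r.cgi_relation].add(r.cpg_id)

    records: list[EnrichmentRecord] = []
    for direction in ("hyper", "hypo"):
        selected = {s.cpg_id for s in stats_list if s.direction == direction}
        if not selected <= background:
            raise ValueError("direction calls include sites absent from the manifest")
        for label in list(REGION_LABELS) + list(CGI_RELATIONS):
            members = by_region.get(label) or by_cgi.get(label) or set()
            rec = hypergeometric_enrichment(
                selected, members, background, category=f"{direction}:{label}"
            )
            records.append(rec)
    return records


def fisher_enrichment_2x2(table: np.ndarray, category: str = "table") -> EnrichmentRecord:
    """One-sided (enrichment) Fisher's exact test on a 2x2 table
    [[k, n-k], [K-k, N-K-n+k]]."""
    table = np.asarray(table, dtype=int)
    k = int(table[0, 0])
    n = int(table[0].sum())
    K = int(table[:, 0].sum())
    N = int(table.sum())
    _, p = stats.fisher_exact(table, alternative="greater")
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentRecord(category, k, n, K, N, fold, p, "fisher")


def gene_set_enrichment(
    selected_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe_genes: set[str],
) -> list[EnrichmentRecord]:
    """One-sided Fisher enrichment of each gene set in the selected genes.

    Genes are counted once regardless of how many CpGs they carry.  Sets
    are intersected with the universe first; empty sets are skipped.
    """
    if not universe_genes:
        raise ValueError("empty gene universe")
    selected = selected_genes & universe_genes
    records: list[EnrichmentRecord] = []
    for name, members in gene_sets.items():
        members = members & universe_genes
        if not members:
            log.info("gene set %r has no genes in the universe; skipped", name)
            continue
        k = len(selected & members)
        n = len(selected)
        K = len(members)
        N = len(universe_genes)
        table = np.array([[k, n - k], [K - k, N - K - n + k]])
        rec = fisher_enrichment_2x2(table, category=name)
        records.append(rec)
    return records
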