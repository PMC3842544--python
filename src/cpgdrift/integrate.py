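"""Methylation–expression integration.

Expression and methylation are joined by gene ID.  Differential expression
uses the same paired machinery as methylation (paired t on log2
intensities, BH adjustment).  The headline association — promoter
hypermethylation vs transcriptional down-regulation — is reduced to a 2x2
quadrant test per gene: (has a hypermethylated CpG in the chosen region) x
(down-regulated), tested one-sided by Fisher's exact test.  Down-regulation
uses the raw paired-t p-value at ``expr_alpha`` (the figure-style scatter
criterion), while the methylation arm uses the FDR-adjusted direction
calls.
"""

from __future__ import annotations

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .context import fisher_enrichment_2x2
from .dm import adjust_pvalues, paired_moderated_t
from .types import (
    CGI_RELATIONS,
    REGION_LABELS,
    BetaMatrix,
    CpGRecord,
    EnrichmentRecord,
    ExpressionMatrix,
    ModerationParams,
    PairedDesign,
    SiteStat,
)


def differential_expression(
    expr: ExpressionMatrix,
    design: PairedDesign,
    alpha: float = 0.05,
    moderation: ModerationParams | str = "estimate",
) -> pd.DataFrame:
    """Per-gene paired differential expression for the contrast b vs a.

    Uses the same empirical-Bayes moderated paired t as the methylation
    arm (the standard choice for three-pair array designs); pass
    ``moderation="none"`` or ``ModerationParams(0, ...)`` for the classical
    paired t-test.  Returns a DataFrame indexed by gene_id with columns
    lfc (mean paired log2 difference), t, p, adj_p and direction
    (up/down/ns on adjusted p).  Zero-variance genes with a nonzero fold
    change get the smallest representable p under the classical test
    (flagged via t = ±inf).
    """
    # paired_moderated_t only touches .values and .site_ids, so log2
    # intensities (outside [0,1]) ride through on a duck-typed carrier
    carrier = SimpleNamespace(values=expr.values, site_ids=list(expr.values.index))
    stats_list = paired_moderated_t(carrier, design, moderation)
    adj = adjust_pvalues(np.array([s.p for s in stats_list]))
    rows = []
    for s, ap in zip(stats_list, adj):
        if ap < alpha and s.delta > 0:
            direction = "up"
        elif ap < alpha and s.delta < 0:
            direction = "down"
        else:
            direction = "ns"
        rows.append(
            {
                "gene_id": s.cpg_id,
                "lfc": s.delta,
                "t": s.t_mod,
                "p": s.p,
                "adj_p": float(ap),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def expression_deciles(expr: ExpressionMatrix, fraction: float = 0.10) -> tuple[set[str], set[str]]:
    """Top and bottom expression deciles by mean signal intensity.

    Genes are ranked by mean log2 intensity across all samples; the top and
    bottom ``ceil(fraction * n)`` genes are returned.  Ties are broken
    deterministically by gene ID.
    """
    n = len(expr.gene_ids)
    if n < 10:
        raise ValueError("need >= 10 genes to take 10% deciles")
    k = math.ceil(fraction * n)
    means = expr.values.mean(axis=1)
    order = sorted(expr.gene_ids, key=lambda g: (means[g], g))
    return set(order[-k:]), set(order[:k])


def mean_dnam_by_context(
    gene_set: set[str],
    manifest: list[CpGRecord],
    beta: BetaMatrix,
) -> pd.DataFrame:
    """Mean beta per (gene-region label x CGI relation) over a gene set.

    Averages all (site, sample) beta values of CpGs affiliated with a gene
    in the set, split by annotation cell; the number of contributing sites
    is reported alongside each mean.  Used to contrast promoter vs body
    methylation of the most and least expressed genes.
    """
    sites = [r for r in manifest if r.gene_ids & gene_set and r.cpg_id in beta.values.index]
    if not sites:
        raise ValueError("gene set does not intersect the manifest genes")
    rows = []
    for label in REGION_LABELS:
        for rel in CGI_RELATIONS:
            members = [r.cpg_id for r in sites if label in r.region_labels and r.cgi_relation == rel]
            vals = beta.values.loc[members].to_numpy(dtype=float) if members else np.array([])
            vals = vals[~np.isnan(vals)] if vals.size else vals
            rows.append(
                {
                    "region": label,
                    "cgi_relation": rel,
                    "n_sites": len(members),
                    "mean_beta": float(vals.mean()) if vals.size else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def dm_de_association(
    dm_stats: list[SiteStat],
    de: pd.DataFrame,
    manifest: list[CpGRecord],
    region_filter: str = "TSS200",
    expr_alpha: float = 0.05,
) -> tuple[np.ndarray, EnrichmentRecord]:
    """Quadrant association between regional hypermethylation and
    down-regulation, over genes present in both data sets.

    A gene is methylation-positive iff ≥1 of its CpGs carrying
    ``region_filter`` is called hyper; expression-negative iff its raw
    paired-t p < ``expr_alpha`` with lfc < 0.  Returns the 2x2 table
    [[both, hyper-only], [down-only, neither]] and the one-sided Fisher
    enrichment record.
    """
    if region_filter not in REGION_LABELS:
        raise ValueError(f"unknown region label {region_filter!r}")
    hyper_ids = {s.cpg_id for s in dm_stats if s.direction == "hyper"}
    meth_genes = set()
    tested_ids = {s.cpg_id for s in dm_stats}
    gene_universe_meth = set()
    for r in manifest:
        if r.cpg_id not in tested_ids or not r.gene_ids:
            continue
        gene_universe_meth |= r.gene_ids
        if region_filter in r.region_labels and r.cpg_id in hyper_ids:
            meth_genes |= r.gene_ids
    joined = sorted(gene_universe_meth & set(de.index))
    if not joined:
        raise ValueError("empty join: no gene shared between methylation and expression")
    down_genes = set(de.index[(de["p"] < expr_alpha) & (de["lfc"] < 0)])
    a = sum(1 for g in joined if g in meth_genes and g in down_genes)
    b = sum(1 for g in joined if g in meth_genes and g not in down_genes)
    c = sum(1 for g in joined if g not in meth_genes and g in down_genes)
    d = len(joined) - a - b - c
    table = np.array([[a, b], [c, d]])
    rec = fisher_enrichment_2x2(table, category=f"hyper[{region_filter}] x down")
    return table, rec
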