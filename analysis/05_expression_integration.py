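#!/usr/bin/env python
"""Methylation-expression integration.

Profiles average methylation of the most and least expressed gene deciles
per genomic context (promoter islands of expressed genes should be nearly
unmethylated) and tests whether promoter (TSS200) hypermethylation is
associated with transcriptional down-regulation (one-sided Fisher on the
gene-level quadrant table).

Note: the default study plants hypermethylation in TSS1500/Shore, so the
TSS200 association here is expected to be weak; 06_promoter_coupling.py
runs the promoter-planted configuration where the coupling is active.
"""

from pathlib import Path

from cpgdrift import io as cio
from cpgdrift.integrate import (
    differential_expression,
    dm_de_association,
    expression_deciles,
    mean_dnam_by_context,
)
from cpgdrift.types import PairedDesign

OUT = Path("results/analysis")
SIM = OUT / "sim"
CONTRAST = ("CD34pos_d0", "CD34pos_woMSC")


def main() -> None:
    manifest = cio.read_manifest(SIM / "manifest.tsv")
    beta = cio.read_beta_matrix(SIM / "beta.tsv", SIM / "samples.tsv")
    expr = cio.read_expression(SIM / "expression.tsv", SIM / "expr_samples.tsv")

    top, bottom = expression_deciles(expr)
    top_table = mean_dnam_by_context(top, manifest, beta)
    bottom_table = mean_dnam_by_context(bottom, manifest, beta)
    top_table.to_csv(OUT / "dnam_by_context_top_decile.tsv", sep="\t", index=False)
    bottom_table.to_csv(OUT / "dnam_by_context_bottom_decile.tsv", sep="\t", index=False)

    def cell(table, region, rel):
        row = table[(table.region == region) & (table.cgi_relation == rel)]
        return float(row["mean_beta"].iloc[0])

    body = top_table[top_table.region == "Body"].dropna(subset=["mean_beta"])
    body_mean = float((body.mean_beta * body.n_sites).sum() / body.n_sites.sum())
    print("highly expressed genes: mean beta "
          f"{cell(top_table, 'TSS200', 'Island'):.3f} at promoter islands vs "
          f"{body_mean:.3f} in gene bodies (promoters are nearly unmethylated)")

    de = differential_expression(expr, PairedDesign.from_samples(expr.samples, *CONTRAST))
    de.to_csv(OUT / "de.tsv", sep="\t", float_format="%.12g")
    n_down = int((de["direction"] == "down").sum())
    print(f"differential expression: {n_down} genes down-regulated (adjusted p < 0.05)")

    stats = cio.read_site_stats(OUT / f"dm_{CONTRAST[0]}_vs_{CONTRAST[1]}.tsv")
    table, rec = dm_de_association(stats, de, manifest, region_filter="TSS200")
    cio.write_results([rec], OUT / "integration.tsv")
    print(f"TSS200 hyper x down quadrants {table.tolist()}: one-sided Fisher p={rec.p:.3g}")


if __name__ == "__main__":
    main()
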