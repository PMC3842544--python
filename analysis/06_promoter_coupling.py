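#!/usr/bin/env python
"""Promoter-planted study: methylation-expression coupling recovery.

Re-runs the generator with hypermethylation planted in TSS200/1st-exon
CpGs and expression coupled at slope -4 log2 units per beta unit, then
tests the TSS200 hyper x down-regulation association.  This is the
configuration in which the coupling is active, mirroring the observation
that promoter hypermethylation accompanies reduced expression.
"""

from pathlib import Path

from cpgdrift import io as cio
from cpgdrift.dm import run_contrast
from cpgdrift.integrate import differential_expression, dm_de_association
from cpgdrift.simulate import SimConfig, simulate_beta, simulate_expression, simulate_manifest
from cpgdrift.types import PairedDesign

OUT = Path("results/analysis")
CONTRAST = ("CD34pos_d0", "CD34pos_woMSC")
SEED = 1


def main() -> None:
    cfg = SimConfig(
        n_cpg=10_000, seed=SEED,
        effect_categories=frozenset({"TSS200", "Exon1"}),
        expression_coupling=-4.0,
    )
    genome = simulate_manifest(cfg)
    beta, truth = simulate_beta(cfg, genome)
    expr = simulate_expression(cfg, genome, truth)

    stats, n_hyper, n_hypo = run_contrast(beta, *CONTRAST)
    print(f"promoter-planted study: {n_hyper} hyper / {n_hypo} hypo calls; "
          f"{len(truth.coupled_genes)} genes expression-coupled")

    de = differential_expression(expr, PairedDesign.from_samples(expr.samples, *CONTRAST))
    table, rec = dm_de_association(stats, de, genome.manifest, region_filter="TSS200")
    cio.write_results([rec], OUT / "integration_promoter_planted.tsv")
    print(f"TSS200 hyper x down quadrants {table.tolist()}: one-sided Fisher p={rec.p:.3g}")


if __name__ == "__main__":
    main()
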