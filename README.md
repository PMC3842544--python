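# cpgdrift

Culture-expanded hematopoietic stem and progenitor cells (HPCs, the CD34+
fraction of cord blood) rapidly lose stemness *in vitro*, and this loss is
accompanied by DNA hypermethylation at specific CpG sites. `cpgdrift`
implements the computational analysis behind that observation as a tested,
reusable pipeline for epigenomics researchers working with
Infinium-450K-style beta-value data:

- **Paired differential methylation** — per CpG, the donor-paired beta
  difference Δβ is tested with an empirical-Bayes **moderated paired
  t-statistic**: the per-site variance s² of pair differences is shrunk
  toward a prior s₀² with d₀ prior degrees of freedom,
  s²ₚₒₛₜ = (d₀·s₀² + df·s²)/(d₀ + df), t = Δβ / √(s²ₚₒₛₜ/n), with p-values
  on d₀+df degrees of freedom and Benjamini–Hochberg FDR control
  (hyper/hypo calls at adjusted p < 0.05). Testing is confined to the 50%
  most variable CpGs; d₀ = 0 recovers the classical paired t-test.
- **Genomic-context enrichment** — hyper/hypomethylated sites tested per
  gene-region label (TSS1500, TSS200, 5′UTR, 1st exon, body, 3′UTR,
  intergenic) and CGI relation (island / 2 kb shore / 2 kb shelf / open
  sea) by the upper-tail hypergeometric distribution against all array
  CpGs; gene sets by one-sided Fisher's exact test.
- **Motif and peak co-location** — PWM log-odds scanning of 124 bp windows
  centred on hypermethylated CpGs against the array background, and
  ChIP-Seq peak co-location at 124/200/500/1,000 bp windows (one-sided
  Fisher).
- **Methylation–expression integration** — expression deciles profiled by
  genomic context, and a gene-level quadrant test (promoter
  hypermethylation × down-regulation, one-sided Fisher).
- **Synthetic-data generator** — a logit-normal beta model over a
  constructed two-chromosome genome (donor effects, condition effects
  calibrated so planted sites have an exact expected Δβ, CG dinucleotides
  at every probe, planted motifs/peaks, expression coupled to promoter
  methylation) with a ground-truth ledger, so every stage is validated by
  recovery tests with known answers.

## Worked example

The `analysis/` scripts run the full study on the synthetic generator
(10,000 CpGs, 3 donors, 4 conditions, hypermethylation planted in 10% of
TSS1500/Shore CpGs at Δβ = +0.15; seed 1):

```sh
python analysis/01_simulate.py
python analysis/02_differential_methylation.py
python analysis/03_context_enrichment.py
python analysis/04_motif_colocation.py
python analysis/05_expression_integration.py
python analysis/06_promoter_coupling.py
```

which prints, among other things:

```
CD34pos_d0 vs CD34pos_woMSC: 5000 sites tested, 174 hypermethylated, 4 hypomethylated
hypermethylation dominates every contrast; 86 CpGs are hypermethylated in all 3 cultured fractions
hyper-enrichment ranking for CD34pos_d0_vs_CD34pos_woMSC (category, fold, p):
  hyper:Shore      fold= 3.02 p=1.26e-81
  hyper:TSS1500    fold= 3.39 p=2.52e-25
motif planted: 26/86 hyper windows vs 190/10000 background (fold=15.9, p=8.41e-25)
peak co-location (width, hyper proportion, array proportion, p):
    124 bp  0.267  0.027  2.87e-17
highly expressed genes: mean beta 0.125 at promoter islands vs 0.537 in gene bodies
TSS200 hyper x down quadrants [[22, 7], [87, 384]]: one-sided Fisher p=1.87e-10
```

Reading the output: culture shifts far more CpGs up than down (174 vs 4),
the planted TSS1500/Shore signal tops the enrichment table, the planted
transcription-factor motif and peaks concentrate around the
hypermethylated sites (with peak co-location proportions rising as the
window widens), and in the promoter-planted configuration TSS200
hypermethylation is strongly associated with down-regulated expression.
Every table lands under `results/analysis/`.

The same pipeline runs as one command from a YAML config:

```sh
cpgdrift run --config config.yaml      # simulate -> dm -> enrich -> motif -> colocate -> integrate
cpgdrift report <run_dir>
```

with per-stage subcommands (`cpgdrift simulate | dm | enrich | motif |
colocate | integrate`) for real (non-synthetic) input files.

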