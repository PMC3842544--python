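# Methods

## Scope and data model

`cpgdrift` analyses Infinium-450K-style DNA-methylation data: per-CpG
beta-values in [0, 1] (0 = unmethylated, 1 = fully methylated), a probe
manifest with gene-region labels (TSS1500, TSS200, 5′UTR, 1st exon, body,
3′UTR, intergenic) and CGI relations (island, shore, shelf, open sea), a
donor-paired sample sheet over culture conditions, CGI and ChIP-Seq peak
intervals (BED), window sequences (FASTA), motif matrices (plain-text
PWM), gene sets (GMT) and a normalized log2 expression matrix. It
consumes already-normalized matrices; raw-array preprocessing, liftover
and probe-level artifacts (cross-reactive or SNP-affected probes) are out
of scope. All coordinates are 0-based half-open internally; manifest
positions (1-based by array convention) are converted on read. A probe
affiliated with several genes accumulates all their region labels;
"Intergenic" is reserved for probes with no gene affiliation.

## Differential methylation

Testing is confined to the fraction (default 50%) of CpGs with the
highest across-sample variance of beta (unbiased sample variance over all
samples of all conditions; ties at the cutoff broken by manifest order).
The filter is computed once on the full matrix, not per contrast.

For a contrast (reference condition a, cultured condition b) samples are
paired by donor and the per-site statistic is the empirical-Bayes
moderated paired t. With pair differences d_ij (b − a) at site i:

- delta_i = mean(d_ij), s2_i = Var(d_ij) (ddof = 1), df_i = n_pairs − 1;
- posterior variance s2_post = (d0·s0² + df·s2) / (d0 + df);
- t_i = delta_i / sqrt(s2_post / n_pairs), two-sided p on d0 + df degrees
  of freedom.

(d0, s0²) are estimated by moment-matching the scaled-F distribution of
the s2 across sites on the log scale (digamma/trigamma moments, with a
Newton inversion of the trigamma function); when the observed variances
are more concordant than their sampling noise alone the prior df is
infinite and every site is shrunk fully to s0². `prior_df = 0` reduces
exactly to the classical paired t-test (verified to 1e-10 relative error
against the textbook formula). Donor pairs missing either value at a site
are dropped pairwise; sites with fewer than two complete pairs are
dropped and logged. Sites with zero posterior variance and zero delta get
t = 0, p = 1; a nonzero delta with exactly zero variance under the
unmoderated test yields t = ±inf with p clamped to the smallest positive
float (never exactly 0), flagged by the infinite statistic.

Multiple testing uses Benjamini–Hochberg step-up FDR (via statsmodels)
with input validation to (0, 1]. A site is called hypermethylated iff
adjusted p < alpha (default 0.05) and delta > 0, hypomethylated for
delta < 0; no minimum |delta| is imposed. Overlaps between contrasts are
reported as the full Venn decomposition of the per-contrast call sets.

## Genomic context and enrichment

CGI relation from coordinates: island if the position lies inside a
(merged) CGI interval; shore within 2 kb of an island edge; shelf within
the next 2 kb; open sea beyond. North/south flanks are collapsed to
symmetric shore/shelf classes. The distance convention treats the first
base outside a half-open interval as 1 bp away, which is exactly the
convention of the brute-force nearest-base oracle used in the tests.
Gene-region assignment is strand-aware: TSS200 = within 200 bp upstream
of a TSS, TSS1500 = the 200–1500 bp band, then 5′UTR/1st-exon/3′UTR from
the gene model bounds with body as the remainder of the span.

Category enrichment of hyper/hypo calls uses the exact upper-tail
hypergeometric distribution P(X ≥ k) with all manifest CpGs as the
background population (one record per direction × category; empty
selections yield k = 0, p = 1). Depletion is visible as fold < 1 without
a second test. Gene-set enrichment works at gene level (a gene is
selected iff ≥ 1 of its CpGs is called) with a one-sided Fisher's exact
test against the genes-on-array universe; the exact equivalence of the
one-sided Fisher p and the hypergeometric tail on matched margins is
cross-validated in the tests. The alternative CpG-level background
weighting is not implemented.

## Motif scanning and peak co-location

Windows are total-width intervals centred on the CpG:
[pos − w/2, pos + w/2), default w = 124 so the C sits at offset w/2.
(The alternative reading — 124 bp per side — is not used; the width is
exposed as a parameter.) PWM hits are log2-odds sums against the
background composition with pseudocount regularisation; an offset is a
hit iff its score reaches `threshold_fraction` (default 0.8) of the
motif's maximum attainable score, both strands scanned, overlapping hits
all reported, offsets containing non-ACGT bases skipped. The score-based
threshold replaces FIMO's p-value machinery, which is out of scope. A
matrix whose maximum score is not positive (no position beats the
background) can never produce hits at a positive threshold. Motif
enrichment counts windows-with-≥1-hit (not hit counts) and applies the
upper-tail hypergeometric test against all array windows.

Peak co-location: peaks are merged first; a site is peak-positive at
width w iff any merged peak intersects [pos − w/2, pos + w/2). Positivity
is therefore monotone in w (nested windows), so the reported proportions
can only rise with width. The test contrasts hypermethylated vs remaining
array sites in a one-sided Fisher 2×2 per width (default widths 124, 200,
500, 1,000 bp); the reported background proportion covers the whole
array, mirroring the figure-style "all CpGs" bar.

## Expression integration

Differential expression uses the identical moderated paired-t machinery
on log2 intensities. The moderated default (rather than the classical
df = 2 paired t) is a deliberate choice: with three donor pairs the
classical test is severely underpowered and variance moderation is the
standard practice for expression arrays of this size;
`moderation="none"` recovers the classical test. Expression deciles are
taken on the mean log2 intensity across all samples (ceil(0.1·n) genes,
ties broken by gene ID), and mean methylation is profiled per
(gene-region × CGI-relation) cell with site counts attached.

The methylation–expression claim is reduced to a gene-level quadrant
association: a gene is methylation-positive iff ≥ 1 of its CpGs carrying
the chosen region label (default TSS200) is called hyper (FDR-based
calls); expression-negative iff its raw paired-t p < 0.05 with a negative
fold change — the raw-p criterion matches the figure-style scatter
selection and keeps the table non-degenerate under a null coupling, where
adjusted-p calls would vanish entirely. The association is tested by a
one-sided Fisher's exact test. Because the exact conditional p-value on a
small discrete table is super-uniform by construction, the null behaviour
is checked one-sidedly (no excess of small p-values), not against strict
uniformity.

## Synthetic-data generator

The generator emulates the study design: four conditions — fresh CD34+
day 0 (reference), CD34+ and CD34− expanded without stromal support,
CD34+ expanded on MSC feeders — across three donors, with
hypermethylation planted in configurable categories (default TSS1500 and
Shore, the signature the analysis is meant to recover).

Genome construction. Genes occupy 12 kb loci on two synthetic
chromosomes, alternating strands at random. Each locus carries a promoter
CGI at [TSS − 200, TSS + 600): TSS200/5′UTR/1st-exon probes fall inside
the island and the TSS1500 band falls inside the upstream shore, so
promoter and shore effects co-occur as they do on the real array. Region
labels are sampled from a mixture approximating the 450K design (body
31%, intergenic 29%, TSS1500 13%, TSS200 10%, 5′UTR 8%, 1st exon 5%,
3′UTR 4%); every label and every CGI class is guaranteed present (four
anchor probes). Probe positions are even offsets within the label's
coordinate range, CGI relations are computed from the actual positions
(so the 2 kb shore / 2 kb shelf definition holds by construction), and
the emitted chromosome sequence carries a CG dinucleotide at every probe.

Beta model. beta = invlogit(baseline + condition shift + donor effect +
noise), with the baseline drawn per CGI class (logit means −2.2 island,
−0.5 shore, +0.8 shelf, +1.2 open sea; islands low, open sea high —
this produces the familiar bimodal beta distribution), donor effects
N(0, 0.15²) shared across conditions within a donor (the pairing
structure), and sample-level noise N(0, 0.25²) on the logit scale. These
dispersions are chosen for testability — the real data's donor-vs-
technical variance split is not published. The planted effect (default:
10% of the CpGs in the effect categories, shared across all cultured
conditions to create the overlapping-hypermethylation structure) is a
logit-scale shift calibrated per site by Gauss–Hermite smoothing and
bisection so that the *expected beta difference* equals `effect_delta`
(default +0.15) exactly, despite the nonlinear link; targets are clipped
to mean beta ≤ 0.985 and the achieved per-site delta is recorded in the
ground-truth ledger.

Sequences, peaks, expression. The motif consensus (default AAGAGGAAGT, a
purine-rich ETS-like 10-mer) is written into a fraction of the
affected-site windows (default 30%) and of background windows (1%),
never overwriting the central CG; chance occurrences of the consensus in
random sequence (~2·10⁻⁴ per 124 bp window) remain possible and are
intentional. Peaks (60 bp) are centred within ±61 bp of a fraction of
affected sites (30% vs 1% background). Expression is
baseline + donor + condition + noise on the log2 scale; the baseline
decreases with the gene's promoter-class methylation (slope 4 log2 units
per beta unit), and genes with planted TSS200/1st-exon CpGs are shifted
by `expression_coupling × (mean achieved delta)` (default −4 × 0.15 =
−0.6) in the cultured conditions. Every stage draws from its own seeded
RNG stream, so outputs are bit-reproducible under a fixed seed and
independent of call order.

What the generator does not emulate: probe-level intensities, batch
effects, cross-reactive/SNP probes, spatially correlated methylation
beyond the locus layout, and a *between-gene* gradient of promoter
methylation (promoter baselines differ by CGI class, not per gene, so
the top-vs-bottom expression deciles differ little in promoter beta;
the promoter-vs-body contrast within a decile is the emulated signal).
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under this generative model, not performance on
real arrays.

## Pipeline, parameters and problem sizes

All thresholds live in the YAML config with the study's analysis values
as defaults: variance keep-fraction 0.5, alpha 0.05 (adjusted), window
width 124 bp, co-location widths 124/200/500/1,000 bp, PWM threshold
fraction 0.8. Seeds are mandatory for every stochastic stage (no
wall-clock seeding); a run is a pure function of its config — outputs
carry no timestamps and re-running reproduces byte-identical files, which
the test suite asserts. The run manifest records config, versions and
per-stage counts and suffices to re-execute the run.

Default problem sizes are 10,000 CpGs, ~500 genes, 3 donors and 4
conditions; replicated analyses (error control, category recovery,
expression association) use 10–20 seeds. These sizes give Monte-Carlo
tolerances of a few per mille on the recovered effect size and run the
entire suite in well under a minute per replicated analysis, while
exercising every code path at array-realistic density (one CpG per
~1.2 kb of synthetic genome).

## Known limitations

- The moderated-t hyperparameter fit uses the plain moment estimator
  (no robustification against variance outliers).
- Gene-set enrichment supports only the Fisher route; weighted
  running-sum (GSEA-style) testing is out of scope.
- The probe-to-gene join is exact-ID only; many-to-many reconciliation
  beyond accumulating region labels is not attempted.
- Windows are clipped at chromosome boundaries by dropping the site
  (logged) rather than truncating the window.
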