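"""Synthetic 450K-style data with planted ground truth.

The generator lays out gene loci on two synthetic chromosomes.  Each locus
carries a promoter CpG island at [TSS-200, TSS+600), so TSS200/5'UTR/1st
exon probes fall inside the island while the TSS1500 band lies in the
upstream shore — promoter and shore hypermethylation co-occur, as on the
real array.  Beta-values arise from a logit-normal model

    beta = invlogit(site baseline + condition shift + donor effect + noise)

with the site baseline drawn per CGI-relation class (islands low, open sea
high).  Culture-induced hypermethylation is planted on a configurable
fraction of the CpGs in chosen categories; the logit-scale condition shift
is calibrated numerically (Gauss–Hermite smoothing + bisection) so the
expected beta difference of a planted site equals ``effect_delta`` exactly
despite the nonlinear link.  Sequences carry a CG dinucleotide at every
probe position; a motif consensus and ChIP-Seq-style peaks are planted
around affected CpGs, and expression is negatively coupled to promoter
methylation.  Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .context import assign_cgi_relations
from .types import (
    BetaMatrix,
    CpGRecord,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
)

# locus geometry (offsets within a 12 kb locus, plus-strand orientation)
LOCUS = 12_000
_TSS = 4_000
_PLUS_RANGES: dict[str, list[tuple[int, int]]] = {
    "TSS1500": [(2_500, 3_800)],
    "TSS200": [(3_800, 4_000)],
    "UTR5": [(4_000, 4_150)],
    "Exon1": [(4_150, 4_450)],
    "Body": [(4_450, 8_700)],
    "UTR3": [(8_700, 9_000)],
    "Intergenic": [(200, 2_500), (9_000, 11_800)],
}
_PLUS_CGI = (3_800, 4_600)
_PLUS_GENE = {"tss": 4_000, "span": (4_000, 9_000), "utr5": (4_000, 4_150),
              "exon1": (4_150, 4_450), "utr3": (8_700, 9_000)}

#: sampling mixture over region labels, loosely mimicking the 450K design
REGION_MIXTURE = {
    "TSS1500": 0.13,
    "TSS200": 0.10,
    "UTR5": 0.08,
    "Exon1": 0.05,
    "Body": 0.31,
    "UTR3": 0.04,
    "Intergenic": 0.29,
}

#: baseline logit-methylation (mean, sd) per CGI relation: islands are
#: largely unmethylated, open sea largely methylated
BASELINE_LOGIT = {
    "Island": (-2.2, 0.6),
    "Shore": (-0.5, 0.8),
    "Shelf": (0.8, 0.6),
    "OpenSea": (1.2, 0.6),
}

DEFAULT_CONDITIONS = ("CD34pos_d0", "CD34pos_woMSC", "CD34neg_woMSC", "CD34pos_wMSC")


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    Defaults mirror the study design: four conditions (fresh CD34+ day 0
    as reference, three cultured fractions), three donors, and
    hypermethylation planted in TSS1500/Shore CpGs at +0.15 beta.
    """

    n_cpg: int = 10_000
    n_genes: int | None = None  # default n_cpg // 20, min 20
    n_donors: int = 3
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    effect_categories: frozenset[str] = frozenset({"TSS1500", "Shore"})
    effect_fraction: float = 0.10
    n_effect_sites: int | None = None  # overrides effect_fraction when set
    effect_delta: float = 0.15
    noise_sd: float = 0.25
    donor_sd: float = 0.15
    missing_rate: float = 0.0
    motif_consensus: str = "AAGAGGAAGT"
    motif_plant_rate_fg: float = 0.30
    motif_plant_rate_bg: float = 0.01
    peak_plant_rate_fg: float = 0.30
    peak_plant_rate_bg: float = 0.01
    peak_width: int = 60
    window_width: int = 124
    expression_coupling: float = -4.0
    expr_noise_sd: float = 0.25
    expr_donor_sd: float = 0.15
    expr_base_mean: float = 7.0
    expr_base_sd: float = 1.5
    expr_promoter_slope: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpg < 100:
            raise ValueError("n_cpg must be >= 100")
        if self.n_genes is None:
            self.n_genes = max(20, self.n_cpg // 20)
        if not (0 < self.effect_fraction <= 1):
            raise ValueError("effect_fraction must be in (0, 1]")
        for rate in (
            self.motif_plant_rate_fg,
            self.motif_plant_rate_bg,
            self.peak_plant_rate_fg,
            self.peak_plant_rate_bg,
            self.missing_rate,
        ):
            if not (0 <= rate <= 1):
                raise ValueError("plant/missing rates must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")
        if len(self.conditions) < 2:
            raise ValueError("need at least a reference and one cultured condition")
        bad = self.effect_categories - (set(REGION_MIXTURE) | set(BASELINE_LOGIT))
        if bad:
            raise ValueError(f"unknown effect categories {sorted(bad)}")

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted, for recovery tests."""

    planted: dict[str, set[str]] = field(default_factory=dict)  # condition -> site ids
    true_delta: dict[str, float] = field(default_factory=dict)  # site id -> beta delta
    motif_fg: set[str] = field(default_factory=set)
    motif_bg: set[str] = field(default_factory=set)
    peak_sites: set[str] = field(default_factory=set)
    coupled_genes: set[str] = field(default_factory=set)

    @property
    def motif_windows(self) -> set[str]:
        return self.motif_fg | self.motif_bg

    @property
    def planted_union(self) -> set[str]:
        out: set[str] = set()
        for s in self.planted.values():
            out |= s
        return out


@dataclass
class SimulatedGenome:
    """Manifest plus the genomic scaffolding it was generated on."""

    manifest: list[CpGRecord]
    cgi_intervals: list[GenomicInterval]
    sequences: dict[str, str]
    gene_models: list[GeneModel]


def _mirror(rng_pair: tuple[int, int]) -> tuple[int, int]:
    s, e = rng_pair
    return (LOCUS - e, LOCUS - s)


def _locus_ranges(strand: str) -> dict[str, list[tuple[int, int]]]:
    if strand == "+":
        return _PLUS_RANGES
    return {lab: [_mirror(r) for r in ranges] for lab, ranges in _PLUS_RANGES.items()}


def _locus_cgi(strand: str) -> tuple[int, int]:
    return _PLUS_CGI if strand == "+" else _mirror(_PLUS_CGI)


def _locus_gene_model(gene_id: str, chrom: str, strand: str, base: int) -> GeneModel:
    g = _PLUS_GENE
    if strand == "+":
        return GeneModel(
            gene_id, chrom, "+", base + g["tss"],
            (base + g["span"][0], base + g["span"][1]),
            (base + g["utr5"][0], base + g["utr5"][1]),
            (base + g["exon1"][0], base + g["exon1"][1]),
            (base + g["utr3"][0], base + g["utr3"][1]),
        )
    span = _mirror(g["span"])
    utr5, exon1, utr3 = _mirror(g["utr5"]), _mirror(g["exon1"]), _mirror(g["utr3"])
    tss = LOCUS - g["tss"] - 1  # last base of the mirrored span
    return GeneModel(
        gene_id, chrom, "-", base + tss,
        (base + span[0], base + span[1]),
        (base + utr5[0], base + utr5[1]),
        (base + exon1[0], base + exon1[1]),
        (base + utr3[0], base + utr3[1]),
    )


def _sample_even_offset(rng: np.random.Generator, ranges: list[tuple[int, int]]) -> int:
    lengths = np.array([e - s for s, e in ranges], dtype=float)
    s, e = ranges[rng.choice(len(ranges), p=lengths / lengths.sum())]
    lo = s + (s % 2)
    n_even = (e - lo + 1) // 2
    return lo + 2 * int(rng.integers(n_even))


def simulate_manifest(config: SimConfig) -> SimulatedGenome:
    """Generate the manifest, CGI intervals, chromosome sequences and gene
    models of the synthetic array.

    Region labels are drawn from :data:`REGION_MIXTURE` (each label forced
    to appear at least once); four anchor probes guarantee every CGI class
    is represented.  CGI relations are computed from the actual positions,
    so they are consistent with the 2 kb shore / 2 kb shelf definition by
    construction, and every probe position carries a CG dinucleotide in the
    emitted sequence.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_genes = config.n_genes
    chroms = ("chr1", "chr2")
    gene_chrom = [chroms[g % 2] for g in range(n_genes)]
    gene_base = [(g // 2) * LOCUS for g in range(n_genes)]
    gene_strand = ["+" if rng.random() < 0.5 else "-" for g in range(n_genes)]
    gene_ids = [f"GENE{g:05d}" for g in range(n_genes)]

    cgi_intervals = []
    gene_models = []
    for g in range(n_genes):
        s, e = _locus_cgi(gene_strand[g])
        cgi_intervals.append(
            GenomicInterval(gene_chrom[g], gene_base[g] + s, gene_base[g] + e, f"CGI_{gene_ids[g]}")
        )
        gene_models.append(
            _locus_gene_model(gene_ids[g], gene_chrom[g], gene_strand[g], gene_base[g])
        )

    labels = list(REGION_MIXTURE)
    probs = np.array([REGION_MIXTURE[l] for l in labels])
    # anchors guarantee all four CGI classes: island (TSS200), shore
    # (TSS1500), shelf (deep gene body) and open sea (far intergenic)
    anchors = [("TSS200", None), ("TSS1500", None), ("Body", "shelf"), ("Intergenic", "opensea")]
    counts = rng.multinomial(config.n_cpg - len(anchors), probs)
    for i, c in enumerate(counts):  # every label represented at least once
        if c == 0:
            counts[int(np.argmax(counts))] -= 1
            counts[i] += 1

    assignments: list[str] = [a[0] for a in anchors]
    zones: list[str | None] = [a[1] for a in anchors]
    for lab, c in zip(labels, counts):
        assignments.extend([lab] * int(c))
        zones.extend([None] * int(c))

    used: set[tuple[str, int]] = set()
    records: list[CpGRecord] = []
    order = rng.permutation(len(assignments))
    pos_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    raw: list[tuple[str, str, int, str, frozenset[str], frozenset[str]]] = []
    for idx in order:
        lab, zone = assignments[idx], zones[idx]
        g = int(rng.integers(n_genes))
        strand = gene_strand[g]
        ranges = _locus_ranges(strand)[lab]
        if zone == "shelf":  # body sub-range 2-4 kb beyond the CGI edge
            ranges = [(7_000, 8_500)] if strand == "+" else [(3_500, 5_000)]
        elif zone == "opensea":  # far downstream intergenic
            ranges = [(9_200, 11_000)] if strand == "+" else [(1_000, 2_800)]
        for _ in range(200):
            off = _sample_even_offset(rng, ranges)
            pos = gene_base[g] + off
            if (gene_chrom[g], pos) not in used:
                break
        else:  # pragma: no cover - locus saturated
            raise RuntimeError("could not place CpG without collision; lower n_cpg")
        used.add((gene_chrom[g], pos))
        if lab == "Intergenic":
            genes, region_labels = frozenset(), frozenset({"Intergenic"})
        else:
            genes, region_labels = frozenset({gene_ids[g]}), frozenset({lab})
        raw.append((gene_chrom[g], strand, pos, lab, genes, region_labels))
        pos_by_chrom[gene_chrom[g]].append(pos)

    # order probes by genome position, name them, compute CGI relation
    raw.sort(key=lambda r: (r[0], r[2]))
    relations: dict[tuple[str, int], str] = {}
    for chrom in chroms:
        positions = np.array(sorted(pos_by_chrom[chrom]), dtype=int)
        if positions.size:
            rel = assign_cgi_relations(positions, chrom, cgi_intervals)
            relations.update({(chrom, int(p)): r for p, r in zip(positions, rel)})
    for i, (chrom, strand, pos, lab, genes, region_labels) in enumerate(raw):
        records.append(
            CpGRecord(
                cpg_id=f"cg{i:08d}",
                chrom=chrom,
                pos=pos,
                strand=strand,
                gene_ids=genes,
                region_labels=region_labels,
                cgi_relation=relations[(chrom, pos)],
            )
        )

    present = {r.cgi_relation for r in records}
    if present != {"Island", "Shore", "Shelf", "OpenSea"}:  # pragma: no cover
        raise RuntimeError(f"CGI classes missing from simulation: {present}")

    sequences = {}
    for chrom in chroms:
        n_loci = sum(1 for c in gene_chrom if c == chrom)
        length = max(n_loci, 1) * LOCUS + 200
        seq = rng.integers(0, 4, size=length).astype(np.uint8)
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[seq].copy()
        for pos in pos_by_chrom[chrom]:
            arr[pos] = ord("C")
            arr[pos + 1] = ord("G")
        sequences[chrom] = arr.tobytes().decode("ascii")

    return SimulatedGenome(records, cgi_intervals, sequences, gene_models)


# ---------------------------------------------------------------------------
# beta values

def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)


def _smoothed_mean(m: np.ndarray, sd: float) -> np.ndarray:
    """E[invlogit(m + N(0, sd^2))] by Gauss–Hermite quadrature."""
    if sd == 0:
        return _invlogit(np.asarray(m, dtype=float))
    m = np.asarray(m, dtype=float)[..., None]
    return (_GH_WEIGHTS * _invlogit(m + math.sqrt(2.0) * sd * _GH_NODES)).sum(-1) / math.sqrt(math.pi)


def _calibrated_shift(baseline: np.ndarray, delta: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Logit shifts s with E[beta(b+s)] - E[beta(b)] = delta (expectations
    under the combined donor+noise kernel).  Targets are clipped to
    [0.015, 0.985] mean beta; returns (shifts, achieved deltas)."""
    base_mean = _smoothed_mean(baseline, sd)
    target = np.clip(base_mean + delta, 0.015, 0.985)
    lo = np.full_like(baseline, -30.0)
    hi = np.full_like(baseline, 30.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _smoothed_mean(mid, sd) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    shift = 0.5 * (lo + hi) - baseline
    return shift, target - base_mean


def simulate_beta(config: SimConfig, genome: SimulatedGenome) -> tuple[BetaMatrix, GroundTruth]:
    """Donor-paired beta matrix with hypermethylation planted in the
    configured categories of every cultured (non-reference) condition.

    Planted sites are sampled from the union of CpGs carrying any effect
    category (as region label or CGI relation); the same set is planted in
    each cultured condition, emulating the overlapping culture-induced
    hypermethylation seen across cell fractions.
    """
    rng = np.random.default_rng([config.seed, 1])
    manifest = genome.manifest
    n = len(manifest)
    site_ids = [r.cpg_id for r in manifest]

    mu = np.array([BASELINE_LOGIT[r.cgi_relation][0] for r in manifest])
    sd = np.array([BASELINE_LOGIT[r.cgi_relation][1] for r in manifest])
    baseline = rng.normal(mu, sd)

    members = [
        i
        for i, r in enumerate(manifest)
        if (r.region_labels & config.effect_categories) or r.cgi_relation in config.effect_categories
    ]
    if not members:
        raise ValueError(f"no CpG falls in effect categories {sorted(config.effect_categories)}")
    n_plant = (
        config.n_effect_sites
        if config.n_effect_sites is not None
        else int(round(config.effect_fraction * len(members)))
    )
    if n_plant > len(members):
        raise ValueError(
            f"requested {n_plant} effect sites but only {len(members)} CpGs lie in "
            f"{sorted(config.effect_categories)}"
        )
    planted_idx = np.sort(rng.choice(members, size=n_plant, replace=False))

    kernel_sd = math.sqrt(config.noise_sd**2 + config.donor_sd**2)
    if config.effect_delta != 0 and n_plant:
        shifts, achieved = _calibrated_shift(baseline[planted_idx], config.effect_delta, kernel_sd)
    else:
        shifts = np.zeros(n_plant)
        achieved = np.zeros(n_plant)

    donors = [f"D{d + 1}" for d in range(config.n_donors)]
    donor_effect = rng.normal(0.0, config.donor_sd, size=(n, config.n_donors))

    cultured = [c for c in config.conditions if c != config.reference_condition]
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    shift_vec = np.zeros(n)
    shift_vec[planted_idx] = shifts
    for cond in config.conditions:
        cond_shift = shift_vec if cond in cultured else np.zeros(n)
        for d, donor in enumerate(donors):
            logit = baseline + cond_shift + donor_effect[:, d] + rng.normal(0, config.noise_sd, n)
            columns[f"{cond}_{donor}"] = _invlogit(logit)
            sheet_rows.append({"sample_id": f"{cond}_{donor}", "donor": donor, "condition": cond})

    values = pd.DataFrame(columns, index=pd.Index(site_ids, name="cpg_id"))
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        arr = values.to_numpy()
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")

    planted_ids = {site_ids[i] for i in planted_idx}
    truth = GroundTruth(
        planted={cond: set(planted_ids) for cond in cultured},
        true_delta={site_ids[i]: float(a) for i, a in zip(planted_idx, achieved)},
    )
    return BetaMatrix(values, samples), truth


# ---------------------------------------------------------------------------
# sequences, motifs and peaks

def simulate_sequences_and_peaks(
    config: SimConfig, genome: SimulatedGenome, truth: GroundTruth
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Per-CpG windows (named by cpg_id) with the consensus planted into a
    fraction of the affected-site windows, and ChIP-Seq-style peaks centred
    within half a window of affected sites.

    Updates ``truth`` in place with the motif-bearing window ids and the
    peak-adjacent site ids.
    """
    rng = np.random.default_rng([config.seed, 2])
    width = config.window_width
    consensus = config.motif_consensus.upper()
    if len(consensus) > width:
        raise ValueError("motif consensus longer than the window")
    half = width // 2
    planted = truth.planted_union
    windows: dict[str, str] = {}
    peaks: list[GenomicInterval] = []
    n_peak = 0
    for site in genome.manifest:
        seq = genome.sequences[site.chrom]
        start, end = site.pos - half, site.pos + half
        if start < 0 or end > len(seq):
            continue
        w = seq[start:end]
        is_fg = site.cpg_id in planted
        plant_rate = config.motif_plant_rate_fg if is_fg else config.motif_plant_rate_bg
        if rng.random() < plant_rate:
            # keep the central CG intact: plant left or right of the centre
            left_max = half - 1 - len(consensus)
            sides = []
            if left_max >= 0:
                sides.append(("L", left_max))
            if half + 2 <= width - len(consensus):
                sides.append(("R", width - len(consensus) - half - 2))
            side, span = sides[int(rng.integers(len(sides)))]
            off = int(rng.integers(span + 1)) + (0 if side == "L" else half + 2)
            w = w[:off] + consensus + w[off + len(consensus) :]
            (truth.motif_fg if is_fg else truth.motif_bg).add(site.cpg_id)
        windows[site.cpg_id] = w
        peak_rate = config.peak_plant_rate_fg if is_fg else config.peak_plant_rate_bg
        if rng.random() < peak_rate:
            center = site.pos + int(rng.integers(-half + 1, half))
            pstart = max(0, center - config.peak_width // 2)
            peaks.append(
                GenomicInterval(site.chrom, pstart, pstart + config.peak_width, f"peak{n_peak:05d}")
            )
            n_peak += 1
            truth.peak_sites.add(site.cpg_id)
    return windows, sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))


# ---------------------------------------------------------------------------
# expression

def _promoter_sites(genome: SimulatedGenome) -> dict[str, list[CpGRecord]]:
    out: dict[str, list[CpGRecord]] = {}
    for r in genome.manifest:
        if r.region_labels & {"TSS200", "Exon1"}:
            for g in r.gene_ids:
                out.setdefault(g, []).append(r)
    return out


def simulate_expression(
    config: SimConfig, genome: SimulatedGenome, truth: GroundTruth
) -> ExpressionMatrix:
    """Log2 expression coupled to promoter methylation.

    The baseline level of each gene decreases with the methylation of its
    promoter (TSS200/1st-exon) CpGs, so highly expressed genes have
    unmethylated promoters; genes whose promoter CpGs were planted hyper
    are additionally shifted by ``expression_coupling * effect_delta`` in
    the cultured conditions.  Updates ``truth.coupled_genes`` in place.
    """
    rng = np.random.default_rng([config.seed, 3])
    gene_ids = sorted({g for r in genome.manifest for g in r.gene_ids})
    promoters = _promoter_sites(genome)
    # approximate promoter methylation from the baseline class means
    class_beta = {rel: _invlogit(np.array([BASELINE_LOGIT[rel][0]]))[0] for rel in BASELINE_LOGIT}
    prom_beta = np.array(
        [
            np.mean([class_beta[r.cgi_relation] for r in promoters[g]]) if g in promoters else 0.3
            for g in gene_ids
        ]
    )
    baseline = (
        config.expr_base_mean
        - config.expr_promoter_slope * (prom_beta - prom_beta.mean())
        + rng.normal(0, config.expr_base_sd, len(gene_ids))
    )

    planted = truth.planted_union
    coupled: list[int] = []
    shift = np.zeros(len(gene_ids))
    for gi, g in enumerate(gene_ids):
        hits = [r for r in promoters.get(g, []) if r.cpg_id in planted]
        if hits:
            mean_delta = float(np.mean([truth.true_delta[r.cpg_id] for r in hits]))
            shift[gi] = config.expression_coupling * mean_delta
            coupled.append(gi)
    truth.coupled_genes = {gene_ids[i] for i in coupled}

    donors = [f"D{d + 1}" for d in range(config.n_donors)]
    donor_effect = rng.normal(0.0, config.expr_donor_sd, size=(len(gene_ids), config.n_donors))
    cultured = [c for c in config.conditions if c != config.reference_condition]
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for cond in config.conditions:
        cond_shift = shift if cond in cultured else np.zeros(len(gene_ids))
        for d, donor in enumerate(donors):
            columns[f"{cond}_{donor}"] = (
                baseline
                + cond_shift
                + donor_effect[:, d]
                + rng.normal(0, config.expr_noise_sd, len(gene_ids))
            )
            sheet_rows.append({"sample_id": f"{cond}_{donor}", "donor": donor, "condition": cond})
    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")
    return ExpressionMatrix(values, samples)


def simulate_gene_sets(
    config: SimConfig, genome: SimulatedGenome, truth: GroundTruth, n_random: int = 5
) -> dict[str, set[str]]:
    """Gene sets for the Fisher gene-set route: one set collecting the
    genes with planted promoter methylation plus seeded random sets."""
    rng = np.random.default_rng([config.seed, 4])
    gene_ids = sorted({g for r in genome.manifest for g in r.gene_ids})
    sets: dict[str, set[str]] = {}
    if truth.coupled_genes:
        sets["PLANTED_PROMOTER"] = set(truth.coupled_genes)
    size = max(5, len(gene_ids) // 20)
    for k in range(n_random):
        sets[f"RANDOM_{k}"] = set(rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False))
    return sets


# ---------------------------------------------------------------------------
# full study + file emission

def simulate_study(config: SimConfig):
    """Run every generator stage; returns (genome, beta, truth, windows,
    peaks, expression, gene_sets)."""
    genome = simulate_manifest(config)
    beta, truth = simulate_beta(config, genome)
    windows, peaks = simulate_sequences_and_peaks(config, genome, truth)
    expr = simulate_expression(config, genome, truth)
    gene_sets = simulate_gene_sets(config, genome, truth)
    return genome, beta, truth, windows, peaks, expr, gene_sets


def write_simulation(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit every file the pipeline readers consume, plus the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, beta, truth, windows, peaks, expr, gene_sets = simulate_study(config)
    paths = {
        "manifest": out / "manifest.tsv",
        "beta": out / "beta.tsv",
        "samples": out / "samples.tsv",
        "cgi": out / "cgi.bed",
        "genome": out / "genome.fa",
        "windows": out / "windows.fa",
        "peaks": out / "peaks.bed",
        "expression": out / "expression.tsv",
        "expr_samples": out / "expr_samples.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "pwm": out / "motifs.txt",
        "truth": out / "ground_truth.tsv",
    }
    cio.write_manifest(genome.manifest, paths["manifest"])
    cio.write_beta_matrix(beta, paths["beta"], paths["samples"])
    cio.write_bed(genome.cgi_intervals, paths["cgi"])
    cio.write_fasta(genome.sequences, paths["genome"])
    cio.write_fasta(windows, paths["windows"])
    cio.write_bed(peaks, paths["peaks"])
    cio.write_expression(expr, paths["expression"], paths["expr_samples"])
    cio.write_gmt(gene_sets, paths["gene_sets"])
    from .types import PWM

    cio.write_pwms([PWM.from_consensus("planted", config.motif_consensus)], paths["pwm"])
    rows = []
    planted = truth.planted_union
    for r in genome.manifest:
        rows.append(
            {
                "cpg_id": r.cpg_id,
                "planted": int(r.cpg_id in planted),
                "true_delta": truth.true_delta.get(r.cpg_id, 0.0),
                "motif_planted": int(r.cpg_id in truth.motif_windows),
                "peak_planted": int(r.cpg_id in truth.peak_sites),
            }
        )
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
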