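"""Domain types shared by every stage of the pipeline.

The pipeline operates on Illumina-450K-style methylation data: per-CpG
beta-values in [0, 1], a probe manifest carrying gene-region and
CpG-island-relation annotation, and donor-paired samples across culture
conditions.  All genomic coordinates are 0-based, half-open internally;
the 1-based manifest convention is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Gene-region vocabulary (Illumina 450K style).  ``Intergenic`` is mutually
#: exclusive with every other label.
REGION_LABELS = ("TSS1500", "TSS200", "UTR5", "Exon1", "Body", "UTR3", "Intergenic")

#: CGI relation classes.  Shore = first 2 kb outside an island, Shelf = the
#: next 2 kb, OpenSea = beyond the shelf.
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

#: Input synonyms normalised on read (Illumina manifests write "1stExon" etc.).
REGION_SYNONYMS = {
    "1stExon": "Exon1",
    "5'UTR": "UTR5",
    "3'UTR": "UTR3",
    "5UTR": "UTR5",
    "3UTR": "UTR3",
}

CGI_SYNONYMS = {
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
    "": "OpenSea",
}

DNA_ALPHABET = "ACGT"


@dataclass(frozen=True)
class CpGRecord:
    """One array probe: position plus gene/CGI annotation.

    ``pos`` is the 0-based position of the C of the CpG dinucleotide.
    A probe affiliated with several genes accumulates all their region
    labels; a probe with no gene affiliation carries exactly
    ``{"Intergenic"}``.
    """

    cpg_id: str
    chrom: str
    pos: int
    strand: str = "+"
    gene_ids: frozenset[str] = field(default_factory=frozenset)
    region_labels: frozenset[str] = field(default_factory=lambda: frozenset({"Intergenic"}))
    cgi_relation: str = "OpenSea"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.cpg_id}: negative position {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.cpg_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.region_labels:
            raise ValueError(f"{self.cpg_id}: region_labels must be nonempty")
        unknown = self.region_labels - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"{self.cpg_id}: unknown region label(s) {sorted(unknown)}")
        if "Intergenic" in self.region_labels and len(self.region_labels) > 1:
            raise ValueError(f"{self.cpg_id}: Intergenic is exclusive with other labels")
        if self.cgi_relation not in CGI_RELATIONS:
            raise ValueError(f"{self.cpg_id}: unknown CGI relation {self.cgi_relation!r}")


@dataclass
class BetaMatrix:
    """Sites x samples beta-values plus the per-sample design columns.

    ``values`` is a pandas DataFrame (index = cpg_id, columns = sample_id)
    holding floats in [0, 1] with NaN for missing.  ``samples`` is a
    DataFrame indexed by sample_id with columns ``donor`` and ``condition``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("beta matrix columns must match sample sheet rows (same order)")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value out of [0,1] at site {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )
        if not self.values.index.is_unique:
            raise ValueError("duplicate cpg_id in beta matrix")
        pairs = list(zip(self.samples["donor"], self.samples["condition"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(donor, condition) pairs must be unique")

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_sites(self, site_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(site_ids)], self.samples)


@dataclass(frozen=True)
class PairedDesign:
    """A donor-paired two-condition contrast.

    ``pairs`` lists (donor, sample_in_a, sample_in_b); differences are taken
    b - a, so ``condition_a`` is the reference (e.g. fresh CD34+ day 0).
    """

    condition_a: str
    condition_b: str
    pairs: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("paired design needs >= 2 donor pairs")
        seen: set[str] = set()
        for _, sa, sb in self.pairs:
            for s in (sa, sb):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, condition_a: str, condition_b: str) -> "PairedDesign":
        """Pair samples of the two conditions by shared donor."""
        for cond in (condition_a, condition_b):
            if cond not in set(samples["condition"]):
                raise ValueError(f"condition {cond!r} not present in sample sheet")
        a = samples[samples["condition"] == condition_a]
        b = samples[samples["condition"] == condition_b]
        pairs = []
        for donor in a["donor"]:
            hit = b[b["donor"] == donor]
            if len(hit) == 1:
                sa = a[a["donor"] == donor].index[0]
                pairs.append((donor, sa, hit.index[0]))
        return cls(condition_a, condition_b, tuple(pairs))


@dataclass
class SiteStat:
    """Per-CpG paired differential-methylation result (delta = b - a)."""

    cpg_id: str
    delta: float
    s2: float
    df: float
    t_mod: float
    p: float
    adj_p: float = float("nan")
    direction: str = "ns"

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.cpg_id}: p must be in (0,1], got {self.p}")


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters (d0, s0^2).

    ``prior_df = 0`` recovers the ordinary paired t-test; ``prior_df = inf``
    replaces every per-site variance with ``prior_var``.
    """

    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if not self.prior_var > 0:
            raise ValueError("prior_var must be > 0")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open [start, end) interval, 0-based."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class EnrichmentRecord:
    """One category's over-representation summary against a background.

    k of n selected items fall in the category; K of N background items do.
    ``fold`` = (k/n)/(K/N); ``p`` is the one-sided enrichment p-value.
    """

    category: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    test: str  # "hypergeometric" or "fisher"

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"{self.category}: inconsistent counts k={self.k} n={self.n} K={self.K} N={self.N}"
            )
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.category}: p must be in (0,1], got {self.p}")


@dataclass
class PWM:
    """Position weight matrix over (A, C, G, T)."""

    motif_id: str
    probs: np.ndarray  # L x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must be an L x 4 matrix")
        if np.any(self.probs < 0) or np.any(self.background < 0):
            raise ValueError("PWM probabilities must be >= 0")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2 odds with pseudocount regularisation."""
        p = self.probs + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        b = self.background + self.pseudocount
        b = b / b.sum()
        return np.log2(p / b)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, match_prob: float = 0.97) -> "PWM":
        """Near-deterministic PWM for a consensus sequence."""
        idx = [DNA_ALPHABET.index(b) for b in consensus.upper()]
        probs = np.full((len(idx), 4), (1 - match_prob) / 3)
        probs[np.arange(len(idx)), idx] = match_prob
        return cls(motif_id, probs)


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized log2 intensities plus design columns."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("expression columns must match sample sheet rows (same order)")
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene_id in expression matrix")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneModel:
    """Minimal strand-aware gene structure used for region-label assignment.

    All coordinates 0-based half-open on the genome (not transcript) axis.
    ``tss`` is the transcription start; for '-' strand genes the numeric
    intervals still satisfy start < end.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: tuple[int, int]
    utr5: tuple[int, int] | None = None
    exon1: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for iv in (self.span, self.utr5, self.exon1, self.utr3):
            if iv is not None and not iv[0] < iv[1]:
                raise ValueError(f"{self.gene_id}: malformed interval {iv}")


@dataclass(frozen=True)
class Window:
    """Fixed-width sequence window centred on a CpG (half-open coordinates)."""

    cpg_id: str
    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"{self.cpg_id}: window span != sequence length")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    """One PWM match inside a window."""

    cpg_id: str
    motif_id: str
    offset: int
    strand: str
    score: float
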