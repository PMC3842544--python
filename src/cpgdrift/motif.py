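"""PWM motif scanning around CpGs and ChIP-Seq peak co-location testing.

Windows are total-width intervals centred on the CpG (the default 124 bp
window spans ±62 bp).  Motif hits are log2-odds matches at or above a
fraction of the PWM's maximum attainable score, on both strands.  Motif
enrichment counts windows-with-≥1-hit against the array background
(hypergeometric); peak co-location tests, per window width, whether
hypermethylated CpGs lie near peaks more often than the rest of the array
(one-sided Fisher).  Peak positivity is monotone in window width by
construction (nested windows).
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .context import fisher_enrichment_2x2, hypergeometric_enrichment, merge_intervals
from .types import CpGRecord, EnrichmentRecord, GenomicInterval, MotifHit, PWM, Window

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def extract_windows(
    cpg_sites: list[CpGRecord],
    sequences: dict[str, str],
    width: int = 124,
) -> list[Window]:
    """Cut a width-bp window centred on each CpG from chromosome sequences.

    The window is [pos - width/2, pos + width/2), so the CpG's C sits at
    offset width/2.  Sites whose window would cross a sequence boundary are
    dropped and logged.
    """
    if width < 2 or width % 2:
        raise ValueError(f"window width must be even and >= 2, got {width}")
    half = width // 2
    windows: list[Window] = []
    n_dropped = 0
    for site in cpg_sites:
        seq = sequences.get(site.chrom)
        if seq is None:
            raise ValueError(f"no sequence for chromosome {site.chrom!r}")
        start, end = site.pos - half, site.pos + half
        if start < 0 or end > len(seq):
            n_dropped += 1
            continue
        windows.append(Window(site.cpg_id, site.chrom, start, end, seq[start:end]))
    if n_dropped:
        log.info("dropped %d window(s) crossing a sequence boundary", n_dropped)
    return windows


def scan_pwm(
    window: Window,
    pwm: PWM,
    threshold_fraction: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All PWM matches in a window scoring ≥ threshold_fraction * max score.

    Scores are summed per-position log2 odds against the background.  On
    the minus strand the reverse complement is scanned; offsets are always
    reported in forward-window coordinates.  Offsets covering a non-ACGT
    base are skipped (logged), never counted as hits.
    """
    L = len(pwm)
    if window.width < L:
        raise ValueError(f"window {window.cpg_id!r} shorter than motif ({window.width} < {L})")
    if pwm.max_score <= 0 and threshold_fraction > 0:
        # uninformative matrix (no position beats the background): no hits
        return []
    threshold = threshold_fraction * pwm.max_score
    lo = pwm.log_odds
    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        seq = window.sequence if strand == "+" else reverse_complement(window.sequence)
        codes = _encode(seq)
        views = sliding_window_view(codes, L)  # (n_offsets, L)
        valid = np.all(views >= 0, axis=1)
        if not valid.all():
            log.debug(
                "window %s: %d offset(s) with non-ACGT base skipped",
                window.cpg_id,
                int((~valid).sum()),
            )
        scores = np.where(
            valid,
            lo[np.arange(L), np.clip(views, 0, 3)].sum(axis=1),
            -np.inf,
        )
        for off in np.nonzero(scores >= threshold)[0]:
            fwd_off = int(off) if strand == "+" else window.width - L - int(off)
            hits.append(MotifHit(window.cpg_id, pwm.motif_id, fwd_off, strand, float(scores[off])))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def windows_with_hit(
    windows: list[Window],
    pwm: PWM,
    threshold_fraction: float = 0.8,
    both_strands: bool = True,
) -> set[str]:
    """IDs of windows containing at least one motif hit."""
    out: set[str] = set()
    for w in windows:
        if scan_pwm(w, pwm, threshold_fraction, both_strands):
            out.add(w.cpg_id)
    return out


def motif_enrichment(
    hyper_windows: list[Window],
    background_windows: list[Window],
    pwm: PWM,
    threshold_fraction: float = 0.8,
) -> EnrichmentRecord:
    """Hypergeometric enrichment of motif-bearing windows among
    hypermethylated CpGs versus the array background.

    The counting unit is the window: a window is positive iff it contains
    ≥1 hit.  Hyper windows must be a subset of the background windows.
    """
    if not background_windows:
        raise ValueError("empty background window set")
    bg_ids = {w.cpg_id for w in background_windows}
    hyper_ids = {w.cpg_id for w in hyper_windows}
    if not hyper_ids <= bg_ids:
        raise ValueError("hyper windows must be a subset of the background windows")
    positive = windows_with_hit(background_windows, pwm, threshold_fraction)
    return hypergeometric_enrichment(hyper_ids, positive, bg_ids, category=pwm.motif_id)


def _peak_positive(
    sites: list[CpGRecord], peaks: list[GenomicInterval], width: int
) -> np.ndarray:
    """Boolean per site: does any merged peak intersect [pos-w/2, pos+w/2)?"""
    merged = merge_intervals(peaks)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in merged}:
        ivs = [p for p in merged if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([p.start for p in ivs]),
            np.array([p.end for p in ivs]),
        )
    half = width // 2
    out = np.zeros(len(sites), dtype=bool)
    for i, site in enumerate(sites):
        if site.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[site.chrom]
        lo, hi = site.pos - half, site.pos + half
        j = int(np.searchsorted(ends, lo, side="right"))  # first peak ending after lo
        out[i] = j < len(starts) and starts[j] < hi
    return out


def peak_colocation(
    hyper_site_ids: set[str],
    all_sites: list[CpGRecord],
    peaks: list[GenomicInterval],
    window_widths: tuple[int, ...] = (124, 200, 500, 1000),
) -> list[dict]:
    """Per window width: proportion of hyper and of all array CpGs with a
    peak inside the window, and a one-sided Fisher enrichment p.

    The 2x2 table contrasts hyper vs non-hyper array sites by peak
    positivity; the reported background proportion covers the whole array
    (the figure-style grey bar).  With no peaks all proportions are 0 and
    p = 1.
    """
    known = {s.cpg_id for s in all_sites}
    if not hyper_site_ids <= known:
        raise ValueError("hyper sites must be drawn from the array sites")
    is_hyper = np.array([s.cpg_id in hyper_site_ids for s in all_sites])
    results: list[dict] = []
    for width in window_widths:
        if not peaks:
            results.append(
                {
                    "width": width,
                    "n_hyper": int(is_hyper.sum()),
                    "k_hyper": 0,
                    "proportion_hyper": 0.0,
                    "n_background": len(all_sites),
                    "k_background": 0,
                    "proportion_background": 0.0,
                    "p": 1.0,
                }
            )
            continue
        pos = _peak_positive(all_sites, peaks, width)
        k_h = int((pos & is_hyper).sum())
        n_h = int(is_hyper.sum())
        k_rest = int((pos & ~is_hyper).sum())
        n_rest = len(all_sites) - n_h
        table = np.array([[k_h, n_h - k_h], [k_rest, n_rest - k_rest]])
        rec = fisher_enrichment_2x2(table, category=f"peaks@{width}bp")
        results.append(
            {
                "width": width,
                "n_hyper": n_h,
                "k_hyper": k_h,
                "proportion_hyper": k_h / n_h if n_h else 0.0,
                "n_background": len(all_sites),
                "k_background": int(pos.sum()),
                "proportion_background": float(pos.mean()),
                "p": rec.p,
            }
        )
    return results
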