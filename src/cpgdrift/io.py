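"""Readers and writers for every external format the pipeline touches.

Tabular formats (manifest, beta matrix, sample sheet, expression, result
tables) are tab-separated with a header.  BED is standard 0-based half-open
BED3/4.  Manifest positions are 1-based on disk (Illumina convention) and
converted to the internal 0-based convention on read.
"""

from __future__ import annotations

import math
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CGI_RELATIONS,
    CGI_SYNONYMS,
    REGION_LABELS,
    REGION_SYNONYMS,
    BetaMatrix,
    CpGRecord,
    EnrichmentRecord,
    ExpressionMatrix,
    GenomicInterval,
    PWM,
    SiteStat,
)

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "NULL"}

MANIFEST_COLUMNS = ["ID", "CHR", "POS", "STRAND", "GENES", "REGIONS", "CGI_RELATION"]


# ---------------------------------------------------------------------------
# manifest

def _normalise_region(token: str, row_id: str) -> str:
    token = REGION_SYNONYMS.get(token, token)
    if token not in REGION_LABELS:
        raise ValueError(f"manifest row {row_id!r}: unknown region token {token!r}")
    return token


def _normalise_cgi(token: str, row_id: str) -> str:
    token = CGI_SYNONYMS.get(token, token)
    if token not in CGI_RELATIONS:
        raise ValueError(f"manifest row {row_id!r}: unknown CGI relation {token!r}")
    return token


def read_manifest(path: str | Path) -> list[CpGRecord]:
    """Read a tab-separated CpG manifest into :class:`CpGRecord` objects.

    Expected columns: ID, CHR, POS (1-based), STRAND, GENES (semicolon
    list, may be empty), REGIONS (semicolon list parallel to GENES),
    CGI_RELATION.  Duplicate IDs and unknown vocabulary are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing column(s) {missing}")
    if df["ID"].duplicated().any():
        dup = df.loc[df["ID"].duplicated(), "ID"].iloc[0]
        raise ValueError(f"manifest {path}: duplicate cpg_id {dup!r}")
    records: list[CpGRecord] = []
    for row in df.itertuples(index=False):
        genes = frozenset(g for g in row.GENES.split(";") if g)
        if genes:
            labels = frozenset(
                _normalise_region(tok, row.ID) for tok in row.REGIONS.split(";") if tok
            )
            if not labels or labels == {"Intergenic"}:
                raise ValueError(
                    f"manifest row {row.ID!r}: gene-affiliated probe needs gene-region labels"
                )
        else:
            labels = frozenset({"Intergenic"})
        records.append(
            CpGRecord(
                cpg_id=row.ID,
                chrom=row.CHR,
                pos=int(row.POS) - 1,  # 1-based on disk
                strand=row.STRAND,
                gene_ids=genes,
                region_labels=labels,
                cgi_relation=_normalise_cgi(row.CGI_RELATION, row.ID),
            )
        )
    return records


def write_manifest(records: list[CpGRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        genes = sorted(r.gene_ids)
        if genes:
            # one region token per gene is not tracked internally; emit the
            # label set as a parallel-independent semicolon list
            regions = sorted(r.region_labels)
        else:
            regions = []
        rows.append(
            {
                "ID": r.cpg_id,
                "CHR": r.chrom,
                "POS": r.pos + 1,
                "STRAND": r.strand,
                "GENES": ";".join(genes),
                "REGIONS": ";".join(regions),
                "CGI_RELATION": r.cgi_relation,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# beta matrix / sample sheet

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "donor", "condition"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet {path}: missing column {col!r}")
    return sheet.set_index("sample_id")


def read_beta_matrix(path: str | Path, sample_sheet_path: str | Path) -> BetaMatrix:
    """Read a sites x samples beta table plus its sample sheet.

    Values outside [0, 1] are hard errors naming the offending cell;
    "NA"/empty cells become missing (NaN).
    """
    samples = read_sample_sheet(sample_sheet_path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    site_col = raw.columns[0]
    raw = raw.set_index(site_col)
    if set(raw.columns) != set(samples.index):
        raise ValueError(
            f"beta matrix {path}: columns {list(raw.columns)} do not match "
            f"sample sheet samples {list(samples.index)}"
        )
    values = raw[list(samples.index)].apply(
        lambda col: col.map(lambda v: math.nan if v.strip() in MISSING_TOKENS else float(v))
    )
    arr = values.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0) | (arr > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"beta matrix {path}: value {arr[i, j]} out of [0,1] at site "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )
    return BetaMatrix(values, samples)


def write_beta_matrix(matrix: BetaMatrix, beta_path: str | Path, sheet_path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "cpg_id"
    out.to_csv(beta_path, sep="\t", na_rep="NA", float_format="%.6g")
    sheet = matrix.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sheet_path, sep="\t")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 (0-based half-open); output sorted by (chrom, start)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else "."
            intervals.append(GenomicInterval(chrom, start, end, name))
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA into an ordered {name: sequence} dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"{path}: duplicate sequence name {name!r}")
                seqs[name] = []
            elif line:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{lineno}: GMT needs name, description, genes")
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# PWM (plain text: one row per position, columns A C G T)

def read_pwms(path: str | Path) -> list[PWM]:
    """Plain-text PWMs: ``>motif_id`` header then one line per position with
    four probabilities (A C G T order)."""
    pwms: list[PWM] = []
    motif_id = None
    rows: list[list[float]] = []

    def flush() -> None:
        if motif_id is not None:
            if not rows:
                raise ValueError(f"{path}: motif {motif_id!r} has no rows")
            pwms.append(PWM(motif_id, np.array(rows)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = []
            else:
                if motif_id is None:
                    raise ValueError(f"{path}: PWM rows before first '>' header")
                rows.append([float(x) for x in line.split()])
    flush()
    return pwms


def write_pwms(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.probs:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# expression

def read_expression(path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    samples = read_sample_sheet(sample_sheet_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if set(raw.columns) != set(samples.index):
        raise ValueError(f"expression matrix {path}: columns do not match sample sheet")
    return ExpressionMatrix(raw[list(samples.index)].astype(float), samples)


def write_expression(expr: ExpressionMatrix, path: str | Path, sheet_path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
    sheet = expr.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sheet_path, sep="\t")


# ---------------------------------------------------------------------------
# result tables (SiteStat / EnrichmentRecord) — write->read round trips

_SITESTAT_COLS = [f.name for f in dataclass_fields(SiteStat)]
_ENRICH_COLS = [f.name for f in dataclass_fields(EnrichmentRecord)]


def write_results(records: list, path: str | Path) -> None:
    """Write a homogeneous list of SiteStat or EnrichmentRecord as TSV."""
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError(f"mixed record kinds: {sorted(k.__name__ for k in kinds)}")
    kind = kinds.pop() if kinds else SiteStat
    if kind is SiteStat:
        cols = _SITESTAT_COLS
    elif kind is EnrichmentRecord:
        cols = _ENRICH_COLS
    else:
        raise ValueError(f"unsupported record kind {kind.__name__}")
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_site_stats(path: str | Path) -> list[SiteStat]:
    df = pd.read_csv(path, sep="\t")
    return [SiteStat(**{c: row[c] for c in _SITESTAT_COLS}) for _, row in df.iterrows()]


def read_enrichment_records(path: str | Path) -> list[EnrichmentRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        EnrichmentRecord(**{c: row[c] for c in _ENRICH_COLS}) for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# summaries

def summarize_beta(matrix: BetaMatrix, n_bins: int = 20) -> pd.DataFrame:
    """Per-sample mean, median and histogram counts over equal bins on [0,1].

    The last bin is right-closed so a beta of exactly 1.0 is counted.
    Histogram counts per sample sum to that sample's non-missing sites.
    """
    rows = []
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for sample in matrix.sample_ids:
        col = matrix.values[sample].to_numpy(dtype=float)
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise ValueError(f"sample {sample!r} has no non-missing beta values")
        counts, _ = np.histogram(col, bins=edges)  # numpy closes the last bin
        row = {"sample_id": sample, "mean": col.mean(), "median": float(np.median(col))}
        row.update({f"bin_{i}": int(c) for i, c in enumerate(counts)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def gene_profile(
    gene_id: str,
    manifest: list[CpGRecord],
    matrix: BetaMatrix,
) -> pd.DataFrame:
    """Mean beta per condition for every CpG affiliated with a gene.

    Rows are the gene's CpGs ordered by genomic position; columns are the
    conditions in sample-sheet order.  Mirrors the per-gene methylation
    profiles used to display locus-level culture effects.
    """
    sites = [r for r in manifest if gene_id in r.gene_ids]
    if not sites:
        raise ValueError(f"gene {gene_id!r} has no affiliated CpG in the manifest")
    sites.sort(key=lambda r: (r.chrom, r.pos))
    conditions = list(dict.fromkeys(matrix.samples["condition"]))
    data = {}
    for cond in conditions:
        cols = matrix.samples.index[matrix.samples["condition"] == cond]
        sub = matrix.values.loc[[r.cpg_id for r in sites], cols]
        data[cond] = sub.mean(axis=1, skipna=True)
    out = pd.DataFrame(data)
    out.insert(0, "pos", [r.pos for r in sites])
    return out
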