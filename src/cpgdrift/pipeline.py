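"""End-to-end orchestration: simulate -> dm -> enrich -> motif/colocate ->
integrate, driven by a single YAML config.

The run is a pure function of the config: every stochastic stage is seeded
from the config seed, outputs carry no timestamps, and re-running with an
identical config reproduces byte-identical files.  A run manifest
(JSON) records inputs, parameters, seed, package versions and per-stage
row counts; on a stage failure the manifest marks the failure point and
partial outputs are preserved.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .context import category_enrichment_profile, gene_set_enrichment
from .dm import overlap_comparisons, run_contrast
from .integrate import differential_expression, dm_de_association
from .motif import motif_enrichment, peak_colocation
from .simulate import SimConfig, simulate_study
from .types import PairedDesign, PWM, Window

log = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclass_fields(SimConfig)}

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "run",
    "simulate": {},
    "dm": {"keep_fraction": 0.5, "alpha": 0.05, "moderation": "estimate", "contrasts": None},
    "enrich": {},
    "motif": {"threshold_fraction": 0.8},
    "colocate": {"widths": [124, 200, 500, 1000]},
    "integrate": {"region": "TSS200", "expr_alpha": 0.05},
}

_SECTION_KEYS = {
    "dm": {"keep_fraction", "alpha", "moderation", "contrasts"},
    "enrich": set(),
    "motif": {"threshold_fraction"},
    "colocate": {"widths"},
    "integrate": {"region", "expr_alpha"},
}


def load_config(source: str | Path | dict) -> dict:
    """Load, default-fill and validate a pipeline config.

    Unknown keys, bad types and contrasts naming absent conditions are all
    pre-flight errors raised before any stage runs.
    """
    if isinstance(source, dict):
        user = dict(source)
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for key, val in user.items():
        if key in ("seed", "out_dir"):
            cfg[key] = val
        else:
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            if key == "simulate":
                bad = set(val) - _SIM_KEYS
            else:
                bad = set(val) - _SECTION_KEYS[key]
            if bad:
                raise ValueError(f"unknown key(s) in [{key}]: {sorted(bad)}")
            cfg[key].update(val)
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")

    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs.setdefault("seed", cfg["seed"])
    if "effect_categories" in sim_kwargs:
        sim_kwargs["effect_categories"] = frozenset(sim_kwargs["effect_categories"])
    if "conditions" in sim_kwargs:
        sim_kwargs["conditions"] = tuple(sim_kwargs["conditions"])
    sim_config = SimConfig(**sim_kwargs)  # validates simulate section

    contrasts = cfg["dm"]["contrasts"]
    if contrasts is None:
        ref = sim_config.reference_condition
        contrasts = [[ref, c] for c in sim_config.conditions if c != ref]
        cfg["dm"]["contrasts"] = contrasts
    for pair in contrasts:
        if len(pair) != 2:
            raise ValueError(f"each contrast must name two conditions, got {pair}")
        for cond in pair:
            if cond not in sim_config.conditions:
                raise ValueError(f"contrast names unknown condition {cond!r}")
    if not (0 < cfg["dm"]["keep_fraction"] <= 1):
        raise ValueError("dm.keep_fraction must be in (0, 1]")
    if not (0 < cfg["dm"]["alpha"] < 1):
        raise ValueError("dm.alpha must be in (0, 1)")
    cfg["_sim_config"] = sim_config
    return cfg


def run_pipeline(source: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """Execute every stage and write outputs plus run_manifest.json."""
    cfg = load_config(source)
    sim_config: SimConfig = cfg.pop("_sim_config")
    run_dir = Path(out_dir if out_dir is not None else cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)

    manifest_info: dict = {
        "config": {k: v for k, v in cfg.items() if not k.startswith("_")},
        "versions": {
            "cpgdrift": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": ".".join(map(str, sys.version_info[:3])),
        },
        "stages": {},
    }

    def _finish_stage(name: str, t0: float, **counts) -> None:
        manifest_info["stages"][name] = {"status": "ok", **counts}
        log.info("stage %-10s done in %.2fs %s", name, time.time() - t0, counts)

    stage = "simulate"
    try:
        t0 = time.time()
        genome, beta, truth, windows, peaks, expr, gene_sets = simulate_study(sim_config)
        sim_dir = run_dir / "sim"
        sim_dir.mkdir(exist_ok=True)
        cio.write_manifest(genome.manifest, sim_dir / "manifest.tsv")
        cio.write_beta_matrix(beta, sim_dir / "beta.tsv", sim_dir / "samples.tsv")
        cio.write_bed(genome.cgi_intervals, sim_dir / "cgi.bed")
        cio.write_fasta(windows, sim_dir / "windows.fa")
        cio.write_bed(peaks, sim_dir / "peaks.bed")
        cio.write_expression(expr, sim_dir / "expression.tsv", sim_dir / "expr_samples.tsv")
        cio.write_gmt(gene_sets, sim_dir / "gene_sets.gmt")
        _finish_stage(stage, t0, n_cpg=len(genome.manifest), n_peaks=len(peaks),
                      n_planted=len(truth.planted_union))

        stage = "dm"
        t0 = time.time()
        dm_cfg = cfg["dm"]
        stats_by_contrast = {}
        hyper_sets: dict[str, set[str]] = {}
        for cond_a, cond_b in dm_cfg["contrasts"]:
            stats, n_hyper, n_hypo = run_contrast(
                beta, cond_a, cond_b,
                keep_fraction=dm_cfg["keep_fraction"],
                alpha=dm_cfg["alpha"],
                moderation=dm_cfg["moderation"],
            )
            name = f"{cond_a}_vs_{cond_b}"
            stats_by_contrast[name] = stats
            hyper_sets[name] = {s.cpg_id for s in stats if s.direction == "hyper"}
            cio.write_results(stats, run_dir / f"dm_{name}.tsv")
            manifest_info["stages"].setdefault("dm_counts", {})[name] = {
                "n_tested": len(stats), "n_hyper": n_hyper, "n_hypo": n_hypo,
            }
        if len(hyper_sets) >= 2:
            venn = overlap_comparisons(hyper_sets)
            rows = [
                {"contrasts": "&".join(sorted(k)), "n_sites": v}
                for k, v in sorted(venn.items(), key=lambda kv: "&".join(sorted(kv[0])))
            ]
            pd.DataFrame(rows).to_csv(run_dir / "overlaps_hyper.tsv", sep="\t", index=False)
        _finish_stage(stage, t0, n_contrasts=len(stats_by_contrast))

        stage = "enrich"
        t0 = time.time()
        n_rec = 0
        gene_universe = {g for r in genome.manifest for g in r.gene_ids}
        for name, stats in stats_by_contrast.items():
            records = category_enrichment_profile(stats, genome.manifest)
            cio.write_results(records, run_dir / f"enrich_{name}.tsv")
            n_rec += len(records)
            hyper_genes = set()
            hyper_ids = hyper_sets[name]
            for r in genome.manifest:
                if r.cpg_id in hyper_ids:
                    hyper_genes |= r.gene_ids
            gs_records = gene_set_enrichment(hyper_genes, gene_sets, gene_universe)
            cio.write_results(gs_records, run_dir / f"gene_sets_{name}.tsv")
        _finish_stage(stage, t0, n_records=n_rec)

        stage = "motif"
        t0 = time.time()
        overlap_hyper = set.intersection(*hyper_sets.values()) if hyper_sets else set()
        pwm = PWM.from_consensus("planted", sim_config.motif_consensus)
        site_by_id = {r.cpg_id: r for r in genome.manifest}
        all_windows = [
            Window(cid, site_by_id[cid].chrom,
                   site_by_id[cid].pos - len(seq) // 2,
                   site_by_id[cid].pos - len(seq) // 2 + len(seq), seq)
            for cid, seq in windows.items()
        ]
        hyper_windows = [w for w in all_windows if w.cpg_id in overlap_hyper]
        motif_rec = motif_enrichment(
            hyper_windows, all_windows, pwm, cfg["motif"]["threshold_fraction"]
        )
        cio.write_results([motif_rec], run_dir / "motif_enrichment.tsv")
        _finish_stage(stage, t0, n_hyper_windows=len(hyper_windows),
                      n_overlap_hyper=len(overlap_hyper))

        stage = "colocate"
        t0 = time.time()
        coloc = peak_colocation(
            overlap_hyper & {r.cpg_id for r in genome.manifest},
            genome.manifest, peaks, tuple(cfg["colocate"]["widths"]),
        )
        pd.DataFrame(coloc).to_csv(
            run_dir / "colocation.tsv", sep="\t", index=False, float_format="%.12g"
        )
        _finish_stage(stage, t0, n_widths=len(coloc))

        stage = "integrate"
        t0 = time.time()
        cond_a, cond_b = cfg["dm"]["contrasts"][0]
        design = PairedDesign.from_samples(expr.samples, cond_a, cond_b)
        de = differential_expression(expr, design)
        de.to_csv(run_dir / "de.tsv", sep="\t", float_format="%.12g")
        first = f"{cond_a}_vs_{cond_b}"
        table, assoc = dm_de_association(
            stats_by_contrast[first], de, genome.manifest,
            region_filter=cfg["integrate"]["region"],
            expr_alpha=cfg["integrate"]["expr_alpha"],
        )
        cio.write_results([assoc], run_dir / "integration.tsv")
        _finish_stage(stage, t0, quadrants=[int(x) for x in table.ravel()],
                      fisher_p=assoc.p)
    except Exception:
        manifest_info["stages"][stage] = {"status": "failed"}
        (run_dir / "run_manifest.json").write_text(
            json.dumps(manifest_info, indent=2, sort_keys=True) + "\n"
        )
        raise

    (run_dir / "run_manifest.json").write_text(
        json.dumps(manifest_info, indent=2, sort_keys=True) + "\n"
    )
    return run_dir


def report(run_dir: str | Path) -> str:
    """Render a plain-text summary of a completed run.

    Every number is read back from the stage output files, so regenerating
    the report from the same directory is byte-identical.  Missing stage
    outputs are a hard error listing what is absent.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "run_manifest.json"
    required = [manifest_path, run_dir / "motif_enrichment.tsv",
                run_dir / "colocation.tsv", run_dir / "integration.tsv"]
    missing = [str(p.name) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory, missing: {missing}")
    info = json.loads(manifest_path.read_text())
    lines = [f"cpgdrift run report (package {info['versions']['cpgdrift']})", ""]

    lines.append("Differential methylation (per contrast):")
    for name, counts in sorted(info["stages"].get("dm_counts", {}).items()):
        lines.append(
            f"  {name}: {counts['n_tested']} sites tested, "
            f"{counts['n_hyper']} hyper, {counts['n_hypo']} hypo"
        )
    lines.append("")

    for enrich_path in sorted(run_dir.glob("enrich_*.tsv")):
        df = pd.read_csv(enrich_path, sep="\t")
        for direction in ("hyper", "hypo"):
            sub = df[df["category"].str.startswith(direction + ":")]
            n_called = int(sub["n"].iloc[0]) if len(sub) else 0
            top = sub.nsmallest(3, "p")
            lines.append(
                f"Top {direction} categories [{enrich_path.stem}] ({n_called} sites):"
            )
            if n_called == 0:
                lines.append("  none called")
            else:
                for _, row in top.iterrows():
                    lines.append(
                        f"  {row['category']:24s} fold={row['fold']:.2f} p={row['p']:.3g}"
                    )
        lines.append("")

    motif = pd.read_csv(run_dir / "motif_enrichment.tsv", sep="\t")
    for _, row in motif.iterrows():
        lines.append(
            f"Motif {row['category']}: {row['k']}/{row['n']} hyper windows with a hit "
            f"vs {row['K']}/{row['N']} background (fold={row['fold']:.2f}, p={row['p']:.3g})"
        )
    lines.append("")

    coloc = pd.read_csv(run_dir / "colocation.tsv", sep="\t")
    lines.append("Peak co-location (proportion with a peak in the window):")
    for _, row in coloc.iterrows():
        lines.append(
            f"  {int(row['width']):5d} bp: hyper {row['proportion_hyper']:.3f} "
            f"vs array {row['proportion_background']:.3f} (p={row['p']:.3g})"
        )
    lines.append("")

    integ = pd.read_csv(run_dir / "integration.tsv", sep="\t")
    for _, row in integ.iterrows():
        lines.append(
            f"Integration {row['category']}: k={row['k']} of n={row['n']} "
            f"(fold={row['fold']:.2f}, p={row['p']:.3g})"
        )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
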