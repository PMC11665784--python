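"""End-to-end workflow: diversity → load → purging → outliers → effect models.

Thin orchestration over the library: reads (or simulates) a cohort, runs each
stage per genomic region, writes TSV/BED/JSON outputs plus a manifest with
config hash, versions and row counts. Re-running with the same config and
seed is idempotent.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bayes, diversity, io, load, model, outliers, purging, roh, simulate

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict = {
    "window_bp": 100_000,
    "weights": {"modifier": 0.0, "low": 0.1, "moderate": 0.3, "high": 0.6},
    "dominance_h": 0.5,
    "normalize": "class",
    "roh": {"epsilon": 1e-3, "rate": 1e-8, "min_bp": 100_000},
    "enrichment": {"strata_mb": [2.5]},
    "relative_load": {"f_min": 0.01, "f_source": "f"},
    "outliers": {"percentile": 90, "pca_k": 1},
    "bayes": {"chains": 3, "iterations": 10_000, "warmup": 1_000},
}


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    params = dict(DEFAULT_PARAMS)
    for key, val in (cfg.get("params") or {}).items():
        if isinstance(val, dict) and isinstance(params.get(key), dict):
            params[key] = {**params[key], **val}
        else:
            params[key] = val
    cfg["params"] = params
    cfg.setdefault("seed", 0)
    cfg.setdefault("regions", ["autosome", "X"])
    return cfg


def _get_cohort(cfg: dict, outdir: Path) -> model.AnnotatedCohort:
    if "simulate" in cfg:
        sim_cfg = cfg["simulate"]
        if "preset" in sim_cfg:
            preset = simulate.scenario_presets(seed=cfg["seed"])[sim_cfg["preset"]]
        else:
            raise model.CohortError("simulate config requires a 'preset' key")
        result = simulate.simulate_cohort(preset, outdir / "sim")
        return result.load_cohort()
    inp = cfg["input"]
    genome = model.GenomeSpec.from_dict(inp["genome"])
    return io.read_cohort(
        inp["vcf"],
        inp["sample_sheet"],
        genome,
        impact_source=inp.get("impact_source", "info_field"),
        impact_table=inp.get("impact_table"),
        multiallelic=inp.get("multiallelic", "error"),
    )


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Run every stage and write the output tree; returns the output directory."""
    cfg = load_config(config)
    outdir = Path(outdir if outdir is not None else cfg.get("outdir", "purgekit_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg["params"]
    t0 = time.time()
    counts: dict[str, int] = {}

    cohort = _get_cohort(cfg, outdir)
    cohort = load.polarize(cohort)
    weights = load.ImpactWeights(**params["weights"])

    regions = list(cfg["regions"])
    available = {r for r in model.REGIONS if len(cohort.region_rows(r))}
    for r in list(regions):
        if r not in available:
            logger.warning("region %s has no sites; stage skipped", r)
            regions.remove(r)

    rohs = roh.call_roh_all(
        cohort,
        epsilon=params["roh"]["epsilon"],
        rate=params["roh"]["rate"],
        min_bp=params["roh"]["min_bp"],
    )
    io.write_bed(rohs, outdir / "roh.bed")
    counts["roh.bed"] = len(rohs.intervals)

    pops = list(pd.unique(cohort.samples["population"]))
    pi_frames, f_frames, load_frames, summaries, rel_frames = [], [], [], [], []
    rxy_rows, enr_frames, sfs_rows = [], [], []
    for region in regions:
        pi_frames.append(
            diversity.pi_windows(cohort, window_bp=params["window_bp"], region=region).assign(region=region)
        )
        f_tab = diversity.inbreeding_f(cohort, region=region)
        f_frames.append(f_tab)
        summary = roh.summarize_roh(rohs, cohort.genome, region, sample_ids=cohort.sample_ids)
        summaries.append(summary)
        loads = load.individual_loads(
            cohort, weights, region=region,
            dominance_h=params["dominance_h"], normalize=params["normalize"],
        )
        load_frames.append(loads)
        if params["relative_load"]["f_source"] == "froh":
            f_for_rel = summary.rename(columns={"froh": "f"})[["sample_id", "region", "f"]]
            f_for_rel = f_for_rel.merge(cohort.samples[["sample_id", "population"]], on="sample_id")
        else:
            f_for_rel = f_tab
        rel_frames.append(
            purging.relative_load(loads, f_for_rel, f_min=params["relative_load"]["f_min"])
        )
        for pop_x, pop_y in itertools.permutations(pops, 2):
            for cls in model.IMPACT_CLASSES:
                try:
                    rxy_rows.append(purging.rxy(cohort, pop_x, pop_y, cls, region=region))
                except model.CohortError as exc:
                    logger.warning("rxy %s/%s %s %s skipped: %s", pop_x, pop_y, cls, region, exc)
        enr_frames.append(
            purging.roh_enrichment(
                cohort, rohs,
                strata_bp=tuple(s * 1e6 for s in params["enrichment"]["strata_mb"]),
                region=region,
            ).assign(region=region)
        )
        for pop in pops:
            res = load.sfs_and_site_classes(cohort, pop, region=region)
            for k, n in enumerate(res["sfs"], start=1):
                sfs_rows.append({"population": pop, "region": region, "derived_copies": k, "n_sites": int(n)})
            for key in ("fixed_ref", "fixed_derived", "polymorphic"):
                sfs_rows.append({"population": pop, "region": region, "derived_copies": key, "n_sites": res[key]})

    outputs = {
        "pi_windows.tsv": pd.concat(pi_frames, ignore_index=True),
        "inbreeding_f.tsv": pd.concat(f_frames, ignore_index=True),
        "roh_summary.tsv": pd.concat(summaries, ignore_index=True),
        "loads.tsv": pd.concat(load_frames, ignore_index=True),
        "relative_load.tsv": pd.concat(rel_frames, ignore_index=True),
        "rxy.tsv": pd.DataFrame(rxy_rows),
        "roh_enrichment.tsv": pd.concat(enr_frames, ignore_index=True),
        "sfs.tsv": pd.DataFrame(sfs_rows),
    }

    # --- outlier scan (needs the reproductive-success contrast) ----------
    has_groups = set(cohort.samples["rs_group"]) >= {"high", "low"}
    if has_groups:
        stats = compute_site_stats(
            cohort, weights,
            k=params["outliers"]["pca_k"],
        )
        result = outliers.intersect_candidates(stats, percentile=params["outliers"]["percentile"])
        outputs["site_stats.tsv"] = result["stats"]
        cands = result["stats"].loc[result["stats"]["candidate"]]
        bed = pd.DataFrame(
            {"contig": cands["contig"], "start": cands["pos"] - 1, "end": cands["pos"]}
        )
        io.write_bed(bed, outdir / "candidates.bed")
        counts["candidates.bed"] = len(bed)
        (outdir / "venn.json").write_text(json.dumps(result["venn"], indent=2) + "\n")

    # --- effect models ----------------------------------------------------
    bayes_rows = []
    loads_all = outputs["loads.tsv"].dropna(subset=["total_load"])
    f_all = outputs["inbreeding_f.tsv"]
    b = params["bayes"]
    for response, frame in (("total_load", loads_all), ("hom_load", loads_all), ("f", f_all)):
        predictors = ["population"] + (["region"] if frame["region"].nunique() > 1 else [])
        spec = bayes.EffectModelSpec(
            response=response, predictors=predictors,
            chains=b["chains"], iterations=b["iterations"], warmup=b["warmup"],
        )
        fit = bayes.fit_effect_model(spec, frame, seed=cfg["seed"])
        bayes_rows.append(fit["summary"].assign(response=response))
    outputs["effects.tsv"] = pd.concat(bayes_rows, ignore_index=True)

    for name, frame in outputs.items():
        io.write_site_table(frame, outdir / name)
        counts[name] = len(frame)

    manifest = {
        "purgekit_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "row_counts": counts,
        "wall_time_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def compute_site_stats(
    cohort: model.AnnotatedCohort,
    weights: load.ImpactWeights = load.ImpactWeights(),
    k: int = 1,
    region: str | None = None,
) -> pd.DataFrame:
    """The three per-site outlier statistics on the high-vs-low RS contrast.

    Returns one row per polarizable site with pca_score, fst and delta_load
    columns (NaN where a statistic is undefined), ready for
    :func:`purgekit.outliers.intersect_candidates`.
    """
    cols_high = cohort.rs_group_columns("high")
    cols_low = cohort.rs_group_columns("low")
    contrast = np.sort(np.r_[cols_high, cols_low])
    pca, _lam = outliers.pca_outlier_scores(cohort, contrast, k=k, region=region)
    fst = outliers.fst_per_site(cohort, cols_low, cols_high, region=region)
    dl = outliers.delta_load(
        load.group_site_load(cohort, cols_low, weights, region=region),
        load.group_site_load(cohort, cols_high, weights, region=region),
    )
    stats = fst.merge(pca[["contig", "pos", "pca_score"]], on=["contig", "pos"], how="left")
    stats = stats.merge(dl, on=["contig", "pos"], how="left")
    return stats[["contig", "pos", "impact", "pca_score", "fst", "delta_load"]]
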