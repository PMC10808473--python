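"""End-to-end cohort orchestration.

``run_cohort`` executes density -> FISH -> CNV -> survival (and ROI
normalization when ROI data are present) on either a fully synthetic cohort
or user-supplied tables, writes every intermediate artifact as CSV, and
records a manifest with parameters, seeds, and output hashes so a re-run
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv, density, fish, roinorm, survival, synth

__all__ = ["run_cohort", "DEFAULT_PARAMS"]

log = logging.getLogger("pfahet.pipeline")

DEFAULT_PARAMS = {
    "density_threshold": density.DENSITY_THRESHOLD,  # cells per 1,000 µm²
    "grid_um": density.GRID_UM,
    "radius_um": 50.0,
    "detect_radius_um": 3.0,
    "fish_min_fraction": 0.10,
    "gain_cutoff": cnv.GAIN_CUTOFF,
    "loss_cutoff": cnv.LOSS_CUTOFF,
    "min_group_size": 1,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, outputs: dict) -> None:
    df.to_csv(path, index=False)
    outputs[path.name] = _sha256(path)


def _density_stage(cfg: dict, params: dict, out_dir: Path, outputs: dict) -> pd.DataFrame:
    """Per-case tissue simulation + detection + compartment summary."""
    n_cases = cfg["n_cases"]
    base_seed = cfg["seed"]
    tissue_kw = dict(cfg.get("tissue", {}))
    rng = np.random.default_rng(base_seed)
    fractions = tissue_kw.pop("nodule_fractions", None)
    rows = []
    for i in range(n_cases):
        frac = fractions[i] if fractions is not None else float(rng.uniform(0.05, 0.95))
        spec = synth.SynthTissueSpec(
            nodule_fraction=round(frac, 3), seed=int(base_seed + 1000 + i), **tissue_kw
        )
        tissue = synth.gen_tissue_image(spec)
        img = density.TissueImage(tissue.image, tissue.scale_um_per_px, ki67=tissue.ki67)
        nuclei = density.detect_nuclei(img, radius_um=params["detect_radius_um"])
        dmap = density.density_map(
            nuclei, img.extent_um, grid_um=params["grid_um"], radius_um=params["radius_um"]
        )
        cmask = density.classify_compartments(dmap, threshold=params["density_threshold"])
        summary = density.ki67_fractions(nuclei, cmask)
        rows.append(
            {
                "case_id": f"case{i:03d}",
                "nodule_fraction_true": tissue.nodule_fraction_realized,
                **asdict(summary),
            }
        )
        log.info("density: case%03d dense_fraction=%.3f", i, summary.dense_fraction)
    df = pd.DataFrame(rows)
    _write(df, out_dir / "density_summary.csv", outputs)
    return df


def _fish_stage(fish_table: pd.DataFrame, aberration: str, params, out_dir, outputs) -> pd.DataFrame:
    calls = fish.call_areas_table(fish_table, aberration, params["fish_min_fraction"])
    calls.insert(0, "aberration", aberration)
    return calls


def _cnv_stage(profiles: pd.DataFrame, params: dict, out_dir: Path, outputs: dict) -> dict:
    calls = cnv.call_arms_table(
        profiles, gain_cutoff=params["gain_cutoff"], loss_cutoff=params["loss_cutoff"]
    )
    _write(calls, out_dir / "arm_calls.csv", outputs)
    result = {"calls": calls, "fisher": {}}
    for arm in sorted(calls["arm"].unique()):
        table = cnv.paired_table(calls, arm)
        p = cnv.fisher_exact_two_sided(table)
        result["fisher"][arm] = {"table": table.tolist(), "p": p}
        log.info("cnv: arm %s table=%s fisher_p=%.4g", arm, table.tolist(), p)
    return result


def _survival_stage(records: pd.DataFrame, params: dict, out_dir: Path, outputs: dict) -> dict:
    t = records["time_months"].to_numpy()
    e = records["event"].to_numpy()
    cov = records["covariate"].to_numpy()
    median_groups = survival.split_at_median(cov)
    _, p_median = survival.logrank_test(t, e, median_groups)
    search = survival.best_cutoff_search(t, e, cov, min_group_size=params["min_group_size"])
    scan = search.scan.copy()
    _write(scan, out_dir / "cutoff_scan.csv", outputs)
    groups = pd.DataFrame(
        {
            "case_id": records["case_id"],
            "median_group": median_groups,
            "bestcut_group": np.where(cov >= search.best_cutoff, "high", "low"),
        }
    )
    _write(groups, out_dir / "survival_groups.csv", outputs)
    log.info(
        "survival: median_p=%.4g best_cutoff=%.3f best_p=%.4g (n=%d/%d)",
        p_median, search.best_cutoff, search.best_p, search.n_low, search.n_high,
    )
    return {"p_median": p_median, "search": search, "groups": groups}


def run_cohort(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the full cohort analysis described by ``config``.

    ``config`` is a dict or a YAML path.  With a ``synthetic`` section every
    input is generated (seed-deterministically) from the given specs; with an
    ``inputs`` section the named CSV tables are loaded instead.  Stages whose
    inputs are absent are skipped with a logged notice.  Returns the stage
    results; all artifacts and a manifest (parameters, seeds, output SHA-256
    hashes) are written to ``out_dir``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    seed = int(config.get("seed", 0))
    outputs: dict[str, str] = {}
    results: dict = {}

    syn = config.get("synthetic")
    inputs = config.get("inputs", {})

    # --- density ---
    if syn is not None:
        dens = _density_stage({"seed": seed, **syn}, params, out_dir, outputs)
        results["density"] = dens

    # --- FISH ---
    fish_table = None
    if syn is not None:
        spec = synth.SynthClonalSpec(seed=seed + 2000, **syn.get("fish", {}))
        aberration = syn.get("fish_aberration", "gain_1q")
        fish_table = synth.gen_fish_counts(spec, aberration)
        _write(fish_table, out_dir / "fish_counts.csv", outputs)
    elif "fish_csv" in inputs:
        from .io import read_fish_csv

        fish_table = read_fish_csv(inputs["fish_csv"])
        aberration = inputs.get("fish_aberration", "gain_1q")
    if fish_table is not None:
        fish_calls = _fish_stage(fish_table, aberration, params, out_dir, outputs)
        _write(fish_calls, out_dir / "fish_calls.csv", outputs)
        results["fish"] = fish_calls
    else:
        log.info("fish: no input table, stage skipped")

    # --- CNV ---
    profiles = None
    if syn is not None:
        arm_cfg = {"clone_fraction_dense": 0.8, "clone_fraction_sparse": 0.1, **syn.get("arms", {})}
        profiles = synth.gen_arm_profiles(
            n_cases=syn["n_cases"], seed=seed + 3000, **arm_cfg
        )
        _write(profiles, out_dir / "arm_profiles.csv", outputs)
    elif "segments_csv" in inputs:
        from .io import read_segments_csv

        profiles = cnv.aggregate_segments(read_segments_csv(inputs["segments_csv"]))
    if profiles is not None:
        results["cnv"] = _cnv_stage(profiles, params, out_dir, outputs)
    else:
        log.info("cnv: no input profiles, stage skipped")

    # --- survival ---
    records = None
    if syn is not None and "survival" in syn:
        spec = synth.SynthCohortSpec(seed=seed + 4000, **syn["survival"])
        records, truth = synth.gen_survival_cohort(spec)
        _write(records, out_dir / "survival_records.csv", outputs)
        results["survival_truth"] = truth
    elif "survival_csv" in inputs:
        from .io import read_survival_csv

        records = read_survival_csv(inputs["survival_csv"])
    if records is not None:
        results["survival"] = _survival_stage(records, params, out_dir, outputs)
    else:
        log.info("survival: no cohort table, stage skipped")

    # --- ROI normalization (optional) ---
    if syn is not None and "rois" in syn:
        spec = synth.SynthRoiSpec(seed=seed + 5000, **syn["rois"])
        rois, roi_truth = synth.gen_roi_counts(spec)
        chain = roinorm.normalize_chain(rois)
        chain["normalized"].counts.to_csv(out_dir / "roi_normalized.tsv", sep="\t")
        outputs["roi_normalized.tsv"] = _sha256(out_dir / "roi_normalized.tsv")
        _write(chain["qc_flags"].reset_index(), out_dir / "roi_qc.csv", outputs)
        results["roi"] = {"chain": chain, "truth": roi_truth}

    # --- case report ---
    if "density" in results:
        report = results["density"][
            ["case_id", "dense_fraction", "ki67_fraction_dense", "ki67_fraction_sparse"]
        ].copy()
        if "cnv" in results:
            calls = results["cnv"]["calls"]
            for arm in sorted(calls["arm"].unique()):
                for area in ("dense", "sparse"):
                    sub = calls[(calls["arm"] == arm) & (calls["area_label"] == area)]
                    report = report.merge(
                        sub[["case_id", "status"]].rename(
                            columns={"status": f"{arm}_{area}_call"}
                        ),
                        on="case_id",
                        how="left",
                    )
        if "survival" in results:
            report = report.merge(results["survival"]["groups"], on="case_id", how="left")
        missing = report.isna().any(axis=1)
        if missing.any():
            log.info("case report: %d cases with missing stage values", int(missing.sum()))
        _write(report, out_dir / "case_report.csv", outputs)
        results["report"] = report

    manifest = {
        "package": "pfahet",
        "seed": seed,
        "params": params,
        "config": {k: v for k, v in config.items() if k != "out_dir"},
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    results["manifest"] = manifest
    return results
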