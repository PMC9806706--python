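"""End-to-end orchestration: simulate -> normalize/fit -> ADC -> reduce -> stats.

``run_all`` reproduces the full analysis layout on a synthetic cohort: a
per-analysis AUC table (whole prostate, peripheral zone, transition zone, and
within-PI-RADS strata; ADC, RSIrs, PI-RADS, and the PI-RADS + RSIrs
combination), a per-category detection-rate table, paired bootstrap
comparisons, and a provenance record.  Everything is seeded and reruns with
the same config are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .adc import fit_adc
from .cohort import CohortConfig, CohortResult, simulate_cohort
from .reduction import label_cspca, reduce_patient
from .rsi import compute_rsirs, fit_compartments, normalize_by_median_b0
from .stats import (
    bootstrap_auc,
    bootstrap_compare,
    combined_roc,
    detection_rate_table,
    pirads_stratum,
    roc_points,
    stratified_posteriors,
)

__all__ = ["RunConfig", "run_all", "compute_markers", "analyze_markers"]

log = logging.getLogger("rsiscope")

#: short keys for marker columns per search region
_REGION_KEY = {"whole": "whole", "peripheral_zone": "pz", "central_gland": "cg"}
#: ADC b-value subsets: vendor-style two-point and alternate three-point
ADC_VARIANTS = {"vendor": (0.0, 1000.0), "alt": (0.0, 500.0, 1000.0)}


class RunConfig(BaseModel):
    """Defaults mirror the published analysis settings."""

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    margin_mm: float = Field(5.0, ge=0)
    regions: tuple[str, ...] = ("whole", "peripheral_zone", "central_gland")
    n_boot: int = Field(10000, ge=1)
    stats_seed: int = 17
    write_maps: bool = False


def _seed_stream(seed: int):
    """Deterministic stream of independent 31-bit seeds for the bootstraps."""
    ss = np.random.SeedSequence(seed)
    while True:
        (child,) = ss.spawn(1)
        yield int(child.generate_state(1)[0] % (2**31))
        ss = child


def compute_markers(cohort: CohortResult, config: RunConfig) -> pd.DataFrame:
    """Normalize, fit, and reduce every patient to its scalar markers.

    One row per patient: truth fields plus, for each search region,
    ``max_rsirs_<r>`` and ``min_adc_<variant>_<r>``.
    """
    rows = []
    for patient in cohort.patients:
        seg = patient.segmentation
        series = normalize_by_median_b0(patient.dwi, seg.prostate)
        # one fit over the expanded whole prostate covers every search region
        from .reduction import expand_mask

        fit_mask = expand_mask(seg.prostate, config.margin_mm, seg.voxel_size_mm)
        maps = fit_compartments(series, fit_mask)
        rsirs = compute_rsirs(maps)
        adc_maps = {
            name: fit_adc(series, fit_mask, subset) for name, subset in ADC_VARIANTS.items()
        }
        row = {
            "patient_id": patient.patient_id,
            "grade_group": patient.grade_group,
            "pirads": patient.pirads,
            "lesion_zone": patient.lesion_zone,
            "cspca": label_cspca(patient.grade_group),
        }
        for region in config.regions:
            rk = _REGION_KEY[region]
            for name, amap in adc_maps.items():
                max_rs, min_adc = reduce_patient(
                    rsirs, amap, seg, search_region=region, margin_mm=config.margin_mm
                )
                row[f"max_rsirs_{rk}"] = max_rs
                row[f"min_adc_{name}_{rk}"] = min_adc
        rows.append(row)
    return pd.DataFrame(rows)


def _auc_cell(scores, labels, n_boot, seed):
    a, ci = bootstrap_auc(scores, labels, n_boot=n_boot, seed=seed)
    return {"auc": a, "ci95": list(ci)}


def _comparison_dict(comp):
    return {
        "auc_a": comp.auc_a,
        "auc_b": comp.auc_b,
        "delta": comp.delta,
        "ci95": list(comp.ci95),
        "p_two_sided": comp.p_two_sided,
        "n_boot": comp.n_boot,
    }


def _one_analysis(sub: pd.DataFrame, region_key: str, seeds, n_boot: int, *, combine=True):
    labels = sub["cspca"].to_numpy(dtype=bool)
    n_pos = int(labels.sum())
    out = {"n": int(len(sub)), "n_pos": n_pos, "n_neg": int(len(sub)) - n_pos}
    if n_pos == 0 or n_pos == len(sub) or len(sub) < 4:
        out["estimable"] = False
        return out, None
    out["estimable"] = True

    rsi = sub[f"max_rsirs_{region_key}"].to_numpy()
    adc_score = -sub[f"min_adc_vendor_{region_key}"].to_numpy()
    alt_adc_score = -sub[f"min_adc_alt_{region_key}"].to_numpy()
    pirads = sub["pirads"].to_numpy(dtype=float)

    out["auc"] = {
        "adc": _auc_cell(adc_score, labels, n_boot, next(seeds)),
        "rsirs": _auc_cell(rsi, labels, n_boot, next(seeds)),
        "pirads": _auc_cell(pirads, labels, n_boot, next(seeds)),
    }
    curves = {
        "adc": roc_points(adc_score, labels, "adc"),
        "rsirs": roc_points(rsi, labels, "rsirs"),
        "pirads": roc_points(pirads, labels, "pirads"),
    }
    combined_score = None
    if combine:
        combo = stratified_posteriors(rsi, labels, pirads_stratum(sub["pirads"]))
        combined_score = combo.combined_score
        out["auc"]["pirads_plus_rsirs"] = _auc_cell(combined_score, labels, n_boot, next(seeds))
        curves["pirads_plus_rsirs"] = combined_roc(combo, labels)

    comps = {
        "rsirs_vs_adc": bootstrap_compare(rsi, adc_score, labels, n_boot, next(seeds)),
        "rsirs_vs_pirads": bootstrap_compare(rsi, pirads, labels, n_boot, next(seeds)),
        "alt_adc_vs_vendor_adc": bootstrap_compare(
            alt_adc_score, adc_score, labels, n_boot, next(seeds)
        ),
    }
    if combined_score is not None:
        comps["combined_vs_pirads"] = bootstrap_compare(
            combined_score, pirads, labels, n_boot, next(seeds)
        )
        comps["combined_vs_rsirs"] = bootstrap_compare(
            combined_score, rsi, labels, n_boot, next(seeds)
        )
    out["comparisons"] = {k: _comparison_dict(v) for k, v in comps.items()}
    return out, curves


def analyze_markers(markers: pd.DataFrame, n_boot: int = 10000, seed: int = 17):
    """All analysis rows from the per-patient marker table."""
    seeds = _seed_stream(seed)
    analyses: dict = {}
    curves: dict = {}

    subsets = [
        ("whole_prostate", markers, "whole", True),
        ("peripheral_zone", markers[markers["lesion_zone"] == "peripheral"], "pz", True),
        ("transition_zone", markers[markers["lesion_zone"] == "transition"], "cg", True),
        (
            "peripheral_zone_whole_search",
            markers[markers["lesion_zone"] == "peripheral"],
            "whole",
            True,
        ),
        (
            "transition_zone_whole_search",
            markers[markers["lesion_zone"] == "transition"],
            "whole",
            True,
        ),
    ]
    for cat in (3, 4, 5):
        subsets.append((f"pirads_{cat}", markers[markers["pirads"] == cat], "whole", False))

    for name, sub, rk, combine in subsets:
        result, cc = _one_analysis(sub, rk, seeds, n_boot, combine=combine)
        analyses[name] = result
        if cc:
            curves[name] = cc
        if not result.get("estimable", False):
            log.warning("analysis %s not estimable (n=%d, n_pos=%d)", name, result["n"], result["n_pos"])

    rates = detection_rate_table(markers)
    return {"analyses": analyses, "detection_rates": rates.reset_index().to_dict("records")}, curves


def _table3(results: dict) -> pd.DataFrame:
    rows = []
    order = [
        "whole_prostate",
        "peripheral_zone",
        "transition_zone",
        "pirads_3",
        "pirads_4",
        "pirads_5",
    ]
    for name in order:
        res = results["analyses"].get(name)
        if res is None:
            continue
        row = {"analysis": name, "n": res["n"]}
        for marker in ("adc", "rsirs", "pirads", "pirads_plus_rsirs"):
            cell = res.get("auc", {}).get(marker)
            row[marker] = (
                f"{cell['auc']:.2f} ({cell['ci95'][0]:.2f}, {cell['ci95'][1]:.2f})"
                if cell
                else "not estimable"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the whole pipeline; optionally write the results bundle to disk."""
    t0 = time.time()
    stages = []

    def stage(name, fn):
        start = time.time()
        value = fn()
        stages.append({"stage": name, "seconds": round(time.time() - start, 3)})
        log.info("stage %s done in %.2fs", name, time.time() - start)
        return value

    cohort = stage("simulate", lambda: simulate_cohort(config.cohort))
    markers = stage("fit_and_reduce", lambda: compute_markers(cohort, config))
    (results, curves) = stage(
        "stats", lambda: analyze_markers(markers, n_boot=config.n_boot, seed=config.stats_seed)
    )

    config_json = config.model_dump_json()
    results["provenance"] = {
        "package": "rsiscope",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "cohort_seed": config.cohort.seed,
        "stats_seed": config.stats_seed,
        "n_boot": config.n_boot,
        "numpy": np.__version__,
        "stages": stages,
        "total_seconds": round(time.time() - t0, 3),
    }
    results["truth_table"] = cohort.table.to_dict("records")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "results.json").write_text(json.dumps(results, indent=2, default=float))
        (out_dir / "run_config.json").write_text(config_json)
        markers.to_csv(out_dir / "cohort_markers.csv", index=False)
        _table3(results).to_csv(out_dir / "table3.csv", index=False)
        pd.DataFrame(results["detection_rates"]).to_csv(
            out_dir / "table2_rates.csv", index=False
        )
        roc_dir = out_dir / "roc_curves"
        roc_dir.mkdir(exist_ok=True)
        for analysis, cc in curves.items():
            for marker, curve in cc.items():
                pd.DataFrame(
                    {
                        "threshold": curve.thresholds,
                        "sensitivity": curve.sensitivity,
                        "specificity": curve.specificity,
                    }
                ).to_csv(roc_dir / f"{analysis}_{marker}.csv", index=False)
        if config.write_maps:
            from .io import write_cohort

            write_cohort(cohort, out_dir / "cohort_data")
        log_lines = [f"{s['stage']}: {s['seconds']}s" for s in stages]
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    results["_markers"] = markers  # in-memory convenience, not serialized
    return results
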