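"""Config-driven orchestration of the full analysis.

A run reads (or simulates) its inputs, then executes: track QC -> 3-day SST
compositing -> animal-centric section extraction -> front detection and
occupancy statistics -> movement/current matchup -> TAT aggregation.  Every
artifact is a CSV/JSON/netCDF file in one run directory, together with a
manifest echoing the full configuration, input hashes, and record counts at
every stage boundary (so conservation — fixes kept + removed = fixes read —
is checkable from the manifest alone).  Outputs are deterministic: the same
config and seed give byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import front_metrics, movement_currents, sst_fields, synthetic, tat_analysis, track_qc
from .config import ScenarioConfig, scenario_from_dict, scenario_to_dict
from .front_metrics import FrontParams

log = logging.getLogger(__name__)


DEFAULT_PARAMS = {
    "vmax_ms": track_qc.DEFAULT_VMAX_MS,
    "filter_window": track_qc.DEFAULT_WINDOW,
    "half_length_km": sst_fields.DEFAULT_HALF_LENGTH_KM,
    "occupancy_bin_pct": 10.0,
    "dist_bin_km": 50.0,
    "sst_bin_c": 0.5,
    "speed_bin_ms": movement_currents.DEFAULT_SPEED_BIN_MS,
    "max_pair_gap_days": movement_currents.MAX_PAIR_GAP_DAYS,
    "tat_threshold_c": 22.0,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg


def run(config: dict, output_dir, overwrite: bool = False) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    ``config`` holds an optional ``scenario`` block (synthetic inputs are
    then generated into the run directory), or an ``inputs`` block with
    paths to tracks/SST/currents/TAT files; an optional ``params`` block
    overriding :data:`DEFAULT_PARAMS` and front-detection parameters; and an
    optional ``end_dates`` mapping (per-tag tag-detachment trim dates).
    Stages with missing inputs (e.g. no currents file) are skipped with a
    logged notice; all other artifacts are unaffected.
    """
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output dir {out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    front_params = FrontParams(**config.get("front_params", {}))
    manifest: dict = {
        "config": {
            k: v for k, v in config.items() if k not in ("scenario",)
        },
        "params": params,
        "front_params": dataclasses.asdict(front_params),
        "counts": {},
        "inputs": {},
        "stages": [],
    }

    # ---- stage: inputs (simulate or load) --------------------------------
    scenario: ScenarioConfig | None = None
    truth_daily = None
    if "scenario" in config:
        scenario = (
            config["scenario"]
            if isinstance(config["scenario"], ScenarioConfig)
            else scenario_from_dict(config["scenario"])
        )
        if "seed" in config:
            scenario.seed = int(config["seed"])
        manifest["config"]["scenario"] = scenario_to_dict(scenario)
        log.info("simulating scenario (seed %d)", scenario.seed)
        sst = synthetic.generate_sst_field(scenario)
        u = synthetic.generate_current_field(scenario)
        fixes, truth_daily, truth_fixes = synthetic.generate_tracks(scenario, sst, u)
        temps = synthetic.sample_true_temperatures(scenario, sst, truth_daily)
        tat = synthetic.generate_tat(scenario, temps)
        synthetic.write_field(sst, out / "sst.nc")
        synthetic.write_field(u, out / "currents.nc")
        fixes.to_csv(out / "fixes.csv", index=False)
        truth_daily.to_csv(out / "truth_daily.csv", index=False)
        truth_fixes.to_csv(out / "truth_fixes.csv", index=False)
        tat.to_csv(out / "tat.csv", index=False)
        tracks_path, sst_path = out / "fixes.csv", out / "sst.nc"
        currents_path, tat_path = out / "currents.nc", out / "tat.csv"
        manifest["stages"].append("simulate")
    else:
        inputs = config.get("inputs", {})
        tracks_path = Path(inputs["tracks"]) if "tracks" in inputs else None
        sst_path = Path(inputs["sst"]) if "sst" in inputs else None
        currents_path = Path(inputs.get("currents")) if inputs.get("currents") else None
        tat_path = Path(inputs.get("tat")) if inputs.get("tat") else None
        if tracks_path is None or sst_path is None:
            raise ValueError("config needs either a 'scenario' or inputs.tracks and inputs.sst")
        fixes = track_qc.read_fixes(tracks_path)
        sst = synthetic.read_field(sst_path)
        u = synthetic.read_field(currents_path) if currents_path else None

    for name, p in (("tracks", tracks_path), ("sst", sst_path),
                    ("currents", currents_path), ("tat", tat_path)):
        if p is not None and Path(p).exists():
            p = Path(p)
            # paths inside the run directory are recorded relative to it so
            # that reruns into different directories stay byte-identical
            shown = p.name if p.parent.resolve() == out.resolve() else str(p)
            manifest["inputs"][name] = {"path": shown, "sha256": _sha256(p)}

    orientation = "zonal" if (scenario and scenario.orientation == "coastal") else config.get(
        "orientation", "meridional"
    )

    # ---- stage: track QC --------------------------------------------------
    n_fixes = len(fixes)
    kept, removed = track_qc.speed_filter(
        fixes, vmax=params["vmax_ms"], window=int(params["filter_window"])
    )
    daily = track_qc.select_daily(kept)
    daily = track_qc.apply_end_dates(daily, config.get("end_dates"))
    kept.to_csv(out / "fixes_kept.csv", index=False)
    removed.to_csv(out / "fixes_removed.csv", index=False)
    daily.to_csv(out / "daily_positions.csv", index=False)
    manifest["counts"]["fixes_total"] = n_fixes
    manifest["counts"]["fixes_kept"] = len(kept)
    manifest["counts"]["fixes_removed"] = len(removed)
    assert len(kept) + len(removed) == n_fixes, "fix count not conserved"
    manifest["counts"]["daily_positions"] = len(daily)
    manifest["stages"].append("track_qc")

    # ---- stage: compositing + sections -----------------------------------
    composites = sst_fields.composite_series(sst)
    sections = []
    n_outside = 0
    for _, row in daily.iterrows():
        it = sst_fields.nearest_time_index(composites, row["date"])
        field2d = composites.isel(time=it)
        try:
            sec = sst_fields.extract_section(
                field2d,
                float(row["lat"]),
                float(row["lon"]),
                orientation=orientation,
                half_length_km=params["half_length_km"],
                tag_id=row["tag_id"],
                date=row["date"],
                min_span_km=front_params.min_span_km,
            )
        except ValueError:
            n_outside += 1
            continue
        sections.append(sec)
    sst_fields.sections_to_frame(sections).to_csv(out / "sections.csv", index=False)
    manifest["counts"]["sections"] = len(sections)
    manifest["counts"]["positions_outside_domain"] = n_outside
    assert len(sections) + n_outside == len(daily), "section count not conserved"
    manifest["stages"].append("sections")

    # ---- stage: front metrics ---------------------------------------------
    geoms = [front_metrics.detect_front(s, front_params) for s in sections]
    records = [front_metrics.percent_distance(g) for g in geoms]
    front_metrics.occupancy_to_frame(records).to_csv(out / "occupancy.csv", index=False)
    geom_df = pd.DataFrame(
        [
            {
                "tag_id": g.tag_id,
                "date": g.date,
                "d_min_km": round(g.d_min, 3) if np.isfinite(g.d_min) else "",
                "d_break_km": round(g.d_break, 3) if np.isfinite(g.d_break) else "",
                "t_min_c": round(g.t_min, 4) if np.isfinite(g.t_min) else "",
                "t_at_animal_c": round(g.t_at_animal, 4),
                "max_gradient_c_per_100km": round(g.max_windowed_gradient, 4)
                if np.isfinite(g.max_windowed_gradient)
                else "",
                "flags": ";".join(g.qc_flags),
            }
            for g in geoms
        ]
    )
    geom_df.to_csv(out / "front_geometry.csv", index=False)
    summary = front_metrics.occupancy_histogram(records, bin_pct=params["occupancy_bin_pct"])
    hist2d = front_metrics.dist_sst_histogram(
        sections, dist_bin_km=params["dist_bin_km"], sst_bin_c=params["sst_bin_c"]
    )
    summary["mean_sst_at_animal_c"] = hist2d.mean_sst_at_animal
    _write_json(summary, out / "occupancy_summary.json")
    hist_df = pd.DataFrame(
        hist2d.percent,
        index=[f"{lo:g}" for lo in hist2d.sst_edges[:-1]],
        columns=[f"{lo:g}" for lo in hist2d.distance_edges[:-1]],
    )
    hist_df.to_csv(out / "hist2d.csv")
    manifest["counts"]["occupancy_valid"] = summary["n_valid"]
    manifest["counts"]["occupancy_flagged"] = summary["n_flagged"]
    assert summary["n_valid"] + summary["n_flagged"] == len(sections)
    manifest["stages"].append("front_metrics")

    # ---- stage: movement vs currents --------------------------------------
    if u is not None:
        pairs, n_skipped = movement_currents.build_pairs(
            daily, max_gap_days=params["max_pair_gap_days"]
        )
        matchups, n_masked = movement_currents.matchup(pairs, u)
        movement_currents.records_to_frame(matchups).to_csv(out / "matchup.csv", index=False)
        if len(matchups) >= 3:
            agree = movement_currents.agreement(matchups, bin_ms=params["speed_bin_ms"])
        else:
            agree = {"n": len(matchups), "r2": None, "r2_reason": "too few matchups"}
        agree["n_pairs_eligible"] = len(pairs)
        agree["n_pairs_skipped_gap"] = n_skipped
        agree["n_pairs_masked"] = n_masked
        _write_json(agree, out / "matchup_summary.json")
        manifest["counts"]["pairs_eligible"] = len(pairs)
        manifest["counts"]["pairs_skipped_gap"] = n_skipped
        manifest["counts"]["matchups"] = len(matchups)
        manifest["stages"].append("matchup")
    else:
        log.info("no currents input; matchup stage skipped")

    # ---- stage: TAT --------------------------------------------------------
    if tat_path is not None and Path(tat_path).exists():
        tat_records = pd.read_csv(tat_path, dtype={"tag_id": str})
        pooled = tat_analysis.aggregate_tat(tat_records, group="pooled")
        per_tag = tat_analysis.aggregate_tat(tat_records, group="per-tag")
        per_tag.to_csv(out / "tat_aggregate_per_tag.csv", index=False)
        pooled.to_csv(out / "tat_aggregate_pooled.csv", index=False)
        thr = params["tat_threshold_c"]
        _write_json(
            {
                "n_records": len(tat_records),
                "n_tags": int(tat_records["tag_id"].nunique()),
                f"fraction_above_{thr:g}C": tat_analysis.fraction_above(pooled, thr),
            },
            out / "tat_summary.json",
        )
        manifest["counts"]["tat_records"] = len(tat_records)
        manifest["stages"].append("tat")
    else:
        log.info("no TAT input; TAT stage skipped")

    _write_json(manifest, out / "manifest.json")
    return manifest
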