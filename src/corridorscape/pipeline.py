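"""End-to-end pipeline: simulate -> prep -> fit -> validate -> corridor ->
circuit -> scenarios, driven by one config mapping and one global seed.

Each stage gets a deterministic per-stage seed derived from the global seed
and the stage name, so stages can be re-run in isolation and a re-run with
the same config reproduces every artifact.  All outputs land in a run
directory together with a manifest (inputs, config hash, seed, SHA-256
checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import circuit as circ
from . import connectivity as conn
from . import covariates as cov
from . import occupancy as occ
from . import scenarios as scen
from . import synth
from . import validation as val
from .grid import write_raster

log = logging.getLogger(__name__)

REQUIRED_BLOCKS = ("landscape", "survey", "occupancy", "corridor")

DEFAULT_OCC_POOL = [
    ["elevation", "raw"], ["slope", "raw"], ["bamboo", "categorical"],
    ["forest_age", "categorical"], ["dist_road", "raw"],
    ["dist_large_residence", "raw"],
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) ^ global_seed) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> None:
    missing = [b for b in REQUIRED_BLOCKS if b not in config]
    if missing:
        raise ValueError(f"config missing stage block(s): {missing}")


def select_corridor_points(table: pd.DataFrame, history, center_x: float,
                           n_per_side: int = 5) -> tuple[list, list]:
    """Detection locations flanking the valley: up to n per side, spread
    north-south, from sites with at least one detection (falling back to
    the highest-true-suitability sites if detections are too few)."""
    detected = np.nansum(history.y, axis=1) > 0
    t = table.copy()
    t["detected"] = detected
    out = []
    for side in ("west", "east"):
        sel = t[(t["x"] < center_x) if side == "west" else (t["x"] >= center_x)]
        hits = sel[sel["detected"]]
        if len(hits) < n_per_side and "true_psi" in sel:
            extra = sel[~sel["detected"]].nlargest(
                n_per_side - len(hits), "true_psi")
            hits = pd.concat([hits, extra])
        if len(hits) < n_per_side:
            raise RuntimeError(f"too few usable corridor points on the {side}")
        hits = hits.sort_values("y")
        pick = hits.iloc[np.linspace(0, len(hits) - 1, n_per_side).astype(int)]
        out.append([(int(r), int(c)) for r, c in zip(pick["row"], pick["col"])])
    return out[0], out[1]


def default_scenarios(stack, features) -> list[scen.ScenarioSpec]:
    """The three standard management scenarios instantiated on a generated
    valley landscape: restore the valley band, relocate large residences,
    and replace the central 1 km of road with a tunnel."""
    grid = stack.grid
    road = features.roads[0].geometry
    valley_band = road.buffer(1500.0)
    mid = road.length / 2.0
    return [
        scen.ScenarioSpec("restoration", [scen.RestoreForest(valley_band)]),
        scen.ScenarioSpec("relocation", [scen.RemoveResidences("large")]),
        scen.ScenarioSpec("tunnel", [scen.Tunnel(0, mid - 500.0, mid + 500.0)]),
    ]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        artifacts.append(p)

    def save_grid(grid, name: str):
        p = out / name
        write_raster(grid, p, "ascii_grid")
        artifacts.append(p)

    # --- simulate -----------------------------------------------------------
    lcfg = synth.LandscapeConfig(
        **{**config["landscape"], "seed": stage_seed(seed, "landscape")})
    stack, features = synth.generate_landscape(lcfg)
    truth_cfg = config.get("truth", "panda_like")
    truth = (synth.TrueModel.panda_like() if truth_cfg == "panda_like"
             else synth.TrueModel(**truth_cfg))
    psi_true = synth.simulate_truth(stack, truth)
    design = synth.SurveyDesign(**config["survey"])
    table, history = synth.simulate_surveys(
        psi_true, stack, truth, design, seed=stage_seed(seed, "survey"))
    for name in stack.names():
        save_grid(stack[name], f"layer_{name}.asc")
    save_grid(psi_true, "psi_true.asc")
    fp = out / "features.geojson"
    features.to_geojson(fp)
    artifacts.append(fp)
    save_df(table, "sites.csv")
    ydf = pd.DataFrame(history.y,
                       columns=[f"occ{t}" for t in range(history.n_occasions)])
    ydf.insert(0, "site_id", history.site_ids)
    save_df(ydf, "history.csv")

    # --- prep: collinearity screen -----------------------------------------
    occ_cfg = config["occupancy"]
    pool = [tuple(t) for t in occ_cfg.get("pool", DEFAULT_OCC_POOL)]
    cont = [n for n, f in pool if f != "categorical"]
    screened = cov.screen_collinearity(table, cont,
                                       priority=occ_cfg.get("priority"))
    pool = [(n, f) for n, f in pool
            if f == "categorical" or n in screened.retained]
    screened.correlation.to_csv(out / "correlation.csv")
    artifacts.append(out / "correlation.csv")

    # --- fit ----------------------------------------------------------------
    fit_kwargs = {"n_starts": int(occ_cfg.get("n_starts", 3)),
                  "seed": stage_seed(seed, "fit")}
    det_terms, _ = occ.select_detection_model(
        history, table, pool, occ_cfg.get("det_pool"), **fit_kwargs)
    mset = occ.all_subsets_selection(history, table, det_terms, pool,
                                     **fit_kwargs)
    avg = occ.model_average(mset, occ_cfg.get("delta_threshold", 2.0))
    save_df(mset.to_dataframe(), "model_set.csv")
    (out / "averaged_model.json").write_text(json.dumps({
        "coefficients": avg.coefficients,
        "det_coefficients": avg.det_coefficients,
        "importance": avg.importance,
        "detection_terms": det_terms,
    }, indent=2))
    artifacts.append(out / "averaged_model.json")
    psi_hat = occ.predict_suitability(avg, stack)
    save_grid(psi_hat, "psi_hat.asc")

    # --- validate -----------------------------------------------------------
    vcfg = config.get("validation", {})
    # adaptive survey effort: if the labelled set lacks confirmed absences
    # (or presences), follow-up transect rounds target the least- (or
    # most-) suitable stratum until both classes are represented
    n_seg = vcfg.get("n_segments", 216)
    min_class = vcfg.get("min_per_class", 5)
    radius = vcfg.get("absence_radius_m", 1000.0)
    batches = []
    best = None
    best_score = -1
    for round_ in range(vcfg.get("max_survey_rounds", 5)):
        # follow-up rounds walk short transects inside the least-suitable
        # stratum so they can confirm absences without scattering new sign
        # records across earlier ones
        frac, quant, spt = ((0.5, 0.5, vcfg.get("segments_per_transect", 8))
                            if round_ == 0 else (0.95, 0.15, 4))
        batch = synth.simulate_validation_transects(
            psi_true, n_seg if round_ == 0 else n_seg // 2,
            seed=stage_seed(seed, f"validation{round_}"),
            segments_per_transect=spt,
            low_psi_fraction=frac, low_psi_quantile=quant,
            use_seed=stage_seed(seed, "latent_use"))
        batch["transect_id"] += 10000 * round_
        batches.append(batch)
        candidate = pd.concat(batches, ignore_index=True)
        labelled = val.assign_validation_labels(candidate, radius)
        n_abs = int((labelled["label"] == 0).sum())
        n_pres = int((labelled["label"] == 1).sum())
        if min(n_abs, n_pres) > best_score:
            best_score = min(n_abs, n_pres)
            best = candidate
        if n_abs >= min_class and n_pres >= min_class:
            break
    segments = best
    save_df(segments, "validation_segments.csv")
    vres = val.validate_map(psi_hat, segments, radius)
    vres["roc"].to_csv(out / "roc.csv", index=False)
    artifacts.append(out / "roc.csv")
    (out / "auc.json").write_text(json.dumps(
        {k: v for k, v in vres.items() if k != "roc"}, indent=2))
    artifacts.append(out / "auc.json")

    # --- corridor -----------------------------------------------------------
    ccfg = config["corridor"]
    cost = conn.cost_surface(psi_hat, ccfg.get("scale", 99.0),
                             ccfg.get("cost_min", 1.0))
    save_grid(cost.grid, "cost.asc")
    center_x = float(np.mean([p[0] for p in
                              features.roads[0].geometry.coords]))
    srcs, snks = select_corridor_points(
        table, history, center_x, ccfg.get("n_points_per_side", 5))
    paths = conn.enumerate_pathways(cost, srcs, snks)
    save_df(pd.DataFrame(paths.to_records()), "paths.csv")

    # --- circuit ------------------------------------------------------------
    cicfg = config.get("circuit", {})
    current = None
    if cicfg.get("enabled", True):
        current = circ.omnidirectional_current(
            cost,
            buffer_width=cicfg.get("buffer_width", 4),
            n_perimeter_nodes=cicfg.get("n_perimeter_nodes", 12),
            pair_subsample=cicfg.get("pair_subsample", 30),
            seed=stage_seed(seed, "circuit"),
        )
        save_grid(current, "current.asc")

    # --- scenarios ----------------------------------------------------------
    sccfg = config.get("scenarios", {})
    result = None
    if sccfg.get("enabled", True):
        specs = default_scenarios(stack, features)
        matrix = scen.scenario_costs(
            stack, features, specs, avg, paths,
            {"scale": ccfg.get("scale", 99.0),
             "cost_min": ccfg.get("cost_min", 1.0)})
        result = scen.compare_scenarios(matrix)
        matrix.to_csv(out / "scenario_matrix.csv")
        artifacts.append(out / "scenario_matrix.csv")
        save_df(result.anova, "scenario_anova.csv")
        save_df(result.pairwise, "scenario_pairwise.csv")
        result.summary.to_csv(out / "scenario_summary.csv")
        artifacts.append(out / "scenario_summary.csv")

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "seed": seed,
        "config_hash": cfg_hash,
        "auc": vres["auc"],
        "n_paths": len(paths.paths),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def demo_config(n_rows: int = 80, n_cols: int = 100, seed: int = 7) -> dict:
    """A small, fast end-to-end configuration."""
    return {
        "seed": seed,
        "landscape": {"n_rows": n_rows, "n_cols": n_cols},
        "survey": {"n_periods": 8},
        "occupancy": {"n_starts": 2},
        "validation": {"n_segments": 216},
        "corridor": {"n_points_per_side": 5},
        "circuit": {"buffer_width": 4, "n_perimeter_nodes": 10,
                    "pair_subsample": 20},
        "scenarios": {"enabled": True},
    }
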