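"""End-to-end orchestration: data -> thin -> screen -> tune -> fit ->
project -> classify/change/centroid -> disperse, from one plain-text
(YAML) config with deterministic per-stage seeds and a machine-readable
run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change as change_mod
from . import dispersal as disp_mod
from . import occurrences as occ_mod
from . import screening
from . import synthetic
from .maxent import MaxentModel, mtsps_threshold, sample_background
from .rasters import read_stack, write_ascii_grid, write_stack
from .selection import run_grid, select_best


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: pure function of master seed + name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


DEFAULTS = {
    "thin": {"cell_km": 5.0, "buffer_km": 5.0},
    "screen": {"r_threshold": 0.7, "min_contribution": 0.0},
    "tune": {"rm_values": [0.5, 1.0, 2.0], "fc_values": ["L", "LQ"],
             "folds": 5, "selection": "auto"},
    "model": {"fc": "LQH", "rm": 1.0, "n_knots": 10,
              "background_size": 10000},
    "classify": {"upper": [0.4, 0.6]},
    "dispersal": {"disp_kernel": list(disp_mod.DEFAULT_KERNEL),
                  "propagule_prod": [1.0], "suitability_threshold": None,
                  "disp_steps_per_env": 20, "barrier_mode": "strong",
                  "invasibility_mode": "binary", "replicates": 10},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def validate(config: dict) -> list[str]:
    """Cross-reference checks before any compute; returns error strings."""
    errors = []
    if "seed" not in config:
        errors.append("missing master 'seed'")
    has_synth = "synthetic" in config
    has_paths = "inputs" in config
    if not has_synth and not has_paths:
        errors.append("config needs either a 'synthetic' scenario or 'inputs'")
    if has_paths:
        inp = config["inputs"]
        occ = inp.get("occurrences")
        if not occ:
            errors.append("inputs.occurrences missing")
        elif not Path(occ).exists():
            errors.append(f"inputs.occurrences path not found: {occ}")
        for p in inp.get("current_rasters", []):
            if not Path(p).exists():
                errors.append(f"raster path not found: {p}")
    labels = [s.get("label") for s in config.get("scenarios", [])]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        errors.append(f"duplicate scenario labels: {sorted(dupes)}")
    for s in config.get("scenarios", []):
        for p in s.get("rasters", []):
            if not Path(p).exists():
                errors.append(f"scenario {s.get('label')}: raster not found: {p}")
    if "output_dir" not in config:
        errors.append("missing 'output_dir'")
    return errors


def _merged(config: dict, section: str) -> dict:
    out = dict(DEFAULTS.get(section, {}))
    out.update(config.get(section, {}) or {})
    return out


def run_all(config: dict) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to <output_dir>/manifest.json)."""
    errors = validate(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    master = int(config["seed"])
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": master, "stages": {}, "config": config}

    # -- stage: data --------------------------------------------------------
    if "synthetic" in config:
        scn_kwargs = dict(config["synthetic"] or {})
        scn_kwargs.setdefault("seed", stage_seed(master, "synthetic"))
        scenario = synthetic.SyntheticScenario(**scn_kwargs)
        products = synthetic.write_scenario_products(scenario, outdir / "data")
        stack = products["stack"]
        occ = products["occurrences"]
        future_stack = products["future"]
        barriers = products["barriers"]
        scenarios = [("future", future_stack)]
        manifest["stages"]["data"] = {"kind": "synthetic",
                                      "seed": scenario.seed,
                                      "n_occurrences": len(occ)}
    else:
        inp = config["inputs"]
        occ = occ_mod.read_occurrences(inp["occurrences"])
        stack = read_stack(inp["current_rasters"])
        scenarios = []
        for s in config.get("scenarios", []):
            scenarios.append((s["label"], read_stack(s["rasters"])))
        barriers = None
        if inp.get("barriers"):
            from .rasters import read_ascii_grid
            b, _ = read_ascii_grid(inp["barriers"])
            barriers = b > 0
        manifest["stages"]["data"] = {"kind": "files",
                                      "n_occurrences": len(occ)}

    # optionally drop the human-footprint layer (climate-only variant)
    if not config.get("include_human", True):
        drop = [n for n in stack.names if n.lower() in ("hfp", "human_footprint")]
        keep = [n for n in stack.names if n not in drop]
        stack = stack.subset(keep)
        scenarios = [(lbl, s.subset([n for n in keep if n in s]))
                     for lbl, s in scenarios]
        barriers = None
        manifest["stages"]["data"]["dropped_layers"] = drop

    # -- stage: thin --------------------------------------------------------
    tcfg = _merged(config, "thin")
    occ_thin = occ_mod.thin(occ, cell_km=tcfg["cell_km"],
                            buffer_km=tcfg["buffer_km"])
    occ_thin.to_csv(outdir / "occurrences_thinned.csv")
    manifest["stages"]["thin"] = {"n_in": len(occ), "n_out": len(occ_thin),
                                  **tcfg}

    # -- stage: screen ------------------------------------------------------
    scfg = _merged(config, "screen")
    mcfg = _merged(config, "model")
    bg_seed = stage_seed(master, "background")
    bg = sample_background(stack, size=mcfg["background_size"], seed=bg_seed)
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    rng = np.random.default_rng(bg_seed)
    pick = rng.choice(len(rows), size=min(len(rows), mcfg["background_size"]),
                      replace=False)
    corr, zero_var = screening.pearson_matrix(stack, rows[pick], cols[pick])
    pre_model = MaxentModel.from_stack(
        stack, occ_thin, fc="L", rm=1.0, n_knots=mcfg["n_knots"],
        background_size=mcfg["background_size"], seed=bg_seed)
    pre_res = pre_model.fit()
    contributions = pre_res.percent_contribution().to_dict()
    report = screening.screen_variables(contributions, corr,
                                        r_threshold=scfg["r_threshold"],
                                        min_contribution=scfg["min_contribution"])
    report.to_frame().to_csv(outdir / "screening.csv", index=False)
    corr.to_csv(outdir / "correlation_matrix.csv")
    kept = report.kept
    stack = stack.subset(kept)
    scenarios = [(lbl, s.subset([n for n in kept if n in s]))
                 for lbl, s in scenarios]
    manifest["stages"]["screen"] = {"kept": kept, "zero_variance": zero_var,
                                    "dropped": [d[0] for d in report.dropped],
                                    "seed": bg_seed, **scfg}

    # -- stage: tune --------------------------------------------------------
    tune_cfg = _merged(config, "tune")
    pres = MaxentModel.from_stack(stack, occ_thin, fc="L",
                                  background_size=mcfg["background_size"],
                                  seed=bg_seed).presences
    bg = sample_background(stack, size=mcfg["background_size"], seed=bg_seed)
    fc, rm = mcfg["fc"], mcfg["rm"]
    if tune_cfg["selection"] == "auto":
        grid = run_grid(pres, bg, rm_values=tune_cfg["rm_values"],
                        fc_values=tune_cfg["fc_values"],
                        folds=tune_cfg["folds"],
                        seed=stage_seed(master, "tune"),
                        n_knots=mcfg["n_knots"])
        grid.to_csv(outdir / "tuning_grid.csv")
        fc, rm = select_best(grid)
    manifest["stages"]["tune"] = {"fc": fc, "rm": rm,
                                  "selection": tune_cfg["selection"]}

    # -- stage: fit ---------------------------------------------------------
    model = MaxentModel(pres, bg, fc=fc, rm=rm, n_knots=mcfg["n_knots"])
    res = model.fit()
    res.to_lambdas(outdir / "model.lambdas")
    (outdir / "summary.txt").write_text(res.summary() + "\n")
    manifest["stages"]["fit"] = {"fc": fc, "rm": rm,
                                 "converged": res.converged,
                                 "n_nonzero": res.n_nonzero,
                                 "entropy": res.entropy}

    # -- stage: project + classify + change + centroid ----------------------
    bg_scores = res.predict(bg, mode="logistic")
    pres_scores = res.predict(pres, mode="logistic")
    mtsps = mtsps_threshold(pres_scores, bg_scores)
    geometry = stack.geometry
    ccfg = _merged(config, "classify")
    # the four-class scheme needs the suitable/unsuitable cut below the
    # first fixed bin edge; cap it there if the data put MTSPS higher
    class_cut = mtsps
    if class_cut >= ccfg["upper"][0]:
        import warnings
        warnings.warn(f"MTSPS {mtsps:.3f} >= first class bound "
                      f"{ccfg['upper'][0]}; capping the classification cut",
                      RuntimeWarning)
        class_cut = ccfg["upper"][0] - 1e-6
    suit_current = res.predict(stack, mode="logistic")
    write_ascii_grid(outdir / "suitability_current.asc", suit_current, geometry)
    cmap_current = change_mod.classify(suit_current, geometry, class_cut,
                                       upper=tuple(ccfg["upper"]))
    maps = [("current", cmap_current)]
    suits = [("current", suit_current)]
    for label, sstack in scenarios:
        suit = res.predict(sstack, mode="logistic")
        write_ascii_grid(outdir / f"suitability_{label}.asc", suit, geometry)
        maps.append((label, change_mod.classify(suit, geometry, class_cut,
                                                upper=tuple(ccfg["upper"]))))
        suits.append((label, suit))
    summaries = []
    for label, cmap in maps[1:]:
        summary, raster = change_mod.change_map(cmap_current, cmap)
        write_ascii_grid(outdir / f"change_{label}.asc",
                         raster.astype(float), geometry)
        row = summary.to_frame()
        row.insert(0, "scenario", label)
        summaries.append(row)
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(
            outdir / "change_summaries.csv", index=False)
    track = change_mod.track_migration([m for _, m in maps],
                                       periods=[l for l, _ in maps])
    track.to_frame().to_csv(outdir / "centroid_track.csv", index=False)
    manifest["stages"]["classify"] = {
        "mtsps": mtsps, "class_cut": class_cut,
        "areas_km2": {l: m.areas_km2 for l, m in maps}}

    # -- stage: disperse ----------------------------------------------------
    dcfg = _merged(config, "dispersal")
    if barriers is None:
        barriers = np.zeros(geometry.shape, dtype=bool)
    thr = dcfg["suitability_threshold"]
    if thr is None:
        thr = disp_mod.threshold_from_mtsps(mtsps)
    maps_1000 = [np.nan_to_num(s * 1000.0).astype(int) for _, s in suits]
    dconf = disp_mod.DispersalConfig(
        disp_kernel=tuple(dcfg["disp_kernel"]),
        propagule_prod=tuple(dcfg["propagule_prod"]),
        suitability_threshold=thr,
        env_chg_steps=len(maps_1000) - 1 if len(maps_1000) > 1 else 1,
        disp_steps_per_env=dcfg["disp_steps_per_env"],
        barrier_mode=dcfg["barrier_mode"],
        invasibility_mode=dcfg["invasibility_mode"],
        replicates=dcfg["replicates"],
        seed=stage_seed(master, "disperse"))
    habitat_maps = maps_1000[1:] if len(maps_1000) > 1 else maps_1000
    outcome = disp_mod.run(maps_1000[0], habitat_maps, barriers, dconf)
    outcome.summary().to_csv(outdir / "dispersal_summary.csv", index=False)
    write_ascii_grid(outdir / "colonization_frequency.asc",
                     outcome.colonization_frequency, geometry)
    manifest["stages"]["disperse"] = {
        "threshold": thr, "seed": dconf.seed,
        "replicate_seeds": outcome.replicate_seeds,
        "ini_dist": outcome.ini_count,
        "mean_colonized": outcome.mean_colonized,
        "mean_lost": outcome.mean_lost}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
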