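"""Run configuration and end-to-end pipeline orchestration.

A run executes: thin → screen → fit → replicates → predict → classify →
areas → centroid → (optional per-scenario land-cover projection with
refreshed distance layers and re-prediction) → resistance → sources →
corridors → metrics. Every intermediate is written as a standard-format
file into the run directory, and a JSON manifest records stages, seeds,
timings and output hashes so a run is auditable and re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .camarkov import (AreaVector, ca_allocate, estimate_transition,
                       markov_project, refresh_distance_layers, scenario_adjust)
from .corridors import (identify_sources, least_cost_corridors, load_scheme,
                        resistance_surface, scheme_from_response, write_scheme)
from .grids import EnvStack, read_grid, write_grid
from .maxent import (MaxEntConfig, evaluate_replicates, fit, pearson_screen,
                     percent_contribution, predict)
from .metrics import metrics
from .occurrences import load_points, thin
from .suitability import (SuitabilityClasses, area_table, centroid, classify)

log = logging.getLogger("habicon")

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    layers: Dict[str, Dict[str, str]]
    occurrences: str
    output_dir: str
    seed: int = 0
    thin_distance: float = 100.0
    maxent: MaxEntConfig = field(default_factory=MaxEntConfig)
    cuts: tuple = (0.2, 0.5, 0.7)
    resistance_scheme: str = "from_model"
    min_area_km2: float = 10.0
    camarkov: Optional[Dict[str, Any]] = None
    screen_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base, p)

        try:
            layers = {
                name: {"path": resolve(entry["path"]),
                       "kind": entry.get("kind", "continuous")}
                for name, entry in raw["layers"].items()
            }
            occurrences = resolve(raw["occurrences"])
            output_dir = resolve(raw.get("output_dir", "run"))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: malformed config ({exc})")
        me_raw = dict(raw.get("maxent", {}))
        if "feature_classes" in me_raw and me_raw["feature_classes"] is not None:
            me_raw["feature_classes"] = tuple(me_raw["feature_classes"])
        me = MaxEntConfig(seed=raw.get("seed", 0), **me_raw)
        cam = raw.get("camarkov")
        if cam is not None:
            for key in ("map_t1", "map_t2"):
                if key not in cam:
                    raise ConfigError(f"camarkov block needs {key!r}")
                cam[key] = resolve(cam[key])
        scheme = raw.get("resistance_scheme", "from_model")
        if scheme != "from_model":
            scheme = resolve(scheme)
        cfg = cls(
            layers=layers,
            occurrences=occurrences,
            output_dir=output_dir,
            seed=int(raw.get("seed", 0)),
            thin_distance=float(raw.get("thin_distance", 100.0)),
            maxent=me,
            cuts=tuple(raw.get("classes", {}).get("cuts", (0.2, 0.5, 0.7))),
            resistance_scheme=scheme,
            min_area_km2=float(raw.get("min_area_km2", 10.0)),
            camarkov=cam,
            screen_threshold=float(raw.get("screen_threshold", 0.8)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [e["path"] for e in self.layers.values()
                   if not os.path.exists(e["path"])]
        if not os.path.exists(self.occurrences):
            missing.append(self.occurrences)
        if self.resistance_scheme != "from_model" and not os.path.exists(self.resistance_scheme):
            missing.append(self.resistance_scheme)
        if self.camarkov:
            for key in ("map_t1", "map_t2"):
                if not os.path.exists(self.camarkov[key]):
                    missing.append(self.camarkov[key])
        if missing:
            raise ConfigError(f"referenced files do not exist: {missing}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> str:
    """Execute every stage; returns the run directory path."""
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: Dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    t0_total = time.time()

    def stage(name: str):
        log.info("[%s] starting", name)
        return time.time()

    def done(name: str, t0: float, outputs: List[str]) -> None:
        for out in outputs:
            manifest["outputs"][os.path.basename(out)] = _sha256(out)
        manifest["stages"].append(
            {"name": name, "seconds": round(time.time() - t0, 3),
             "outputs": [os.path.basename(o) for o in outputs]}
        )
        log.info("[%s] done (%.2fs)", name, time.time() - t0)

    out = lambda *parts: os.path.join(config.output_dir, *parts)

    # 1. load + thin occurrences
    t = stage("thin")
    raw_points = load_points(config.occurrences)
    thinned = thin(raw_points, config.thin_distance, config.seed)
    raw_points.to_csv(out("occurrences_thinned.csv"), kept=thinned)
    done("thin", t, [out("occurrences_thinned.csv")])

    # 2. load layers + screen variables
    t = stage("screen")
    layers = {name: read_grid(e["path"], e["kind"])
              for name, e in config.layers.items()}
    stack = EnvStack(layers)
    if len(stack.continuous_names()) >= 2:
        pre_model = fit(thinned, stack, config.maxent)
        pre_contrib = percent_contribution(pre_model)
        report = pearson_screen(stack, pre_contrib, config.screen_threshold)
        selected = report.selected
        pd.DataFrame(report.pearson_matrix, index=report.variable_names,
                     columns=report.variable_names).to_csv(out("pearson_matrix.csv"))
    else:
        selected = stack.names
    stack = stack.subset(selected)
    with open(out("selected_variables.json"), "w") as fh:
        json.dump(selected, fh)
    done("screen", t, [out("selected_variables.json")])

    # 3. fit
    t = stage("fit")
    model = fit(thinned, stack, config.maxent)
    model.to_json(out("model.json"))
    contributions = percent_contribution(model)
    pd.Series(contributions, name="pct").rename_axis("variable").to_csv(
        out("contributions.csv"))
    done("fit", t, [out("model.json"), out("contributions.csv")])

    # 4. replicate evaluation
    t = stage("replicates")
    auc_mean, auc_sd, per_rep = evaluate_replicates(thinned, stack, config.maxent)
    with open(out("replicates.json"), "w") as fh:
        json.dump({"auc_mean": auc_mean, "auc_sd": auc_sd, "per_rep": per_rep}, fh)
    done("replicates", t, [out("replicates.json")])

    # 5. predict
    t = stage("predict")
    suit = predict(model, stack, "logistic")
    write_grid(suit, out("suitability.asc"), "ascii")
    done("predict", t, [out("suitability.asc")])

    # 6. classify
    t = stage("classify")
    classes = SuitabilityClasses(config.cuts)
    classified = classify(suit, classes)
    write_grid(classified, out("classified.asc"), "ascii")
    done("classify", t, [out("classified.asc")])

    # 7. areas
    t = stage("areas")
    table = area_table(classified, scenario="present")
    rows = [dict(scenario="present", **table.to_row())]
    done_areas_path = out("areas.csv")

    # 8. centroid
    tc = stage("centroid")
    dem = stack["DEM"] if "DEM" in stack else None
    cen = centroid(suit, classified, dem)
    with open(out("centroid.geojson"), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [{
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [cen.x, cen.y]},
            "properties": {"scenario": "present",
                           "mean_elevation": cen.mean_elevation},
        }]}, fh)
    done("centroid", tc, [out("centroid.geojson")])

    # 9. optional land-cover projection per scenario
    t9 = stage("lucc-project")
    scenario_outputs: List[str] = []
    if config.camarkov and "LUCC" in stack:
        cam = config.camarkov
        m1 = read_grid(cam["map_t1"], "categorical")
        m2 = read_grid(cam["map_t2"], "categorical")
        tm = estimate_transition(m1, m2, cam.get("step_years", 0))
        tm.to_csv(out("transition_matrix.csv"))
        scenario_outputs.append(out("transition_matrix.csv"))
        water = cam.get("water_codes", [1])
        grass = cam.get("grassland_codes", [2])
        for scen, mult in dict(cam.get("scenario_multipliers", {"base": 1.0})).items():
            tm_s = scenario_adjust(tm, float(mult))
            current = stack["LUCC"]
            counts = AreaVector(tm_s.classes, [
                int(((current.values == c) & current.valid_mask).sum())
                for c in tm_s.classes], epoch="now")
            for step in range(1, int(cam.get("epochs", 1)) + 1):
                target = markov_project(counts, tm_s, step)
                # integer targets that conserve the valid-cell count
                tgt = np.floor(target.areas).astype(int)
                remainder = int(counts.areas.sum()) - int(tgt.sum())
                frac_order = np.argsort(-(target.areas - tgt))
                for k in range(remainder):
                    tgt[frac_order[k % len(tgt)]] += 1
                alloc = ca_allocate(current, AreaVector(tm_s.classes, tgt),
                                    seed=config.seed + step)
                name = f"lucc_{scen}_step{step}"
                write_grid(alloc, out(name + ".asc"), "ascii")
                scenario_outputs.append(out(name + ".asc"))
                dw, dh = refresh_distance_layers(alloc, water, grass)
                scen_stack = stack.with_layer("LUCC", alloc)
                if "DW" in stack:
                    scen_stack = scen_stack.with_layer("DW", dw)
                if "DH" in stack:
                    scen_stack = scen_stack.with_layer("DH", dh)
                scen_suit = predict(model, scen_stack, "logistic")
                scen_classified = classify(scen_suit, classes)
                write_grid(scen_suit, out(f"suitability_{scen}_step{step}.asc"), "ascii")
                scenario_outputs.append(out(f"suitability_{scen}_step{step}.asc"))
                rows.append(dict(
                    scenario=f"{scen}_step{step}",
                    **area_table(scen_classified,
                                 scenario=f"{scen}_step{step}").to_row()))
    done("lucc-project", t9, scenario_outputs)

    pd.DataFrame(rows).to_csv(done_areas_path, index=False)
    manifest["outputs"][os.path.basename(done_areas_path)] = _sha256(done_areas_path)
    manifest["stages"].append({"name": "areas", "seconds": 0.0,
                               "outputs": [os.path.basename(done_areas_path)]})

    # 10. resistance surface + sources + corridors
    t = stage("corridors")
    if config.resistance_scheme == "from_model":
        scheme = scheme_from_response(model, stack, contributions)
    else:
        scheme = load_scheme(config.resistance_scheme)
    write_scheme(scheme, out("resistance_scheme.csv"))
    resist = resistance_surface(stack, scheme)
    write_grid(resist, out("resistance.asc"), "ascii")
    sources = identify_sources(classified, config.min_area_km2)
    corridor_files = [out("resistance_scheme.csv"), out("resistance.asc")]
    if len(sources) >= 2:
        corridor_set = least_cost_corridors(resist, sources)
        corridor_set.to_geojson(out("corridors.geojson"))
        corridor_files.append(out("corridors.geojson"))
    done("corridors", t, corridor_files)

    # 11. landscape metrics
    t = stage("metrics")
    report = metrics(classified)
    pd.DataFrame([dict(scenario="present", **report.as_dict())]).to_csv(
        out("landscape_metrics.csv"), index=False)
    done("metrics", t, [out("landscape_metrics.csv")])

    manifest["total_seconds"] = round(time.time() - t0_total, 3)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return config.output_dir
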