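"""End-to-end pipeline: simulate -> GEA -> classify -> ENM -> connectivity.

The pipeline runs the full vulnerability-assessment workflow on a synthetic
study system, writing every stage's outputs (Genepop genotypes, candidate
CSVs, ASCII-grid rasters, distance matrices) plus a machine-readable
``summary.json`` into a run directory.  Every random operation receives a
seed derived from the single top-level seed, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import adaptclass, connect, enm, experiments, gea, synthio
from .popgen import pairwise_fst, write_genepop
from .rasters import write_ascii_grid

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "validate_inputs"]

log = logging.getLogger("adaptscape")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["simulate", "gea", "classify", "enm", "overlap", "connect", "rescue"],
    "landscape": {
        "grid": 48,
        # species occupies a precipitation band orthogonal to the
        # temperature gradient; roosts are placed within it
        "species_niche": {"intercept": 4.0, "clim2^2": -16.0},
    },
    "population": {
        "n_populations": 10,
        "inds_per_population": 20,
        "n_neutral_loci": 1000,
        "n_adaptive_loci": 20,
        "fst_target": 0.1,
        "adaptive_slope": 2.0,
    },
    "gea": {
        "sd_threshold": 3.0,
        "q_threshold": 0.05,
        "k_max": 12,
    },
    "classify": {
        "t": 0.25,
        "majority": 0.6,
    },
    "enm": {
        "n_background": 800,
        "tss_cutoff": 0.4,
        "min_group_size": 5,
        "warming_deltas": [1.0, 1.5, 2.0],
        "n_extra_occurrences": 100,
    },
    "connect": {
        "ibr_beta": 1.0,
        "ibr_noise_frac": 0.25,
        "n_perm": 199,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown configuration key: {path}{key}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"configuration section {path}{key} must be a mapping")
            out[key] = _merge(base[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def validate_config(config: dict | None) -> dict:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    known = set(DEFAULT_CONFIG["stages"])
    unknown = [s for s in cfg["stages"] if s not in known]
    if unknown:
        raise KeyError(f"unknown stages: {unknown}")
    stages = cfg["stages"]
    for later, deps in {
        "classify": ["gea"],
        "enm": ["classify"],
        "overlap": ["enm"],
        "rescue": ["connect", "classify"],
    }.items():
        for dep in deps:
            if later in stages and dep not in stages:
                raise KeyError(f"stage {later!r} requires stage {dep!r}")
    return cfg


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run the configured stages; returns (and writes) the summary dict."""
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    summary: dict = {"seed": seed, "stages": stages, "table": {}}
    t0 = time.time()

    state: dict = {}
    runners = {
        "simulate": _stage_simulate,
        "gea": _stage_gea,
        "classify": _stage_classify,
        "enm": _stage_enm,
        "overlap": _stage_overlap,
        "connect": _stage_connect,
        "rescue": _stage_rescue,
    }
    for stage in ["simulate", "gea", "classify", "enm", "overlap", "connect", "rescue"]:
        if stage not in stages:
            continue
        start = time.time()
        try:
            runners[stage](cfg, seed, state, summary, out)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1fs", stage, time.time() - start)

    summary["runtime_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, seed, state, summary, out):
    study = experiments.simulate_study(
        seed,
        grid=cfg["landscape"]["grid"],
        orthogonal_gradients=True,
        roost_suitability=cfg["landscape"]["species_niche"],
        **cfg["population"],
    )
    state["study"] = study
    write_genepop(study.genotypes, out / "genotypes.gen")
    x, y = study.stack.template.rowcol_to_xy(
        study.individual_cells[:, 0], study.individual_cells[:, 1]
    )
    pd.DataFrame(
        {
            "id": study.genotypes.sample_ids,
            "lon": x,
            "lat": y,
            "population": study.genotypes.populations,
        }
    ).to_csv(out / "samples.csv", index=False)
    for name in study.stack.names:
        write_ascii_grid(study.stack[name], out / f"present_{name}.asc")
    deltas = cfg["enm"]["warming_deltas"]
    futures = [
        synthio.generate_future_rasters(
            study.stack, {"clim1": d, "clim2": -d / 2.0}, seed=seed + 300 + i
        )
        for i, d in enumerate(deltas)
    ]
    state["futures"] = futures
    summary["n_individuals"] = study.genotypes.n_individuals
    summary["n_loci"] = study.genotypes.n_loci


def _stage_gea(cfg, seed, state, summary, out):
    res = experiments.run_gea(state["study"], **cfg["gea"])
    state["gea"] = res
    res["rda"].to_csv(out / "candidates_rda.csv")
    res["latent"].to_csv(out / "candidates_latent.csv")
    res["intersection"].to_csv(out / "candidates_intersection.csv")
    summary["gea"] = {
        "K": res["K"],
        "n_rda": len(res["rda"]),
        "n_latent": len(res["latent"]),
        "n_intersection": len(res["intersection"]),
        "lambda_gc": res["latent_result"].lambda_gc,
    }


def _stage_classify(cfg, seed, state, summary, out):
    study = state["study"]
    cand = state["gea"]["intersection"]
    score = adaptclass.score_individuals(
        study.genotypes, cand, study.climate, temperature_variable=study.climate.names[0]
    )
    assignment = adaptclass.classify_individuals(score, t=cfg["classify"]["t"])
    assignment = adaptclass.classify_populations(assignment, majority=cfg["classify"]["majority"])
    state["assignment"] = assignment
    assignment.individual.to_csv(out / "individual_groups.csv", index=False)
    assignment.population.to_csv(out / "population_groups.csv", index=False)
    summary["classification"] = {
        "individual_proportions": assignment.individual_proportions(),
        "population_labels": dict(
            zip(assignment.population["population"], assignment.population["label"])
        ),
    }


def _stage_enm(cfg, seed, state, summary, out):
    study = state["study"]
    assignment = state["assignment"]
    stack = study.stack
    futures = state["futures"]
    template = stack.template
    mask = template.copy_with(np.where(stack.valid_mask, 1.0, template.nodata))
    state["mask"] = mask

    # group occurrence sets from classified individuals; the full set adds
    # extra records drawn from a truth suitability surface built on both
    # climate gradients (stand-in for non-genotyped occurrence records)
    ind = assignment.individual
    cells = study.individual_cells
    occ_sets = {}
    for group in (adaptclass.HOT_DRY, adaptclass.COLD_WET):
        rows = cells[(ind["label"] == group).to_numpy()]
        if rows.shape[0] < cfg["enm"]["min_group_size"]:
            raise ValueError(f"group {group!r} has fewer than min_group_size individuals")
        x, y = template.rowcol_to_xy(rows[:, 0], rows[:, 1])
        occ_sets[group] = enm.clean_occurrences(
            enm.OccurrenceSet(np.column_stack([x, y]), group=group), stack
        )
    extra = synthio.simulate_occurrences(
        stack,
        cfg["landscape"]["species_niche"],
        max(cfg["enm"]["n_extra_occurrences"], 5),
        seed=seed + 400,
    )
    x, y = template.rowcol_to_xy(cells[:, 0], cells[:, 1])
    occ_sets["all"] = enm.clean_occurrences(
        enm.OccurrenceSet(
            np.vstack([np.column_stack([x, y]), extra.coordinates]), group="all"
        ),
        stack,
    )

    table = {}
    state["present_binary"] = {}
    state["future_binary"] = {}
    state["present_continuous"] = {}
    for name, occ in occ_sets.items():
        ens = enm.fit_ensemble_enm(
            stack,
            occ,
            seed=seed + 500,
            n_background=cfg["enm"]["n_background"],
            tss_cutoff=cfg["enm"]["tss_cutoff"],
        )
        cont = ens.predict_raster(stack)
        pres_bin = ens.binarize(cont)
        fut_cont, fut_bin = enm.project(ens, futures)
        report = enm.range_change(pres_bin, fut_bin, mask)
        write_ascii_grid(cont, out / f"suitability_present_{name}.asc")
        write_ascii_grid(pres_bin, out / f"range_present_{name}.asc")
        write_ascii_grid(fut_bin, out / f"range_future_{name}.asc")
        state["present_binary"][name] = pres_bin
        state["future_binary"][name] = fut_bin
        state["present_continuous"][name] = cont
        table[name] = {
            "n": occ.n,
            "auc": round(float(np.mean([e.auc for e in ens.evaluations])), 4),
            "tss": round(float(np.mean([e.tss for e in ens.evaluations])), 4),
            "pct_suitable_present": round(report.percent_present, 2),
            "pct_suitable_future": round(report.percent_future, 2),
            "pct_range_change": round(report.percent_change, 2),
        }
    summary["table"] = table


def _stage_overlap(cfg, seed, state, summary, out):
    pres = state["present_binary"]
    fut = state["future_binary"]
    mask = state["mask"]
    union_p = enm.combine_ranges(pres[adaptclass.HOT_DRY], pres[adaptclass.COLD_WET])
    union_f = enm.combine_ranges(fut[adaptclass.HOT_DRY], fut[adaptclass.COLD_WET])
    union_report = enm.range_change(union_p, union_f, mask)
    d = enm.schoener_d(
        state["present_continuous"][adaptclass.HOT_DRY],
        state["present_continuous"][adaptclass.COLD_WET],
    )
    summary["overlap"] = {
        "union_pct_present": round(union_report.percent_present, 2),
        "union_pct_future": round(union_report.percent_future, 2),
        "union_pct_change": round(union_report.percent_change, 2),
        "range_overlap_present": round(
            enm.range_overlap(pres[adaptclass.HOT_DRY], pres[adaptclass.COLD_WET], mask), 2
        ),
        "range_overlap_future": round(
            enm.range_overlap(fut[adaptclass.HOT_DRY], fut[adaptclass.COLD_WET], mask), 2
        ),
        "schoeners_d_hot_vs_cold": round(d.d, 3),
    }


def _stage_connect(cfg, seed, state, summary, out):
    study = state["study"]
    surfaces = experiments._landscape_surfaces(seed, grid=cfg["landscape"]["grid"])
    state["surfaces"] = surfaces
    roosts = study.roost_cells
    distances = {}
    for name, surf in surfaces.items():
        graph = connect.build_graph(surf)
        nodes = [int(graph.node_of_cell[r, c]) for r, c in roosts]
        distances[name] = connect.effective_resistance(graph, nodes).values

    fst = pairwise_fst(study.genotypes)
    genetic = fst.linearized
    ranked = connect.rank_surfaces(
        genetic, distances, n_perm=cfg["connect"]["n_perm"], seed=seed + 600
    )
    state["best_surface"] = surfaces[ranked[0].surface]
    pd.DataFrame(genetic, index=fst.population_ids, columns=fst.population_ids).to_csv(
        out / "fst_linearized.csv"
    )
    pd.DataFrame(
        [
            {
                "surface": r.surface,
                "mantel_r": r.mantel_r,
                "mantel_p": r.mantel_p,
                "r_squared": r.r_squared,
            }
            for r in ranked
        ]
    ).to_csv(out / "ibr_regression.csv", index=False)
    summary["connect"] = {
        "best_surface": ranked[0].surface,
        "r_squared": round(ranked[0].r_squared, 4),
        "mantel_r": round(ranked[0].mantel_r, 4),
        "mantel_p": round(ranked[0].mantel_p, 4),
    }


def _stage_rescue(cfg, seed, state, summary, out):
    study = state["study"]
    assignment = state["assignment"]
    pop_table = assignment.population
    labels = dict(zip(pop_table["population"], pop_table["label"]))
    pops = sorted(labels)
    roost_of = {p: tuple(study.roost_cells[i]) for i, p in enumerate(sorted(set(study.genotypes.populations)))}
    sources = [roost_of[p] for p in pops if labels[p] == adaptclass.HOT_DRY]
    targets = [roost_of[p] for p in pops if labels[p] == adaptclass.COLD_WET]
    if not sources or not targets:
        summary["rescue"] = {"note": "no hot_dry sources or no cold_wet targets among populations"}
        return
    cmap, per_target = connect.rescue_potential(
        state["best_surface"],
        sources,
        targets,
        source_ids=[p for p in pops if labels[p] == adaptclass.HOT_DRY],
        target_ids=[p for p in pops if labels[p] == adaptclass.COLD_WET],
    )
    write_ascii_grid(cmap.raster, out / "rescue_current_density.asc")
    summary["rescue"] = {
        "n_sources": len(sources),
        "n_targets": len(targets),
        "mean_resistance_per_target": {k: round(v, 4) for k, v in per_target.items()},
    }


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(
    raster_paths: list | None = None,
    genepop_path=None,
    sample_table_path=None,
) -> list[str]:
    """Check raster co-registration and Genepop/sample-table id agreement.

    Returns a list of human-readable problems; an empty list means the
    inputs are consistent."""
    from .popgen import read_genepop
    from .rasters import read_ascii_grid

    problems: list[str] = []
    rasters = []
    for p in raster_paths or []:
        try:
            rasters.append((p, read_ascii_grid(p)))
        except Exception as exc:  # noqa: BLE001
            problems.append(f"cannot read raster {p}: {exc}")
    for path, r in rasters[1:]:
        if not rasters[0][1].same_geometry(r):
            problems.append(f"raster {path} is not co-registered with {rasters[0][0]}")

    gm = None
    if genepop_path is not None:
        try:
            gm = read_genepop(genepop_path)
        except Exception as exc:  # noqa: BLE001
            problems.append(f"cannot read Genepop {genepop_path}: {exc}")
    if sample_table_path is not None:
        table = pd.read_csv(sample_table_path)
        for col in ("id", "lon", "lat"):
            if col not in table.columns:
                problems.append(f"sample table missing column {col!r}")
        if gm is not None and "id" in table.columns:
            geno_ids = set(gm.sample_ids)
            table_ids = set(table["id"].astype(str))
            for missing in sorted(geno_ids - table_ids):
                problems.append(f"id {missing!r} in Genepop but not in sample table")
            for missing in sorted(table_ids - geno_ids):
                problems.append(f"id {missing!r} in sample table but not in Genepop")
        if rasters and {"lon", "lat"}.issubset(table.columns):
            template = rasters[0][1]
            outside = ~template.contains_xy(
                table["lon"].to_numpy(float), table["lat"].to_numpy(float)
            )
            if outside.any():
                problems.append(f"{int(outside.sum())} sample(s) fall outside the raster extent")
    return problems
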