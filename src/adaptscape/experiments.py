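"""Seeded end-to-end simulation studies on synthetic landscapes.

These are the package's benchmark experiments: each one builds a synthetic
study system (climate landscape, structured genotypes with climate-clinal
adaptive loci, occurrences, resistance surfaces), runs the corresponding
analysis stage, and measures how well the known truth is recovered.  They
back both the test suite and the reproducibility script.

Default study conditions: a 64x64 landscape with two opposing climate
gradients (a temperature-like and a precipitation-like layer), 10
populations x 30 individuals, 2000 neutral + 20 adaptive loci at
differentiation F_ST = 0.1 and adaptive cline slope 2 (log-odds per climate
SD).  ENM experiments use a 40x40 landscape to keep single-CPU runtimes in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import adaptclass, connect, enm, gea, synthio
from .popgen import GenotypeMatrix
from .rasters import RasterStack

__all__ = [
    "StudySystem",
    "simulate_study",
    "gea_recovery",
    "classification_recovery",
    "headline_direction",
    "ibr_ranking",
    "mantel_type1_error",
]


@dataclass
class StudySystem:
    """A simulated landscape-genomics study with its generating truth."""

    stack: RasterStack
    sim: synthio.SimulatedGenotypes
    climate: gea.ClimatePredictors
    individual_cells: np.ndarray        # (n, 2) row/col per individual
    roost_cells: np.ndarray             # (n_populations, 2)

    @property
    def genotypes(self) -> GenotypeMatrix:
        return self.sim.genotypes


def simulate_study(
    seed: int,
    grid: int = 64,
    n_populations: int = 10,
    inds_per_population: int = 30,
    n_neutral_loci: int = 2000,
    n_adaptive_loci: int = 20,
    fst_target: float = 0.1,
    adaptive_slope: float = 2.0,
    jitter: int = 3,
    orthogonal_gradients: bool = False,
    roost_suitability: dict | None = None,
) -> StudySystem:
    """Simulate the default study system.

    Populations are cave-roost cells placed at random valid cells (or
    weighted by a ``roost_suitability`` surface, same parameter form as
    :func:`adaptscape.synthio.simulate_occurrences`); individuals scatter
    within ``jitter`` cells of their roost, so climate varies both among
    and within populations.  Climate predictors are the layer values at
    individual cells, standardized across individuals.  With
    ``orthogonal_gradients`` the two layers run east-west and north-south
    instead of being opposing gradients on one axis.
    """
    config = synthio.LandscapeConfig(
        grid_rows=grid, grid_cols=grid, autocorrelation_range=max(grid // 8, 2), seed=seed
    )
    if orthogonal_gradients:
        cfg2 = synthio.LandscapeConfig(
            grid_rows=grid, grid_cols=grid, autocorrelation_range=max(grid // 8, 2),
            gradient_direction=np.pi / 2.0, seed=seed + 1_000_000,
        )
        stack = RasterStack(
            {
                "clim1": synthio.generate_climate_rasters(config, n_layers=1)["clim1"],
                "clim2": synthio.generate_climate_rasters(cfg2, n_layers=1)["clim1"],
            }
        )
    else:
        stack = synthio.generate_climate_rasters(config, n_layers=2)
    rng = np.random.default_rng(seed + 10_000)
    rows, cols = np.nonzero(stack.valid_mask)
    if roost_suitability is None:
        roost_idx = rng.choice(rows.size, size=n_populations, replace=False)
    else:
        suit = synthio.simulate_occurrences(
            stack, roost_suitability, max(n_populations, 5), seed=seed + 10_001
        ).true_suitability
        w = suit.values[rows, cols]
        roost_idx = rng.choice(rows.size, size=n_populations, replace=False, p=w / w.sum())
    roosts = np.column_stack([rows[roost_idx], cols[roost_idx]])
    n = n_populations * inds_per_population
    cells = np.repeat(roosts, inds_per_population, axis=0)
    cells = cells + rng.integers(-jitter, jitter + 1, size=cells.shape)
    cells = np.clip(cells, 0, grid - 1)

    raw = stack.env_at_rowcol(cells[:, 0], cells[:, 1])
    climate = gea.standardize_predictors(raw, stack.names)

    model = synthio.PopulationModel(
        n_populations=n_populations,
        inds_per_population=inds_per_population,
        n_neutral_loci=n_neutral_loci,
        n_adaptive_loci=n_adaptive_loci,
        fst_target=fst_target,
        adaptive_slope=adaptive_slope,
        seed=seed + 20_000,
    )
    sim = synthio.simulate_genotypes(model, climate.values, variable_names=climate.names)
    return StudySystem(stack, sim, climate, cells, roosts)


# ---------------------------------------------------------------------------
# GEA recovery
# ---------------------------------------------------------------------------

def run_gea(
    study: StudySystem,
    sd_threshold: float = 3.0,
    q_threshold: float = 0.05,
    k_max: int = 12,
) -> dict:
    """Run both GEA methods and their intersection on a study system."""
    gm, X = study.genotypes, study.climate
    model = gea.fit_rda(gm, X)
    rda_set = gea.rda_outliers(model, X, gm, sd_threshold=sd_threshold)
    K = gea.select_K(gm, k_max=k_max)
    latent_res = gea.fit_latent_association(gm, X, K, q_threshold=q_threshold)
    latent_set = gea.latent_candidates(latent_res, gm, X)
    inter = gea.intersect_candidates(rda_set, latent_set)
    return {
        "rda": rda_set,
        "latent": latent_set,
        "intersection": inter,
        "K": K,
        "rda_model": model,
        "latent_result": latent_res,
    }


def _power_fdp(candidates: set[str], truth: set[str]) -> tuple[float, float]:
    tp = len(candidates & truth)
    power = tp / len(truth) if truth else float("nan")
    fdp = (len(candidates) - tp) / len(candidates) if candidates else 0.0
    return power, fdp


def gea_recovery(seed: int, **study_kwargs) -> dict:
    """One GEA recovery replicate: power and false-discovery proportion of
    each method and of their conservative intersection."""
    study = simulate_study(seed, **study_kwargs)
    res = run_gea(study)
    truth = study.sim.adaptive_locus_ids
    out = {}
    for name in ("rda", "latent", "intersection"):
        power, fdp = _power_fdp(res[name].locus_ids, truth)
        out[f"{name}_power"] = power
        out[f"{name}_fdp"] = fdp
    out["K"] = res["K"]
    return out


# ---------------------------------------------------------------------------
# Classification recovery
# ---------------------------------------------------------------------------

def classification_recovery(seed: int, t: float = 0.25, **study_kwargs) -> dict:
    """Score individuals on their true adaptive loci and compare with the
    true climate at their sampling cells."""
    study = simulate_study(seed, **study_kwargs)
    gm, X = study.genotypes, study.climate
    truth_ids = sorted(study.sim.adaptive_locus_ids)
    cand = gea.CandidateSet(
        pd.DataFrame(
            {
                "locus_id": truth_ids,
                "method": "truth",
                "variable": X.names[0],
                "direction": 1,
                "statistic": 0.0,
            }
        )
    )
    score = adaptclass.score_individuals(gm, cand, X, temperature_variable=X.names[0])
    temp = X.values[:, 0]
    r = float(np.corrcoef(score.scores, temp)[0, 1])
    assignment = adaptclass.classify_individuals(score, t=t)
    labels = assignment.individual["label"].to_numpy()
    hot_true = temp > 1.0
    cold_true = temp < -1.0
    n_extreme = int(hot_true.sum() + cold_true.sum())
    n_correct = int(
        (labels[hot_true] == adaptclass.HOT_DRY).sum()
        + (labels[cold_true] == adaptclass.COLD_WET).sum()
    )
    return {
        "score_climate_r": r,
        "extreme_accuracy": n_correct / n_extreme if n_extreme else float("nan"),
        "n_extreme": n_extreme,
    }


# ---------------------------------------------------------------------------
# Headline direction: union of adaptive ranges vs full-species model
# ---------------------------------------------------------------------------

def headline_direction(
    seed: int,
    grid: int = 40,
    n_full: int = 120,
    n_hot: int = 40,
    n_cold: int = 40,
    n_background: int = 800,
    warming_deltas: tuple[float, ...] = (1.0, 1.5, 2.0),
) -> dict:
    """One replicate of the range-loss comparison.

    Two adaptive groups with divergent unimodal true niches, offset along a
    temperature-like gradient (hot-dry optimum on the warm side, cold-wet on
    the cool side) and both restricted along an orthogonal
    precipitation-like gradient; the full-species occurrence set pools
    both.  Ensembles are fit per group and for the pooled set, projected
    onto three warming scenarios (pseudo-GCMs), and range change is
    computed over the whole grid; the union of the two adaptive binary
    ranges is compared with the full-model range."""
    # orthogonal gradients so the species niche is a band, not the whole grid
    cfg1 = synthio.LandscapeConfig(
        grid_rows=grid, grid_cols=grid, autocorrelation_range=max(grid // 8, 2),
        noise_sd=0.3, gradient_direction=0.0, seed=seed,
    )
    cfg2 = synthio.LandscapeConfig(
        grid_rows=grid, grid_cols=grid, autocorrelation_range=max(grid // 8, 2),
        noise_sd=0.3, gradient_direction=np.pi / 2.0, seed=seed + 1_000_000,
    )
    stack = RasterStack(
        {
            "clim1": synthio.generate_climate_rasters(cfg1, n_layers=1)["clim1"],
            "clim2": synthio.generate_climate_rasters(cfg2, n_layers=1)["clim1"],
        }
    )
    # overlapping Gaussian niches offset along the temperature axis (optima
    # +/-0.7 SD, width ~0.7 SD — substantial intergroup overlap, as real
    # hot/cold adaptive groups show) with a shared narrow band (width ~0.35
    # SD) along the orthogonal precipitation axis that defines the species
    # The hot-dry niche is warm-open: monotone tolerance to heat, with no
    # upper thermal limit inside the landscape (the group already occupies
    # the warmest cells).  The cold-wet niche is unimodal with a cool
    # optimum.  Both share a narrow precipitation band (width ~0.35 SD)
    # that defines the species.
    sharp_t, sharp_p, mu = 1.0, 4.0, 0.7
    hot_params = {"intercept": 0.5, "clim1": 1.5, "clim2^2": -sharp_p}
    cold_params = {
        "intercept": 1.5 - sharp_t * mu**2,
        "clim1": -2 * sharp_t * mu,
        "clim1^2": -sharp_t,
        "clim2^2": -sharp_p,
    }
    # The full-species record set is dominated by core (intermediate-
    # climate) occurrences, with the climatically adapted margins as
    # minorities — as in real occurrence datasets where only a fraction of
    # individuals carry extreme adaptive genotypes.
    core_params = {"intercept": 1.2, "clim1^2": -0.8, "clim2^2": -sharp_p}
    n_fh, n_fc = int(0.15 * n_full), int(0.25 * n_full)
    n_core = n_full - n_fh - n_fc
    hot = synthio.simulate_occurrences(stack, hot_params, n_hot, seed=seed + 1)
    cold = synthio.simulate_occurrences(stack, cold_params, n_cold, seed=seed + 2)
    full_parts = [
        synthio.simulate_occurrences(stack, hot_params, max(n_fh, 5), seed=seed + 3),
        synthio.simulate_occurrences(stack, cold_params, max(n_fc, 5), seed=seed + 4),
        synthio.simulate_occurrences(stack, core_params, max(n_core, 5), seed=seed + 5),
    ]
    occ_hot = enm.clean_occurrences(
        enm.OccurrenceSet(hot.coordinates, group="hot_dry"), stack
    )
    occ_cold = enm.clean_occurrences(
        enm.OccurrenceSet(cold.coordinates, group="cold_wet"), stack
    )
    occ_all = enm.clean_occurrences(
        enm.OccurrenceSet(
            np.vstack([p.coordinates for p in full_parts]), group="all"
        ),
        stack,
    )
    # warming acts mainly on the temperature axis; drying is mild so the
    # precipitation band is displaced, not pushed off the grid
    futures = [
        synthio.generate_future_rasters(stack, {"clim1": d, "clim2": -d / 4.0}, seed=seed + 50 + i)
        for i, d in enumerate(warming_deltas)
    ]
    mask = stack.template.copy_with(np.where(stack.valid_mask, 1.0, stack.template.nodata))

    # one shared background sample pairs the three models' evaluations
    all_cells = enm.OccurrenceSet(
        np.vstack([occ_all.coordinates, occ_hot.coordinates, occ_cold.coordinates]),
        rows=np.concatenate([occ_all.rows, occ_hot.rows, occ_cold.rows]),
        cols=np.concatenate([occ_all.cols, occ_hot.cols, occ_cold.cols]),
    )
    nb = min(n_background, int(stack.valid_mask.sum()) - len(np.unique(all_cells.rows * grid + all_cells.cols)))
    shared_bg = enm.sample_background(stack, nb, seed=seed + 99, exclusion=all_cells)

    reports = {}
    binaries_present: dict[str, object] = {}
    binaries_future: dict[str, object] = {}
    for name, occ in (("all", occ_all), ("hot_dry", occ_hot), ("cold_wet", occ_cold)):
        ens = enm.fit_ensemble_enm(
            stack, occ, seed=seed + 100, n_background=n_background, background=shared_bg
        )
        present_cont = ens.predict_raster(stack)
        present_bin = ens.binarize(present_cont)
        _, future_bin = enm.project(ens, futures)
        reports[name] = enm.range_change(present_bin, future_bin, mask)
        binaries_present[name] = present_bin
        binaries_future[name] = future_bin

    union_present = enm.combine_ranges(binaries_present["hot_dry"], binaries_present["cold_wet"])
    union_future = enm.combine_ranges(binaries_future["hot_dry"], binaries_future["cold_wet"])
    union_report = enm.range_change(union_present, union_future, mask)

    full_loss = -reports["all"].percent_change
    union_loss = -union_report.percent_change
    return {
        "full_change": reports["all"].percent_change,
        "hot_change": reports["hot_dry"].percent_change,
        "cold_change": reports["cold_wet"].percent_change,
        "union_change": union_report.percent_change,
        "union_loss_le_full_loss": bool(union_loss <= full_loss),
    }


# ---------------------------------------------------------------------------
# Isolation-by-resistance
# ---------------------------------------------------------------------------

def _landscape_surfaces(seed: int, grid: int = 30) -> dict[str, connect.ResistanceSurface]:
    """Three candidate resistance surfaces from two synthetic landscape
    layers (forest-like and slope-like): each single layer plus their mean."""
    config = synthio.LandscapeConfig(
        grid_rows=grid, grid_cols=grid, autocorrelation_range=max(grid // 6, 2),
        noise_sd=1.5, seed=seed,
    )
    stack = synthio.generate_climate_rasters(config, n_layers=2)
    table = [(-3.0, 100.0), (-1.5, 75.0), (0.0, 50.0), (1.5, 25.0), (3.0, 1.0)]
    forest = connect.reclassify_to_resistance(
        stack["clim1"], table, interpolate=True, provenance="forest"
    )
    slope = connect.reclassify_to_resistance(
        stack["clim2"], table, interpolate=True, provenance="slope"
    )
    combo = connect.combine_surfaces([forest, slope], method="mean", provenance="forest+slope")
    return {"forest": forest, "slope": slope, "forest+slope": combo}


def ibr_ranking(
    seed: int,
    grid: int = 30,
    n_focal: int = 12,
    beta: float = 1.0,
    noise_frac: float = 0.25,
    n_perm: int = 99,
) -> dict:
    """One replicate of resistance-surface model selection.

    Genetic distances are generated from the combined forest+slope surface
    with Gaussian noise at ``noise_frac`` of the resistance-distance spread;
    the experiment asks whether R^2 ranks the generating surface first among
    the three candidates."""
    surfaces = _landscape_surfaces(seed, grid=grid)
    rng = np.random.default_rng(seed + 5_000)
    template = surfaces["forest+slope"].raster
    valid_cells = np.argwhere(template.valid_mask)
    focal = valid_cells[rng.choice(valid_cells.shape[0], size=n_focal, replace=False)]

    distances = {}
    for name, surf in surfaces.items():
        graph = connect.build_graph(surf)
        nodes = [int(graph.node_of_cell[r, c]) for r, c in focal]
        distances[name] = connect.effective_resistance(graph, nodes).values

    true_R = distances["forest+slope"]
    off = true_R[np.triu_indices(n_focal, 1)]
    noise_sd = noise_frac * off.std()
    genetic = synthio.simulate_ibr_distances(true_R, beta=beta, noise_sd=noise_sd, seed=seed + 6_000)
    ranked = connect.rank_surfaces(genetic, distances, n_perm=n_perm, seed=seed + 7_000)
    return {
        "best_surface": ranked[0].surface,
        "correct_first": ranked[0].surface == "forest+slope",
        "r_squared": {r.surface: r.r_squared for r in ranked},
        "mantel_r_best": ranked[0].mantel_r,
        "mantel_p_best": ranked[0].mantel_p,
    }


def mantel_type1_error(
    n_trials: int = 200, n: int = 20, n_perm: int = 199, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical Mantel rejection rate under independence."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_trials):
        A = _random_distance_matrix(rng, n)
        B = _random_distance_matrix(rng, n)
        _, p = connect.mantel_test(A, B, n_perm=n_perm, seed=int(rng.integers(2**31)))
        if p <= alpha:
            rejections += 1
    return rejections / n_trials


def _random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    M = rng.normal(size=(n, n))
    M = np.abs(M + M.T)
    np.fill_diagonal(M, 0.0)
    return M
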