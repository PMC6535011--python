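"""Synthetic landscapes, genotypes, occurrences and genetic distances.

Every downstream stage of the pipeline (GEA, classification, niche models,
connectivity) is exercised on data from this module, which emulates the
statistical structure the analysis assumes:

* spatially autocorrelated climate layers with a directional gradient,
  standing in for bioclimatic grids;
* hierarchically structured neutral genotypes (Balding-Nichols island
  model, so the realized multilocus theta is analytically checkable)
  plus adaptive loci whose allele frequencies follow logistic clines
  along a climate gradient;
* occurrence records drawn from a known suitability surface;
* genetic distances generated under isolation-by-resistance.

All generators are bit-reproducible for a fixed seed, and every simulated
dataset carries its generating truth so recovery tests are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .popgen import GenotypeMatrix
from .rasters import GeometryError, Raster, RasterStack

__all__ = [
    "LandscapeConfig",
    "PopulationModel",
    "SimulatedGenotypes",
    "OccurrenceSample",
    "generate_climate_rasters",
    "generate_future_rasters",
    "simulate_genotypes",
    "simulate_occurrences",
    "simulate_ibr_distances",
]


@dataclass
class LandscapeConfig:
    """Geometry and texture of a synthetic climate landscape.

    ``gradient_direction`` is the compass-free angle (radians) of increase:
    0 points east (increasing column), pi/2 points north (decreasing row).
    ``autocorrelation_range`` is the Gaussian smoothing SD in cells;
    ``noise_sd`` scales the smoothed random field relative to the unit-range
    deterministic gradient before standardization.
    """

    grid_rows: int = 64
    grid_cols: int = 64
    cell_size: float = 1.0
    gradient_direction: float = 0.0
    autocorrelation_range: float = 8.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.autocorrelation_range <= 0:
            raise ValueError("autocorrelation_range must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass
class PopulationModel:
    """Demographic and selective parameters of the simulated species.

    Neutral differentiation follows a Balding-Nichols island model with
    target F_ST ``fst_target``; ``adaptive_slope`` is the log-odds change in
    allele frequency per SD of climate at the adaptive loci.
    """

    n_populations: int = 10
    inds_per_population: int = 30
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 20
    fst_target: float = 0.1
    adaptive_slope: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in (0, 1)")
        if self.n_adaptive_loci >= self.n_neutral_loci:
            raise ValueError("n_adaptive_loci must be < n_neutral_loci")


@dataclass
class SimulatedGenotypes:
    """Genotype matrix together with its generating truth."""

    genotypes: GenotypeMatrix
    truth: pd.DataFrame          # locus_id, is_adaptive, variable, slope, ancestral_freq
    model: PopulationModel

    @property
    def adaptive_locus_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["is_adaptive"], "locus_id"])


@dataclass
class OccurrenceSample:
    """Sampled presence points plus the true suitability surface."""

    coordinates: np.ndarray      # (n, 2) x/y of sampled cell centers
    rows: np.ndarray
    cols: np.ndarray
    true_suitability: Raster
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit variance."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_climate_rasters(config: LandscapeConfig, n_layers: int = 2) -> RasterStack:
    """Generate standardized climate layers: directional gradient + smooth noise.

    Each layer is a linear gradient along ``config.gradient_direction`` plus
    a Gaussian random field smoothed to ``autocorrelation_range`` and scaled
    by ``noise_sd``; the result is standardized to mean 0, SD 1 over the
    grid.  Alternate layers reverse the gradient so that two layers mimic a
    temperature/precipitation pair varying in opposition.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_rows, config.grid_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    # unit-range gradient along the requested direction
    gx = np.cos(config.gradient_direction)
    gy = np.sin(config.gradient_direction)
    raw = gx * cc / max(cols - 1, 1) - gy * rr / max(rows - 1, 1)
    span = raw.max() - raw.min()
    gradient = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)

    stack = RasterStack()
    for i in range(n_layers):
        sign = 1.0 if i % 2 == 0 else -1.0
        layer = sign * gradient
        if config.noise_sd > 0:
            layer = layer + config.noise_sd * _smooth_field(
                rng, (rows, cols), config.autocorrelation_range
            )
        layer = (layer - layer.mean()) / layer.std()
        stack.add(
            f"clim{i + 1}",
            Raster(layer, cellsize=config.cell_size),
        )
    return stack


def generate_future_rasters(
    present: RasterStack,
    delta_mean: dict[str, float] | float,
    delta_sd: float = 0.0,
    seed: int = 0,
) -> RasterStack:
    """Shift present-day layers to a pseudo-future scenario.

    ``future = present + delta_mean`` per layer, optionally plus a spatially
    smooth anomaly of scale ``delta_sd`` that is demeaned over valid cells
    (so the realized mean shift equals ``delta_mean`` exactly).  Distinct
    shift sets stand in for distinct general-circulation models.
    """
    if delta_sd < 0:
        raise ValueError("delta_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = RasterStack()
    for name in present.names:
        r = present[name]
        d = delta_mean[name] if isinstance(delta_mean, dict) else delta_mean
        values = r.values.copy()
        valid = r.valid_mask
        if np.ndim(d) == 2:
            d = np.asarray(d, dtype=float)
            if d.shape != r.shape:
                raise GeometryError(
                    f"spatially varying delta for layer {name!r} does not match grid"
                )
            shifted = values[valid] + d[valid]
        else:
            shifted = values[valid] + float(d)
        if delta_sd > 0:
            anomaly = _smooth_field(rng, r.shape, sigma=max(min(r.shape) / 8.0, 1.0))[valid]
            anomaly = anomaly - anomaly.mean()
            shifted = shifted + delta_sd * anomaly
        values[valid] = shifted
        out.add(name, r.copy_with(values))
    return out


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    model: PopulationModel, climate_at_samples: np.ndarray, variable_names: list[str] | None = None
) -> SimulatedGenotypes:
    """Simulate structured neutral loci plus climate-clinal adaptive loci.

    ``climate_at_samples`` is (n_individuals,) or (n_individuals,
    n_variables) of standardized climate values, one row per individual in
    population order.  Neutral loci follow the Balding-Nichols model:
    ancestral frequency p ~ U(0.05, 0.95); population frequency ~
    Beta with mean p and variance p(1-p)*fst_target; genotypes ~
    Binomial(2, population frequency).  Each adaptive locus is tied to one
    climate variable: the individual-level allele frequency is
    logistic(logit(p) + adaptive_slope * climate).
    """
    climate = np.atleast_2d(np.asarray(climate_at_samples, dtype=float))
    if climate.shape[0] == 1 and climate.shape[1] > 1 and np.ndim(climate_at_samples) == 1:
        climate = climate.T
    n = model.n_populations * model.inds_per_population
    if climate.shape[0] != n:
        raise ValueError(
            f"climate_at_samples has {climate.shape[0]} rows; model implies {n} individuals"
        )
    n_vars = climate.shape[1]
    if variable_names is None:
        variable_names = [f"clim{i + 1}" for i in range(n_vars)]

    rng = np.random.default_rng(model.seed)
    F = model.fst_target
    shape_factor = (1.0 - F) / F

    pop_labels = [f"pop{k + 1}" for k in range(model.n_populations) for _ in range(model.inds_per_population)]
    pop_index = np.repeat(np.arange(model.n_populations), model.inds_per_population)
    sample_ids = [f"ind{i + 1}" for i in range(n)]

    L_neutral, L_adapt = model.n_neutral_loci, model.n_adaptive_loci
    values = np.empty((n, L_neutral + L_adapt), dtype=np.int16)

    # neutral block
    p_anc = rng.uniform(0.05, 0.95, size=L_neutral)
    a = p_anc * shape_factor
    b = (1.0 - p_anc) * shape_factor
    pop_freq = rng.beta(a, b, size=(model.n_populations, L_neutral))
    values[:, :L_neutral] = rng.binomial(2, pop_freq[pop_index])

    # adaptive block: individual-level clines, independent of population
    p_adapt = rng.uniform(0.2, 0.8, size=L_adapt)
    which_var = rng.integers(0, n_vars, size=L_adapt)
    logit_p = special.logit(p_adapt)
    ind_freq = special.expit(
        logit_p[None, :] + model.adaptive_slope * climate[:, which_var]
    )
    values[:, L_neutral:] = rng.binomial(2, ind_freq)

    locus_ids = [f"neu{j + 1}" for j in range(L_neutral)] + [
        f"adp{j + 1}" for j in range(L_adapt)
    ]
    truth = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "is_adaptive": [False] * L_neutral + [True] * L_adapt,
            "variable": [""] * L_neutral + [variable_names[v] for v in which_var],
            "slope": [0.0] * L_neutral + [model.adaptive_slope] * L_adapt,
            "ancestral_freq": np.concatenate([p_anc, p_adapt]),
        }
    )
    gm = GenotypeMatrix(values, sample_ids, locus_ids, pop_labels)
    return SimulatedGenotypes(gm, truth, model)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def simulate_occurrences(
    stack: RasterStack,
    suitability_params: dict[str, float],
    n_points: int,
    seed: int = 0,
) -> OccurrenceSample:
    """Draw presence cells with probability proportional to a logistic
    suitability surface.

    ``suitability_params`` maps layer names to linear coefficients, with an
    optional ``"intercept"`` and optional quadratic terms keyed as
    ``"<layer>^2"`` (for unimodal niches); suitability = expit(intercept +
    sum(coef * feature)).  The true suitability raster is returned for
    validation.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    template = stack.template
    eta = np.full(template.shape, float(suitability_params.get("intercept", 0.0)))
    for name, coef in suitability_params.items():
        if name == "intercept":
            continue
        if name.endswith("^2"):
            eta = eta + coef * stack[name[:-2]].values ** 2
        else:
            eta = eta + coef * stack[name].values
    suit = special.expit(eta)
    valid = stack.valid_mask
    weights = np.where(valid, suit, 0.0).ravel()
    # treat an exact-zero suitability surface as an error
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability surface is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(weights.size, size=n_points, replace=True, p=weights / total)
    rows, cols = np.unravel_index(flat_idx, template.shape)
    x, y = template.rowcol_to_xy(rows, cols)
    suit_raster = template.copy_with(np.where(valid, suit, template.nodata))
    return OccurrenceSample(
        coordinates=np.column_stack([x, y]),
        rows=rows,
        cols=cols,
        true_suitability=suit_raster,
        params=dict(suitability_params),
    )


# ---------------------------------------------------------------------------
# Isolation-by-resistance distances
# ---------------------------------------------------------------------------

def simulate_ibr_distances(
    resistance_distances: np.ndarray, beta: float, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Linearized genetic distances under isolation-by-resistance.

    genetic = beta * resistance + symmetric Gaussian noise, clipped at 0;
    the output is symmetric with zero diagonal.
    """
    R = np.asarray(resistance_distances, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("resistance_distances must be square")
    if not np.allclose(R, R.T):
        raise ValueError("resistance_distances must be symmetric")
    if not np.allclose(np.diag(R), 0.0):
        raise ValueError("resistance_distances must have zero diagonal")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=R.shape) if noise_sd > 0 else np.zeros_like(R)
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    G = np.clip(beta * R + noise, 0.0, None)
    np.fill_diagonal(G, 0.0)
    return G
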