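"""Ensemble ecological niche models, projection, range change and overlap.

The ensemble combines three transparent presence/background algorithms —
a percentile climate envelope, a quadratic logistic regression, and an
L1-regularized "Maxent-like" exponential model with product features —
evaluated by cross-validation (rank AUC and the true skill statistic, TSS),
weighted by TSS, and binarized at the ensemble's TSS-maximizing threshold.
Projection to pseudo-future scenarios averages predictions across scenario
stacks before binarizing with the present-day threshold, mirroring the
practice of merging per-GCM model ensembles into a single layer.

Niche overlap uses Schoener's D on normalized suitability surfaces, with an
identity-test style permutation null that reassigns pooled occurrences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .rasters import GeometryError, Raster, RasterStack

__all__ = [
    "OccurrenceSet",
    "ModelEvaluation",
    "EnsembleMember",
    "EnsembleModel",
    "RangeChangeReport",
    "NicheOverlapReport",
    "clean_occurrences",
    "remove_correlated_variables",
    "sample_background",
    "fit_envelope",
    "fit_logistic",
    "fit_maxent_like",
    "rank_auc",
    "max_tss",
    "cross_validate",
    "build_ensemble",
    "fit_ensemble_enm",
    "null_model_test",
    "project",
    "range_change",
    "combine_ranges",
    "range_overlap",
    "schoener_d",
    "niche_similarity_test",
]


@dataclass
class OccurrenceSet:
    """Presence records, optionally snapped to raster cells.

    ``group`` tags the dataset ("all", "hot_dry", "cold_wet", ...).
    """

    coordinates: np.ndarray              # (n, 2) x/y
    group: str = "all"
    source: str = ""
    rows: np.ndarray | None = None
    cols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]


def clean_occurrences(occ: OccurrenceSet, stack: RasterStack) -> OccurrenceSet:
    """Snap occurrences to cell centers, drop points outside the grid or on
    nodata cells, and collapse duplicates within a cell."""
    template = stack.template
    x, y = occ.coordinates[:, 0], occ.coordinates[:, 1]
    inside = template.contains_xy(x, y)
    rows, cols = template.xy_to_rowcol(x[inside], y[inside])
    valid = stack.valid_mask[rows, cols]
    rows, cols = rows[valid], cols[valid]
    # dedupe per cell, preserving first-seen order
    _, keep = np.unique(rows * template.shape[1] + cols, return_index=True)
    keep.sort()
    rows, cols = rows[keep], cols[keep]
    cx, cy = template.rowcol_to_xy(rows, cols)
    return OccurrenceSet(
        np.column_stack([cx, cy]), group=occ.group, source=occ.source, rows=rows, cols=cols
    )


@dataclass
class ModelEvaluation:
    """Held-out evaluation of one cross-validation replicate."""

    algorithm: str
    replicate: int
    auc: float
    tss: float
    tss_threshold: float


@dataclass
class EnsembleMember:
    algorithm: str
    model: object
    tss: float
    weight: float = 0.0


@dataclass
class EnsembleModel:
    """TSS-weighted ensemble of suitability models with a binarization threshold."""

    members: list[EnsembleMember]
    tss_cutoff: float
    threshold: float
    evaluations: list[ModelEvaluation] = field(default_factory=list)

    def predict_env(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros(X.shape[0])
        for m in self.members:
            out += m.weight * m.model.predict_env(X)
        return out

    def predict_raster(self, stack: RasterStack) -> Raster:
        template = stack.template
        valid = stack.valid_mask
        rows, cols = np.nonzero(valid)
        X = stack.env_at_rowcol(rows, cols)
        suit = self.predict_env(X)
        values = np.full(template.shape, template.nodata)
        values[rows, cols] = suit
        return template.copy_with(values)

    def binarize(self, suitability: Raster) -> Raster:
        valid = suitability.valid_mask
        values = np.where(valid, (suitability.values >= self.threshold).astype(float), suitability.nodata)
        return suitability.copy_with(values)


@dataclass
class RangeChangeReport:
    percent_present: float
    percent_future: float
    percent_change: float


@dataclass
class NicheOverlapReport:
    d: float
    null_d: np.ndarray | None = None
    p_lower: float | None = None


# ---------------------------------------------------------------------------
# Predictor screening & background
# ---------------------------------------------------------------------------

def remove_correlated_variables(stack: RasterStack, r_threshold: float = 0.75) -> RasterStack:
    """Greedily drop layers until no pairwise |Pearson r| exceeds the threshold.

    While any pair exceeds ``r_threshold``, the member of the worst pair with
    the larger mean absolute correlation to all other remaining layers is
    dropped.  Deterministic (ties broken by layer order).
    """
    names = list(stack.names)
    valid = stack.valid_mask
    data = {n: stack[n].values[valid] for n in names}
    while len(names) > 1:
        k = len(names)
        corr = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                corr[i, j] = corr[j, i] = np.corrcoef(data[names[i]], data[names[j]])[0, 1]
        absc = np.abs(corr)
        np.fill_diagonal(absc, 0.0)
        i, j = np.unravel_index(np.argmax(absc), absc.shape)
        if absc[i, j] <= r_threshold:
            break
        mean_i = absc[i].sum() / (k - 1)
        mean_j = absc[j].sum() / (k - 1)
        drop = names[i] if mean_i >= mean_j else names[j]
        names.remove(drop)
    return stack.subset(names)


def sample_background(
    stack: RasterStack, n: int, seed: int, exclusion: OccurrenceSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random valid cells, excluding presence cells; returns rows, cols."""
    valid = stack.valid_mask.copy()
    if exclusion is not None:
        occ = exclusion if exclusion.rows is not None else clean_occurrences(exclusion, stack)
        valid[occ.rows, occ.cols] = False
    free = np.flatnonzero(valid.ravel())
    if n > free.size:
        raise ValueError(f"requested {n} background cells but only {free.size} are free")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(free, size=n, replace=False)
    return np.unravel_index(chosen, stack.template.shape)


# ---------------------------------------------------------------------------
# Member algorithms
# ---------------------------------------------------------------------------

class EnvelopeModel:
    """Percentile climate envelope: suitability is the fraction of variables
    whose value falls inside the presence [percentile, 1-percentile] range."""

    algorithm = "envelope"

    def __init__(self, lower: np.ndarray, upper: np.ndarray):
        self.lower = lower
        self.upper = upper

    def predict_env(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        inside = (X >= self.lower) & (X <= self.upper)
        return inside.mean(axis=1)


def fit_envelope(presence_env: np.ndarray, percentile: float = 0.05) -> EnvelopeModel:
    if not 0.0 <= percentile < 0.5:
        raise ValueError("percentile must be in [0, 0.5)")
    P = np.atleast_2d(presence_env)
    lower = np.quantile(P, percentile, axis=0)
    upper = np.quantile(P, 1.0 - percentile, axis=0)
    return EnvelopeModel(lower, upper)


def _poly_features(X: np.ndarray, interactions: bool) -> np.ndarray:
    """Linear + quadratic features, optionally with pairwise products."""
    X = np.atleast_2d(X)
    feats = [X, X**2]
    if interactions:
        p = X.shape[1]
        feats += [X[:, [i]] * X[:, [j]] for i in range(p) for j in range(i + 1, p)]
    return np.hstack(feats)


class LogisticModel:
    """Presence/background logistic regression; suitability = fitted probability.

    Predictors are clamped to the training range at prediction time (the
    Maxent "clamping" convention) so novel future climates do not
    extrapolate the polynomial surface.
    """

    algorithm = "logistic"

    def __init__(self, clf: LogisticRegression, interactions: bool, clamp: np.ndarray | None):
        self.clf = clf
        self.interactions = interactions
        self.clamp = clamp          # (2, p) training min/max, or None

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([self.clf.intercept_, self.clf.coef_.ravel()])

    def predict_env(self, X: np.ndarray) -> np.ndarray:
        X = _apply_clamp(np.atleast_2d(X), self.clamp)
        return self.clf.predict_proba(_poly_features(X, self.interactions))[:, 1]


def _apply_clamp(X: np.ndarray, clamp: np.ndarray | None) -> np.ndarray:
    if clamp is None:
        return X
    return np.clip(X, clamp[0], clamp[1])


def fit_logistic(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    interactions: bool = False,
    clamp: bool = True,
) -> LogisticModel:
    """Maximum-likelihood logistic fit on presence (1) vs background (0)."""
    P, B = np.atleast_2d(presence_env), np.atleast_2d(background_env)
    if P.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("need both presence and background points")
    Xall = np.vstack([P, B])
    X = _poly_features(Xall, interactions)
    y = np.concatenate([np.ones(P.shape[0]), np.zeros(B.shape[0])])
    clf = LogisticRegression(penalty=None, max_iter=2000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    bounds = np.vstack([Xall.min(axis=0), Xall.max(axis=0)]) if clamp else None
    return LogisticModel(clf, interactions, bounds)


class MaxentLikeModel:
    """L1-regularized exponential-family suitability model.

    Fits a penalized logistic discrimination of presences against
    background on linear, quadratic and pairwise-product features; the
    suitability score is exp(linear predictor) rescaled to [0, 1] by its
    maximum over the cells being predicted (raw normalization, no
    cumulative transform).
    """

    algorithm = "maxent_like"

    def __init__(self, intercept: float, coef: np.ndarray, clamp: np.ndarray | None = None):
        self.intercept = intercept
        self.coef = coef
        self.clamp = clamp

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coef])

    def predict_env(self, X: np.ndarray) -> np.ndarray:
        F = _poly_features(_apply_clamp(np.atleast_2d(X), self.clamp), interactions=True)
        eta = self.intercept + F @ self.coef
        return np.exp(eta - eta.max())


def fit_maxent_like(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    l1_penalty: float = 0.1,
    clamp: bool = True,
) -> MaxentLikeModel:
    P, B = np.atleast_2d(presence_env), np.atleast_2d(background_env)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 presence points")
    if l1_penalty < 0:
        raise ValueError("l1_penalty must be non-negative")
    Xall = np.vstack([P, B])
    X = _poly_features(Xall, interactions=True)
    y = np.concatenate([np.ones(P.shape[0]), np.zeros(B.shape[0])])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if l1_penalty == 0:
            clf = LogisticRegression(penalty=None, max_iter=2000, tol=1e-8)
        else:
            clf = LogisticRegression(
                penalty="l1", C=1.0 / l1_penalty, solver="liblinear", max_iter=2000, tol=1e-8
            )
        clf.fit(X, y)
    bounds = np.vstack([Xall.min(axis=0), Xall.max(axis=0)]) if clamp else None
    return MaxentLikeModel(float(clf.intercept_[0]), clf.coef_.ravel(), bounds)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney statistic / (n_pos * n_neg))."""
    pos, neg = np.asarray(pos_scores, float), np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need scores for both classes")
    all_scores = np.concatenate([pos, neg])
    order = all_scores.argsort(kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, all_scores.size + 1)
    # midranks for ties
    sorted_scores = all_scores[order]
    i = 0
    while i < sorted_scores.size:
        j = i
        while j + 1 < sorted_scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def max_tss(pos_scores: np.ndarray, neg_scores: np.ndarray, n_thresholds: int = 101) -> tuple[float, float]:
    """Maximize TSS = sensitivity + specificity - 1 over evenly spaced
    thresholds in [0, 1]; returns (TSS, threshold), lowest threshold on ties."""
    pos, neg = np.asarray(pos_scores, float), np.asarray(neg_scores, float)
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    k = int(np.argmax(tss))
    return float(tss[k]), float(thresholds[k])


FITTERS = {
    "envelope": lambda P, B: fit_envelope(P),
    "logistic": lambda P, B: fit_logistic(P, B),
    "maxent_like": lambda P, B: fit_maxent_like(P, B),
}


def cross_validate(
    fitter,
    presence_env: np.ndarray,
    background_env: np.ndarray,
    n_replicates: int | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
    algorithm: str = "",
) -> list[ModelEvaluation]:
    """Random split cross-validation: 70/30 presence (and background) splits.

    Replicates default to 10, or 5 when there are fewer than 50 presences.
    AUC is the rank statistic on held-out points; TSS is maximized over 101
    thresholds.
    """
    P = np.atleast_2d(presence_env)
    B = np.atleast_2d(background_env)
    n_pres = P.shape[0]
    if n_replicates is None:
        n_replicates = 5 if n_pres < 50 else 10
    rng = np.random.default_rng(seed)
    evals = []
    for rep in range(n_replicates):
        p_idx = rng.permutation(n_pres)
        b_idx = rng.permutation(B.shape[0])
        n_ptrain = max(int(round(train_fraction * n_pres)), 1)
        n_btrain = max(int(round(train_fraction * B.shape[0])), 1)
        if n_ptrain >= n_pres:
            n_ptrain = n_pres - 1
        if n_btrain >= B.shape[0]:
            n_btrain = B.shape[0] - 1
        model = fitter(P[p_idx[:n_ptrain]], B[b_idx[:n_btrain]])
        # presence and background scored in one call so score-normalizing
        # models (the Maxent-like member) share a common scale
        Ptest, Btest = P[p_idx[n_ptrain:]], B[b_idx[n_btrain:]]
        scores = model.predict_env(np.vstack([Ptest, Btest]))
        pos, neg = scores[: Ptest.shape[0]], scores[Ptest.shape[0] :]
        tss, thr = max_tss(pos, neg)
        evals.append(
            ModelEvaluation(
                algorithm=algorithm or getattr(model, "algorithm", "model"),
                replicate=rep,
                auc=rank_auc(pos, neg),
                tss=tss,
                tss_threshold=thr,
            )
        )
    return evals


def build_ensemble(
    members: list[tuple[object, float]],
    presence_env: np.ndarray,
    background_env: np.ndarray,
    tss_cutoff: float = 0.4,
    evaluations: list[ModelEvaluation] | None = None,
) -> EnsembleModel:
    """Assemble a TSS-weighted ensemble from (model, mean TSS) pairs.

    Members with TSS below the cutoff are excluded; weights are proportional
    to TSS over the included members.  The binarization threshold is the
    TSS-maximizing threshold of the ensemble's predictions on the pooled
    presence/background evaluation data.
    """
    included = [
        EnsembleMember(getattr(m, "algorithm", "model"), m, t) for m, t in members if t >= tss_cutoff
    ]
    if not included:
        best = max((t for _, t in members), default=float("nan"))
        raise ValueError(f"no ensemble member reached TSS cutoff {tss_cutoff}; best TSS = {best:.3f}")
    total = sum(m.tss for m in included)
    if total <= 0:
        for m in included:
            m.weight = 1.0 / len(included)
    else:
        for m in included:
            m.weight = m.tss / total
    ens = EnsembleModel(included, tss_cutoff, threshold=0.5, evaluations=evaluations or [])
    P, B = np.atleast_2d(presence_env), np.atleast_2d(background_env)
    scores = ens.predict_env(np.vstack([P, B]))
    pos, neg = scores[: P.shape[0]], scores[P.shape[0] :]
    _, thr = max_tss(pos, neg)
    ens.threshold = thr
    return ens


def fit_ensemble_enm(
    stack: RasterStack,
    occurrences: OccurrenceSet,
    seed: int = 0,
    n_background: int = 10_000,
    tss_cutoff: float = 0.4,
    algorithms: tuple[str, ...] = ("envelope", "logistic", "maxent_like"),
    background: tuple[np.ndarray, np.ndarray] | None = None,
) -> EnsembleModel:
    """End-to-end ensemble fit: clean occurrences, sample background,
    cross-validate each algorithm, refit on all data, and assemble.

    ``background`` (rows, cols) lets several models share one background
    sample, which pairs their evaluations."""
    occ = occurrences if occurrences.rows is not None else clean_occurrences(occurrences, stack)
    if occ.n < 5:
        raise ValueError("need at least 5 presence cells after cleaning")
    P = stack.env_at_rowcol(occ.rows, occ.cols)
    if background is None:
        free = int(stack.valid_mask.sum()) - occ.n
        nb = min(n_background, free)
        background = sample_background(stack, nb, seed=seed, exclusion=occ)
    brows, bcols = background
    B = stack.env_at_rowcol(brows, bcols)
    members: list[tuple[object, float]] = []
    all_evals: list[ModelEvaluation] = []
    for i, name in enumerate(algorithms):
        fitter = FITTERS[name]
        evals = cross_validate(fitter, P, B, seed=seed + 1000 + i, algorithm=name)
        all_evals.extend(evals)
        model = fitter(P, B)
        members.append((model, float(np.mean([e.tss for e in evals]))))
    return build_ensemble(members, P, B, tss_cutoff=tss_cutoff, evaluations=all_evals)


def null_model_test(
    stack: RasterStack,
    observed_auc: float,
    n_presences: int,
    n_null: int = 99,
    seed: int = 0,
    fitter=None,
    n_background: int = 1000,
) -> dict:
    """Compare an observed AUC against models fit to random presence sets.

    Each null replicate draws ``n_presences`` random valid cells, runs the
    same cross-validation pipeline, and records the mean held-out AUC.  The
    observed model beats random when its AUC exceeds the null maximum
    (rank-test p = 1/(n_null + 1))."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if fitter is None:
        fitter = FITTERS["logistic"]
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_null)
    for i in range(n_null):
        rrows, rcols = sample_background(stack, n_presences, seed=int(rng.integers(2**31)))
        occ_null = OccurrenceSet(
            np.column_stack(stack.template.rowcol_to_xy(rrows, rcols)), rows=rrows, cols=rcols
        )
        P = stack.env_at_rowcol(rrows, rcols)
        nb = min(n_background, int(stack.valid_mask.sum()) - n_presences)
        brows, bcols = sample_background(stack, nb, seed=int(rng.integers(2**31)), exclusion=occ_null)
        B = stack.env_at_rowcol(brows, bcols)
        evals = cross_validate(fitter, P, B, seed=int(rng.integers(2**31)))
        null_aucs[i] = np.mean([e.auc for e in evals])
    significant = observed_auc > null_aucs.max()
    return {
        "null_aucs": null_aucs,
        "null_range": (float(null_aucs.min()), float(null_aucs.max())),
        "observed_auc": float(observed_auc),
        "significant": bool(significant),
        "p_value": 1.0 / (n_null + 1) if significant else float((null_aucs >= observed_auc).sum() + 1) / (n_null + 1),
    }


# ---------------------------------------------------------------------------
# Projection and range arithmetic
# ---------------------------------------------------------------------------

def project(ensemble: EnsembleModel, future_stacks: list[RasterStack]) -> tuple[Raster, Raster]:
    """Project an ensemble onto pseudo-GCM future stacks.

    Predicts on each stack, averages per cell (unweighted), then binarizes
    with the present-day ensemble threshold.  Returns (continuous, binary).
    """
    if not future_stacks:
        raise ValueError("need at least one future stack")
    first = future_stacks[0]
    for s in future_stacks[1:]:
        if not first.same_geometry(s):
            raise GeometryError("future stacks are not co-registered")
    preds = [ensemble.predict_raster(s) for s in future_stacks]
    template = preds[0]
    valid = np.ones(template.shape, dtype=bool)
    for p in preds:
        valid &= p.valid_mask
    mean_vals = np.mean([p.values for p in preds], axis=0)
    continuous = template.copy_with(np.where(valid, mean_vals, template.nodata))
    return continuous, ensemble.binarize(continuous)


def _binary_cells(binary: Raster, mask: Raster) -> tuple[int, int]:
    if not binary.same_geometry(mask):
        raise GeometryError("binary raster and mask are not co-registered")
    m = mask.valid_mask & (mask.values > 0)
    n_mask = int(m.sum())
    if n_mask == 0:
        raise ValueError("mask is empty")
    suitable = int(((binary.values > 0) & binary.valid_mask & m).sum())
    return suitable, n_mask


def range_change(present_binary: Raster, future_binary: Raster, mask: Raster) -> RangeChangeReport:
    """Percent of the mask suitable now and in the future, and percent change."""
    pres, n_mask = _binary_cells(present_binary, mask)
    fut, _ = _binary_cells(future_binary, mask)
    pct_present = 100.0 * pres / n_mask
    pct_future = 100.0 * fut / n_mask
    if pres == 0:
        change = float("nan") if fut == 0 else float("inf")
    else:
        change = 100.0 * (pct_future - pct_present) / pct_present
    return RangeChangeReport(pct_present, pct_future, change)


def combine_ranges(binary_a: Raster, binary_b: Raster) -> Raster:
    """Cellwise OR of two binary ranges (the combined adaptive range)."""
    if not binary_a.same_geometry(binary_b):
        raise GeometryError("ranges are not co-registered")
    valid = binary_a.valid_mask & binary_b.valid_mask
    union = ((binary_a.values > 0) | (binary_b.values > 0)).astype(float)
    return binary_a.copy_with(np.where(valid, union, binary_a.nodata))


def range_overlap(binary_a: Raster, binary_b: Raster, mask: Raster) -> float:
    """Percent of the mask where both ranges are suitable."""
    if not binary_a.same_geometry(binary_b):
        raise GeometryError("ranges are not co-registered")
    m = mask.valid_mask & (mask.values > 0)
    n_mask = int(m.sum())
    if n_mask == 0:
        raise ValueError("mask is empty")
    both = (binary_a.values > 0) & (binary_b.values > 0) & binary_a.valid_mask & binary_b.valid_mask & m
    return float(100.0 * both.sum() / n_mask)


# ---------------------------------------------------------------------------
# Niche overlap
# ---------------------------------------------------------------------------

def schoener_d(suit_a: Raster, suit_b: Raster) -> NicheOverlapReport:
    """Schoener's D between two suitability surfaces on their common support.

    Each surface is normalized to sum 1 over the shared valid cells;
    D = 1 - 0.5 * sum |p_a - p_b|, so identical surfaces give 1 and
    disjoint supports give 0.  Invariant to positive rescaling.
    """
    if not suit_a.same_geometry(suit_b):
        raise GeometryError("suitability rasters are not co-registered")
    valid = suit_a.valid_mask & suit_b.valid_mask
    a = np.clip(suit_a.values[valid], 0.0, None)
    b = np.clip(suit_b.values[valid], 0.0, None)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("suitability surfaces must have positive mass")
    pa = a / a.sum()
    pb = b / b.sum()
    d = 1.0 - 0.5 * np.abs(pa - pb).sum()
    return NicheOverlapReport(d=float(d))


def niche_similarity_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    stack: RasterStack,
    n_perm: int = 99,
    seed: int = 0,
    fitter=None,
    n_background: int = 1000,
) -> NicheOverlapReport:
    """Identity-test permutation null for Schoener's D.

    Pools the two occurrence sets, reassigns labels at random preserving
    sizes, refits both suitability models, and recomputes D.  The one-sided
    p-value asks whether the observed overlap is lower than random:
    p = (1 + #{D_null <= D_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if fitter is None:
        fitter = FITTERS["logistic"]
    a = occ_a if occ_a.rows is not None else clean_occurrences(occ_a, stack)
    b = occ_b if occ_b.rows is not None else clean_occurrences(occ_b, stack)
    rng = np.random.default_rng(seed)
    nb = min(n_background, int(stack.valid_mask.sum()) - a.n - b.n)
    brows, bcols = sample_background(
        stack,
        nb,
        seed=int(rng.integers(2**31)),
        exclusion=OccurrenceSet(
            np.vstack([a.coordinates, b.coordinates]),
            rows=np.concatenate([a.rows, b.rows]),
            cols=np.concatenate([a.cols, b.cols]),
        ),
    )
    B = stack.env_at_rowcol(brows, bcols)

    def surface_d(rows_a, cols_a, rows_b, cols_b) -> float:
        Pa = stack.env_at_rowcol(rows_a, cols_a)
        Pb = stack.env_at_rowcol(rows_b, cols_b)
        model_a = fitter(Pa, B)
        model_b = fitter(Pb, B)
        ra = _predict_raster(model_a, stack)
        rb = _predict_raster(model_b, stack)
        return schoener_d(ra, rb).d

    d_obs = surface_d(a.rows, a.cols, b.rows, b.cols)
    pool_rows = np.concatenate([a.rows, b.rows])
    pool_cols = np.concatenate([a.cols, b.cols])
    n_a = a.n
    null_d = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pool_rows.size)
        ia, ib = perm[:n_a], perm[n_a:]
        null_d[i] = surface_d(pool_rows[ia], pool_cols[ia], pool_rows[ib], pool_cols[ib])
    p_lower = (1.0 + (null_d <= d_obs).sum()) / (n_perm + 1.0)
    return NicheOverlapReport(d=float(d_obs), null_d=null_d, p_lower=float(p_lower))


def _predict_raster(model, stack: RasterStack) -> Raster:
    template = stack.template
    valid = stack.valid_mask
    rows, cols = np.nonzero(valid)
    values = np.full(template.shape, template.nodata)
    values[rows, cols] = model.predict_env(stack.env_at_rowcol(rows, cols))
    return template.copy_with(values)
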