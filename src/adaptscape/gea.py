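"""Genotype-environment association: RDA outliers and latent-factor tests.

Two complementary methods detect loci whose allele frequencies track climate
gradients:

* **Redundancy analysis (RDA)** — a constrained ordination: the centered
  genotype matrix is regressed on the climate predictors and the fitted
  values are decomposed by SVD.  Loci with extreme loadings on the
  constrained axes (beyond ``sd_threshold`` standard deviations) are flagged.
* **Latent-factor association** — a per-locus regression of genotype on each
  climate variable, adjusting for unobserved population structure through K
  principal-component latent factors, with genomic-control calibration of
  the test statistics and Benjamini-Hochberg FDR control.

Only loci flagged by *both* methods (for either climate variable) enter the
conservative candidate set used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import GenotypeMatrix

__all__ = [
    "ClimatePredictors",
    "RDAModel",
    "LatentAssociationResult",
    "CandidateSet",
    "standardize_predictors",
    "fit_rda",
    "rda_outliers",
    "fit_latent_association",
    "select_K",
    "intersect_candidates",
    "bh_qvalues",
]


@dataclass
class ClimatePredictors:
    """Per-individual standardized climate values (one column per variable)."""

    values: np.ndarray          # (n_individuals, n_variables)
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.names) == 1 and self.values.shape[1] > 1:
            self.values = self.values.T
        if self.values.shape[1] != len(self.names):
            raise ValueError("predictor names do not match columns")
        if np.isnan(self.values).any():
            raise ValueError("climate predictors contain missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def standardize_predictors(values: np.ndarray, names: list[str]) -> ClimatePredictors:
    """Standardize each climate variable to mean 0, SD 1 within the dataset."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[0] == 1 and len(names) == 1:
        v = v.T
    sd = v.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant climate variable cannot be standardized")
    return ClimatePredictors((v - v.mean(axis=0)) / sd, list(names))


@dataclass
class RDAModel:
    """Fitted constrained ordination of genotypes on climate."""

    n_axes: int
    loadings: np.ndarray          # (n_loci, n_axes) SNP loadings
    site_scores: np.ndarray       # (n, n_axes) projections of Y onto axes
    fitted_site_scores: np.ndarray  # (n, n_axes) projections of Y-hat
    biplot_scores: np.ndarray     # (p, n_axes) predictor-axis correlations
    eigenvalues: np.ndarray
    constrained_fraction: float   # share of total genotype variance explained
    predictor_names: list[str]
    locus_ids: list[str]


@dataclass
class LatentAssociationResult:
    """Per-locus association statistics for each climate variable."""

    table: pd.DataFrame           # locus, variable, beta, z, p_raw, p_cal, q
    K: int
    lambda_gc: dict[str, float]   # genomic inflation factor per variable
    q_threshold: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] < self.q_threshold]


@dataclass
class CandidateSet:
    """Climate-adaptive candidate loci with per-method evidence."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["locus_id", "method", "variable", "direction", "statistic"]
        )
    )

    @property
    def locus_ids(self) -> set[str]:
        return set(self.table["locus_id"])

    def __len__(self) -> int:
        return len(self.locus_ids)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def fit_rda(gm: GenotypeMatrix, X: ClimatePredictors, scale_genotypes: bool = False) -> RDAModel:
    """Constrained ordination of the genotype matrix on climate predictors.

    The genotype matrix is centered (optionally scaled), projected onto the
    column space of X, and the fitted matrix is decomposed by SVD.  SNP
    loadings are the right singular vectors scaled by singular values over
    sqrt(n - 1); site scores are projections of Y (and of the fitted matrix)
    onto the axes; biplot scores are correlations between each predictor and
    the fitted site scores.
    """
    if gm.missing_mask.any():
        raise ValueError("RDA requires a complete (imputed) genotype matrix")
    n = gm.n_individuals
    if n <= X.p:
        raise ValueError("need more individuals than predictors")
    Xc = X.values - X.values.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.p:
        corr = np.corrcoef(Xc, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors: {X.names[i]!r} and {X.names[j]!r} "
            f"(|r| = {abs(corr[i, j]):.3f})"
        )

    Y = gm.values.astype(float)
    Y = Y - Y.mean(axis=0)
    if scale_genotypes:
        sd = Y.std(axis=0, ddof=0)
        Y = Y / np.where(sd > 0, sd, 1.0)

    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    Yhat = Xc @ beta

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(X.p, int((s > 1e-10 * max(s[0], 1.0)).sum()))
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]

    loadings = (Vt.T * s) / np.sqrt(n - 1)
    site_scores = Y @ Vt.T
    fitted_scores = Yhat @ Vt.T          # = U * s
    eigenvalues = s**2 / (n - 1)

    total = float((Y**2).sum())
    constrained = float((Yhat**2).sum())
    frac = constrained / total if total > 0 else 0.0

    biplot = np.zeros((X.p, n_axes))
    for k in range(n_axes):
        fs = fitted_scores[:, k]
        if fs.std() > 0:
            for j in range(X.p):
                biplot[j, k] = np.corrcoef(Xc[:, j], fs)[0, 1]
    return RDAModel(
        n_axes=n_axes,
        loadings=loadings,
        site_scores=site_scores,
        fitted_site_scores=fitted_scores,
        biplot_scores=biplot,
        eigenvalues=eigenvalues,
        constrained_fraction=frac,
        predictor_names=list(X.names),
        locus_ids=list(gm.locus_ids),
    )


def _assign_variable(
    gm: GenotypeMatrix, X: ClimatePredictors, locus_idx: np.ndarray
) -> tuple[list[str], list[int], list[float]]:
    """Assign each candidate locus to the climate variable with the largest
    absolute genotype correlation; direction is the sign of that correlation."""
    Y = gm.values.astype(float)
    Yc = Y - Y.mean(axis=0)
    Xc = X.values - X.values.mean(axis=0)
    ys = Yc.std(axis=0)
    xs = Xc.std(axis=0)
    corr = (Yc.T @ Xc) / (gm.n_individuals * np.outer(np.where(ys > 0, ys, np.inf), xs))
    variables, directions, stats_ = [], [], []
    for j in locus_idx:
        k = int(np.argmax(np.abs(corr[j])))
        variables.append(X.names[k])
        directions.append(int(np.sign(corr[j, k])) or 1)
        stats_.append(float(corr[j, k]))
    return variables, directions, stats_


def rda_outliers(
    model: RDAModel,
    X: ClimatePredictors,
    gm: GenotypeMatrix,
    n_axes: int | None = None,
    sd_threshold: float = 3.0,
) -> CandidateSet:
    """Flag loci with extreme RDA loadings on the retained constrained axes.

    A locus is a candidate when its loading deviates from the mean loading
    by more than ``sd_threshold`` standard deviations on any retained axis.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    if n_axes is None:
        n_axes = model.n_axes
    if n_axes > model.n_axes:
        raise ValueError(f"n_axes={n_axes} exceeds constrained axes ({model.n_axes})")
    flagged = np.zeros(len(model.locus_ids), dtype=bool)
    for k in range(n_axes):
        lo = model.loadings[:, k]
        flagged |= np.abs(lo - lo.mean()) > sd_threshold * lo.std(ddof=0)
    idx = np.flatnonzero(flagged)
    variables, directions, stats_ = _assign_variable(gm, X, idx)
    table = pd.DataFrame(
        {
            "locus_id": [model.locus_ids[i] for i in idx],
            "method": "rda",
            "variable": variables,
            "direction": directions,
            "statistic": stats_,
        }
    )
    return CandidateSet(table)


# ---------------------------------------------------------------------------
# Latent-factor association
# ---------------------------------------------------------------------------

def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up adjustment)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def select_K(gm: GenotypeMatrix, k_max: int = 10, ratio_threshold: float = 2.0) -> int:
    """Choose the number of latent factors from the PCA eigenvalue scree.

    K is placed at the largest consecutive eigenvalue drop (ratio of
    successive eigenvalues), provided the drop exceeds ``ratio_threshold``;
    an unstructured matrix (no dominant drop) yields K = 0.  Deterministic.
    """
    if gm.missing_mask.any():
        raise ValueError("select_K requires a complete matrix")
    Y = gm.values.astype(float)
    Y = Y - Y.mean(axis=0)
    s = np.linalg.svd(Y, compute_uv=False)
    ev = s**2
    upper = min(k_max, ev.size - 1)
    if upper < 1:
        return 0
    ratios = ev[:upper] / np.maximum(ev[1 : upper + 1], 1e-300)
    best = int(np.argmax(ratios))
    return best + 1 if ratios[best] > ratio_threshold else 0


def fit_latent_association(
    gm: GenotypeMatrix,
    X: ClimatePredictors,
    K: int,
    q_threshold: float = 0.05,
) -> LatentAssociationResult:
    """Per-locus climate association adjusted for K latent factors.

    Latent factors are the first K principal components of the centered
    genotype matrix after regressing out the climate predictors.  Each locus
    is then fit by least squares on [intercept, climate, factors]; z-scores
    are calibrated by the genomic inflation factor lambda =
    median(z^2)/0.4549 and converted to chi-square p-values, with
    Benjamini-Hochberg q-values per climate variable.
    """
    if gm.missing_mask.any():
        raise ValueError("latent association requires a complete matrix")
    n, L = gm.values.shape
    p = X.p
    if not 0 <= K < n - p - 2:
        raise ValueError(f"K={K} out of range for n={n}, p={p}")

    Y = gm.values.astype(float)
    Y = Y - Y.mean(axis=0)
    Xc = X.values - X.values.mean(axis=0)

    if K > 0:
        beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        resid = Y - Xc @ beta
        U, s, _ = np.linalg.svd(resid, full_matrices=False)
        factors = U[:, :K] * s[:K]
    else:
        factors = np.empty((n, 0))

    D = np.column_stack([np.ones(n), Xc, factors])
    q_dim = D.shape[1]
    DtD_inv = np.linalg.pinv(D.T @ D)
    coef = DtD_inv @ D.T @ Y                       # (q_dim, L)
    resid = Y - D @ coef
    dof = n - q_dim
    sigma2 = (resid**2).sum(axis=0) / dof
    zero_var = Y.std(axis=0) == 0

    rows = []
    lambda_gc: dict[str, float] = {}
    for j, name in enumerate(X.names):
        var_beta = DtD_inv[1 + j, 1 + j] * sigma2
        with np.errstate(invalid="ignore", divide="ignore"):
            z = coef[1 + j] / np.sqrt(var_beta)
        z = np.where(zero_var | ~np.isfinite(z), 0.0, z)
        z2 = z**2
        lam = float(np.median(z2[~zero_var]) / 0.4549) if (~zero_var).any() else 1.0
        lam = max(lam, 1e-12)
        p_raw = stats.chi2.sf(z2, df=1)
        p_cal = stats.chi2.sf(z2 / lam, df=1)
        p_cal = np.where(zero_var, 1.0, p_cal)
        q = bh_qvalues(p_cal)
        lambda_gc[name] = lam
        rows.append(
            pd.DataFrame(
                {
                    "locus_id": gm.locus_ids,
                    "variable": name,
                    "beta": coef[1 + j],
                    "z": z,
                    "p_raw": p_raw,
                    "p": p_cal,
                    "q": q,
                    "zero_variance": zero_var,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return LatentAssociationResult(table, K, lambda_gc, q_threshold)


def latent_candidates(
    result: LatentAssociationResult, gm: GenotypeMatrix, X: ClimatePredictors
) -> CandidateSet:
    """Candidate set from the latent-factor test: loci significant for either
    climate variable, assigned by largest absolute genotype correlation."""
    sig = result.significant()
    locus_ids = sorted(set(sig["locus_id"]))
    pos = {l: i for i, l in enumerate(gm.locus_ids)}
    idx = np.array([pos[l] for l in locus_ids], dtype=int)
    variables, directions, stats_ = _assign_variable(gm, X, idx)
    table = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "method": "latent",
            "variable": variables,
            "direction": directions,
            "statistic": stats_,
        }
    )
    return CandidateSet(table)


def intersect_candidates(rda_set: CandidateSet, latent_set: CandidateSet) -> CandidateSet:
    """Conservative intersection: loci flagged by both methods (union over
    climate variables within each method first).  Method evidence is merged."""
    common = rda_set.locus_ids & latent_set.locus_ids
    if not common:
        return CandidateSet()
    a = rda_set.table[rda_set.table["locus_id"].isin(common)]
    b = latent_set.table[latent_set.table["locus_id"].isin(common)]
    merged = (
        pd.concat([a, b], ignore_index=True)
        .sort_values(["locus_id", "method"], kind="stable")
        .reset_index(drop=True)
    )
    merged["method"] = "rda+latent"
    merged = merged.drop_duplicates(subset=["locus_id", "variable", "direction"]).reset_index(
        drop=True
    )
    return CandidateSet(merged)
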