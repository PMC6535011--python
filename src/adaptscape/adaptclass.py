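"""Classify individuals and populations into climatic-adaptation groups.

Individuals are scored along the climate-adaptation axis of a constrained
ordination refit on the candidate (climate-adaptive) loci only.  The axis is
the constrained axis most correlated with the temperature predictor and is
oriented so positive scores mean hot-dry-adapted.  Individuals beyond a
threshold (in SD units of the scores) are labelled ``hot_dry`` or
``cold_wet``; the rest are ``intermediate``.  Populations are labelled by
the majority group among their non-intermediate members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gea import CandidateSet, ClimatePredictors, fit_rda
from .popgen import GenotypeMatrix

__all__ = [
    "AdaptiveScore",
    "GroupAssignment",
    "score_individuals",
    "classify_individuals",
    "classify_populations",
]

HOT_DRY = "hot_dry"
COLD_WET = "cold_wet"
INTERMEDIATE = "intermediate"
MIXED = "mixed"


@dataclass
class AdaptiveScore:
    """Per-individual coordinate along the climate-adaptation axis.

    Positive scores are hot-dry-adapted: the axis is oriented so the
    temperature predictor's biplot vector points positive.
    """

    scores: np.ndarray
    sample_ids: list[str]
    populations: list[str] | None
    axis_index: int
    temperature_variable: str
    temperature_biplot_score: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.sample_ids,
                "score": self.scores,
                "population": self.populations
                if self.populations is not None
                else [""] * len(self.sample_ids),
            }
        )


@dataclass
class GroupAssignment:
    """Individual and (optionally) population adaptation labels."""

    individual: pd.DataFrame                  # id, score, label, population
    population: pd.DataFrame | None = None    # population, n, proportions, label

    def individual_proportions(self) -> dict[str, float]:
        counts = self.individual["label"].value_counts()
        n = len(self.individual)
        return {g: float(counts.get(g, 0)) / n for g in (HOT_DRY, COLD_WET, INTERMEDIATE)}


def score_individuals(
    gm: GenotypeMatrix,
    candidates: CandidateSet,
    X: ClimatePredictors,
    temperature_variable: str | None = None,
) -> AdaptiveScore:
    """Score individuals on the adaptive-genotype ordination axis.

    Refits the constrained ordination on the candidate loci only, picks the
    constrained axis with the largest absolute temperature biplot score, and
    orients it so the temperature vector points positive (hot-dry).
    """
    locus_ids = sorted(candidates.locus_ids)
    if len(locus_ids) < 2:
        raise ValueError(
            "need at least 2 candidate loci to score individuals; "
            "relax the outlier/FDR thresholds to enlarge the candidate set"
        )
    present = set(gm.locus_ids)
    missing = [l for l in locus_ids if l not in present]
    if missing:
        raise ValueError(f"candidate loci not in genotype matrix: {missing[:5]}")
    if temperature_variable is None:
        temperature_variable = X.names[0]
    t_idx = X.names.index(temperature_variable)

    sub = gm.subset_loci(locus_ids)
    model = fit_rda(sub, X)
    axis = int(np.argmax(np.abs(model.biplot_scores[t_idx, :])))
    sign = 1.0 if model.biplot_scores[t_idx, axis] >= 0 else -1.0
    scores = sign * model.site_scores[:, axis]
    return AdaptiveScore(
        scores=scores,
        sample_ids=list(gm.sample_ids),
        populations=list(gm.populations) if gm.populations is not None else None,
        axis_index=axis,
        temperature_variable=temperature_variable,
        temperature_biplot_score=abs(model.biplot_scores[t_idx, axis]),
    )


def classify_individuals(scores: AdaptiveScore, t: float = 0.25) -> GroupAssignment:
    """Label individuals hot_dry / cold_wet / intermediate.

    hot_dry if score > +t*SD(scores), cold_wet if score < -t*SD(scores),
    else intermediate.  ``t = 0`` yields a pure sign split (no
    intermediates, zeros counted hot_dry).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    s = scores.scores
    sd = s.std(ddof=0)
    cut = t * sd
    if t == 0:
        labels = np.where(s >= 0, HOT_DRY, COLD_WET)
    else:
        labels = np.full(s.shape, INTERMEDIATE, dtype=object)
        labels[s > cut] = HOT_DRY
        labels[s < -cut] = COLD_WET
    table = pd.DataFrame(
        {
            "id": scores.sample_ids,
            "score": s,
            "label": labels,
            "population": scores.populations
            if scores.populations is not None
            else [""] * len(s),
        }
    )
    return GroupAssignment(individual=table)


def classify_populations(
    assignment: GroupAssignment, majority: float = 0.6, min_individuals: int = 3
) -> GroupAssignment:
    """Label populations by majority among their non-intermediate members.

    A population is hot_dry (cold_wet) when that group's share of
    non-intermediate individuals is at least ``majority``; otherwise it is
    mixed.  Populations with fewer than ``min_individuals`` members are
    flagged low-confidence.
    """
    if not 0.5 < majority <= 1.0:
        raise ValueError("majority must be in (0.5, 1]")
    ind = assignment.individual
    if (ind["population"] == "").all():
        raise ValueError("population labels required for population classification")
    rows = []
    for pop, grp in ind.groupby("population", sort=True):
        n = len(grp)
        n_hot = int((grp["label"] == HOT_DRY).sum())
        n_cold = int((grp["label"] == COLD_WET).sum())
        n_int = int((grp["label"] == INTERMEDIATE).sum())
        informative = n_hot + n_cold
        if informative == 0:
            label = MIXED
        elif n_hot / informative >= majority:
            label = HOT_DRY
        elif n_cold / informative >= majority:
            label = COLD_WET
        else:
            label = MIXED
        rows.append(
            {
                "population": pop,
                "n": n,
                "prop_hot_dry": n_hot / n,
                "prop_cold_wet": n_cold / n,
                "prop_intermediate": n_int / n,
                "label": label,
                "low_confidence": n < min_individuals,
            }
        )
    return GroupAssignment(individual=ind, population=pd.DataFrame(rows))
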