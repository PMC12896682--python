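"""Scalar quality scores, five grades, and warehouse actions.

The quality score is the min-max-normalised projection of a record's six
indicators onto the first principal component of the training records,
oriented so that lower oxidation means a higher score (the hydrolysis and
oxidation indicators dominate PC1 with negative loadings).  Scores map to
five grades through fixed half-open intervals, and each grade carries a
warehouse action from routine storage up to retirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .reference import (GRADE_ACTIONS, GRADE_SCORE_BOUNDS, INDICATORS,
                        STORAGE_PHASES)


@dataclass(frozen=True)
class GradeScheme:
    """Ordered lower score bounds for grades 1..K-1; grade K is the rest."""

    bounds: tuple[float, ...] = GRADE_SCORE_BOUNDS
    actions: dict[int, str] = field(default_factory=lambda: dict(GRADE_ACTIONS))

    def __post_init__(self):
        if list(self.bounds) != sorted(self.bounds, reverse=True):
            raise ValueError("bounds must strictly decrease")

    @property
    def n_grades(self) -> int:
        return len(self.bounds) + 1


class QualityScorer:
    """PC1-projection quality score fitted on training records."""

    def __init__(self):
        self._fitted = False

    def fit(self, records: pd.DataFrame | np.ndarray) -> "QualityScorer":
        X = self._matrix(records)
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        if np.all(self.std_ < 1e-12):
            raise ValueError("all records identical: PC1 orientation is "
                             "undefined")
        self.std_ = np.where(self.std_ < 1e-12, 1.0, self.std_)
        Z = (X - self.mean_) / self.std_
        pca = PCA(n_components=1)
        proj = pca.fit_transform(Z)[:, 0]
        loadings = pca.components_[0]
        # orient so oxidation indicators load negatively: fresher -> higher
        if loadings[INDICATORS.index("fatty_acid")] > 0:
            loadings = -loadings
            proj = -proj
        self.loadings_ = loadings
        self.explained_variance_ratio_ = float(pca.explained_variance_ratio_[0])
        self.min_, self.max_ = float(proj.min()), float(proj.max())
        if self.max_ - self.min_ < 1e-12:
            raise ValueError("degenerate PC1 projection: no score spread")
        self._fitted = True
        return self

    @staticmethod
    def _matrix(records) -> np.ndarray:
        if isinstance(records, pd.DataFrame):
            return records[INDICATORS].to_numpy(dtype=float)
        X = np.asarray(records, dtype=float)
        if X.ndim == 1:
            X = X[None]
        return X

    def score(self, records: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Scores in [0, 1) for inputs inside the fitted projection range."""
        if not self._fitted:
            raise RuntimeError("QualityScorer must be fitted before scoring")
        Z = (self._matrix(records) - self.mean_) / self.std_
        proj = Z @ self.loadings_
        return (proj - self.min_) / (self.max_ - self.min_)


def quality_score(records, scorer: QualityScorer) -> np.ndarray:
    return scorer.score(records)


def assign_grade(score: float | np.ndarray,
                 scheme: GradeScheme = GradeScheme()) -> int | np.ndarray:
    """Grade by half-open interval membership; out-of-range scores clamp.

    Scores >= 1 clamp to grade 1 and scores < 0 to the worst grade, each
    with a warning; NaN scores are rejected.
    """
    arr = np.asarray(score, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN quality score")
    if (arr >= 1).any():
        warnings.warn("score(s) >= 1 clamped to grade 1", stacklevel=2)
    if (arr < 0).any():
        warnings.warn(f"score(s) < 0 clamped to grade {scheme.n_grades}",
                      stacklevel=2)
    bounds = np.asarray(scheme.bounds)
    grades = np.searchsorted(-bounds, -arr, side="left") + 1
    grades = np.minimum(grades, scheme.n_grades)
    return int(grades) if np.isscalar(score) else grades


def grade_table(table: pd.DataFrame, scorer: QualityScorer,
                scheme: GradeScheme = GradeScheme()) -> pd.DataFrame:
    """Score and grade every record; returns day, condition, score, grade."""
    scores = scorer.score(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grades = assign_grade(scores, scheme)
    return pd.DataFrame({
        "day": table["day"].to_numpy(),
        "condition_id": table["condition_id"].to_numpy(),
        "score": np.clip(scores, 0.0, np.nextafter(1.0, 0.0)),
        "grade": grades,
    })


def grade_time_distribution(assignments: pd.DataFrame,
                            n_grades: int = 5) -> pd.DataFrame:
    """Per-condition, per-day fraction of records in each grade.

    Rows are (condition_id, day); columns ``grade_1..grade_K`` sum to 1.
    """
    if assignments.empty:
        raise ValueError("no assignments")
    counts = (assignments
              .groupby(["condition_id", "day", "grade"])
              .size().unstack("grade", fill_value=0))
    for g in range(1, n_grades + 1):
        if g not in counts.columns:
            counts[g] = 0
    counts = counts[sorted(counts.columns)]
    frac = counts.div(counts.sum(axis=1), axis=0)
    frac.columns = [f"grade_{g}" for g in frac.columns]
    return frac.reset_index()


def storage_recommendation(condition_temperature: float, day: int,
                           distribution: pd.DataFrame | None = None,
                           ) -> tuple[str, str]:
    """Storage phase and warehouse action for a condition and day.

    Phase boundaries by chamber temperature: 15 deg C premium to day 100
    and good to day 150; 25 deg C premium to 60, good to 100; 35 deg C
    premium to 40, good to 90.  ``distribution`` is accepted for context
    but the rule table is declarative.
    """
    temp = int(round(condition_temperature))
    if temp not in STORAGE_PHASES:
        raise ValueError(f"unknown storage condition {condition_temperature} "
                         f"deg C; configured: {sorted(STORAGE_PHASES)}")
    if day < 0:
        raise ValueError("day must be non-negative")
    premium_end, good_end = STORAGE_PHASES[temp]
    if day <= premium_end:
        return "premium", GRADE_ACTIONS[1]
    if day <= good_end:
        return "good", GRADE_ACTIONS[3]
    return "late", GRADE_ACTIONS[4]
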