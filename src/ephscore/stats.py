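"""Ranking statistics for score columns against experimental activities.

Three statistics summarise how well a score column orders a congeneric
inhibitor series:

* Pearson R between score and pIC50, with an orientation convention:
  columns where a *higher* score means stronger predicted binding are
  sign-flipped, so a more negative R always means better ranking.
* Npred, the concordant-pair success rate: the percentage of unordered
  inhibitor pairs whose predicted stability ordering matches the
  experimental one.  Pairs with exactly equal experimental pIC50 are
  excluded from the denominator; a predicted-score tie counts as a
  failed prediction (a model that cannot order a pair has not predicted
  it).
* SE, the standard error of estimate of the least-squares fit of the
  energy on pIC50, in kcal/mol — reported for energy-like columns only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .ledger import ActivityRecord

__all__ = [
    "Orientation",
    "ScoreColumn",
    "EvaluationResult",
    "pearson_r",
    "npred",
    "standard_error_estimate",
    "evaluate_model",
]


class Orientation(str, Enum):
    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


@dataclass(frozen=True)
class ScoreColumn:
    """One named score per ligand, with its orientation.

    ``energy_like`` marks columns in kcal/mol, for which the standard
    error of estimate is meaningful.
    """

    name: str
    values: Mapping[str, float]
    orientation: Orientation = Orientation.LOWER_IS_BETTER
    energy_like: bool = True

    def paired(self, activities: Sequence[ActivityRecord]) -> tuple[np.ndarray, np.ndarray]:
        """Score and activity vectors aligned on ligand ID."""
        missing = [a.ligand_id for a in activities if a.ligand_id not in self.values]
        if missing:
            raise KeyError(f"column {self.name!r} lacks ligands: {missing}")
        s = np.array([self.values[a.ligand_id] for a in activities], dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError(f"column {self.name!r} contains non-finite scores")
        a = np.array([a.pic50 for a in activities], dtype=float)
        return s, a

    def normalized(self, activities: Sequence[ActivityRecord]) -> tuple[np.ndarray, np.ndarray]:
        """As :meth:`paired` but sign-flipped to lower-is-better."""
        s, a = self.paired(activities)
        if self.orientation is Orientation.HIGHER_IS_BETTER:
            s = -s
        return s, a


@dataclass(frozen=True)
class EvaluationResult:
    """Footer-row statistics for one score column."""

    column: str
    r: float
    r_squared: float
    npred_percent: float
    n_pairs_total: int
    n_pairs_excluded_ties: int
    n_pairs_concordant: int
    se: float | None = None


def pearson_r(scores: ScoreColumn, activities: Sequence[ActivityRecord]) -> float:
    """Pearson correlation of raw score vs pIC50, orientation-normalised.

    For higher-is-better columns the returned value is negated so that a
    more negative R uniformly indicates better ranking.
    """
    s, a = scores.paired(activities)
    if len(s) < 3:
        raise ValueError("need at least 3 ligands for a correlation")
    if np.ptp(s) == 0 or np.ptp(a) == 0:
        raise ValueError(f"degenerate column: zero variance in {scores.name!r}")
    r = float(_sps.pearsonr(s, a).statistic)
    if scores.orientation is Orientation.HIGHER_IS_BETTER:
        r = -r
    return r


def npred(scores: ScoreColumn, activities: Sequence[ActivityRecord]) -> EvaluationResult:
    """Concordant-pair success rate over all unordered ligand pairs.

    Pairs with exactly equal pIC50 (at the recorded precision) are
    excluded from the denominator.  After normalising to
    lower-is-better, a pair is concordant when the lower score belongs
    to the higher-activity ligand; score ties are non-concordant.
    R/SE fields of the returned result are NaN/None placeholders.
    """
    s, a = scores.normalized(activities)
    if len(s) < 2:
        raise ValueError("need at least 2 ligands to enumerate pairs")
    total = excluded = concordant = 0
    for i, j in combinations(range(len(s)), 2):
        total += 1
        if a[i] == a[j]:
            excluded += 1
            continue
        ds, da = s[i] - s[j], a[i] - a[j]
        if ds != 0 and (ds < 0) == (da > 0):
            concordant += 1
    counted = total - excluded
    if counted == 0:
        raise ValueError("all pairs are experimental ties")
    return EvaluationResult(
        column=scores.name,
        r=float("nan"),
        r_squared=float("nan"),
        npred_percent=100.0 * concordant / counted,
        n_pairs_total=total,
        n_pairs_excluded_ties=excluded,
        n_pairs_concordant=concordant,
    )


def standard_error_estimate(
    scores: ScoreColumn, activities: Sequence[ActivityRecord]
) -> float:
    """Residual SD of the OLS fit of energy on pIC50, kcal/mol.

    The energy is the dependent variable (so the result carries energy
    units): se = sqrt(SS_res / (n - 2)).
    """
    if not scores.energy_like:
        raise ValueError(f"column {scores.name!r} is not energy-like")
    s, a = scores.paired(activities)
    if len(s) < 3:
        raise ValueError("need at least 3 ligands for a regression")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in activities")
    fit = _sps.linregress(a, s)
    resid = s - (fit.slope * a + fit.intercept)
    return float(np.sqrt(np.sum(resid**2) / (len(s) - 2)))


def evaluate_model(
    columns: Sequence[ScoreColumn], activities: Sequence[ActivityRecord]
) -> list[EvaluationResult]:
    """Apply all three statistics to each column.

    Results are ordered by column name for determinism; SE is included
    for energy-like columns only.
    """
    results = []
    for col in sorted(columns, key=lambda c: c.name):
        r = pearson_r(col, activities)
        frag = npred(col, activities)
        se = standard_error_estimate(col, activities) if col.energy_like else None
        results.append(
            EvaluationResult(
                column=col.name,
                r=r,
                r_squared=r * r,
                npred_percent=frag.npred_percent,
                n_pairs_total=frag.n_pairs_total,
                n_pairs_excluded_ties=frag.n_pairs_excluded_ties,
                n_pairs_concordant=frag.n_pairs_concordant,
                se=se,
            )
        )
    return results
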