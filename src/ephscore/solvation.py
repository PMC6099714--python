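"""Solvation-free-energy applicability screen.

A purely enthalpic, gas-phase interaction-energy score can only rank a
ligand series whose members pay comparable desolvation penalties.  The
spread of the continuum-solvation free energies within the series —
their sample standard deviation — therefore acts as a cheap
applicability predictor: a series with an elevated SD relative to
systems where the long-range composite score is known to work is
unlikely to be ranked well until the solvation outliers are removed.

This module validates the electrostatic/non-electrostatic split of
solvation records, computes the SD screen, selects reduced ligand sets
(by an explicit exclusion list or by a distance-from-median rule) and
re-runs the ranking statistics on the reduced set.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .ledger import ActivityRecord
from .stats import EvaluationResult, ScoreColumn, evaluate_model

__all__ = [
    "SolvationRecord",
    "Verdict",
    "ApplicabilityResult",
    "ScreenComparison",
    "REFERENCE_SDS",
    "SPLIT_TOL",
    "sample_sd",
    "validate_solvation",
    "select_reduced_set",
    "screen_and_reevaluate",
    "applicability_index",
]

#: dGsolv sample SDs (kcal/mol) of inhibitor series where the composite
#: long-range score has been benchmarked; comparison metadata for the
#: applicability verdict.
REFERENCE_SDS: Mapping[str, float] = {
    "menin-MLL": 2.5,
    "FAAH": 1.5,
    "TbPTR1": 1.1,
}

#: Printed-rounding tolerance for the el + non-el additivity check.
SPLIT_TOL: float = 0.15


@dataclass(frozen=True)
class SolvationRecord:
    """Continuum-solvation free energy of one ligand with its split.

    ``dg_solv`` should equal ``dg_solv_el + dg_solv_nonel`` within the
    printed-rounding tolerance; use :func:`validate_solvation` to check.
    """

    ligand_id: str
    dg_solv: float
    dg_solv_el: float
    dg_solv_nonel: float


class Verdict(str, Enum):
    COMPARABLE = "comparable"
    ELEVATED = "elevated"


@dataclass(frozen=True)
class ApplicabilityResult:
    sd: float
    n: int
    reference_sds: Mapping[str, float]
    verdict: Verdict


@dataclass(frozen=True)
class ScreenComparison:
    """Full-set vs reduced-set statistics for the evaluated columns."""

    kept_ligands: tuple[str, ...]
    excluded_ligands: tuple[str, ...]
    sd_before: float
    sd_after: float
    full: list[EvaluationResult]
    reduced: list[EvaluationResult]

    def deltas(self) -> dict[str, dict[str, float]]:
        by_col = {r.column: r for r in self.reduced}
        return {
            f.column: {
                "delta_r": by_col[f.column].r - f.r,
                "delta_npred": by_col[f.column].npred_percent - f.npred_percent,
            }
            for f in self.full
            if f.column in by_col
        }


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator), kcal/mol."""
    if len(values) < 2:
        raise ValueError("need at least 2 values for a standard deviation")
    return statistics.stdev(values)


def validate_solvation(
    records: Sequence[SolvationRecord],
    tol: float = SPLIT_TOL,
    require_nonel_positive: bool = True,
) -> list[str]:
    """Report additivity and sign violations; empty list when consistent."""
    problems = []
    for r in records:
        resid = abs(r.dg_solv - (r.dg_solv_el + r.dg_solv_nonel))
        if resid > tol:
            problems.append(
                f"[{r.ligand_id}] el + non-el split off by {resid:.3g} kcal/mol"
            )
        if require_nonel_positive and r.dg_solv_nonel < 0:
            problems.append(
                f"[{r.ligand_id}] non-electrostatic part negative "
                f"({r.dg_solv_nonel:g})"
            )
    return problems


def select_reduced_set(
    records: Sequence[SolvationRecord],
    exclusions: Sequence[str] | None = None,
    k_most_distant: int | None = None,
) -> tuple[list[str], float, float]:
    """Drop solvation outliers; return (kept IDs, sd_before, sd_after).

    Either an explicit exclusion list (the reproduction default) or a
    rule dropping the ``k_most_distant`` ligands whose dGsolv deviates
    most from the series median.  At least 3 ligands must remain.
    """
    if (exclusions is None) == (k_most_distant is None):
        raise ValueError("give exactly one of exclusions or k_most_distant")
    values = {r.ligand_id: r.dg_solv for r in records}
    sd_before = sample_sd(list(values.values()))
    if exclusions is not None:
        unknown = set(exclusions) - set(values)
        if unknown:
            raise KeyError(f"exclusion list names unknown ligands: {sorted(unknown)}")
        kept = [i for i in values if i not in set(exclusions)]
    else:
        med = statistics.median(values.values())
        ranked = sorted(values, key=lambda i: (abs(values[i] - med), i), reverse=True)
        kept = [i for i in values if i not in set(ranked[:k_most_distant])]
    if len(kept) < 3:
        raise ValueError(f"over-exclusion: only {len(kept)} ligands would remain")
    sd_after = sample_sd([values[i] for i in kept])
    return kept, sd_before, sd_after


def screen_and_reevaluate(
    columns: Sequence[ScoreColumn],
    activities: Sequence[ActivityRecord],
    records: Sequence[SolvationRecord],
    exclusions: Sequence[str] | None = None,
    k_most_distant: int | None = None,
) -> ScreenComparison:
    """Evaluate the columns on the full set and on the solvation-reduced set."""
    act_ids = {a.ligand_id for a in activities}
    solv_ids = {r.ligand_id for r in records}
    if act_ids != solv_ids:
        orphans = sorted(act_ids ^ solv_ids)
        raise KeyError(f"activity and solvation tables disagree on ligands: {orphans}")
    if exclusions is None and k_most_distant is None:
        kept = sorted(act_ids)
        sd = sample_sd([r.dg_solv for r in records])
        full = evaluate_model(columns, activities)
        return ScreenComparison(
            kept_ligands=tuple(kept),
            excluded_ligands=(),
            sd_before=sd,
            sd_after=sd,
            full=full,
            reduced=full,
        )
    kept, sd_before, sd_after = select_reduced_set(records, exclusions, k_most_distant)
    kept_set = set(kept)
    reduced_acts = [a for a in activities if a.ligand_id in kept_set]
    full = evaluate_model(columns, activities)
    reduced = evaluate_model(columns, reduced_acts)
    return ScreenComparison(
        kept_ligands=tuple(sorted(kept_set)),
        excluded_ligands=tuple(sorted(act_ids - kept_set)),
        sd_before=sd_before,
        sd_after=sd_after,
        full=full,
        reduced=reduced,
    )


def applicability_index(
    records: Sequence[SolvationRecord],
    reference_sds: Mapping[str, float] = REFERENCE_SDS,
) -> ApplicabilityResult:
    """SD-based applicability verdict for a ligand series.

    ``elevated`` when the series' dGsolv SD exceeds every reference
    system's SD, ``comparable`` otherwise.
    """
    sd = sample_sd([r.dg_solv for r in records])
    verdict = (
        Verdict.ELEVATED
        if all(sd > ref for ref in reference_sds.values())
        else Verdict.COMPARABLE
    )
    return ApplicabilityResult(
        sd=sd, n=len(records), reference_sds=dict(reference_sds), verdict=verdict
    )
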