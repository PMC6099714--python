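"""Bookkeeping for the HVPT interaction-energy decomposition.

Hybrid Variation-Perturbation Theory partitions the MP2 interaction energy
into terms of increasing computational cost,

    E_MP2 = E_EL,MTP(10) + E_EL,PEN(10) + E_EX(10) + E_DEL(R0) + E_CORR(2),

arranged as cumulative theory levels: the multipole electrostatic energy
E_EL,MTP(10), the first-order electrostatic energy E_EL(10) (adds charge
penetration), the Heitler-London energy E(10) (adds exchange repulsion),
the SCF interaction energy E_SCF (adds delocalization) and finally E_MP2
(adds electron correlation).  A cheap long-range composite substitutes a
fitted atom-atom dispersion term for the correlation contribution:
E_EL,MTP(10) + E_Das.

This module holds per-(ligand, residue-group) component records, composes
the level totals, aggregates per-residue contributions and validates the
physical sign constraints and the additive bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HvptTerms",
    "LevelEnergies",
    "ActivityRecord",
    "Violation",
    "COMPONENT_FIELDS",
    "LEVEL_FIELDS",
    "DEFAULT_RESIDUE_GROUPS",
    "ROUNDED_TABLE_TOL",
    "compose_levels",
    "aggregate_residue_contributions",
    "validate_decomposition",
    "levels_to_components",
]

#: Residue grouping of the six-residue EphA2 binding-site model.  The
#: disulfide-bonded cysteines and the sequential Val/Met pair are treated
#: as dimer groups; the charged Arg103 and aromatic Phe108 stand alone.
#: Grouping is configuration data, not code.
DEFAULT_RESIDUE_GROUPS: tuple[str, ...] = (
    "Arg103",
    "Phe108",
    "Cys70-Cys188",
    "Val72-Met73",
)

#: Tolerance for bookkeeping checks on tables printed at one decimal:
#: up to three rounded terms enter a level sum, each contributing at most
#: 0.05 kcal/mol of rounding error.
ROUNDED_TABLE_TOL: float = 0.15

COMPONENT_FIELDS = ("eel_mtp", "eel_pen", "eex", "edel", "ecorr", "edas")
LEVEL_FIELDS = ("eel_mtp10", "eel10", "e10", "escf", "emp2", "eelmtp_plus_edas")


@dataclass(frozen=True)
class HvptTerms:
    """Interaction-energy components for one ligand / residue-group pair.

    All energies in kcal/mol.  ``edas`` (approximate dispersion from the
    fitted atom-atom potential) is optional per record; composite totals
    that need it are produced only when every record carries it.
    """

    ligand_id: str
    residue_group: str
    eel_mtp: float
    eel_pen: float
    eex: float
    edel: float
    ecorr: float
    edas: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"non-finite value for {f.name}")


@dataclass(frozen=True)
class LevelEnergies:
    """Cumulative theory-level totals for one ligand (kcal/mol)."""

    ligand_id: str
    eel_mtp10: float
    eel10: float
    e10: float
    escf: float
    emp2: float
    eelmtp_plus_edas: float | None = None


@dataclass(frozen=True)
class ActivityRecord:
    """Experimental potency of one ligand (pIC50, dimensionless)."""

    ligand_id: str
    label: str
    pic50: float

    def __post_init__(self) -> None:
        if not (self.pic50 > 0):
            raise ValueError(f"pIC50 must be positive, got {self.pic50}")


@dataclass(frozen=True)
class Violation:
    """One violated invariant, with the residual magnitude in kcal/mol."""

    ligand_id: str
    rule: str
    residual: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.ligand_id}] {self.rule} (residual {self.residual:.3g})"


def _check_single_ligand(terms: Sequence[HvptTerms]) -> str:
    if not terms:
        raise ValueError("at least one HvptTerms record required")
    ids = {t.ligand_id for t in terms}
    if len(ids) != 1:
        raise ValueError(f"mixed ligand IDs in term list: {sorted(ids)}")
    return terms[0].ligand_id


def compose_levels(terms: Sequence[HvptTerms]) -> LevelEnergies:
    """Compose cumulative theory-level totals from component records.

    Totals are sums over residue groups; each level adds one component
    class to the previous level.  The long-range composite
    ``eelmtp_plus_edas`` is present only when every record carries an
    ``edas`` value.
    """
    ligand_id = _check_single_ligand(terms)
    eel_mtp = sum(t.eel_mtp for t in terms)
    eel_pen = sum(t.eel_pen for t in terms)
    eex = sum(t.eex for t in terms)
    edel = sum(t.edel for t in terms)
    ecorr = sum(t.ecorr for t in terms)

    eel10 = eel_mtp + eel_pen
    e10 = eel10 + eex
    escf = e10 + edel
    emp2 = escf + ecorr

    composite: float | None = None
    if all(t.edas is not None for t in terms):
        composite = eel_mtp + sum(t.edas for t in terms)  # type: ignore[misc]

    return LevelEnergies(
        ligand_id=ligand_id,
        eel_mtp10=eel_mtp,
        eel10=eel10,
        e10=e10,
        escf=escf,
        emp2=emp2,
        eelmtp_plus_edas=composite,
    )


def aggregate_residue_contributions(
    terms: Sequence[HvptTerms], component: str
) -> dict[str, float]:
    """Sum one component (raw field or composed level) per residue group.

    The returned map conserves the ligand total: its values sum to the
    corresponding entry of :func:`compose_levels` applied to ``terms``.
    """
    valid = COMPONENT_FIELDS + LEVEL_FIELDS
    if component not in valid:
        raise ValueError(
            f"unknown component {component!r}; valid names: {', '.join(valid)}"
        )
    if not terms:
        return {}
    _check_single_ligand(terms)

    def per_record(t: HvptTerms) -> float:
        if component in COMPONENT_FIELDS:
            v = getattr(t, component)
            if v is None:
                raise ValueError(
                    f"record ({t.ligand_id}, {t.residue_group}) lacks {component}"
                )
            return v
        acc = {"eel_mtp10": t.eel_mtp}
        acc["eel10"] = acc["eel_mtp10"] + t.eel_pen
        acc["e10"] = acc["eel10"] + t.eex
        acc["escf"] = acc["e10"] + t.edel
        acc["emp2"] = acc["escf"] + t.ecorr
        if component == "eelmtp_plus_edas":
            if t.edas is None:
                raise ValueError(
                    f"record ({t.ligand_id}, {t.residue_group}) lacks edas"
                )
            return t.eel_mtp + t.edas
        return acc[component]

    out: dict[str, float] = {}
    for t in terms:
        out[t.residue_group] = out.get(t.residue_group, 0.0) + per_record(t)
    return out


# sign rules: (field, predicate description, ok given tolerance)
_SIGN_RULES = (
    ("eex", "exchange repulsion negative", lambda v, tol: v >= -tol),
    ("edel", "delocalization positive", lambda v, tol: v <= tol),
    ("ecorr", "correlation positive", lambda v, tol: v <= tol),
    ("eel_pen", "penetration positive", lambda v, tol: v <= tol),
)


def validate_decomposition(
    terms: Sequence[HvptTerms],
    levels: LevelEnergies | None = None,
    tol: float = 0.0,
) -> list[Violation]:
    """Report every violated sign or additivity invariant.

    Violations are reported, never silently repaired.  ``tol`` relaxes
    the sign checks; level residual checks (when ``levels`` is given)
    use ``tol`` as well, so pass :data:`ROUNDED_TABLE_TOL` for data read
    from one-decimal tables and a strict tolerance for synthetic data.
    """
    report: list[Violation] = []
    for t in terms:
        for field, rule, ok in _SIGN_RULES:
            v = getattr(t, field)
            if v is not None and not ok(v, tol):
                report.append(Violation(t.ligand_id, f"{rule} ({field}={v:g})", abs(v)))

    if levels is not None and terms:
        composed = compose_levels(terms)
        for name in LEVEL_FIELDS:
            want = getattr(levels, name)
            have = getattr(composed, name)
            if want is None or have is None:
                continue
            resid = abs(want - have)
            if resid > tol:
                report.append(Violation(levels.ligand_id, f"{name} residual", resid))
    return report


def levels_to_components(levels: LevelEnergies) -> HvptTerms:
    """Reconstruct total components by successive subtraction of levels.

    Inverse of :func:`compose_levels` for a single aggregate record; the
    residue group of the result is ``"total"``.  ``edas`` is recovered as
    the composite minus the multipole electrostatic term when available.
    """
    edas = None
    if levels.eelmtp_plus_edas is not None:
        edas = levels.eelmtp_plus_edas - levels.eel_mtp10
    return HvptTerms(
        ligand_id=levels.ligand_id,
        residue_group="total",
        eel_mtp=levels.eel_mtp10,
        eel_pen=levels.eel10 - levels.eel_mtp10,
        eex=levels.e10 - levels.eel10,
        edel=levels.escf - levels.e10,
        ecorr=levels.emp2 - levels.escf,
        edas=edas,
    )
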