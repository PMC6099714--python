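"""Readers, writers, packaged reference tables and the pipeline driver.

Canonical CSV dialects (UTF-8, decimal point, energies in kcal/mol):

* activities:    ``ligand_id,label,pic50``
* level tables:  ``ligand_id,eel_mtp10,eel10,e10,escf,emp2,eelmtp_plus_edas``
* energy terms:  ``ligand_id,residue_group,eel_mtp,eel_pen,eex,edel,ecorr,edas``
* solvation:     ``ligand_id,dg_solv,dg_solv_el,dg_solv_nonel``

The packaged fixtures transcribe the published EphA2-ephrin A1 study
tables at printed precision (15 ligands each): experimental activities,
interaction-energy level totals, solvation free energies, and the
cross-system reference statistics used by the applicability screen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ledger import (
    LEVEL_FIELDS,
    ActivityRecord,
    HvptTerms,
    LevelEnergies,
    ROUNDED_TABLE_TOL,
    levels_to_components,
    validate_decomposition,
)
from .solvation import SolvationRecord, screen_and_reevaluate, validate_solvation
from .stats import EvaluationResult, Orientation, ScoreColumn, evaluate_model

__all__ = [
    "FIXTURE_NAMES",
    "DEFAULT_EXCLUSIONS",
    "RunConfig",
    "load_fixture",
    "read_activities",
    "read_levels",
    "read_terms",
    "read_solvation",
    "write_activities",
    "write_levels",
    "write_terms",
    "write_solvation",
    "levels_to_columns",
    "results_to_frame",
    "run_pipeline",
]

logger = logging.getLogger("ephscore")

FIXTURE_NAMES = (
    "table1_activities",
    "table2_levels",
    "table2_components",
    "table3_solvation",
    "table4_reference_sds",
)

#: Solvation outliers excluded from the published reduced set.
DEFAULT_EXCLUSIONS = ("20", "7", "2", "18")

#: Further exclusions probed in the 9-ligand variant.
EXTRA_EXCLUSIONS = ("4", "9")


def _fixture_frame(name: str) -> pd.DataFrame:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = resources.files("ephscore.data") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"ligand_id": str}, float_precision="round_trip")


def load_fixture(name: str):
    """Load a packaged reference table as typed records.

    ``table4_reference_sds`` returns a DataFrame (comparison metadata);
    the others return lists of the corresponding record types.
    """
    df = _fixture_frame(name)
    if name == "table1_activities":
        return [ActivityRecord(r.ligand_id, r.label, r.pic50) for r in df.itertuples()]
    if name == "table2_levels":
        return [
            LevelEnergies(
                r.ligand_id, r.eel_mtp10, r.eel10, r.e10, r.escf, r.emp2,
                r.eelmtp_plus_edas,
            )
            for r in df.itertuples()
        ]
    if name == "table2_components":
        return _frame_to_terms(df)
    if name == "table3_solvation":
        return [
            SolvationRecord(r.ligand_id, r.dg_solv, r.dg_solv_el, r.dg_solv_nonel)
            for r in df.itertuples()
        ]
    return df


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _frame_to_terms(df: pd.DataFrame) -> list[HvptTerms]:
    has_edas = "edas" in df.columns
    return [
        HvptTerms(
            ligand_id=str(r.ligand_id),
            residue_group=str(r.residue_group),
            eel_mtp=r.eel_mtp,
            eel_pen=r.eel_pen,
            eex=r.eex,
            edel=r.edel,
            ecorr=r.ecorr,
            edas=(r.edas if has_edas and pd.notna(r.edas) else None),
        )
        for r in df.itertuples()
    ]


def read_activities(path: str | Path) -> list[ActivityRecord]:
    df = pd.read_csv(path, dtype={"ligand_id": str}, float_precision="round_trip")
    return [ActivityRecord(r.ligand_id, r.label, r.pic50) for r in df.itertuples()]


def read_levels(path: str | Path) -> list[LevelEnergies]:
    df = pd.read_csv(path, dtype={"ligand_id": str}, float_precision="round_trip")
    return [
        LevelEnergies(
            r.ligand_id, r.eel_mtp10, r.eel10, r.e10, r.escf, r.emp2,
            getattr(r, "eelmtp_plus_edas", None),
        )
        for r in df.itertuples()
    ]


def read_terms(path: str | Path) -> list[HvptTerms]:
    return _frame_to_terms(pd.read_csv(path, dtype={"ligand_id": str}, float_precision="round_trip"))


def read_solvation(path: str | Path) -> list[SolvationRecord]:
    df = pd.read_csv(path, dtype={"ligand_id": str}, float_precision="round_trip")
    return [
        SolvationRecord(r.ligand_id, r.dg_solv, r.dg_solv_el, r.dg_solv_nonel)
        for r in df.itertuples()
    ]


def _write(df: pd.DataFrame, path: str | Path) -> None:
    # repr-based formatting + round_trip parsing keep the canonical
    # dialect lossless for doubles
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = df.copy()
    for c in df.columns:
        if df[c].dtype.kind == "f":
            df[c] = df[c].map(lambda v: repr(float(v)) if pd.notna(v) else "")
    df.to_csv(path, index=False, lineterminator="\n")


def write_activities(records: Sequence[ActivityRecord], path: str | Path) -> None:
    _write(
        pd.DataFrame(
            {"ligand_id": [r.ligand_id for r in records],
             "label": [r.label for r in records],
             "pic50": [r.pic50 for r in records]}
        ),
        path,
    )


def write_levels(records: Sequence[LevelEnergies], path: str | Path) -> None:
    _write(
        pd.DataFrame(
            {"ligand_id": [r.ligand_id for r in records],
             **{f: [getattr(r, f) for r in records] for f in LEVEL_FIELDS}}
        ),
        path,
    )


def write_terms(records: Sequence[HvptTerms], path: str | Path) -> None:
    _write(
        pd.DataFrame(
            {"ligand_id": [r.ligand_id for r in records],
             "residue_group": [r.residue_group for r in records],
             **{f: [getattr(r, f) for r in records]
                for f in ("eel_mtp", "eel_pen", "eex", "edel", "ecorr", "edas")}}
        ),
        path,
    )


def write_solvation(records: Sequence[SolvationRecord], path: str | Path) -> None:
    _write(
        pd.DataFrame(
            {"ligand_id": [r.ligand_id for r in records],
             "dg_solv": [r.dg_solv for r in records],
             "dg_solv_el": [r.dg_solv_el for r in records],
             "dg_solv_nonel": [r.dg_solv_nonel for r in records]}
        ),
        path,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

#: Human-readable names of the theory levels, in increasing cost order.
LEVEL_LABELS: Mapping[str, str] = {
    "eel_mtp10": "EEL,MTP(10)",
    "eel10": "EEL(10)",
    "e10": "E(10)",
    "escf": "ESCF",
    "emp2": "EMP2",
    "eelmtp_plus_edas": "EEL,MTP(10)+EDas",
}


def levels_to_columns(
    levels: Sequence[LevelEnergies], which: Sequence[str] = LEVEL_FIELDS
) -> list[ScoreColumn]:
    """Turn a level table into energy-oriented score columns."""
    cols = []
    for name in which:
        if name not in LEVEL_FIELDS:
            raise KeyError(f"unknown level {name!r}; valid: {LEVEL_FIELDS}")
        vals = {r.ligand_id: getattr(r, name) for r in levels}
        if any(v is None for v in vals.values()):
            raise ValueError(f"level {name!r} missing for some ligands")
        cols.append(ScoreColumn(name=name, values=vals))
    return cols


def results_to_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column": [r.column for r in results],
            "r": [r.r for r in results],
            "r2": [r.r_squared for r in results],
            "npred": [r.npred_percent for r in results],
            "n_pairs": [r.n_pairs_total - r.n_pairs_excluded_ties for r in results],
            "se": [r.se for r in results],
        }
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Paths default to ``None``, meaning the packaged reference tables.
    ``score_csv``/``orientation`` ingest free-form external score
    columns (e.g. third-party scoring functions) alongside the theory
    levels.
    """

    levels_path: str | None = None
    activities_path: str | None = None
    solvation_path: str | None = None
    score_csv: str | None = None
    orientation: Mapping[str, str] = field(default_factory=dict)
    model_columns: Sequence[str] = LEVEL_FIELDS
    exclusions: Sequence[str] | None = DEFAULT_EXCLUSIONS
    k_most_distant: int | None = None
    tolerance: float = ROUNDED_TABLE_TOL
    out_dir: str = "reports"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _load_or_fixture(path: str | None, reader, fixture: str):
    if path is None:
        return load_fixture(fixture)
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input table not found: {p}")
    return reader(p)


def run_pipeline(config: RunConfig) -> dict:
    """Evaluate, screen, re-evaluate; write CSV and text reports.

    Returns a dict with the full/reduced evaluation frames, the
    solvation SDs and the validation report.  Raises on ligand-ID
    mismatches between tables (listing the orphans) and on missing
    files.
    """
    levels = _load_or_fixture(config.levels_path, read_levels, "table2_levels")
    activities = _load_or_fixture(
        config.activities_path, read_activities, "table1_activities"
    )
    solvation = _load_or_fixture(
        config.solvation_path, read_solvation, "table3_solvation"
    )

    level_ids = {l.ligand_id for l in levels}
    act_ids = {a.ligand_id for a in activities}
    if level_ids != act_ids:
        raise KeyError(
            f"level/activity tables disagree on ligands: {sorted(level_ids ^ act_ids)}"
        )

    # ledger consistency on the level table, at the configured tolerance
    violations = []
    for lev in levels:
        terms = [levels_to_components(lev)]
        violations += validate_decomposition(terms, lev, tol=config.tolerance)
    solvation_problems = validate_solvation(solvation, tol=config.tolerance)
    for v in violations:
        logger.warning("decomposition: %s", v)
    for p in solvation_problems:
        logger.warning("solvation: %s", p)
    logger.info(
        "validated %d ligands at tolerance %.2f kcal/mol (%d violations)",
        len(levels), config.tolerance, len(violations),
    )

    columns = levels_to_columns(levels, config.model_columns) if config.model_columns else []
    if config.score_csv:
        df = pd.read_csv(config.score_csv, dtype={"ligand_id": str})
        for name in df.columns:
            if name == "ligand_id":
                continue
            orient = Orientation(config.orientation.get(name, "lower_is_better"))
            columns.append(
                ScoreColumn(
                    name=name,
                    values=dict(zip(df["ligand_id"], df[name])),
                    orientation=orient,
                    energy_like=False,
                )
            )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not columns:
        (out / "evaluation_full.csv").write_text("column,r,r2,npred,n_pairs,se\n")
        return {"full": pd.DataFrame(), "reduced": pd.DataFrame(),
                "violations": violations, "solvation_problems": solvation_problems}

    screen = screen_and_reevaluate(
        columns, activities, solvation,
        exclusions=config.exclusions, k_most_distant=config.k_most_distant,
    )
    full_df = results_to_frame(screen.full)
    reduced_df = results_to_frame(screen.reduced)
    _write(full_df, out / "evaluation_full.csv")
    _write(reduced_df, out / "evaluation_reduced.csv")

    text = ["Full-set evaluation", full_df.round(3).to_string(index=False), ""]
    text += [
        f"Solvation SD before/after exclusion: "
        f"{screen.sd_before:.2f} / {screen.sd_after:.2f} kcal/mol",
        f"Excluded ligands: {', '.join(screen.excluded_ligands) or '(none)'}",
        "",
        "Reduced-set evaluation",
        reduced_df.round(3).to_string(index=False),
    ]
    if violations or solvation_problems:
        text += ["", "Validation findings:"]
        text += [f"  {v}" for v in violations]
        text += [f"  {p}" for p in solvation_problems]
    (out / "report.txt").write_text("\n".join(text) + "\n")

    return {
        "full": full_df,
        "reduced": reduced_df,
        "screen": screen,
        "violations": violations,
        "solvation_problems": solvation_problems,
    }
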