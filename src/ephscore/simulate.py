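"""Synthetic congeneric-series and toy-complex generators.

The generators emulate the statistical structure the analysis assumes
about a congeneric inhibitor series bound in a small residue-cluster
binding site:

* one dominant charged residue group carrying most of the electrostatic
  binding energy (a salt bridge between a charged residue and a
  counter-charged ligand head group);
* short-range components with their physical signs (exchange repulsive,
  penetration / delocalization / correlation stabilising), exactly;
* experimental activities linearly coupled to the total interaction
  energy with Gaussian noise calibrated so the population correlation
  matches a requested target;
* solvation free energies with a controllable spread, split exactly
  into electrostatic and non-electrostatic parts.

Everything is reproducible from a single integer seed (NumPy PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ledger import (
    DEFAULT_RESIDUE_GROUPS,
    ActivityRecord,
    HvptTerms,
)
from .longrange import (
    DispersionParams,
    Molecule,
    MultipoleSite,
    detrace_quadrupole,
)
from .solvation import SolvationRecord

__all__ = ["SeriesSpec", "generate_series", "generate_toy_complex", "reference_series_spec"]

#: Identifier of the pseudo-random algorithm used, recorded so emitted
#: tables can state their provenance.
RNG_ALGORITHM = "numpy-PCG64"

# Mean magnitudes (kcal/mol) of the per-group electrostatic term by
# charge class, and exponential scales of the short-range magnitudes.
_EL_MEAN = {"charged": 80.0, "neutral": 4.0}
_EL_SD = {"charged": 6.0, "neutral": 1.5}
_SCALES = {"eel_pen": 2.0, "eex": 4.0, "edel": 2.0, "ecorr": 2.5, "edas": 3.0}


@dataclass(frozen=True)
class SeriesSpec:
    """Study-condition parameters for one synthetic series.

    ``residue_groups`` pairs each group name with a charge class
    (``"charged"`` or ``"neutral"``); the ``dominant_group`` must be a
    charged one and receives the large electrostatic mean, so it
    contributes >= 70% of the total first-order electrostatic energy in
    expectation.  ``target_r`` is the population Pearson correlation
    between the MP2-level total and pIC50 (negative: lower energy,
    higher potency).  ``noise_floor`` is the smallest admissible
    activity-noise SD; a target correlation requiring less noise is
    rejected as infeasible.
    """

    n_ligands: int = 15
    residue_groups: tuple[tuple[str, str], ...] = tuple(
        (g, "charged" if g == "Arg103" else "neutral") for g in DEFAULT_RESIDUE_GROUPS
    )
    dominant_group: str = "Arg103"
    target_r: float = -0.72
    activity_range: tuple[float, float] = (4.0, 5.7)
    solvation_sd: float = 3.0
    seed: int = 0
    noise_floor: float = 0.0
    round_activities: int | None = None
    tie_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        names = [g for g, _ in self.residue_groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate residue group names")
        classes = dict(self.residue_groups)
        if self.dominant_group not in classes:
            raise ValueError(f"dominant group {self.dominant_group!r} not in groups")
        if classes[self.dominant_group] != "charged":
            raise ValueError("dominant group must be charged")
        if not -1.0 < self.target_r < 0.0:
            raise ValueError("target_r must lie in (-1, 0)")
        if self.solvation_sd < 0:
            raise ValueError("solvation_sd must be non-negative")
        if self.n_ligands < 2:
            raise ValueError("need at least 2 ligands")
        lo, hi = self.activity_range
        if not (0 < lo < hi):
            raise ValueError("activity_range must satisfy 0 < min < max")


def _emp2_population_sd(spec: SeriesSpec) -> float:
    """Population SD of the MP2-level total under the generative model."""
    var = 0.0
    for _, cls in spec.residue_groups:
        var += _EL_SD[cls] ** 2
        # exponential magnitudes: var = scale^2
        for name in ("eel_pen", "eex", "edel", "ecorr"):
            var += _SCALES[name] ** 2
    return math.sqrt(var)


def generate_series(
    spec: SeriesSpec,
) -> tuple[list[HvptTerms], list[ActivityRecord], list[SolvationRecord]]:
    """Draw one synthetic series: decomposition terms, activities, solvation.

    Activities are ``pIC50 = a + b * E_MP2 + eps`` with ``b < 0`` and the
    noise SD solved from the requested population correlation.  Raises
    when the required noise falls below ``spec.noise_floor``.
    """
    rng = np.random.default_rng(spec.seed)
    classes = dict(spec.residue_groups)

    terms: list[HvptTerms] = []
    emp2_totals = np.zeros(spec.n_ligands)
    ids = [f"L{i + 1:02d}" for i in range(spec.n_ligands)]
    for li, lid in enumerate(ids):
        for gname, cls in spec.residue_groups:
            # non-dominant charged groups get a reduced mean so the
            # dominant one keeps its >=70% share of the electrostatic total
            mean = _EL_MEAN[cls]
            if cls == "charged" and gname != spec.dominant_group:
                mean = 15.0
            eel_mtp = -rng.normal(mean, _EL_SD[cls])
            eel_pen = -rng.exponential(_SCALES["eel_pen"])
            eex = rng.exponential(_SCALES["eex"])
            edel = -rng.exponential(_SCALES["edel"])
            ecorr = -rng.exponential(_SCALES["ecorr"])
            edas = -rng.exponential(_SCALES["edas"])
            terms.append(
                HvptTerms(lid, gname, eel_mtp, eel_pen, eex, edel, ecorr, edas)
            )
            emp2_totals[li] += eel_mtp + eel_pen + eex + edel + ecorr

    sigma_e = _emp2_population_sd(spec)
    lo, hi = spec.activity_range
    slope = -(hi - lo) / (4.0 * sigma_e)  # +/-2 sigma of energy spans the range
    noise_sd = abs(slope) * sigma_e * math.sqrt(1.0 / spec.target_r**2 - 1.0)
    if noise_sd < spec.noise_floor:
        raise ValueError(
            f"target_r={spec.target_r} needs noise SD {noise_sd:.3g} below the "
            f"declared floor {spec.noise_floor:.3g}"
        )
    center = 0.5 * (lo + hi)
    mean_e = float(np.mean(emp2_totals))
    pic50 = center + slope * (emp2_totals - mean_e) + rng.normal(0.0, noise_sd, spec.n_ligands)
    pic50 = np.maximum(pic50, 0.01)  # potency scale is positive by definition
    if spec.round_activities is not None:
        pic50 = np.round(pic50, spec.round_activities)
    if spec.tie_pair is not None:
        i, j = spec.tie_pair
        pic50[j] = pic50[i]
    activities = [
        ActivityRecord(lid, f"syn-{lid}", float(p)) for lid, p in zip(ids, pic50)
    ]

    dg = rng.normal(-67.0, spec.solvation_sd, spec.n_ligands)
    nonel = rng.uniform(5.0, 8.0, spec.n_ligands)
    solvation = []
    for lid, g, ne in zip(ids, dg, nonel):
        el = float(g) - float(ne)
        # store the recomposed sum so the additivity invariant is exact
        solvation.append(SolvationRecord(lid, el + float(ne), el, float(ne)))
    return terms, activities, solvation


def reference_series_spec(seed: int = 0) -> SeriesSpec:
    """Preset mirroring the study's dimensions: 15 ligands, the four
    binding-site residue groups, activities printed at two decimals with
    one exact experimental tie."""
    return SeriesSpec(
        n_ligands=15,
        seed=seed,
        round_activities=2,
        tie_pair=(7, 8),
    )


# ---------------------------------------------------------------------------
# Toy complexes for the physics core
# ---------------------------------------------------------------------------

_TOY_ELEMENTS = ("C", "N", "O", "H")

#: Homo-atomic C6 (kcal/mol A^6) and damping beta (1/A) used by the toy
#: generator; hetero pairs via the geometric combining rule.
TOY_DISPERSION = DispersionParams(
    c6={
        frozenset(("C",)): 30.0,
        frozenset(("N",)): 20.0,
        frozenset(("O",)): 15.0,
        frozenset(("H",)): 2.5,
    },
    damping_beta={
        frozenset(("C",)): 1.8,
        frozenset(("N",)): 1.9,
        frozenset(("O",)): 2.0,
        frozenset(("H",)): 2.2,
    },
    combining_rule="geometric",
)


def _random_sites(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    spread: float,
    net_charge: float,
) -> tuple[MultipoleSite, ...]:
    pos = center + rng.uniform(-spread, spread, size=(n, 3))
    # enforce minimal intra-molecular separation by jittered grid offsets
    for i in range(1, n):
        while np.linalg.norm(pos[i] - pos[:i], axis=1).min() < 0.8:
            pos[i] = center + rng.uniform(-spread, spread, 3)
    charges = rng.normal(0.0, 0.15, n)
    charges += (net_charge - charges.sum()) / n
    sites = []
    for i in range(n):
        quad = rng.normal(0.0, 0.05, (3, 3))
        quad = detrace_quadrupole((quad + quad.T) / 2.0)
        sites.append(
            MultipoleSite(
                element=str(rng.choice(_TOY_ELEMENTS)),
                position=pos[i],
                charge=float(charges[i]),
                dipole=rng.normal(0.0, 0.05, 3),
                quadrupole=quad,
            )
        )
    return tuple(sites)


def generate_toy_complex(
    n_atoms_ligand: int = 6,
    n_residues: int = 4,
    seed: int = 0,
    separation: float = 5.0,
) -> tuple[Molecule, list[Molecule], DispersionParams, dict[str, tuple[str, ...]]]:
    """Random non-overlapping ligand/binding-site geometry with multipoles.

    The ligand carries net charge -1; the first residue carries +1 (the
    salt-bridge partner) and the rest are neutral.  Residue centers sit
    on random directions at ``separation`` (+/-1 A) from the ligand
    center.  Returns (ligand, residues, dispersion parameters, grouping
    with one group per residue); deterministic for a given seed.
    """
    if n_atoms_ligand < 1:
        raise ValueError("ligand needs at least one atom")
    rng = np.random.default_rng(seed)
    ligand = Molecule(
        "ligand", _random_sites(rng, n_atoms_ligand, np.zeros(3), 1.5, -1.0)
    )
    residues = []
    for ri in range(n_residues):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = direction * (separation + rng.uniform(-1.0, 1.0))
        net = 1.0 if ri == 0 else 0.0
        name = f"Res{ri + 1}{'+' if net else ''}"
        residues.append(Molecule(name, _random_sites(rng, 3, center, 1.0, net)))
    groups = {m.name: (m.name,) for m in residues}
    return ligand, residues, TOY_DISPERSION, groups
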