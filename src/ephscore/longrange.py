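"""Long-range interaction terms from molecular geometry.

The two ingredients of the cheap composite score are computed here:

* ``mtp_electrostatics`` — first-order electrostatic energy from
  atom-centered (cumulative) multipole moments, truncated so that only
  multipole-pair terms with overall distance dependence R^-1 ... R^-4
  are retained (charge-charge through dipole-quadrupole and
  charge-octopole).

* ``das_dispersion`` — approximate dispersion from damped atom-atom
  C6 (optionally C8) potentials with Tang-Toennies damping.

Multipoles follow the traceless (Buckingham) convention.  Units at the
interface are Angstrom and elementary charge; energies are kcal/mol with
the Coulomb constant fixed at 332.06 kcal mol^-1 A e^-2 so that numeric
tests are bit-stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "COULOMB_CONSTANT",
    "MultipoleSite",
    "DispersionParams",
    "Molecule",
    "detrace_quadrupole",
    "detrace_octopole",
    "mtp_electrostatics",
    "das_dispersion",
    "score_complex",
    "read_xyz",
    "read_pdb_residues",
    "read_multipole_json",
    "read_dispersion_params",
]

#: kcal mol^-1 Angstrom e^-2; common molecular-mechanics convention.
COULOMB_CONSTANT = 332.06

_TRACE_TOL = 1e-9


def detrace_quadrupole(primitive: np.ndarray) -> np.ndarray:
    """Convert a primitive second moment sum(q r r) to Buckingham form.

    Theta_ab = (3 M_ab - tr(M) delta_ab) / 2.
    """
    m = np.asarray(primitive, dtype=float)
    return (3.0 * m - np.trace(m) * np.eye(3)) / 2.0


def detrace_octopole(primitive: np.ndarray) -> np.ndarray:
    """Convert a primitive third moment sum(q r r r) to Buckingham form.

    Omega_abc = (5 M_abc - (s_a d_bc + s_b d_ac + s_c d_ab)) / 2 with
    s_a = sum_b M_abb the partial trace.
    """
    m = np.asarray(primitive, dtype=float)
    s = np.einsum("abb->a", m)
    d = np.eye(3)
    corr = (
        np.einsum("a,bc->abc", s, d)
        + np.einsum("b,ac->abc", s, d)
        + np.einsum("c,ab->abc", s, d)
    )
    return (5.0 * m - corr) / 2.0


@dataclass(frozen=True)
class MultipoleSite:
    """Atom-centered traceless multipoles: charge (e), dipole (e A),
    quadrupole (e A^2), optional octopole (e A^3)."""

    element: str
    position: np.ndarray
    charge: float = 0.0
    dipole: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quadrupole: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    octopole: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "dipole", np.asarray(self.dipole, dtype=float))
        q = np.asarray(self.quadrupole, dtype=float)
        object.__setattr__(self, "quadrupole", q)
        if abs(np.trace(q)) > _TRACE_TOL:
            raise ValueError(f"quadrupole trace {np.trace(q):.3g} exceeds {_TRACE_TOL}")
        if self.octopole is not None:
            o = np.asarray(self.octopole, dtype=float)
            object.__setattr__(self, "octopole", o)
            for ax in ("abb->a", "bab->a", "bba->a"):
                if np.abs(np.einsum(ax, o)).max() > _TRACE_TOL:
                    raise ValueError("octopole partial trace exceeds tolerance")


@dataclass(frozen=True)
class Molecule:
    """A geometry with optional multipoles, used by :func:`score_complex`."""

    name: str
    sites: tuple[MultipoleSite, ...]

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])


@dataclass(frozen=True)
class DispersionParams:
    """Damped atom-atom dispersion parameters keyed by unordered element pair.

    ``c6`` in kcal mol^-1 A^6, optional ``c8`` in kcal mol^-1 A^8,
    ``damping_beta`` in A^-1.  ``combining_rule="geometric"`` fills a
    missing pair from the homo-atomic entries (geometric mean of C6/C8,
    arithmetic mean of beta); the default is to reject missing pairs.
    """

    c6: Mapping[frozenset, float]
    damping_beta: Mapping[frozenset, float]
    c8: Mapping[frozenset, float] | None = None
    combining_rule: str | None = None

    def __post_init__(self) -> None:
        for pair, v in self.c6.items():
            if v < 0:
                raise ValueError(f"C6 must be non-negative for pair {set(pair)}")
        for pair, v in self.damping_beta.items():
            if not v > 0:
                raise ValueError(f"damping beta must be positive for pair {set(pair)}")
        if self.combining_rule not in (None, "geometric"):
            raise ValueError(f"unknown combining rule {self.combining_rule!r}")

    def lookup(self, el_a: str, el_b: str) -> tuple[float, float | None, float]:
        pair = frozenset((el_a, el_b))
        if pair in self.c6:
            c8 = self.c8.get(pair) if self.c8 else None
            return self.c6[pair], c8, self.damping_beta[pair]
        if self.combining_rule == "geometric":
            pa, pb = frozenset((el_a,)), frozenset((el_b,))
            if pa in self.c6 and pb in self.c6:
                c6 = math.sqrt(self.c6[pa] * self.c6[pb])
                c8 = None
                if self.c8 and pa in self.c8 and pb in self.c8:
                    c8 = math.sqrt(self.c8[pa] * self.c8[pb])
                beta = 0.5 * (self.damping_beta[pa] + self.damping_beta[pb])
                return c6, c8, beta
        raise KeyError(f"no dispersion parameters for element pair {el_a}-{el_b}")


# ---------------------------------------------------------------------------
# Multipole electrostatics
# ---------------------------------------------------------------------------
#
# Interaction tensors D_n = grad^n (1/R).  The energy of traceless
# multipoles M^A (rank la) and M^B (rank lb) separated by R = r_B - r_A is
#
#   U = k (-1)^la C_la C_lb  M^A (x) M^B : D_{la+lb}(R),
#
# with C = (1, 1, 1/3, 1/15) for charge, dipole, quadrupole, octopole.
# The overall distance dependence of the (la, lb) term is R^-(la+lb+1),
# which is what the truncation order selects on.

_C_COEF = (1.0, 1.0, 1.0 / 3.0, 1.0 / 15.0)


def _d_tensors(rvec: np.ndarray, max_rank: int) -> list[np.ndarray]:
    r2 = float(rvec @ rvec)
    r = math.sqrt(r2)
    d = [np.array(1.0 / r)]
    if max_rank >= 1:
        d.append(-rvec / r**3)
    if max_rank >= 2:
        d.append((3.0 * np.outer(rvec, rvec) - r2 * np.eye(3)) / r**5)
    if max_rank >= 3:
        eye = np.eye(3)
        rrr = np.einsum("a,b,c->abc", rvec, rvec, rvec)
        sym = (
            np.einsum("a,bc->abc", rvec, eye)
            + np.einsum("b,ac->abc", rvec, eye)
            + np.einsum("c,ab->abc", rvec, eye)
        )
        d.append(-(15.0 * rrr - 3.0 * r2 * sym) / r**7)
    return d


def _site_moments(site: MultipoleSite) -> list[np.ndarray | None]:
    oct_ = site.octopole
    return [
        np.array(site.charge),
        site.dipole,
        site.quadrupole,
        oct_ if oct_ is not None else None,
    ]


def _contract(ma: np.ndarray, mb: np.ndarray, d: np.ndarray, la: int, lb: int) -> float:
    # D is fully symmetric: feed A's indices first, B's after.
    letters = "abcd"
    ia, ib = letters[:la], letters[la : la + lb]
    spec = f"{ia},{ib},{ia + ib}->" if (la or lb) else ",,->"
    return float(np.einsum(spec, ma, mb, d))


def mtp_electrostatics(
    sites_a: Sequence[MultipoleSite],
    sites_b: Sequence[MultipoleSite],
    max_inverse_power: int = 4,
    include_octopole: bool = True,
) -> float:
    """Multipole electrostatic interaction energy (kcal/mol).

    Sums, over all inter-molecular site pairs, every multipole-pair term
    whose overall distance dependence is R^-1 ... R^-max_inverse_power.
    Symmetric under exchange of the two molecules.  ``include_octopole``
    controls whether charge-octopole terms enter at R^-4 (the maximum
    site rank of the expansion is a modelling choice).
    """
    if max_inverse_power not in (1, 2, 3, 4):
        raise ValueError("max_inverse_power must be in {1, 2, 3, 4}")
    energy = 0.0
    for sa in sites_a:
        ma = _site_moments(sa)
        for sb in sites_b:
            rvec = sb.position - sa.position
            if float(rvec @ rvec) < 1e-20:
                raise ValueError(
                    f"coincident sites: {sa.element} and {sb.element} overlap"
                )
            mb = _site_moments(sb)
            d = _d_tensors(rvec, min(3, max_inverse_power - 1))
            for la in range(4):
                if ma[la] is None:
                    continue
                for lb in range(4):
                    if mb[lb] is None:
                        continue
                    if la + lb + 1 > max_inverse_power:
                        continue
                    if not include_octopole and 3 in (la, lb):
                        continue
                    term = (
                        (-1.0) ** la
                        * _C_COEF[la]
                        * _C_COEF[lb]
                        * _contract(ma[la], mb[lb], d[la + lb], la, lb)
                    )
                    energy += term
    return COULOMB_CONSTANT * energy


# ---------------------------------------------------------------------------
# Damped atom-atom dispersion
# ---------------------------------------------------------------------------


def _tang_toennies(n: int, x: float) -> float:
    """Damping f_n(x) = 1 - exp(-x) sum_{k=0..n} x^k / k!."""
    s = 0.0
    term = 1.0
    for k in range(n + 1):
        if k > 0:
            term *= x / k
        s += term
    return 1.0 - math.exp(-x) * s


def das_dispersion(
    coords_a: Sequence[tuple[str, np.ndarray]],
    coords_b: Sequence[tuple[str, np.ndarray]],
    params: DispersionParams,
) -> float:
    """Approximate dispersion energy E_Das (kcal/mol), always <= 0.

    Sum over inter-molecular atom pairs of
    -f6(beta R) C6 / R^6 [- f8(beta R) C8 / R^8], with Tang-Toennies
    damping factors f_n; vanishes as all separations grow.
    """
    energy = 0.0
    for el_a, ra in coords_a:
        ra = np.asarray(ra, dtype=float)
        for el_b, rb in coords_b:
            c6, c8, beta = params.lookup(el_a, el_b)
            r = float(np.linalg.norm(np.asarray(rb, dtype=float) - ra))
            if r < 1e-10:
                raise ValueError(f"coincident atoms {el_a}/{el_b}")
            x = beta * r
            energy -= _tang_toennies(6, x) * c6 / r**6
            if c8 is not None:
                energy -= _tang_toennies(8, x) * c8 / r**8
    return energy


# ---------------------------------------------------------------------------
# Complex scoring
# ---------------------------------------------------------------------------


def score_complex(
    ligand: Molecule,
    binding_site: Sequence[Molecule],
    params: DispersionParams,
    groups: Mapping[str, Sequence[str]] | None = None,
    max_inverse_power: int = 4,
) -> dict:
    """Per-residue-group long-range terms for a ligand in a binding site.

    Returns ``{"groups": {group: {"eel_mtp": .., "edas": ..}},
    "totals": {"eel_mtp": .., "edas": .., "eelmtp_plus_edas": ..}}``.
    Each residue must belong to exactly one group; when ``groups`` is
    omitted every residue forms its own group.  Totals are exact sums of
    the per-group values and can feed the decomposition ledger as the
    composite-score source.
    """
    residues = {m.name: m for m in binding_site}
    if len(residues) != len(binding_site):
        raise ValueError("duplicate residue names in binding site")
    if groups is None:
        groups = {name: (name,) for name in residues}
    seen: dict[str, str] = {}
    for gname, members in groups.items():
        for res in members:
            if res not in residues:
                raise ValueError(f"group {gname!r} references unknown residue {res!r}")
            if res in seen:
                raise ValueError(
                    f"residue {res!r} assigned to both {seen[res]!r} and {gname!r}"
                )
            seen[res] = gname
    missing = set(residues) - set(seen)
    if missing:
        raise ValueError(f"residues not assigned to any group: {sorted(missing)}")

    lig_coords = [(s.element, s.position) for s in ligand.sites]
    out: dict[str, dict[str, float]] = {}
    for gname, members in groups.items():
        eel = 0.0
        das = 0.0
        for res in members:
            mol = residues[res]
            eel += mtp_electrostatics(ligand.sites, mol.sites, max_inverse_power)
            das += das_dispersion(
                lig_coords, [(s.element, s.position) for s in mol.sites], params
            )
        out[gname] = {"eel_mtp": eel, "edas": das}

    tot_eel = sum(g["eel_mtp"] for g in out.values())
    tot_das = sum(g["edas"] for g in out.values())
    return {
        "groups": out,
        "totals": {
            "eel_mtp": tot_eel,
            "edas": tot_das,
            "eelmtp_plus_edas": tot_eel + tot_das,
        },
    }


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read an XYZ file: element symbol + Cartesian coordinates in A."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    atoms = []
    for line in lines[2 : 2 + n]:
        el, x, y, z = line.split()[:4]
        atoms.append((el, np.array([float(x), float(y), float(z)])))
    if len(atoms) != n:
        raise ValueError(f"XYZ header promised {n} atoms, found {len(atoms)}")
    return atoms


def read_pdb_residues(path: str | Path) -> dict[str, list[tuple[str, np.ndarray]]]:
    """Minimal PDB reader: ATOM/HETATM records grouped by residue.

    Keys are ``<resName><resSeq>`` (1-based residue numbering as in the
    PDB standard); values are (element, position) lists.  The element is
    taken from columns 77-78 when present, else inferred from the atom
    name.
    """
    residues: dict[str, list[tuple[str, np.ndarray]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        resname = line[17:20].strip()
        resseq = line[22:26].strip()
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = "".join(c for c in line[12:16].strip() if c.isalpha())[:1]
        key = f"{resname}{resseq}"
        residues.setdefault(key, []).append((element, np.array([x, y, z])))
    return residues


def read_multipole_json(path: str | Path, name: str = "molecule") -> Molecule:
    """Read multipole sites from JSON.

    Schema: ``{"sites": [{"element", "xyz", "q", "mu", "theta",
    "omega"?}]}`` with ``theta`` a traceless 3x3 and ``omega`` an
    optional traceless rank-3 tensor (nested lists).
    """
    doc = json.loads(Path(path).read_text())
    sites = []
    for s in doc["sites"]:
        sites.append(
            MultipoleSite(
                element=s["element"],
                position=np.array(s["xyz"], dtype=float),
                charge=float(s.get("q", 0.0)),
                dipole=np.array(s.get("mu", [0.0, 0.0, 0.0]), dtype=float),
                quadrupole=np.array(s.get("theta", np.zeros((3, 3))), dtype=float),
                octopole=(
                    np.array(s["omega"], dtype=float) if "omega" in s else None
                ),
            )
        )
    return Molecule(name=name, sites=tuple(sites))


def read_dispersion_params(path: str | Path) -> DispersionParams:
    """Read dispersion parameters from YAML or JSON.

    Schema: ``{"pairs": {"C-C": {"c6": .., "beta": .., "c8"?: ..}},
    "combining_rule"?: "geometric"}``; pair keys are unordered
    ``EL1-EL2`` strings (single elements for homo-atomic entries used by
    the combining rule).
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    c6, c8, beta = {}, {}, {}
    for key, entry in doc["pairs"].items():
        pair = frozenset(key.split("-"))
        c6[pair] = float(entry["c6"])
        beta[pair] = float(entry["beta"])
        if "c8" in entry:
            c8[pair] = float(entry["c8"])
    return DispersionParams(
        c6=c6,
        damping_beta=beta,
        c8=c8 or None,
        combining_rule=doc.get("combining_rule"),
    )
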