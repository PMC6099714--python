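"""Physics core: multipole electrostatics and damped dispersion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ephscore import (
    COULOMB_CONSTANT,
    DispersionParams,
    Molecule,
    MultipoleSite,
    das_dispersion,
    detrace_octopole,
    detrace_quadrupole,
    mtp_electrostatics,
    score_complex,
)
from ephscore.longrange import _tang_toennies


def charge(el, pos, q):
    return MultipoleSite(el, np.asarray(pos, dtype=float), charge=q)


def coulomb_sum(sites_a, sites_b):
    """Brute-force pairwise Coulomb oracle."""
    e = 0.0
    for a in sites_a:
        for b in sites_b:
            e += a.charge * b.charge / np.linalg.norm(b.position - a.position)
    return COULOMB_CONSTANT * e


def random_cloud(rng, n, center, net=None):
    pos = center + rng.uniform(-1, 1, (n, 3))
    q = rng.normal(0, 0.5, n)
    if net is not None:
        q += (net - q.sum()) / n
    return [charge("C", p, float(c)) for p, c in zip(pos, q)]


class TestMtpElectrostatics:
    def test_two_unit_charges_coulomb_law(self):
        e = mtp_electrostatics([charge("X", [0, 0, 0], 1.0)],
                               [charge("Y", [0, 0, 3.32], -1.0)], 1)
        assert e == pytest.approx(-COULOMB_CONSTANT / 3.32, rel=1e-12)
        assert e == pytest.approx(-100.0, abs=0.1)

    def test_exchange_symmetry(self):
        rng = np.random.default_rng(3)
        quad = detrace_quadrupole(np.diag([0.1, -0.05, 0.2]))
        a = [MultipoleSite("C", [0.0, 0, 0], charge=0.4, dipole=[0.1, 0, -0.1],
                           quadrupole=quad)]
        b = [MultipoleSite("N", [1.0, 2, 2], charge=-0.3, dipole=[0, 0.2, 0],
                           quadrupole=-quad)]
        assert mtp_electrostatics(a, b, 4) == pytest.approx(
            mtp_electrostatics(b, a, 4), rel=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_charge_only_clouds_reduce_to_coulomb(self, seed):
        """With all higher moments zero, the truncated expansion at any
        order equals the direct pairwise Coulomb sum."""
        rng = np.random.default_rng(seed)
        a = random_cloud(rng, 4, np.zeros(3))
        b = random_cloud(rng, 5, np.array([0.0, 0.0, 6.0]))
        want = coulomb_sum(a, b)
        for power in (1, 2, 3, 4):
            assert mtp_electrostatics(a, b, power) == pytest.approx(want, rel=1e-12)

    def test_point_dipole_is_small_separation_limit(self):
        """A dipole modelled as +/-q at separation d converges to the
        exact point-dipole energy with error O(d^2)."""
        mu = np.array([0.05, -0.02, 0.03])
        probe = [charge("Y", [4.0, 1.0, 2.0], 0.7)]
        exact = mtp_electrostatics(
            [MultipoleSite("X", np.zeros(3), dipole=mu)], probe, 4)
        errs = []
        for d in (0.2, 0.1, 0.05):
            u = mu / np.linalg.norm(mu)
            q = np.linalg.norm(mu) / d
            pair = [charge("X", u * d / 2, q), charge("X", -u * d / 2, -q)]
            errs.append(abs(mtp_electrostatics(pair, probe, 4) - exact))
        # halving d should quarter the error
        assert errs[1] == pytest.approx(errs[0] / 4, rel=0.05)
        assert errs[2] == pytest.approx(errs[1] / 4, rel=0.05)

    def test_traceless_expansion_matches_point_cloud(self):
        """Charge+dipole+quadrupole+octopole of a compact cloud reproduce
        the cloud's Coulomb interaction with a distant probe."""
        rng = np.random.default_rng(1)
        pos = rng.normal(0, 0.05, (4, 3))
        q = rng.normal(0, 1, 4)
        cloud = [charge("X", p, float(c)) for p, c in zip(pos, q)]
        m2 = np.einsum("i,ia,ib->ab", q, pos, pos)
        m3 = np.einsum("i,ia,ib,ic->abc", q, pos, pos, pos)
        expansion = [MultipoleSite(
            "X", np.zeros(3), charge=float(q.sum()),
            dipole=(q[:, None] * pos).sum(0),
            quadrupole=detrace_quadrupole(m2),
            octopole=detrace_octopole(m3),
        )]
        probe = [charge("Y", [5.0, -2.0, 3.0], 1.0)]
        assert mtp_electrostatics(expansion, probe, 4) == pytest.approx(
            coulomb_sum(cloud, probe), rel=1e-4
        )

    def test_rotational_invariance(self):
        """Rigidly rotating both molecules together leaves the energy
        unchanged."""
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(7)
        rot = Rotation.random(random_state=5).as_matrix()

        def make(center):
            quad = rng.normal(0, 0.1, (3, 3))
            quad = detrace_quadrupole((quad + quad.T) / 2)
            return MultipoleSite("C", center + rng.uniform(-1, 1, 3),
                                 charge=float(rng.normal(0, 0.3)),
                                 dipole=rng.normal(0, 0.1, 3), quadrupole=quad)

        def rotate(s):
            return MultipoleSite(s.element, rot @ s.position, s.charge,
                                 rot @ s.dipole, rot @ s.quadrupole @ rot.T)

        a = [make(np.zeros(3)) for _ in range(3)]
        b = [make(np.array([0.0, 0.0, 7.0])) for _ in range(3)]
        e1 = mtp_electrostatics(a, b, 4)
        e2 = mtp_electrostatics([rotate(s) for s in a], [rotate(s) for s in b], 4)
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_truncation_refinement_on_separated_systems(self):
        """Raising the truncation order from R^-2 to R^-4 moves the
        expansion closer to the exact point-cloud energy."""
        rng = np.random.default_rng(11)
        pos = rng.normal(0, 0.3, (5, 3))
        q = rng.normal(0, 0.5, 5)
        cloud = [charge("X", p, float(c)) for p, c in zip(pos, q)]
        m2 = np.einsum("i,ia,ib->ab", q, pos, pos)
        m3 = np.einsum("i,ia,ib,ic->abc", q, pos, pos, pos)
        expansion = [MultipoleSite(
            "X", np.zeros(3), charge=float(q.sum()),
            dipole=(q[:, None] * pos).sum(0),
            quadrupole=detrace_quadrupole(m2), octopole=detrace_octopole(m3))]
        probe = random_cloud(rng, 4, np.array([0.0, 0.0, 9.0]), net=0.8)
        exact = coulomb_sum(cloud, probe)
        err2 = abs(mtp_electrostatics(expansion, probe, 2) - exact)
        err4 = abs(mtp_electrostatics(expansion, probe, 4) - exact)
        assert err4 <= err2

    def test_coincident_sites_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            mtp_electrostatics([charge("X", [0, 0, 0], 1)],
                               [charge("Y", [0, 0, 0], -1)], 1)

    def test_invalid_truncation_rejected(self):
        a = [charge("X", [0, 0, 0], 1)]
        b = [charge("Y", [0, 0, 2], -1)]
        with pytest.raises(ValueError, match="max_inverse_power"):
            mtp_electrostatics(a, b, 5)

    def test_nontraceless_quadrupole_rejected(self):
        with pytest.raises(ValueError, match="trace"):
            MultipoleSite("X", np.zeros(3), quadrupole=np.eye(3))


class TestDasDispersion:
    params = DispersionParams(
        c6={frozenset(("C",)): 30.0, frozenset(("H",)): 2.5,
            frozenset(("C", "H")): 8.0},
        damping_beta={frozenset(("C",)): 1.8, frozenset(("H",)): 2.2,
                      frozenset(("C", "H")): 2.0},
    )

    def test_zero_c6_gives_zero(self):
        p = DispersionParams(c6={frozenset(("C",)): 0.0},
                             damping_beta={frozenset(("C",)): 1.0})
        e = das_dispersion([("C", np.zeros(3))], [("C", np.array([0, 0, 3.0]))], p)
        assert e == 0.0

    def test_undamped_asymptotic_limit(self):
        p = DispersionParams(c6={frozenset(("C",)): 1.0},
                             damping_beta={frozenset(("C",)): 1.0})
        e = das_dispersion([("C", np.zeros(3))], [("C", np.array([0, 0, 100.0]))], p)
        assert e == pytest.approx(-1e-12, rel=0.01)

    def test_matches_double_loop_reference(self):
        """Vector path equals an explicit pairwise reference with the
        Tang-Toennies closed form written out independently."""
        rng = np.random.default_rng(5)
        a = [("C" if i % 2 else "H", rng.uniform(-1.5, 1.5, 3)) for i in range(5)]
        b = [("H" if i % 2 else "C", np.array([0, 0, 4.5]) + rng.uniform(-1.5, 1.5, 3))
             for i in range(5)]
        ref = 0.0
        for el_a, ra in a:
            for el_b, rb in b:
                c6, _, beta = self.params.lookup(el_a, el_b)
                r = float(np.linalg.norm(rb - ra))
                x = beta * r
                f6 = 1.0 - math.exp(-x) * sum(x**k / math.factorial(k)
                                              for k in range(7))
                ref -= f6 * c6 / r**6
        assert das_dispersion(a, b, self.params) == pytest.approx(ref, rel=1e-12)

    def test_always_attractive_and_translation_invariant(self):
        rng = np.random.default_rng(9)
        a = [("C", rng.uniform(-1, 1, 3)) for _ in range(4)]
        b = [("C", np.array([0, 0, 5.0]) + rng.uniform(-1, 1, 3)) for _ in range(4)]
        e = das_dispersion(a, b, self.params)
        assert e < 0
        shift = np.array([3.0, -2.0, 1.0])
        e_shift = das_dispersion([(el, p + shift) for el, p in a],
                                 [(el, p + shift) for el, p in b], self.params)
        assert e_shift == pytest.approx(e, rel=1e-12)

    def test_monotone_decay_with_separation(self):
        """Scaling all inter-molecular distances up weakens the (already
        damped) attraction monotonically toward zero."""
        a = [("C", np.zeros(3))]
        energies = [das_dispersion(a, [("C", np.array([0, 0, d]))], self.params)
                    for d in (3.0, 4.0, 6.0, 9.0, 14.0)]
        assert all(e1 < e2 < 0 for e1, e2 in zip(energies, energies[1:]))

    def test_missing_pair_rejected_by_name(self):
        with pytest.raises(KeyError, match="C-O|O-C"):
            das_dispersion([("C", np.zeros(3))], [("O", np.array([0, 0, 3.0]))],
                           self.params)

    def test_geometric_combining_rule_fallback(self):
        p = DispersionParams(
            c6={frozenset(("C",)): 16.0, frozenset(("O",)): 4.0},
            damping_beta={frozenset(("C",)): 1.0, frozenset(("O",)): 3.0},
            combining_rule="geometric",
        )
        c6, c8, beta = p.lookup("C", "O")
        assert (c6, c8, beta) == (8.0, None, 2.0)

    def test_tang_toennies_limits(self):
        assert _tang_toennies(6, 0.0) == pytest.approx(0.0)
        assert _tang_toennies(6, 50.0) == pytest.approx(1.0)


class TestScoreComplex:
    def _one_residue(self):
        lig = Molecule("lig", (charge("C", [0, 0, 0], -1.0),))
        res = Molecule("Res1", (charge("N", [0, 0, 4.0], 1.0),))
        params = DispersionParams(c6={frozenset(("C", "N")): 10.0},
                                  damping_beta={frozenset(("C", "N")): 2.0})
        return lig, res, params

    def test_single_residue_equals_direct_computation(self):
        lig, res, params = self._one_residue()
        out = score_complex(lig, [res], params)
        direct_e = mtp_electrostatics(lig.sites, res.sites, 4)
        direct_d = das_dispersion([("C", np.zeros(3))], [("N", np.array([0, 0, 4.0]))],
                                  params)
        assert out["groups"]["Res1"]["eel_mtp"] == pytest.approx(direct_e)
        assert out["groups"]["Res1"]["edas"] == pytest.approx(direct_d)
        assert out["totals"]["eelmtp_plus_edas"] == pytest.approx(direct_e + direct_d)

    def test_duplicate_residue_across_groups_rejected(self):
        lig, res, params = self._one_residue()
        with pytest.raises(ValueError, match="assigned to both"):
            score_complex(lig, [res], params,
                          groups={"A": ("Res1",), "B": ("Res1",)})

    def test_unassigned_residue_rejected(self):
        lig, res, params = self._one_residue()
        res2 = Molecule("Res2", (charge("N", [0, 4.0, 0], 0.0),))
        with pytest.raises(ValueError, match="not assigned"):
            score_complex(lig, [res, res2], params, groups={"A": ("Res1",)})

    def test_totals_are_group_sums_and_charged_group_dominates(self):
        """A charged arginine-like residue dominates |E_el,MTP| against
        neutral groups at comparable distance."""
        rng = np.random.default_rng(2)
        lig = Molecule("lig", (charge("C", [0, 0, 0], -1.0),))
        residues, centers = [], [[4.5, 0, 0], [0, 4.5, 0], [0, 0, 4.5]]
        for i, c in enumerate(centers):
            q = 1.0 if i == 0 else 0.0
            name = "ArgLike" if i == 0 else f"Neutral{i}"
            residues.append(Molecule(name, (
                charge("N", np.asarray(c) + rng.normal(0, 0.1, 3), q),
            )))
        params = DispersionParams(c6={frozenset(("C", "N")): 10.0},
                                  damping_beta={frozenset(("C", "N")): 2.0})
        out = score_complex(lig, residues, params)
        groups = out["groups"]
        assert out["totals"]["eel_mtp"] == pytest.approx(
            sum(g["eel_mtp"] for g in groups.values()))
        assert max(groups, key=lambda g: abs(groups[g]["eel_mtp"])) == "ArgLike"
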