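"""Energy terms against closed forms and hand evaluation."""

import numpy as np
import pytest

from flexsaxs._kernels import COULOMB_KCAL
from flexsaxs.energy import (EnergyCalculator, EnergyModel, bonded_energy,
                             default_contact_matrix, load_contact_matrix,
                             membrane_energy, nonbonded_energy, total_energy)
from flexsaxs.topology import (Bead, ComplexTopology, Conformation,
                               LinkerChain, RigidBody)

from .conftest import make_two_body_toy, random_rigid_transform


def chain_topology(n, residue="G", charges=None):
    charges = charges if charges is not None else [0.0] * n
    beads = [Bead(i, residue, np.array([3.8 * i, 0.0, 0.0]), charges[i], "l0")
             for i in range(n)]
    return ComplexTopology(beads, [], [LinkerChain("l0", np.arange(n))])


class TestBonded:
    def test_relaxed_chain_is_zero(self):
        # straight chain at bond length: stretch 0; angles at 180 deg are
        # penalised unless angle_0 is pi, so set it so and kill torsion
        topo = chain_topology(6)
        model = EnergyModel(angle_0=np.pi, torsion_amp=0.0)
        conf = Conformation(topo.initial_coords())
        assert bonded_energy(conf, topo, model) == pytest.approx(0.0, abs=1e-18)

    def test_single_stretched_bond(self):
        topo = chain_topology(2)
        model = EnergyModel(bond_k=10.0, torsion_amp=0.0)
        coords = topo.initial_coords()
        coords[1, 0] += 1.0  # bond now b0 + 1
        assert bonded_energy(Conformation(coords), topo, model) == \
            pytest.approx(5.0)

    def test_random_chain_matches_per_term_oracle(self, rng):
        topo = chain_topology(6)
        model = EnergyModel(bond_k=7.0, angle_k=3.0, angle_0=1.9,
                            torsion_amp=0.4)
        coords = topo.initial_coords() + rng.normal(0, 1.0, (6, 3))

        def angle(a, b, c):
            v1, v2 = a - b, c - b
            cosv = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
            return np.arccos(np.clip(cosv, -1, 1))

        def dihedral(a, b, c, d):
            b1, b2, b3 = b - a, c - b, d - c
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            cosv = np.dot(n1, n2) / np.linalg.norm(n1) / np.linalg.norm(n2)
            return np.arccos(np.clip(cosv, -1, 1))

        expected = 0.0
        for i in range(5):
            b = np.linalg.norm(coords[i + 1] - coords[i])
            expected += 0.5 * 7.0 * (b - 3.8) ** 2
        for i in range(4):
            expected += 0.5 * 3.0 * (angle(coords[i], coords[i + 1],
                                           coords[i + 2]) - 1.9) ** 2
        for i in range(3):
            expected += 0.4 * (1 + np.cos(dihedral(*coords[i:i + 4])))
        got = bonded_energy(Conformation(coords), topo, model)
        assert got == pytest.approx(expected, rel=1e-10)


class TestNonbonded:
    def test_neutral_beads_beyond_contact_range(self):
        topo = make_two_body_toy(d_inter=10.0)
        model = EnergyModel(contact_range=6.5)
        conf = Conformation(topo.initial_coords())
        assert nonbonded_energy(conf, topo, model) == 0.0

    def test_screened_coulomb_closed_form(self):
        lam = 10.0
        topo = make_two_body_toy(d_inter=lam)
        for bead in topo.beads:
            bead.charge = 1.0
        model = EnergyModel(debye_length=lam, dielectric=80.0,
                            contact_matrix=np.zeros((20, 20)))
        conf = Conformation(topo.initial_coords())
        expected = COULOMB_KCAL / 80.0 * np.exp(-1.0) / lam
        assert nonbonded_energy(conf, topo, model) == pytest.approx(expected,
                                                                    rel=1e-12)

    def test_zero_charges_no_electrostatics(self):
        topo = make_two_body_toy(d_inter=5.0)
        model_plain = EnergyModel(contact_matrix=np.zeros((20, 20)))
        conf = Conformation(topo.initial_coords())
        # within contact range but zero matrix and zero charges -> only
        # possible term is repulsion; at 5.0 A > excluded radius it is 0
        assert nonbonded_energy(conf, topo, model_plain) == 0.0

    def test_doubling_charges_quadruples_electrostatics(self, rng):
        n = 8
        charges = rng.choice([-1.0, 0.0, 1.0], n)
        topo = chain_topology(n, charges=list(charges))
        coords = topo.initial_coords() + rng.normal(0, 2, (n, 3))
        model0 = EnergyModel(contact_matrix=np.zeros((20, 20)),
                             excluded_radius=1e-6, repulsion_k=0.0)
        e1 = nonbonded_energy(Conformation(coords), topo, model0)
        for bead in topo.beads:
            bead.charge *= 2
        e2 = nonbonded_energy(Conformation(coords), topo, model0)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_overlapping_beads_finite(self):
        topo = make_two_body_toy(d_inter=0.01)
        for bead in topo.beads:
            bead.charge = 1.0
        model = EnergyModel()
        e = nonbonded_energy(Conformation(topo.initial_coords()), topo, model)
        assert np.isfinite(e) and e > 0

    def test_same_body_pairs_excluded(self):
        beads = [Bead(0, "I", np.zeros(3), 0.0, "b0"),
                 Bead(1, "I", np.array([2.0, 0, 0]), 0.0, "b0")]
        body = RigidBody("b0", np.array([0, 1]),
                         np.array([[-1.0, 0, 0], [1.0, 0, 0]]))
        topo = ComplexTopology(beads, [body], [])
        assert nonbonded_energy(Conformation(topo.initial_coords()), topo,
                                EnergyModel()) == 0.0


class TestMembrane:
    def test_restraint_at_target_is_zero(self, single_bead_topology):
        topo = single_bead_topology
        topo.membrane_restraints.append((0, 20.0, 0.1))
        coords = np.array([[0.0, 0.0, 20.0]])
        model = EnergyModel(membrane_depths=np.zeros(20))
        assert membrane_energy(Conformation(coords), topo, model) == 0.0

    def test_restraint_displaced(self, single_bead_topology):
        topo = single_bead_topology
        topo.membrane_restraints = [(0, 20.0, 0.1)]
        coords = np.array([[0.0, 0.0, 25.0]])
        model = EnergyModel(membrane_depths=np.zeros(20))
        assert membrane_energy(Conformation(coords), topo, model) == \
            pytest.approx(0.5 * 0.1 * 25)

    def test_far_above_plane_no_terms(self, single_bead_topology):
        topo = single_bead_topology
        topo.membrane_restraints = []
        coords = np.array([[0.0, 0.0, 200.0]])
        assert membrane_energy(Conformation(coords), topo, EnergyModel()) == 0.0


class TestGlobalMotionInvariance:
    def test_solution_energy_invariant_under_rigid_motion(self, dumbbell, rng):
        topo, ref = dumbbell
        model = EnergyModel()
        e0 = total_energy(ref, topo, model)
        rot, shift = random_rigid_transform(rng)
        moved = ref.coords @ rot.T + shift
        e1 = total_energy(Conformation(moved), topo, model)
        assert e1 == pytest.approx(e0, abs=1e-6)

    def test_membrane_energy_invariant_under_xy_and_z_rotation(
            self, anchored_dumbbell, rng):
        topo, ref = anchored_dumbbell
        model = EnergyModel()
        e0 = total_energy(ref, topo, model, membrane=True)
        theta = rng.uniform(0, 2 * np.pi)
        rot_z = np.array([[np.cos(theta), -np.sin(theta), 0],
                          [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = ref.coords @ rot_z.T + np.array([17.0, -4.0, 0.0])
        e1 = total_energy(Conformation(moved), topo, model, membrane=True)
        assert e1 == pytest.approx(e0, abs=1e-6)


class TestModelValidation:
    def test_contact_matrix_symmetry_enforced(self):
        bad = default_contact_matrix()
        bad[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            EnergyModel(contact_matrix=bad)

    def test_contact_matrix_roundtrip(self, tmp_path):
        m = default_contact_matrix()
        path = tmp_path / "contacts.txt"
        np.savetxt(path, m)
        np.testing.assert_allclose(load_contact_matrix(path), m, atol=1e-12)

    def test_incremental_delta_matches_full_recompute(self, dumbbell, rng):
        topo, ref = dumbbell
        model = EnergyModel()
        calc = EnergyCalculator(topo, model, membrane=False)
        coords = np.ascontiguousarray(ref.coords)
        e0 = calc.total(coords)
        body = topo.rigid_bodies[1]
        moved_idx = np.asarray(body.bead_indices)
        new_moved = coords[moved_idx] + rng.normal(0, 2, 3)
        is_moved = np.zeros(topo.n_beads, dtype=bool)
        is_moved[moved_idx] = True
        d = calc.delta(coords, moved_idx, new_moved, is_moved)
        coords2 = coords.copy()
        coords2[moved_idx] = new_moved
        assert e0 + d == pytest.approx(calc.total(coords2), abs=1e-8)
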