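"""Pairwise nonbonded forces and punctual stress against brute-force oracles."""

import numpy as np
import pytest

from pocketdyn.errors import InputError
from pocketdyn.forces import (
    COULOMB_KE,
    NonbondedParams,
    pair_force,
    punctual_stress_frame,
    stress_profile,
    top_stressed,
)
from pocketdyn.model import Selection, Topology, Trajectory
from pocketdyn.synthetic import gen_state_switching_trajectory, gen_toy_complex


class TestPairForce:
    def test_lj_minimum_zero_force(self):
        sigma = 0.34
        r = 2 ** (1 / 6) * sigma
        f = pair_force([0, 0, 0], [r, 0, 0], 0, 0, sigma, sigma, 0.5, 0.5)
        assert np.linalg.norm(f) == pytest.approx(0.0, abs=1e-9)

    def test_unit_charges_at_one_nm(self):
        f = pair_force([1.0, 0, 0], [0, 0, 0], 1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        assert np.linalg.norm(f) == pytest.approx(COULOMB_KE)
        assert f[0] > 0  # repulsion pushes i away from j

    def test_newtons_third_law_exact(self, rng):
        for _ in range(20):
            ri, rj = rng.normal(size=3), rng.normal(size=3)
            args = rng.uniform(0.1, 0.5, 6)
            fij = pair_force(ri, rj, args[0], args[1], args[2], args[3],
                             args[4], args[5], cutoff=10.0)
            fji = pair_force(rj, ri, args[1], args[0], args[3], args[2],
                             args[5], args[4], cutoff=10.0)
            np.testing.assert_array_equal(fij, -fji)

    def test_beyond_cutoff_zero(self):
        f = pair_force([0, 0, 0], [2.0, 0, 0], 1.0, 1.0, 0.3, 0.3, 0.5, 0.5,
                       cutoff=1.2)
        assert np.all(f == 0.0)

    def test_coincident_atoms_singular(self):
        with pytest.raises(InputError):
            pair_force([0, 0, 0], [0, 0, 0], 1, 1, 0.3, 0.3, 0.5, 0.5)


def _random_fixture(rng, n_res=5, n_lig=4):
    x = np.concatenate([rng.normal(scale=0.4, size=(n_res, 3)),
                        rng.normal(scale=0.4, size=(n_lig, 3)) + 0.8])
    params = NonbondedParams(
        rng.uniform(-0.8, 0.8, n_res + n_lig),
        rng.uniform(0.25, 0.4, n_res + n_lig),
        rng.uniform(0.1, 1.0, n_res + n_lig),
        cutoff=1.2,
    )
    return x, params, Selection("res", np.arange(n_res)), \
        Selection("lig", np.arange(n_res, n_res + n_lig))


class TestPunctualStress:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            x, params, res, lig = _random_fixture(rng)
            fast = punctual_stress_frame(x, res, lig, params)
            slow = 0.0
            for i in res.atom_indices:
                for j in lig.atom_indices:
                    f = pair_force(
                        x[i], x[j], params.charge[i], params.charge[j],
                        params.sigma[i], params.sigma[j],
                        params.epsilon[i], params.epsilon[j], params.cutoff,
                    )
                    slow += np.linalg.norm(f)
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_beyond_cutoff_is_zero(self):
        x = np.array([[0, 0, 0], [5.0, 0, 0]])
        params = NonbondedParams([0.5, -0.5], [0.3, 0.3], [0.5, 0.5], cutoff=1.2)
        assert punctual_stress_frame(
            x, Selection("r", [0]), Selection("l", [1]), params) == 0.0

    def test_single_pair_reduction(self):
        x = np.array([[0, 0, 0], [0.5, 0, 0]])
        params = NonbondedParams([0.5, -0.5], [0.3, 0.32], [0.5, 0.4], cutoff=1.2)
        expected = np.linalg.norm(pair_force(
            x[0], x[1], 0.5, -0.5, 0.3, 0.32, 0.5, 0.4))
        assert punctual_stress_frame(
            x, Selection("r", [0]), Selection("l", [1]), params
        ) == pytest.approx(expected, rel=1e-14)

    def test_overlapping_selections_rejected(self):
        x = np.zeros((3, 3))
        params = NonbondedParams(np.zeros(3), np.full(3, 0.3), np.zeros(3))
        with pytest.raises(InputError):
            punctual_stress_frame(x, Selection("r", [0, 1]), Selection("l", [1, 2]), params)

    def test_distance_decay_monotone(self):
        """Pulling the ligand rigidly away never increases any stress once
        every pair is past the LJ minimum."""
        rng = np.random.default_rng(5)
        x, params, res, lig = _random_fixture(rng)
        sigma_max = params.sigma.max()
        start = 2 ** (1 / 6) * sigma_max + 0.1
        prev = np.inf
        for shift in np.linspace(start, 1.1, 8):
            moved = x.copy()
            moved[lig.atom_indices] = x[lig.atom_indices] + np.array([shift + 2.0, 0, 0])
            s = punctual_stress_frame(moved, res, lig, params)
            assert s <= prev + 1e-9
            prev = s


class TestStressProfile:
    def test_constant_geometry_aggregate(self, toy):
        traj = gen_state_switching_trajectory(toy, ["state0"] * 3,
                                              noise_sigma=0.0, seed=0)
        params = NonbondedParams.from_topology(toy.topology)
        prof = stress_profile([traj], toy.topology, params)
        one = stress_profile([traj.subset(np.array([0]))], toy.topology, params)
        np.testing.assert_allclose(prof.aggregate, one.aggregate, rtol=1e-12)

    def test_two_identical_trajectories_double(self, toy):
        traj = gen_state_switching_trajectory(toy, ["state1"] * 2,
                                              noise_sigma=0.0, seed=0)
        params = NonbondedParams.from_topology(toy.topology)
        single = stress_profile([traj], toy.topology, params)
        double = stress_profile([traj, traj], toy.topology, params)
        np.testing.assert_allclose(double.aggregate, 2 * single.aggregate, rtol=1e-12)

    def test_coulomb_quadratic_in_charge(self, toy):
        traj = gen_state_switching_trajectory(toy, ["state0"], noise_sigma=0.0, seed=0)
        q = np.array([a.partial_charge for a in toy.topology.atoms])
        zeros = np.zeros(toy.topology.n_atoms)
        p1 = NonbondedParams(q, zeros, zeros)
        p2 = NonbondedParams(2 * q, zeros, zeros)
        s1 = stress_profile([traj], toy.topology, p1)
        s2 = stress_profile([traj], toy.topology, p2)
        np.testing.assert_allclose(s2.aggregate, 4 * s1.aggregate, rtol=1e-12)

    def test_per_state_argmax_moves_between_secondary_structures(self, toy, three_state):
        """Carboxylate at the I33/G34/I35 backbone (state 0) stresses the
        betaB strand most; the rearranged poses (states 1/2) stress alphaB
        residues most."""
        schedule, traj = three_state
        sched = np.asarray(schedule)
        params = NonbondedParams.from_topology(toy.topology)
        argmax = {}
        for state in ("state0", "state1", "state2"):
            prof = stress_profile([traj], toy.topology, params, [sched == state])
            argmax[state] = top_stressed(prof, 1)[0][0][1]
        assert toy.ss_map[argmax["state0"]] == "betaB"
        assert toy.ss_map[argmax["state1"]] == "alphaB"
        assert toy.ss_map[argmax["state2"]] == "alphaB"


class TestTopStressed:
    def _profile(self, values):
        from pocketdyn.forces import StressProfile

        residues = [("RES", 10 + i) for i in range(len(values))]
        return StressProfile(residues, [], np.asarray(values, float))

    def test_ordering(self):
        top = top_stressed(self._profile([5.0, 3.0, 1.0]), 2)
        assert [t[1] for t in top] == [5.0, 3.0]

    def test_zero_profile_stable_order(self):
        top = top_stressed(self._profile([0.0, 0.0, 0.0]), 3)
        assert [t[0][1] for t in top] == [10, 11, 12]

    def test_n_exceeding_residues(self):
        assert len(top_stressed(self._profile([1.0]), 10)) == 1
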