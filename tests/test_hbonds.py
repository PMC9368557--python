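"""Break rule, state classification, dissociation and distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocketdyn.errors import InputError
from pocketdyn.hbonds import (
    BondStateSeries,
    HBondPair,
    assign_states,
    build_canonical_pairs,
    classify_bond,
    dissociation_scan,
    distance_distribution,
    min_distance_series,
    pair_distance_series,
)
from pocketdyn.model import Selection, Trajectory


def _traj(*frames):
    return Trajectory(np.asarray(frames, dtype=float))


class TestPairDistance:
    def test_single_ligand_atom(self):
        t = _traj([[0, 0, 0], [0.3, 0, 0]])
        pair = HBondPair("p", 0, [1])
        s = pair_distance_series(t, pair)
        assert s.distances[0] == pytest.approx(0.3)
        assert s.formed[0]

    def test_min_over_equivalent_oxygens(self):
        t = _traj([[0, 0, 0], [0.7, 0, 0], [0.4, 0, 0]])
        s = pair_distance_series(t, HBondPair("p", 0, [1, 2]))
        assert s.distances[0] == pytest.approx(0.4)
        assert s.formed[0]

    def test_beyond_half_nanometre_is_broken(self):
        t = _traj([[0, 0, 0], [0.62, 0, 0]])
        s = pair_distance_series(t, HBondPair("p", 0, [1]))
        assert not s.formed[0]


class TestBreakRule:
    @pytest.mark.parametrize(
        "d,expected", [(0.30, "formed"), (0.50, "formed"), (0.51, "broken")]
    )
    def test_boundary(self, d, expected):
        assert classify_bond(d) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            classify_bond(-0.1)

    @given(st.floats(0, 5, allow_nan=False), st.floats(0.01, 2))
    @settings(max_examples=50, derandomize=True)
    def test_consistent_with_threshold(self, d, thr):
        assert (classify_bond(d, thr) == "broken") == (d > thr)


def _series(pattern):
    """BondStateSeries list for one frame from a 5-tuple over the canonical
    pairs (I33c, G34c, I35c, I37c, I37k)."""
    labels = ["I33-carboxyl", "G34-carboxyl", "I35-carboxyl",
              "I37-carboxyl", "I37-ketone"]
    out = []
    for lab, formed in zip(labels, pattern):
        d = np.array([0.3 if formed else 0.9])
        out.append(BondStateSeries(lab, d, d <= 0.5, 0.5))
    return out


class TestStateAssignment:
    @pytest.mark.parametrize(
        "pattern,state",
        [
            ((1, 1, 1, 0, 0), "state0"),
            ((1, 1, 0, 0, 0), "state0"),  # 2-of-3 rule
            ((0, 0, 0, 0, 1), "state1"),
            ((0, 0, 0, 1, 0), "state2"),
            ((0, 0, 0, 1, 1), "state1"),  # ketone precedence
            ((0, 0, 0, 0, 0), "unassigned"),
            ((1, 0, 0, 0, 0), "unassigned"),  # one bond is not enough
            ((1, 1, 1, 1, 0), "state2"),  # I37 formed vetoes state0
        ],
    )
    def test_patterns(self, pattern, state):
        assert assign_states(_series(pattern)).labels == [state]

    def test_dissociation_precedence(self):
        a = assign_states(_series((1, 1, 1, 0, 0)), np.array([True]))
        assert a.labels == ["dissociated"]

    def test_missing_pair_named(self):
        with pytest.raises(InputError, match="I37-ketone"):
            assign_states(_series((1, 1, 1, 0, 0))[:4])

    def test_fractions_sum_to_one(self, toy, three_state):
        schedule, traj = three_state
        pairs = build_canonical_pairs(toy.topology, toy.groups)
        a = assign_states([pair_distance_series(traj, p) for p in pairs])
        assert sum(a.fractions.values()) == pytest.approx(1.0, abs=0)

    def test_recovers_planted_schedule(self, toy, three_state):
        schedule, traj = three_state
        pairs = build_canonical_pairs(toy.topology, toy.groups)
        a = assign_states([pair_distance_series(traj, p) for p in pairs])
        assert a.labels == schedule


class TestDissociation:
    def _traj_at(self, distances):
        return Trajectory(
            np.array([[[0, 0, 0], [d, 0, 0]] for d in distances], dtype=float)
        )

    def test_bound_throughout(self):
        t = self._traj_at([0.4] * 20)
        flags, first = dissociation_scan(
            t, Selection("l", [1]), Selection("p", [0]), cutoff=0.8, window=1
        )
        assert first is None and not flags.any()

    def test_step_exit_frame(self):
        t = self._traj_at([0.4] * 10 + [2.0] * 10)
        flags, first = dissociation_scan(
            t, Selection("l", [1]), Selection("p", [0]), cutoff=0.8, window=1
        )
        assert first == 10
        assert flags[10:].all() and not flags[:10].any()

    def test_single_spike_not_sustained(self):
        t = self._traj_at([0.4] * 10 + [2.0] + [0.4] * 10)
        flags, first = dissociation_scan(
            t, Selection("l", [1]), Selection("p", [0]), cutoff=0.8, window=5
        )
        assert first is None and not flags.any()

    def test_reentry(self):
        t = self._traj_at([2.0] * 10 + [0.4] * 10)
        flags, first = dissociation_scan(
            t, Selection("l", [1]), Selection("p", [0]), cutoff=0.8, window=3
        )
        assert first == 0
        assert flags[:10].all() and not flags[10:].any()


class TestMinDistance:
    def test_minimum_and_symmetry(self):
        t = _traj([[0, 0, 0], [1.0, 0, 0], [0.2, 0, 0]])
        a, b = Selection("a", [0]), Selection("b", [1, 2])
        assert min_distance_series(t, a, b)[0] == pytest.approx(0.2)
        np.testing.assert_allclose(
            min_distance_series(t, a, b), min_distance_series(t, b, a)
        )

    def test_overlap_rejected(self):
        t = _traj([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(InputError):
            min_distance_series(t, Selection("a", [0, 1]), Selection("b", [1]))

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(3, 20, 3))
        t = Trajectory(x)
        a = Selection("a", np.arange(10))
        b = Selection("b", np.arange(10, 20))
        fast = min_distance_series(t, a, b)
        for f in range(3):
            slow = min(
                np.linalg.norm(x[f, i] - x[f, j])
                for i in range(10)
                for j in range(10, 20)
            )
            assert fast[f] == pytest.approx(slow, rel=1e-12)


class TestDistributions:
    def test_gaussian_sample_unimodal(self, rng):
        d = distance_distribution(rng.normal(0.3, 0.02, 10_000))
        assert d.unimodal is True
        assert d.gaussian_mu == pytest.approx(0.3, abs=0.002)

    def test_mixture_bimodal(self, rng):
        v = np.concatenate(
            [rng.normal(0.3, 0.02, 5000), rng.normal(0.7, 0.02, 5000)]
        )
        d = distance_distribution(v)
        assert d.n_modes == 2
        assert d.unimodal is False

    def test_constant_degenerate(self):
        d = distance_distribution(np.full(100, 0.42))
        assert d.n_modes == 1 and d.unimodal is True
        assert d.gaussian_sigma == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_flagged(self, rng):
        d = distance_distribution(rng.normal(0.3, 0.02, 10))
        assert d.unimodal is None

    def test_counts_sum_to_sample_size(self, rng):
        v = rng.normal(0.5, 0.1, 500)
        d = distance_distribution(v)
        assert d.counts.sum() == 500
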