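"""Geometric hydrogen-bond detection against constructed cases and a brute-force oracle."""

import numpy as np
import pytest

from conftest import brute_hbonds
from dnabow.core import DnabowError, NoHydrogensError, Selection, Topology
from dnabow.hbonds import (
    HBondCriteria,
    all_pair_hbond_counts,
    find_hbonds,
    hbond_distribution,
    mean_hbonds_per_bp,
    pair_hbond_series,
    smooth_series,
)
from dnabow.synthetic import TrajectorySimSpec, simulate_trajectory


def tiny_topology(elements):
    """Minimal one-residue topology from a list of element symbols."""
    n = len(elements)
    return Topology(
        serial=np.arange(1, n + 1),
        name=np.array([f"{el}{i}" for i, el in enumerate(elements)]),
        element=np.array(elements),
        res_name=np.array(["DA"] * n),
        res_id=np.ones(n, dtype=int),
        chain_id=np.array(["B"] * n),
    )


def donor_h_acceptor_frame(d_da, deviation_deg):
    """N(donor)-H ... O(acceptor) with given D...A distance and D-H...A deviation."""
    D = np.array([0.0, 0.0, 0.0])
    H = np.array([1.0, 0.0, 0.0])
    # place A so that the angle at H deviates from linear by deviation_deg
    ang = np.radians(180.0 - deviation_deg)
    direction = np.array([-np.cos(ang), np.sin(ang), 0.0])  # from H
    r = None
    # solve |D - (H + r*dir)| = d_da for r > 0
    b = 2 * np.dot(H - D, direction)
    c = np.dot(H - D, H - D) - d_da**2
    r = (-b + np.sqrt(b * b - 4 * c)) / 2
    A = H + r * direction
    return np.array([D, H, A])


class TestConstructedTriples:
    def _detect(self, d_da, dev):
        topo = tiny_topology(["N", "H", "O"])
        frame = donor_h_acceptor_frame(d_da, dev)
        return find_hbonds(frame, topo)

    def test_inside_both_cutoffs(self):
        bonds = self._detect(2.8, 5.0)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8, abs=1e-9)
        assert bonds[0].angle_deviation == pytest.approx(5.0, abs=1e-6)

    def test_distance_cutoff_excludes(self):
        assert self._detect(3.2, 5.0) == []

    def test_angle_cutoff_excludes(self):
        assert self._detect(2.8, 25.0) == []

    def test_no_hydrogens_is_an_error(self):
        topo = tiny_topology(["N", "O"])
        frame = np.array([[0.0, 0, 0], [2.8, 0, 0]])
        with pytest.raises(NoHydrogensError):
            find_hbonds(frame, topo)


class TestOracleEquivalence:
    def test_random_frames_match_brute_force(self):
        rng = np.random.default_rng(42)
        crit = HBondCriteria()
        for _ in range(25):
            n = int(rng.integers(20, 50))
            elements = rng.choice(["N", "O", "C", "H"], size=n, p=[0.25, 0.25, 0.2, 0.3])
            topo = tiny_topology(list(elements))
            frame = rng.uniform(0, 12, size=(n, 3))
            if not (elements == "H").any():
                continue
            fast = {(b.donor, b.hydrogen, b.acceptor) for b in find_hbonds(frame, topo, crit)}
            slow = brute_hbonds(frame, topo, crit.d_cut, crit.angle_cut)
            assert fast == slow

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(7)
        elements = ["N", "O", "H"] * 8
        topo = tiny_topology(elements)
        frame = rng.uniform(0, 8, size=(len(elements), 3))
        loose = {
            (b.donor, b.hydrogen, b.acceptor)
            for b in find_hbonds(frame, topo, HBondCriteria(d_cut=3.5, angle_cut=35.0))
        }
        tight = {
            (b.donor, b.hydrogen, b.acceptor)
            for b in find_hbonds(frame, topo, HBondCriteria(d_cut=3.0, angle_cut=20.0))
        }
        assert tight <= loose

    def test_rigid_transform_invariance(self, static_traj):
        traj, _ = static_traj
        scope = Selection.of(res_ids={4, 57})
        base = find_hbonds(traj.coords[0], traj.topology, donor_scope=scope, acceptor_scope=scope)
        th = 0.7
        R = np.array(
            [[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]]
        )
        moved = traj.coords[0] @ R.T + np.array([3.0, -8.0, 11.0])
        after = find_hbonds(moved, traj.topology, donor_scope=scope, acceptor_scope=scope)
        assert [(b.donor, b.hydrogen, b.acceptor) for b in base] == [
            (b.donor, b.hydrogen, b.acceptor) for b in after
        ]


class TestPairCounts:
    def test_canonical_counts_per_pair_type(self, static_traj):
        traj, _ = static_traj
        counts = all_pair_hbond_counts(traj)
        expected = np.array([3 if b in "GC" else 2 for b in traj.topology.sequence_b])
        assert np.array_equal(counts[0], expected)

    def test_pair_series_matches_single_pair_route(self, static_traj):
        traj, _ = static_traj
        pair = traj.topology.pairs[3]  # a G.C pair
        series = pair_hbond_series(traj, pair)
        assert np.all(series.counts == 3)

    def test_open_pair_has_no_bonds(self):
        p = np.zeros(30)
        p[7] = 1.0
        traj, _ = simulate_trajectory(
            TrajectorySimSpec(
                n_frames=3,
                sigma_per_residue=np.zeros(30),
                open_prob_per_residue=p,
                open_displacement=9.0,
                seed=0,
            )
        )
        series = pair_hbond_series(traj, traj.topology.pairs[7])
        assert np.all(series.counts == 0)

    def test_mean_per_bp_closed_and_scalar(self, static_traj):
        traj, _ = static_traj
        seq = traj.topology.sequence_b
        expected = (2 * sum(b in "AT" for b in seq) + 3 * sum(b in "GC" for b in seq)) / 30
        per_frame, scalar = mean_hbonds_per_bp(traj)
        assert np.allclose(per_frame, expected)
        assert scalar == pytest.approx(expected)


class TestSmoothing:
    def test_constant_unchanged(self):
        v = np.full(300, 2.0)
        assert np.allclose(smooth_series(v, 101), v)

    def test_window_one_is_identity(self):
        v = np.arange(10.0)
        assert np.array_equal(smooth_series(v, 1), v)

    def test_impulse_response_plateau(self):
        v = np.zeros(501)
        v[250] = 1.0
        s = smooth_series(v, 101)
        inside = s[200:301]
        assert np.allclose(inside, 1 / 101)
        assert s[150] == 0.0 and s[350] == 0.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_series(np.zeros(10), 4)


class TestDistribution:
    def test_identical_means_single_bin(self):
        counts, edges = hbond_distribution(np.full(30, 2.5), bin_width=0.25)
        assert counts.sum() == 30
        assert (counts > 0).sum() == 1

    def test_empty_profile_rejected(self):
        with pytest.raises(DnabowError):
            hbond_distribution(np.array([]))

    def test_mode_shifts_right_for_lower_open_probability(self):
        def mode_centre(p_open, seed):
            traj, _ = simulate_trajectory(
                TrajectorySimSpec(
                    n_frames=300,
                    sigma_per_residue=np.zeros(30),
                    open_prob_per_residue=np.full(30, p_open),
                    mean_open_dwell_ns=0.5,
                    seed=seed,
                )
            )
            counts = all_pair_hbond_counts(traj)
            means = counts.mean(axis=0)
            hist, edges = hbond_distribution(means, bin_width=0.25)
            k = np.argmax(hist)
            return 0.5 * (edges[k] + edges[k + 1])

        assert mode_centre(0.0, 31) > mode_centre(0.4, 31)
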