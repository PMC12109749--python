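"""Base-pair distance metrics and trailing-window profiles."""

import numpy as np
import pytest

from dnabow.basepairs import (
    BasePairSeries,
    delta_c6,
    delta_wc,
    molecule_mean,
    open_fraction,
    residue_profile,
    spring_pair_distance,
)
from dnabow.core import BasePair, DnabowError, MissingAtomError, Trajectory
from dnabow.synthetic import TrajectorySimSpec, simulate_trajectory


def one_pair_open_spec(pair_index, n_frames=4, displacement=9.0):
    p = np.zeros(30)
    p[pair_index] = 1.0
    return TrajectorySimSpec(
        n_frames=n_frames,
        sigma_per_residue=np.zeros(30),
        open_prob_per_residue=p,
        open_displacement=displacement,
        seed=0,
    )


class TestDistanceSeries:
    def test_closed_pair_values(self, static_traj):
        traj, _ = static_traj
        for k in (0, 3, 20):
            pair = traj.topology.pairs[k]
            assert delta_c6(traj, pair).values.mean() == pytest.approx(6.4, abs=0.3)
            assert 2.7 <= delta_wc(traj, pair).values.mean() <= 3.0

    def test_open_pair_adds_displacement(self):
        traj, _ = simulate_trajectory(one_pair_open_spec(9))
        closed, _ = simulate_trajectory(one_pair_open_spec(9, displacement=0.0))
        pair = traj.topology.pairs[9]
        d_open = delta_c6(traj, pair).values.mean()
        d_closed = delta_c6(closed, pair).values.mean()
        assert d_open == pytest.approx(d_closed + 9.0, abs=1e-6)
        w_open = delta_wc(traj, pair).values.mean()
        w_closed = delta_wc(closed, pair).values.mean()
        assert w_open == pytest.approx(w_closed + 9.0, abs=0.2)

    def test_rigid_motion_invariance(self, static_traj):
        traj, _ = static_traj
        pair = traj.topology.pairs[5]
        base = delta_c6(traj, pair).values
        rng = np.random.default_rng(3)
        th = rng.uniform(0, np.pi)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        moved = Trajectory(traj.topology, traj.coords @ R.T + rng.normal(size=3), traj.dt_ns)
        assert np.allclose(delta_c6(moved, pair).values, base, atol=1e-9)

    def test_missing_atom_error_names_residue(self, static_traj):
        traj, _ = static_traj
        bad = BasePair(1, 60, traj.topology.pairs[0].wc_type)
        topo = traj.topology
        # strip C6 from residue 1 by building a fake lookup
        with pytest.raises(MissingAtomError):
            topo.atom_index(1, "NOPE")

    def test_degenerate_zero_distance_flagged(self):
        pair = BasePair(1, 60, "CG")
        with pytest.raises(DnabowError):
            BasePairSeries(pair, np.array([6.4, 0.0]), "dC6")

    def test_triangle_bound_wc_vs_c6(self, static_traj):
        # dWC <= dC6 + intra-base C6->N offsets, per frame
        traj, _ = static_traj
        topo = traj.topology
        for pair in topo.pairs:
            c6 = delta_c6(traj, pair).values
            wc = delta_wc(traj, pair).values
            frame = traj.coords[0]
            if pair.wc_type[0] in "AG":
                off_b = np.linalg.norm(
                    frame[topo.atom_index(pair.res_b, "C6")]
                    - frame[topo.atom_index(pair.res_b, "N1")]
                )
                off_c = np.linalg.norm(
                    frame[topo.atom_index(pair.res_c, "C6")]
                    - frame[topo.atom_index(pair.res_c, "N3")]
                )
            else:
                off_b = np.linalg.norm(
                    frame[topo.atom_index(pair.res_b, "C6")]
                    - frame[topo.atom_index(pair.res_b, "N3")]
                )
                off_c = np.linalg.norm(
                    frame[topo.atom_index(pair.res_c, "C6")]
                    - frame[topo.atom_index(pair.res_c, "N1")]
                )
            assert np.all(wc <= c6 + off_b + off_c + 1e-9)


class TestSpringDistance:
    def test_equals_direct_distance_and_constant_on_static(self, static_traj):
        traj, _ = static_traj
        d = spring_pair_distance(traj)
        topo = traj.topology
        direct = np.linalg.norm(
            traj.coords[0][topo.atom_index(2, "C6")]
            - traj.coords[0][topo.atom_index(29, "C6")]
        )
        assert d[0] == pytest.approx(direct, abs=1e-12)
        assert np.allclose(d, d[0])


class TestProfiles:
    def _series(self, values):
        return BasePairSeries(BasePair(1, 60, "CG"), np.asarray(values, float), "dC6")

    def test_constant_series(self):
        prof = residue_profile([self._series([6.4] * 10)], window_fraction=0.5)
        assert prof.mean[0] == pytest.approx(6.4)
        assert prof.sd[0] == pytest.approx(0.0)

    def test_full_window_equals_global_mean(self):
        vals = np.linspace(5, 9, 20)
        prof = residue_profile([self._series(vals)], window_fraction=1.0)
        assert prof.mean[0] == pytest.approx(vals.mean())

    def test_two_level_trailing_mean(self):
        vals = [6.4] * 5 + [10.0] * 5
        prof = residue_profile([self._series(vals)], window_fraction=0.5)
        assert prof.mean[0] == pytest.approx(10.0)

    def test_molecule_mean_arithmetic(self):
        series = [
            BasePairSeries(
                BasePair(k, 61 - k, "CG"),
                np.full(4, 6.4 if k < 30 else 16.4),
                "dC6",
            )
            for k in range(1, 31)
        ]
        prof = residue_profile(series, window_fraction=1.0)
        assert molecule_mean(prof) == pytest.approx((29 * 6.4 + 16.4) / 30)

    def test_bad_window_fraction(self):
        with pytest.raises(ValueError):
            residue_profile([self._series([6.4] * 4)], window_fraction=0.0)


class TestOpenProbabilityMonotonicity:
    def test_molecule_mean_increases_with_open_probability(self):
        means = []
        for p_open in (0.0, 0.2, 0.5):
            spec = TrajectorySimSpec(
                n_frames=400,
                sigma_per_residue=np.zeros(30),
                open_prob_per_residue=np.full(30, p_open),
                mean_open_dwell_ns=0.5,
                seed=21,
            )
            traj, _ = simulate_trajectory(spec)
            series = [delta_wc(traj, p) for p in traj.topology.pairs]
            means.append(molecule_mean(residue_profile(series, 1.0)))
        assert means[0] < means[1] < means[2]

    def test_open_fraction_recovers_forced_state(self):
        traj, truth = simulate_trajectory(one_pair_open_spec(4, n_frames=50))
        pair = traj.topology.pairs[4]
        assert open_fraction(delta_wc(traj, pair), threshold=7.0) == 1.0
        closed_pair = traj.topology.pairs[10]
        assert open_fraction(delta_wc(traj, closed_pair), threshold=7.0) == 0.0
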