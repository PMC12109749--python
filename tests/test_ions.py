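"""Ion-shell occupancy, Q5 charge statistic, residence times, Mg-P pairs."""

import numpy as np
import pytest

from conftest import brute_shell_counts
from dnabow.core import Trajectory
from dnabow.ions import (
    mg_p_pairs,
    residence_analysis,
    shell_charge,
    shell_counts,
    shell_series,
)
from dnabow.synthetic import IonSpec, TrajectorySimSpec, simulate_trajectory


def traj_with_ions(n_frames=30, seed=0, **ion_kwargs):
    spec = TrajectorySimSpec(
        n_frames=n_frames,
        sigma_per_residue=np.zeros(30),
        open_prob_per_residue=np.zeros(30),
        ions=(IonSpec(**ion_kwargs),),
        seed=seed,
    )
    return simulate_trajectory(spec)


def place_ion(traj, ion_index, position):
    coords = traj.coords.copy()
    coords[:, ion_index, :] = position
    return Trajectory(traj.topology, coords, traj.dt_ns, box=traj.box)


class TestShellCounts:
    def test_constructed_in_and_out(self):
        traj, _ = traj_with_ions(n_frames=1, species="MG", count=1)
        topo = traj.topology
        ion = topo.species_indices("MG")[0]
        p_atom = np.flatnonzero((topo.name == "P") & topo.dna_mask)[0]
        near = place_ion(traj, ion, traj.coords[0, p_atom] + [3.3, 0, 0])
        assert shell_counts(near.coords[0], topo, 5.0)["MG"] == 1
        # a corner of the box is far from the centred DNA
        far = place_ion(traj, ion, np.array([1.0, 1.0, 1.0]))
        assert shell_counts(far.coords[0], topo, 5.0)["MG"] == 0

    def test_matches_all_pairs_oracle(self):
        spec = TrajectorySimSpec(
            n_frames=1,
            sigma_per_residue=np.zeros(30),
            open_prob_per_residue=np.zeros(30),
            ions=(
                IonSpec("MG", 15, bound_fraction=0.4),
                IonSpec("NA", 10),
                IonSpec("CL", 10),
            ),
            seed=5,
        )
        traj, _ = simulate_trajectory(spec)
        fast = shell_counts(traj.coords[0], traj.topology, 5.0, traj.box)
        slow = brute_shell_counts(traj.coords[0], traj.topology, 5.0, traj.box)
        assert fast == slow

    def test_minimal_image_agrees_away_from_faces(self):
        traj, _ = traj_with_ions(n_frames=1, species="NA", count=3, seed=9)
        frame = traj.coords[0]
        with_box = shell_counts(frame, traj.topology, 5.0, traj.box)
        without = shell_counts(frame, traj.topology, 5.0, None)
        assert with_box == without

    def test_no_ions_empty_counts(self, static_traj):
        traj, _ = static_traj
        assert shell_counts(traj.coords[0], traj.topology) == {"MG": 0, "NA": 0, "CL": 0}


class TestShellCharge:
    @pytest.mark.parametrize(
        "counts,q",
        [
            ({"MG": 1, "NA": 1, "CL": 1}, 2),
            ({"MG": 0, "NA": 0, "CL": 0}, 0),
            ({"MG": 29, "NA": 0, "CL": 0}, 58),
        ],
    )
    def test_formula(self, counts, q):
        assert shell_charge(counts) == q

    def test_phosphate_count_is_58(self, straight_build):
        topo, _ = straight_build
        assert int((topo.name == "P").sum()) == 58

    def test_series_invariant_reasserted(self):
        spec = TrajectorySimSpec(
            n_frames=10,
            ions=(IonSpec("MG", 5, bound_fraction=0.5), IonSpec("CL", 5)),
            seed=2,
        )
        traj, _ = simulate_trajectory(spec)
        series = shell_series(traj)
        assert np.array_equal(
            series.q5, 2 * series.counts["MG"] + series.counts["NA"] - series.counts["CL"]
        )


class TestResidence:
    def test_permanently_bound_ion_full_duration(self):
        traj, _ = traj_with_ions(
            n_frames=40, species="MG", count=1, bound_fraction=1.0,
            mean_residence_ns=1e9,
        )
        rec = residence_analysis(traj, "MG")[0]
        assert rec.total_ns == pytest.approx(traj.n_frames * traj.dt_ns)
        assert len(rec.intervals_ns) == 1

    def test_alternating_frames_one_frame_intervals(self):
        traj, _ = traj_with_ions(n_frames=6, species="MG", count=1)
        topo = traj.topology
        ion = topo.species_indices("MG")[0]
        p_atom = np.flatnonzero((topo.name == "P") & topo.dna_mask)[0]
        coords = traj.coords.copy()
        for f in range(6):
            coords[f, ion] = (
                coords[f, p_atom] + [3.0, 0, 0] if f % 2 == 0 else [1.0, 1.0, 1.0]
            )
        alt = Trajectory(topo, coords, traj.dt_ns, box=traj.box)
        rec = residence_analysis(alt, "MG", gap_tolerance_frames=0)[0]
        assert len(rec.intervals_ns) == 3
        assert all((e - s) == pytest.approx(traj.dt_ns) for s, e in rec.intervals_ns)
        merged = residence_analysis(alt, "MG", gap_tolerance_frames=1)[0]
        assert len(merged.intervals_ns) == 1

    def test_exponential_residence_mean_recovered(self):
        spec = TrajectorySimSpec(
            n_frames=800,
            dt_ns=0.1,
            sigma_per_residue=np.zeros(30),
            open_prob_per_residue=np.zeros(30),
            ions=(IonSpec("MG", 60, bound_fraction=1.0, mean_residence_ns=5.0),),
            seed=17,
        )
        traj, _ = simulate_trajectory(spec)
        recs = residence_analysis(traj, "MG")
        # the first contiguous visit is the bound dwell; later visits are
        # diffusive re-entries of the freed ion
        mean_t = np.mean([r.intervals_ns[0][1] - r.intervals_ns[0][0] for r in recs])
        assert mean_t == pytest.approx(5.0, rel=0.2)


class TestMgPPairs:
    def test_bound_ion_recovers_bind_distance(self):
        traj, truth = traj_with_ions(
            n_frames=60, species="MG", count=4, bound_fraction=1.0,
            mean_residence_ns=1e9, bind_distance=3.3,
        )
        found = mg_p_pairs(traj)
        # every generator host contact is recovered at the bind distance;
        # incidental persistent contacts with a second nearby phosphate may
        # also (correctly) be reported
        by_key = {(p.mg_serial, p.p_serial): p for p in found}
        for ion in truth.ions:
            key = (ion.serial, ion.host_p_serial)
            assert key in by_key
            assert by_key[key].trailing_mean == pytest.approx(3.3, abs=0.1)

    def test_free_ions_yield_no_pairs(self):
        traj, _ = traj_with_ions(n_frames=30, species="MG", count=5, bound_fraction=0.0)
        assert mg_p_pairs(traj) == []

    def test_zero_threshold_empty(self):
        traj, _ = traj_with_ions(
            n_frames=10, species="MG", count=2, bound_fraction=1.0, mean_residence_ns=1e9
        )
        assert mg_p_pairs(traj, pair_distance_threshold=0.0) == []
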