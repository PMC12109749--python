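"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dnabow.builder import DuplexBuildSpec, build_bent_duplex
from dnabow.synthetic import TrajectorySimSpec, simulate_trajectory


@pytest.fixture(scope="session")
def straight_build():
    """Ideal straight (0 deg) duplex of the printed 30-bp sequence."""
    return build_bent_duplex(DuplexBuildSpec(bend_angle_deg=0.0))


@pytest.fixture(scope="session")
def bent_build():
    """Sharply bent (160 deg) duplex of the printed sequence."""
    return build_bent_duplex(DuplexBuildSpec(bend_angle_deg=160.0))


@pytest.fixture(scope="session")
def static_traj():
    """Noiseless 5-frame trajectory: every frame identical to the build."""
    spec = TrajectorySimSpec(
        build=DuplexBuildSpec(bend_angle_deg=0.0),
        n_frames=5,
        dt_ns=0.1,
        sigma_per_residue=np.zeros(30),
        open_prob_per_residue=np.zeros(30),
        seed=0,
    )
    traj, truth = simulate_trajectory(spec)
    return traj, truth


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)
# ---------------------------------------------------------------------------

def brute_hbonds(frame, topology, d_cut, angle_cut, polar=("N", "O", "S", "F")):
    """Exhaustive all-triples hydrogen-bond enumeration."""
    n = topology.n_atoms
    el = topology.element
    heavy = [i for i in range(n) if el[i] != "H"]
    hydro = [i for i in range(n) if el[i] == "H"]
    attached = {}
    for h in hydro:
        best, bd = None, np.inf
        for a in heavy:
            d = np.linalg.norm(frame[h] - frame[a])
            if d < bd:
                best, bd = a, d
        if bd <= 1.25:
            attached.setdefault(best, []).append(h)
    bonds = set()
    for d_i in heavy:
        if el[d_i] not in polar or d_i not in attached:
            continue
        for a_i in heavy:
            if a_i == d_i or el[a_i] not in polar:
                continue
            dist = np.linalg.norm(frame[d_i] - frame[a_i])
            if dist > d_cut or dist <= 1.8:
                continue
            for h_i in attached[d_i]:
                v1 = frame[d_i] - frame[h_i]
                v2 = frame[a_i] - frame[h_i]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                dev = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if dev <= angle_cut:
                    bonds.add((d_i, h_i, a_i))
    return bonds


def quat_to_rot(q):
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def grid_min_rmsd(mobile, reference, rng, n_coarse=3000, n_refine=400, n_stages=12):
    """Minimum RMSD over rotations by quaternion sampling with local refinement.

    Centres both sets (the optimal translation aligns centroids), scans
    random unit quaternions, then repeatedly samples shrinking neighbourhoods
    of the incumbent.  Converges to the optimum well below 1e-6 A for small
    point sets.
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def rmsd_for(q):
        R = quat_to_rot(q)
        d = P @ R.T - Q
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best_q, best = None, np.inf
    for _ in range(n_coarse):
        q = rng.normal(size=4)
        r = rmsd_for(q)
        if r < best:
            best_q, best = q, r
    scale = 0.3
    for _ in range(n_stages):
        for _ in range(n_refine):
            q = best_q + scale * rng.normal(size=4) * np.linalg.norm(best_q)
            r = rmsd_for(q)
            if r < best:
                best_q, best = q, r
        scale *= 0.35
    return best


def brute_shell_counts(frame, topology, cutoff, box=None):
    """All-pairs minimum-distance ion-shell counts."""
    dna = [i for i in range(topology.n_atoms) if topology.chain_id[i] in ("B", "C")]
    out = {}
    for sp in ("MG", "NA", "CL"):
        count = 0
        for i in range(topology.n_atoms):
            if topology.res_name[i] != sp:
                continue
            dmin = np.inf
            for j in dna:
                delta = frame[i] - frame[j]
                if box is not None:
                    delta = delta - box * np.round(delta / box)
                dmin = min(dmin, np.linalg.norm(delta))
            if dmin <= cutoff:
                count += 1
        out[sp] = count
    return out
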