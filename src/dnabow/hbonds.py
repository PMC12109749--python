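"""Geometric hydrogen-bond detection and per-base-pair counting.

A bond is a (donor, hydrogen, acceptor) triple with donor and acceptor both
polar heavy atoms (N, O, S, F by default), donor-acceptor distance <= 3.0 A
and the D-H...A angle within 20 deg of linearity — the VMD HBonds
convention.  Hydrogen attachment is inferred from a 1.25 A hydrogen-to-heavy
distance rule in the frame under analysis (the generator keeps residues
internally rigid, so attachment is unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    BasePair,
    DnabowError,
    NoHydrogensError,
    Selection,
    Topology,
    Trajectory,
    trailing_window,
)
from .basepairs import DEFAULT_WINDOW_FRACTION

__all__ = [
    "HBondCriteria",
    "HBond",
    "HbondCountSeries",
    "find_hbonds",
    "pair_hbond_series",
    "all_pair_hbond_counts",
    "smooth_series",
    "mean_hbonds_per_bp",
    "hbond_distribution",
]

_H_ATTACH_MAX = 1.25  # A, hydrogen-to-heavy covalent attachment rule
_COVALENT_MAX = 1.8  # A, heavy-heavy covalent exclusion


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: distance cutoff, deviation-from-linearity cutoff, polar elements."""

    d_cut: float = 3.0
    angle_cut: float = 20.0
    polar_elements: frozenset[str] = frozenset({"N", "O", "S", "F"})

    def __post_init__(self):
        if not self.d_cut > 0:
            raise ValueError("d_cut must be positive")
        if not 0 < self.angle_cut < 90:
            raise ValueError("angle_cut must be in (0, 90)")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor-acceptor, A
    angle_deviation: float  # deg from linear D-H...A


def _hydrogen_attachments(topology: Topology, frame: np.ndarray):
    """heavy-index -> list of attached hydrogen indices, by the distance rule."""
    h_idx = np.flatnonzero(topology.element == "H")
    heavy_idx = np.flatnonzero(topology.element != "H")
    if h_idx.size == 0:
        raise NoHydrogensError(
            "topology contains no hydrogens; geometric H-bond detection requires "
            "explicit polar hydrogens"
        )
    tree = cKDTree(frame[heavy_idx])
    dist, j = tree.query(frame[h_idx], k=1)
    attached: dict[int, list[int]] = {}
    for h, d, jj in zip(h_idx, dist, j):
        if d <= _H_ATTACH_MAX:
            attached.setdefault(int(heavy_idx[jj]), []).append(int(h))
    return attached


def find_hbonds(
    frame: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    donor_scope: Selection | None = None,
    acceptor_scope: Selection | None = None,
) -> list[HBond]:
    """All hydrogen bonds in one frame satisfying ``criteria``.

    ``donor_scope``/``acceptor_scope`` restrict which atoms may act as donor
    heavy atoms and acceptors (default: all).
    """
    attached = _hydrogen_attachments(topology, frame)
    polar = np.isin(topology.element, list(criteria.polar_elements))
    donor_mask = polar.copy()
    if donor_scope is not None:
        donor_mask &= donor_scope.mask(topology)
    acc_mask = polar.copy()
    if acceptor_scope is not None:
        acc_mask &= acceptor_scope.mask(topology)
    donors = np.array([i for i in np.flatnonzero(donor_mask) if i in attached], dtype=int)
    acceptors = np.flatnonzero(acc_mask)
    if donors.size == 0 or acceptors.size == 0:
        return []
    tree = cKDTree(frame[acceptors])
    neigh = tree.query_ball_point(frame[donors], r=criteria.d_cut)
    bonds: list[HBond] = []
    for d_i, hits in zip(donors, neigh):
        D = frame[d_i]
        for k in hits:
            a_i = int(acceptors[k])
            if a_i == d_i:
                continue
            dist = float(np.linalg.norm(frame[a_i] - D))
            if dist <= _COVALENT_MAX:  # covalently bonded heavy atoms
                continue
            A = frame[a_i]
            for h_i in attached[int(d_i)]:
                H = frame[h_i]
                v1, v2 = D - H, A - H
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                dev = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if dev <= criteria.angle_cut:
                    bonds.append(HBond(int(d_i), int(h_i), a_i, dist, float(dev)))
    bonds.sort(key=lambda b: (b.donor, b.hydrogen, b.acceptor))
    return bonds


@dataclass
class HbondCountSeries:
    pair: BasePair
    counts: np.ndarray  # per frame, non-negative ints
    smoothed: np.ndarray | None = None
    smoothing_window: int = 101

    def smooth(self) -> np.ndarray:
        self.smoothed = smooth_series(self.counts, self.smoothing_window)
        return self.smoothed


def _pair_count_from_bonds(bonds, topology, res_b, res_c) -> int:
    n = 0
    for b in bonds:
        rd = int(topology.res_id[b.donor])
        ra = int(topology.res_id[b.acceptor])
        if (rd == res_b and ra == res_c) or (rd == res_c and ra == res_b):
            n += 1
    return n


def pair_hbond_series(
    traj: Trajectory,
    pair: BasePair,
    criteria: HBondCriteria = HBondCriteria(),
    smoothing_window: int = 101,
) -> HbondCountSeries:
    """Per-frame count of hydrogen bonds between the two residues of ``pair``."""
    scope = Selection.of(res_ids={pair.res_b, pair.res_c})
    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        bonds = find_hbonds(traj.coords[f], traj.topology, criteria, scope, scope)
        counts[f] = _pair_count_from_bonds(bonds, traj.topology, pair.res_b, pair.res_c)
    return HbondCountSeries(pair, counts, smoothing_window=smoothing_window)


def all_pair_hbond_counts(
    traj: Trajectory, criteria: HBondCriteria = HBondCriteria()
) -> np.ndarray:
    """(n_frames, n_pairs) WC-pair hydrogen-bond counts in one pass per frame.

    Only bonds whose donor and acceptor sit on the two residues of the same
    base pair are counted; intra-residue and non-pair interstrand bonds are
    excluded.
    """
    topo = traj.topology
    pairs = topo.pairs
    dna_scope = Selection.of(chains={"B", "C"})
    pair_of_res = {}
    for k, p in enumerate(pairs):
        pair_of_res[p.res_b] = (k, p.res_c)
        pair_of_res[p.res_c] = (k, p.res_b)
    out = np.zeros((traj.n_frames, len(pairs)), dtype=int)
    for f in range(traj.n_frames):
        bonds = find_hbonds(traj.coords[f], topo, criteria, dna_scope, dna_scope)
        for b in bonds:
            rd = int(topo.res_id[b.donor])
            ra = int(topo.res_id[b.acceptor])
            hit = pair_of_res.get(rd)
            if hit is not None and hit[1] == ra:
                out[f, hit[0]] += 1
    return out


def smooth_series(values: np.ndarray, window: int = 101) -> np.ndarray:
    """Centered moving average with truncated windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = v.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def mean_hbonds_per_bp(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    pair_counts: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-frame mean H-bond count over the 30 pairs, <Nhb>, and its trailing-window scalar."""
    if pair_counts is None:
        pair_counts = all_pair_hbond_counts(traj, criteria)
    per_frame = pair_counts.mean(axis=1)
    win = trailing_window(len(per_frame), window_fraction)
    return per_frame, float(per_frame[win].mean())


def hbond_distribution(
    per_pair_means: np.ndarray, bin_width: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin_edges) of per-pair trailing-mean H-bond numbers."""
    vals = np.asarray(per_pair_means, dtype=float)
    if vals.size == 0:
        raise DnabowError("empty per-pair profile")
    hi = max(np.ceil(vals.max() / bin_width) * bin_width, bin_width)
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return counts, edges
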