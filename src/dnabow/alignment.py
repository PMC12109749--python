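"""Rigid-body superposition, RMSD time series, and two-pass RMSF.

Superposition weights are uniform (no mass weighting by default; an optional
``masses`` argument is accepted where stated).  The RMSF procedure is the
two-pass one: align every frame to the final frame, average the aligned
coordinates, then re-align every frame to that average structure and measure
each atom's root-mean-square displacement about its mean position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateInputError,
    DnabowError,
    InsufficientFramesError,
    Selection,
    Trajectory,
)

__all__ = [
    "SuperpositionResult",
    "RmsfProfile",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_two_pass",
    "check_molecule_whole",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, A
    rmsd: float  # A

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation + translation minimising the (optionally
    weighted) RMSD; reflections are excluded.  Requires >= 3 points spanning
    at least a plane.
    """
    P = np.asarray(mobile, dtype=np.float64)
    Q = np.asarray(reference, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateInputError("point sets must have identical (n, 3) shapes")
    if P.shape[0] < 3:
        raise DegenerateInputError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(P.shape[0], 1.0 / P.shape[0])
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    pc = w @ P
    qc = w @ Q
    H = (P - pc).T @ ((Q - qc) * w[:, None])
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-300):
        raise DegenerateInputError("collinear or coincident points: rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return SuperpositionResult(R, t, rmsd)


def _selected(traj: Trajectory, selection: Selection | None) -> np.ndarray:
    # default scope is "all the atoms of the DNA molecule": diffusing ions
    # would otherwise dominate the deviation metrics
    if selection is None:
        return np.flatnonzero(traj.topology.dna_mask)
    idx = selection.indices(traj.topology)
    if idx.size == 0:
        raise DnabowError("empty selection")
    return idx


def rmsd_series(
    traj: Trajectory,
    reference_frame_index: int = 0,
    selection: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference frame, after superposition over ``selection``."""
    if not 0 <= reference_frame_index < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame_index} out of range")
    idx = _selected(traj, selection)
    ref = traj.coords[reference_frame_index][idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch_superpose(traj.coords[f][idx], ref).rmsd
    return out


@dataclass(frozen=True)
class RmsfProfile:
    atom_indices: np.ndarray
    rmsf: np.ndarray  # A, one value per selected atom
    mean_coords: np.ndarray  # the average structure used as reference


def rmsf_two_pass(traj: Trajectory, selection: Selection | None = None) -> RmsfProfile:
    """Two-pass RMSF: frames aligned to the last frame to form the average
    structure, then re-aligned to that average; fluctuation about the mean."""
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    idx = _selected(traj, selection)
    last = traj.coords[-1][idx]
    aligned = np.empty((traj.n_frames, idx.size, 3))
    for f in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[f][idx], last)
        aligned[f] = sup.apply(traj.coords[f][idx])
    avg = aligned.mean(axis=0)
    for f in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[f][idx], avg)
        aligned[f] = sup.apply(traj.coords[f][idx])
    mean_pos = aligned.mean(axis=0)
    disp2 = np.sum((aligned - mean_pos) ** 2, axis=2)
    return RmsfProfile(idx, np.sqrt(disp2.mean(axis=0)), mean_pos)


def check_molecule_whole(traj: Trajectory, max_gap: float = 5.0) -> None:
    """Guard against periodic-image splitting of the DNA.

    Each residue's atoms must form a single cluster under single-linkage at
    ``max_gap`` A in every frame (any covalently bonded pair is far closer
    than 5 A, so a split image shows up as a disconnected cluster).  Raises
    DnabowError on violation.
    """
    from scipy.sparse.csgraph import connected_components

    topo = traj.topology
    for res_id in np.unique(topo.res_id[topo.dna_mask]):
        ridx = topo.residue_indices(int(res_id))
        if ridx.size < 2:
            continue
        pts = traj.coords[:, ridx, :]  # (F, m, 3)
        d = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=3)
        for f in range(traj.n_frames):
            n_comp, _ = connected_components(d[f] <= max_gap, directed=False)
            if n_comp > 1:
                raise DnabowError(
                    f"residue {res_id} appears split across images in frame {f} "
                    f"({n_comp} clusters at a {max_gap} A linkage threshold)"
                )
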