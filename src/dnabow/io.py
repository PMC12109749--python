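"""File I/O: PDB structures (biotite), DCD/XYZ trajectories (MDAnalysis), CSV tables.

PDB files carry the duplex on chains B/C (residues 1..30 / 31..60) and ions
on chain I; round-tripping a topology + frame preserves names, residues,
chains and coordinates to PDB writer precision (1e-3 A).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

import MDAnalysis as mda

from .core import (
    DUPLEX_LENGTH,
    ION_SPECIES,
    Topology,
    Trajectory,
    infer_element,
)

__all__ = [
    "write_pdb",
    "read_pdb",
    "write_dcd",
    "write_xyz",
    "read_trajectory",
    "ground_truth_frames",
]


def _to_atom_array(topology: Topology, frame: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame, dtype=np.float32)
    arr.chain_id = topology.chain_id.astype("U4")
    arr.res_id = topology.res_id.astype(int)
    arr.res_name = topology.res_name.astype("U5")
    arr.atom_name = topology.name.astype("U6")
    arr.element = topology.element.astype("U2")
    arr.hetero = np.isin(topology.res_name, ION_SPECIES)
    return arr


def write_pdb(path, topology: Topology, frame: np.ndarray) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(topology, frame))
    pdb.write(str(path))


def read_pdb(path) -> tuple[Topology, np.ndarray]:
    """Read a duplex (+ ions) PDB back into a Topology and one frame."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    names = arr.atom_name.astype("U6")
    res_names = arr.res_name.astype("U5")
    elements = np.array(
        [
            el if el else infer_element(nm, rn)
            for el, nm, rn in zip(arr.element, names, res_names)
        ],
        dtype="U2",
    )
    b_mask = arr.chain_id == "B"
    b_res = arr.res_id[b_mask]
    seq = []
    for r in range(1, DUPLEX_LENGTH + 1):
        hits = np.flatnonzero(b_res == r)
        if hits.size == 0:
            raise ValueError(f"chain B residue {r} missing from {path}")
        seq.append(res_names[b_mask][hits[0]][1])
    topo = Topology(
        serial=np.arange(1, arr.array_length() + 1),
        name=names,
        element=elements,
        res_name=res_names,
        res_id=arr.res_id.astype(int),
        chain_id=arr.chain_id.astype("U1"),
        sequence_b="".join(seq),
    )
    return topo, arr.coord.astype(np.float64)


def write_dcd(path, traj: Trajectory) -> None:
    u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f].astype(np.float32)
            if traj.box is not None:
                u.dimensions = [*traj.box, 90.0, 90.0, 90.0]
            w.write(u.atoms)


def write_xyz(path, traj: Trajectory) -> None:
    """Multi-frame plain-text XYZ fallback; atoms labelled by element."""
    with open(path, "w") as fh:
        n = traj.topology.n_atoms
        for f in range(traj.n_frames):
            fh.write(f"{n}\nframe {f} t_ns {f * traj.dt_ns:.6f}\n")
            for el, (x, y, z) in zip(traj.topology.element, traj.coords[f]):
                fh.write(f"{el} {x:.5f} {y:.5f} {z:.5f}\n")


def read_trajectory(
    pdb_path, traj_path, dt_ns: float, box=None
) -> Trajectory:
    """Load a trajectory (DCD or XYZ) against its PDB topology."""
    topo, _ = read_pdb(pdb_path)
    u = mda.Universe(str(pdb_path), str(traj_path))
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float64)
    return Trajectory(topo, frames, dt_ns, box=None if box is None else np.asarray(box, float))


def ground_truth_frames(truth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth sidecar tables: per-pair parameters and per-ion bound intervals."""
    pairs = pd.DataFrame(
        {
            "pair": np.arange(1, len(truth.sigma_per_pair) + 1),
            "sigma_A": truth.sigma_per_pair,
            "open_prob": truth.open_prob,
            "realized_open_fraction": truth.realized_open_fraction,
        }
    )
    rows = []
    for ion in truth.ions:
        if ion.bound_intervals_ns:
            for s, e in ion.bound_intervals_ns:
                rows.append(
                    {
                        "serial": ion.serial,
                        "species": ion.species,
                        "host_p_serial": ion.host_p_serial,
                        "bind_distance_A": ion.bind_distance,
                        "t_start_ns": s,
                        "t_end_ns": e,
                    }
                )
        else:
            rows.append(
                {
                    "serial": ion.serial,
                    "species": ion.species,
                    "host_p_serial": None,
                    "bind_distance_A": ion.bind_distance,
                    "t_start_ns": np.nan,
                    "t_end_ns": np.nan,
                }
            )
    ions = pd.DataFrame(
        rows,
        columns=[
            "serial", "species", "host_p_serial", "bind_distance_A",
            "t_start_ns", "t_end_ns",
        ],
    )
    return pairs, ions
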