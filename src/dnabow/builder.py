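"""Minimal bent B-form duplex builder.

Base-pair reference frames are placed along a circular arc whose tangent
turns by the requested total bend angle end-to-end, with a fixed rise and
twist per step; each frame carries the ideal Watson-Crick pair geometry from
:mod:`dnabow.refgeom`.  Phosphates arrive with each nucleotide's internal
(CCD-ideal) geometry, i.e. by a fixed offset from the base frame; 5'-terminal
residues (1 and 31) carry no phosphate group.

This is a geometry generator, not a structure-refinement tool: successive
backbone residues are not covalently spliced, sugar puckers are the CCD
ideals, and helical parameters are sequence-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DUPLEX_LENGTH,
    InvalidSequenceError,
    Topology,
    build_pair_map,
    complement_sequence,
    infer_element,
)
from .refgeom import TERMINAL_PHOSPHATE, ideal_base_pair

__all__ = ["DuplexBuildSpec", "build_bent_duplex", "pair_frames", "PAPER_SEQUENCE_B"]

#: printed strand-B sequence of the 30-bp DNA-bow duplex
PAPER_SEQUENCE_B = "CTGCTGAATTCTGTGGAGTCGTCGTATGTC"


@dataclass(frozen=True)
class DuplexBuildSpec:
    """Geometry of the duplex to build.

    bend_angle_deg is the total turning of the helical axis (160 deg for the
    sharply bent sensor conformation, 0 for the straight B-form reference);
    rise/twist defaults are canonical B-DNA.
    """

    sequence_b: str = PAPER_SEQUENCE_B
    bend_angle_deg: float = 160.0
    rise_per_bp: float = 3.38
    twist_per_bp: float = 36.0

    def __post_init__(self):
        if len(self.sequence_b) != DUPLEX_LENGTH:
            raise InvalidSequenceError(
                f"sequence must be {DUPLEX_LENGTH} bases, got {len(self.sequence_b)}"
            )
        if not 0 <= self.bend_angle_deg < 360:
            raise ValueError("bend_angle_deg must be in [0, 360)")
        if not self.rise_per_bp > 0:
            raise ValueError("rise_per_bp must be positive")


def pair_frames(
    n_pairs: int, bend_angle_deg: float, rise: float, twist_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Origins (n,3) and rotation matrices (n,3,3) of the base-pair frames.

    The helical axis is a circular arc in the y-z plane starting at the
    origin with tangent +z; the pair long axis additionally rotates by the
    helical twist about the local tangent at every step.
    """
    s = np.arange(n_pairs) * rise
    theta = np.radians(bend_angle_deg)
    if theta < 1e-12:
        phi = np.zeros(n_pairs)
        origins = np.column_stack([np.zeros(n_pairs), np.zeros(n_pairs), s])
    else:
        arc_len = (n_pairs - 1) * rise
        radius = arc_len / theta
        phi = s / radius
        origins = np.column_stack(
            [np.zeros(n_pairs), radius * (1.0 - np.cos(phi)), radius * np.sin(phi)]
        )
    tang = np.column_stack([np.zeros(n_pairs), np.sin(phi), np.cos(phi)])
    nrm = np.array([1.0, 0.0, 0.0])  # bend-plane normal, constant along the arc
    e1 = np.cross(np.broadcast_to(nrm, tang.shape), tang)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(tang, e1)
    psi = np.radians(twist_deg) * np.arange(n_pairs)
    x = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
    z = tang
    y = np.cross(z, x)
    rots = np.stack([x, y, z], axis=2)  # columns are the frame vectors
    return origins, rots


def build_bent_duplex(spec: DuplexBuildSpec) -> tuple[Topology, np.ndarray]:
    """Build the duplex: returns (Topology, coordinates of one frame in A)."""
    seq_b = spec.sequence_b
    seq_c = complement_sequence(seq_b)
    pairs = build_pair_map(seq_b)
    origins, rots = pair_frames(
        DUPLEX_LENGTH, spec.bend_angle_deg, spec.rise_per_bp, spec.twist_per_bp
    )

    # per-residue atom lists; residue j in 1..60
    res_names: dict[int, tuple] = {}
    res_coords: dict[int, np.ndarray] = {}
    res_resname: dict[int, str] = {}
    for i, pair in enumerate(pairs):
        ref = ideal_base_pair(pair.wc_type)
        o, R = origins[i], rots[i]
        for res_id, names, local, rn in (
            (pair.res_b, ref.names_b, ref.coords_b, ref.res_name_b),
            (pair.res_c, ref.names_c, ref.coords_c, ref.res_name_c),
        ):
            res_names[res_id] = names
            res_coords[res_id] = local @ R.T + o
            res_resname[res_id] = rn

    # 5'-terminal residues (B: 1, C: 31) lack the phosphate group
    for term in (1, DUPLEX_LENGTH + 1):
        keep = [
            k
            for k, nm in enumerate(res_names[term])
            if nm not in TERMINAL_PHOSPHATE
        ]
        res_names[term] = tuple(res_names[term][k] for k in keep)
        res_coords[term] = res_coords[term][keep]

    names, elements, resnames, resids, chains, coords = [], [], [], [], [], []
    for res_id in range(1, 2 * DUPLEX_LENGTH + 1):
        chain = "B" if res_id <= DUPLEX_LENGTH else "C"
        rn = res_resname[res_id]
        for nm, xyz in zip(res_names[res_id], res_coords[res_id]):
            names.append(nm)
            elements.append(infer_element(nm))
            resnames.append(rn)
            resids.append(res_id)
            chains.append(chain)
            coords.append(xyz)

    n = len(names)
    topo = Topology(
        serial=np.arange(1, n + 1),
        name=np.array(names),
        element=np.array(elements),
        res_name=np.array(resnames),
        res_id=np.array(resids),
        chain_id=np.array(chains),
        sequence_b=seq_b,
        pairs=pairs,
    )
    return topo, np.asarray(coords, dtype=np.float64)
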