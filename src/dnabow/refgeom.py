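"""Ideal Watson-Crick base-pair reference geometry.

Each pair type (AT/TA/GC/CG) is assembled once from the ideal nucleotide
coordinates bundled with biotite's Chemical Component Dictionary (which
include all hydrogens) and cached.  The two nucleotides are first placed in
an idealised pair frame (C1'-C1' axis along x, bases coplanar in the xy
plane, glycosidic angle lambda ~54.5 deg), then the pose of the second
nucleotide is refined in-plane by least squares against canonical WC
hydrogen-bond heavy-atom distances with a collinearity (D-H...A) penalty.

The resulting geometry reproduces the canonical values the analyses assume:
intra-pair C6-C6 ~6.4 A, purine-N1 to pyrimidine-N3 ~2.9 A, and exactly
3 (G.C) / 2 (A.T) hydrogen bonds under a 3.0 A / 20 deg geometric criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

import biotite.structure.info as struc_info

from .core import COMPLEMENT, PURINES

__all__ = ["IdealPair", "ideal_base_pair", "BACKBONE_STRIP", "TERMINAL_PHOSPHATE"]

#: atoms removed from the CCD monomers for polymer context (free-nucleotide caps)
BACKBONE_STRIP = ("OP3", "HOP3", "HOP2", "HO5'", "HO3'")
#: additionally removed from 5'-terminal residues (standard PDB convention)
TERMINAL_PHOSPHATE = ("P", "OP1", "OP2")

_RING = {
    True: ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    False: ("N1", "C2", "N3", "C4", "C5", "C6"),
}

# donor residue, donor atom, acceptor residue, acceptor atom, canonical D...A distance (A)
_HB_TARGETS = {
    frozenset(("DA", "DT")): (
        ("DA", "N6", "DT", "O4", 2.95),
        ("DT", "N3", "DA", "N1", 2.82),
    ),
    frozenset(("DG", "DC")): (
        ("DC", "N4", "DG", "O6", 2.91),
        ("DG", "N1", "DC", "N3", 2.95),
        ("DG", "N2", "DC", "O2", 2.86),
    ),
}

_C1C1 = 10.44  # C1'-C1' distance used for initial placement (A)
_LAMBDA_DEG = 54.5  # glycosidic angle for initial placement
_ANGLE_WEIGHT = 3.0  # weight of the collinearity residuals (rad -> A scale)


@dataclass(frozen=True)
class IdealPair:
    """One WC pair in its local frame: C1'-C1' midpoint at the origin, axis along x.

    ``coords_b``/``coords_c`` hold the strand-B and complementary nucleotide;
    atom names follow PDB v3 (``names_b``/``names_c``).
    """

    res_name_b: str
    res_name_c: str
    names_b: tuple[str, ...]
    names_c: tuple[str, ...]
    coords_b: np.ndarray
    coords_c: np.ndarray

    def atom_b(self, name: str) -> np.ndarray:
        return self.coords_b[self.names_b.index(name)]

    def atom_c(self, name: str) -> np.ndarray:
        return self.coords_c[self.names_c.index(name)]


def _monomer(res_name: str):
    res = struc_info.residue(res_name)
    keep = ~np.isin(res.atom_name, BACKBONE_STRIP)
    return tuple(res.atom_name[keep]), res.coord[keep].astype(np.float64)


def _base_normal(names, coords, is_purine: bool) -> np.ndarray:
    idx = [names.index(a) for a in _RING[is_purine]]
    pts = coords[idx]
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    n = vt[2]
    return n / np.linalg.norm(n)


def _kabsch(P: np.ndarray, Q: np.ndarray):
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc

def _place(names, coords, res_name, c1_target, n_target):
    """Rigidly place a nucleotide so C1' and the glycosidic N hit their targets
    with the base plane in z=const; the normal sign putting the WC edge nearest
    the pair origin is kept."""
    is_pur = res_name[1] in PURINES
    n_gly = "N9" if is_pur else "N1"
    wc_atom = "N1" if is_pur else "N3"
    c1 = coords[names.index("C1'")]
    ng = coords[names.index(n_gly)]
    nrm = _base_normal(names, coords, is_pur)
    best = None
    for s in (1.0, -1.0):
        P = np.array([c1, ng, ng + nrm])
        Q = np.array([c1_target, n_target, n_target + np.array([0.0, 0.0, s])])
        R, t = _kabsch(P, Q)
        placed = coords @ R.T + t
        d_wc = np.linalg.norm(placed[names.index(wc_atom)][:2])
        if best is None or d_wc < best[0]:
            best = (d_wc, placed)
    return best[1]


def _attached_hydrogens(names, coords, heavy_idx):
    d = np.linalg.norm(coords - coords[heavy_idx], axis=1)
    return [
        i for i, nm in enumerate(names) if nm.startswith("H") and 0 < d[i] < 1.25
    ]


def _bond_geometry(names_d, coords_d, di, coords_a, ai):
    """(D...A distance, smallest D-H...A deviation from linearity in deg)."""
    D, A = coords_d[di], coords_a[ai]
    dev = 180.0
    for hi in _attached_hydrogens(names_d, coords_d, di):
        H = coords_d[hi]
        v1, v2 = D - H, A - H
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        dev = min(dev, 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return float(np.linalg.norm(D - A)), dev


@lru_cache(maxsize=None)
def ideal_base_pair(wc_type: str) -> IdealPair:
    """Reference WC pair for ``wc_type`` in {"AT", "TA", "GC", "CG"} (strand-B base first)."""
    if len(wc_type) != 2 or COMPLEMENT.get(wc_type[0]) != wc_type[1]:
        raise ValueError(f"invalid Watson-Crick pair type {wc_type!r}")
    rn_b, rn_c = "D" + wc_type[0], "D" + wc_type[1]
    names_b, raw_b = _monomer(rn_b)
    names_c, raw_c = _monomer(rn_c)
    lam = np.radians(_LAMBDA_DEG)
    gly_b = "N9" if wc_type[0] in PURINES else "N1"
    gly_c = "N9" if wc_type[1] in PURINES else "N1"
    blen = lambda names, coords, g: np.linalg.norm(
        coords[names.index("C1'")] - coords[names.index(g)]
    )
    c1_b = np.array([-_C1C1 / 2, 0.0, 0.0])
    c1_c = np.array([+_C1C1 / 2, 0.0, 0.0])
    n_b = c1_b + blen(names_b, raw_b, gly_b) * np.array([np.cos(lam), np.sin(lam), 0.0])
    n_c = c1_c + blen(names_c, raw_c, gly_c) * np.array([-np.cos(lam), np.sin(lam), 0.0])
    coords_b = _place(names_b, raw_b, rn_b, c1_b, n_b)
    coords_c0 = _place(names_c, raw_c, rn_c, c1_c, n_c)

    targets = _HB_TARGETS[frozenset((rn_b, rn_c))]

    def transform(x):
        tx, ty, th = x
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        cen = coords_c0.mean(axis=0)
        return (coords_c0 - cen) @ R.T + cen + np.array([tx, ty, 0.0])

    def residuals(x):
        coords_c = transform(x)
        out = []
        for dn_rn, dn_a, ac_rn, ac_a, d_tgt in targets:
            if dn_rn == rn_b:
                nd, cd, di = names_b, coords_b, names_b.index(dn_a)
            else:
                nd, cd, di = names_c, coords_c, names_c.index(dn_a)
            if ac_rn == rn_b:
                ca, ai = coords_b, names_b.index(ac_a)
            else:
                ca, ai = coords_c, names_c.index(ac_a)
            dist, dev = _bond_geometry(nd, cd, di, ca, ai)
            out.append(dist - d_tgt)
            out.append(_ANGLE_WEIGHT * np.radians(dev))
        return out

    sol = least_squares(residuals, np.zeros(3), method="trf")
    coords_c = transform(sol.x)
    mid = 0.5 * (coords_b[names_b.index("C1'")] + coords_c[names_c.index("C1'")])
    return IdealPair(
        rn_b, rn_c, names_b, names_c, coords_b - mid, coords_c - mid
    )
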