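"""Ion-shell occupancy, charge neutralization, residence times, Mg-P pairs.

An ion is "at the proximity of the DNA" if its minimum distance to any DNA
atom is within the cutoff (default 5 A).  The shell charge statistic is
Q5 = 2*N_Mg + N_Na - N_Cl; a fully neutralized 30-bp duplex (58 phosphates)
corresponds to Q5 = 58.  The minimal-image convention applies when the
trajectory carries an orthorhombic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ION_CHARGE, ION_SPECIES, Topology, Trajectory, trailing_window
from .basepairs import DEFAULT_WINDOW_FRACTION

__all__ = [
    "IonShellSeries",
    "ResidenceRecord",
    "PairDistanceSeries",
    "shell_counts",
    "shell_charge",
    "shell_series",
    "residence_analysis",
    "mg_p_pairs",
]


def _min_dist_to_dna(
    ion_xyz: np.ndarray, dna_xyz: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Minimum distance of each ion to any DNA atom (minimal image if box)."""
    delta = ion_xyz[:, None, :] - dna_xyz[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta)).min(axis=1)


def shell_counts(
    frame: np.ndarray,
    topology: Topology,
    cutoff: float = 5.0,
    box: np.ndarray | None = None,
) -> dict[str, int]:
    """Per-species ion counts within ``cutoff`` A of any DNA atom."""
    dna = frame[topology.dna_mask]
    out = {}
    for sp in ION_SPECIES:
        idx = topology.species_indices(sp)
        if idx.size == 0:
            out[sp] = 0
            continue
        dmin = _min_dist_to_dna(frame[idx], dna, box)
        out[sp] = int(np.sum(dmin <= cutoff))
    return out


def shell_charge(counts: dict[str, int]) -> int:
    """Net shell charge: 2*N_MG + N_NA - N_CL."""
    return sum(ION_CHARGE[sp] * counts.get(sp, 0) for sp in ION_SPECIES)


@dataclass
class IonShellSeries:
    """Per-frame shell counts per species and the per-frame net charge Q5."""

    cutoff: float
    counts: dict[str, np.ndarray]
    q5: np.ndarray = field(init=False)

    def __post_init__(self):
        q5 = np.zeros(len(next(iter(self.counts.values()))), dtype=int)
        for sp in ION_SPECIES:
            q5 += ION_CHARGE[sp] * self.counts[sp]
        self.q5 = q5
        # re-assert the defining identity frame-wise
        assert np.array_equal(
            self.q5,
            2 * self.counts["MG"] + self.counts["NA"] - self.counts["CL"],
        )

    def trailing_means(self, window_fraction: float = DEFAULT_WINDOW_FRACTION):
        win = trailing_window(len(self.q5), window_fraction)
        means = {sp: float(self.counts[sp][win].mean()) for sp in ION_SPECIES}
        means["Q5"] = float(self.q5[win].mean())
        return means

    def to_frame(self, dt_ns: float) -> pd.DataFrame:
        n = len(self.q5)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_ns": np.arange(n) * dt_ns,
                "n_mg": self.counts["MG"],
                "n_na": self.counts["NA"],
                "n_cl": self.counts["CL"],
                "q5": self.q5,
            }
        )


def shell_series(traj: Trajectory, cutoff: float = 5.0) -> IonShellSeries:
    """Shell occupancy over the whole trajectory."""
    counts = {sp: np.zeros(traj.n_frames, dtype=int) for sp in ION_SPECIES}
    for f in range(traj.n_frames):
        c = shell_counts(traj.coords[f], traj.topology, cutoff, traj.box)
        for sp in ION_SPECIES:
            counts[sp][f] = c[sp]
    return IonShellSeries(cutoff, counts)


@dataclass(frozen=True)
class ResidenceRecord:
    """Shell residence of one ion: total time Tn5 and its contiguous intervals."""

    ion_index: int
    serial: int
    species: str
    total_ns: float
    intervals_ns: tuple[tuple[float, float], ...]  # (start, end) per visit

    def __post_init__(self):
        total = sum(e - s for s, e in self.intervals_ns)
        assert abs(total - self.total_ns) < 1e-9


def _runs(mask: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """[start, end) index runs of True, merging gaps <= gap_tolerance frames."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > gap_tolerance:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def residence_analysis(
    traj: Trajectory,
    species: str,
    cutoff: float = 5.0,
    gap_tolerance_frames: int = 0,
) -> list[ResidenceRecord]:
    """Per-ion shell residence bookkeeping.

    Tn5 is the *total* occupancy time (sum over visits), not the longest
    single interval.  Runs separated by at most ``gap_tolerance_frames``
    out-of-shell frames are merged.
    """
    topo = traj.topology
    ions = topo.species_indices(species)
    if ions.size == 0:
        return []
    dna_mask = topo.dna_mask
    in_shell = np.zeros((traj.n_frames, ions.size), dtype=bool)
    for f in range(traj.n_frames):
        dmin = _min_dist_to_dna(traj.coords[f][ions], traj.coords[f][dna_mask], traj.box)
        in_shell[f] = dmin <= cutoff
    records = []
    for k, ion in enumerate(ions):
        runs = _runs(in_shell[:, k], gap_tolerance_frames)
        ivals = tuple(
            (s * traj.dt_ns, e * traj.dt_ns) for s, e in runs
        )
        total = sum(e - s for s, e in ivals)
        records.append(
            ResidenceRecord(
                int(ion), int(topo.serial[ion]), species, float(total), ivals
            )
        )
    return records


@dataclass(frozen=True)
class PairDistanceSeries:
    """Distance track of one persistent Mg-P contact."""

    mg_index: int
    p_index: int
    mg_serial: int
    p_serial: int
    distances: np.ndarray  # per frame, A
    trailing_mean: float
    trailing_sd: float


def mg_p_pairs(
    traj: Trajectory,
    pair_distance_threshold: float = 3.5,
    min_persistence_fraction: float = 0.5,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
) -> list[PairDistanceSeries]:
    """Lasting Mg-P contacts: pairs within the threshold for at least the
    stated fraction of trailing-window frames."""
    topo = traj.topology
    mg = topo.species_indices("MG")
    p = np.flatnonzero((topo.name == "P") & topo.dna_mask)
    if mg.size == 0 or p.size == 0 or pair_distance_threshold <= 0:
        return []
    win = trailing_window(traj.n_frames, window_fraction)
    delta = traj.coords[win][:, mg, None, :] - traj.coords[win][:, None, p, :]
    if traj.box is not None:
        delta -= traj.box * np.round(delta / traj.box)
    dwin = np.sqrt(np.einsum("fijk,fijk->fij", delta, delta))  # (W, n_mg, n_p)
    frac = (dwin <= pair_distance_threshold).mean(axis=0)
    out = []
    for i, j in zip(*np.nonzero(frac >= min_persistence_fraction)):
        mi, pj = int(mg[i]), int(p[j])
        d_all = np.linalg.norm(traj.coords[:, mi, :] - traj.coords[:, pj, :], axis=1)
        out.append(
            PairDistanceSeries(
                mi,
                pj,
                int(topo.serial[mi]),
                int(topo.serial[pj]),
                d_all,
                float(dwin[:, i, j].mean()),
                float(dwin[:, i, j].std(ddof=0)),
            )
        )
    return out
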