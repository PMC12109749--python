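"""Per-base-pair distance series: Delta-C6 and the Watson-Crick distance.

Delta-C6 is the distance between the C6 atoms of the two paired nucleotides
(~6.4 A in intact B-DNA); Delta-WC is the distance along the central WC
hydrogen-bond axis, read as purine N1 to pyrimidine N3 (~2.9 A when paired).
Both are plain Euclidean distances per frame and therefore invariant under
rigid motions of the frame; no superposition is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BasePair,
    DnabowError,
    PURINES,
    Trajectory,
    trailing_window,
)

__all__ = [
    "BasePairSeries",
    "ResidueProfile",
    "delta_c6",
    "delta_wc",
    "spring_pair_distance",
    "residue_profile",
    "molecule_mean",
    "open_fraction",
    "DEFAULT_WINDOW_FRACTION",
]

#: trailing-window proportion mirroring "last 100 ns of 260 ns"
DEFAULT_WINDOW_FRACTION = 100 / 260


@dataclass(frozen=True)
class BasePairSeries:
    pair: BasePair
    values: np.ndarray  # distance per frame, A
    metric_name: str  # "dC6" | "dWC"

    def __post_init__(self):
        if np.any(self.values <= 0):
            raise DnabowError(
                f"{self.metric_name} series for pair {self.pair.res_b} contains "
                "non-positive distances (degenerate/coincident atoms)"
            )


def _pair_distance(traj: Trajectory, pair: BasePair, atom_b: str, atom_c: str,
                   metric: str) -> BasePairSeries:
    ib = traj.topology.atom_index(pair.res_b, atom_b)
    ic = traj.topology.atom_index(pair.res_c, atom_c)
    vals = np.linalg.norm(traj.coords[:, ib, :] - traj.coords[:, ic, :], axis=1)
    return BasePairSeries(pair, vals, metric)


def delta_c6(traj: Trajectory, pair: BasePair) -> BasePairSeries:
    """Distance between the C6 atoms of the two bases of ``pair``, per frame."""
    return _pair_distance(traj, pair, "C6", "C6", "dC6")


def delta_wc(traj: Trajectory, pair: BasePair) -> BasePairSeries:
    """Watson-Crick axis distance (purine N1 to pyrimidine N3), per frame."""
    if pair.wc_type[0] in PURINES:
        atom_b, atom_c = "N1", "N3"
    else:
        atom_b, atom_c = "N3", "N1"
    return _pair_distance(traj, pair, atom_b, atom_c, "dWC")


def spring_pair_distance(traj: Trajectory) -> np.ndarray:
    """Per-frame C6-C6 distance between strand-B residues 2 and 29.

    This is the separation the virtual spring of the bent-sensor setup acts
    on; it visualises the tightening of the constraint.
    """
    i2 = traj.topology.atom_index(2, "C6")
    i29 = traj.topology.atom_index(29, "C6")
    return np.linalg.norm(traj.coords[:, i2, :] - traj.coords[:, i29, :], axis=1)


@dataclass(frozen=True)
class ResidueProfile:
    """Per-pair mean/sd of a base-pair metric over a trailing frame window."""

    pair_res_b: np.ndarray  # strand-B residue id of each pair
    mean: np.ndarray  # A
    sd: np.ndarray  # A
    metric_name: str
    window_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pair_res_b": self.pair_res_b, "mean_A": self.mean, "sd_A": self.sd}
        )


def residue_profile(
    series: list[BasePairSeries],
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
) -> ResidueProfile:
    """Trailing-window mean and sd for each pair's distance series."""
    if not series:
        raise DnabowError("no series given")
    n_frames = len(series[0].values)
    win = trailing_window(n_frames, window_fraction)
    res_b = np.array([s.pair.res_b for s in series])
    means = np.array([s.values[win].mean() for s in series])
    sds = np.array([s.values[win].std(ddof=0) for s in series])
    return ResidueProfile(res_b, means, sds, series[0].metric_name, window_fraction)


def molecule_mean(profile: ResidueProfile) -> float:
    """Molecule-wide metric: arithmetic mean of the per-pair means."""
    if profile.mean.size == 0:
        raise DnabowError("empty profile")
    return float(profile.mean.mean())


def open_fraction(series: BasePairSeries, threshold: float) -> float:
    """Fraction of frames in which the pair distance exceeds ``threshold``.

    With the synthetic generator's bimodal open/closed geometry this
    estimates the pair's stationary open probability.
    """
    return float(np.mean(series.values > threshold))
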