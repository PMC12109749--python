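"""FRET proximity-ratio analysis of donor/acceptor emission spectra.

The proximity ratio E_PR = F_A / (F_A + F_D) approximates the FRET
efficiency without spectral-leakage, quantum-yield or detector corrections;
F_D is the donor (Cy3) intensity at 570 nm and F_A the acceptor (Cy5)
intensity at 670 nm.  Sensitivity across methods is compared through the
relative change delta(c) = (Q(c)/Q(0) - 1) x 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DnabowError

__all__ = [
    "EmissionSpectrum",
    "FretResult",
    "DONOR_NM",
    "ACCEPTOR_NM",
    "intensities_at",
    "proximity_ratio",
    "dose_response",
    "relative_change",
]

DONOR_NM = 570.0
ACCEPTOR_NM = 670.0


@dataclass
class EmissionSpectrum:
    """One emission spectrum: wavelengths (nm, increasing) vs intensity.

    ``construct`` identifies the labelling geometry: "PI" (acceptor at
    residue 1) or "PX" (acceptor at residue 10); ``label`` carries the
    condition (Mg2+ concentration, uM).
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str | float = ""
    construct: str = "PI"

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity lengths differ")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (
            self.wavelengths[0] <= DONOR_NM and self.wavelengths[-1] >= ACCEPTOR_NM
        ):
            raise ValueError("spectrum must cover 570 and 670 nm")


@dataclass(frozen=True)
class FretResult:
    f_d: float
    f_a: float
    e_pr: float


def intensities_at(
    spectrum: EmissionSpectrum,
    donor_nm: float = DONOR_NM,
    acceptor_nm: float = ACCEPTOR_NM,
    window_nm: float = 0.0,
) -> tuple[float, float]:
    """Donor/acceptor intensities at the nearest grid points, or means over
    +-window_nm when a window is given."""
    wl, it = spectrum.wavelengths, spectrum.intensities
    out = []
    for target in (donor_nm, acceptor_nm):
        if not wl[0] <= target <= wl[-1]:
            raise DnabowError(f"wavelength {target} nm outside spectrum range")
        if window_nm > 0:
            mask = np.abs(wl - target) <= window_nm
            out.append(float(it[mask].mean()))
        else:
            out.append(float(it[np.argmin(np.abs(wl - target))]))
    return out[0], out[1]


def proximity_ratio(f_d: float, f_a: float) -> float:
    """E_PR = F_A / (F_A + F_D)."""
    if f_d < 0 or f_a < 0:
        raise DnabowError("intensities must be non-negative")
    total = f_d + f_a
    if total <= 0:
        raise DnabowError("zero total intensity: proximity ratio undefined")
    return f_a / total


def fret_result(spectrum: EmissionSpectrum, window_nm: float = 0.0) -> FretResult:
    f_d, f_a = intensities_at(spectrum, window_nm=window_nm)
    return FretResult(f_d, f_a, proximity_ratio(f_d, f_a))


def dose_response(spectra: list[EmissionSpectrum], window_nm: float = 0.0) -> pd.DataFrame:
    """Table (construct, concentration, f_d, f_a, e_pr), sorted by construct then condition."""
    if not spectra:
        raise DnabowError("no spectra given")
    rows = []
    for s in spectra:
        r = fret_result(s, window_nm)
        rows.append(
            {
                "construct": s.construct,
                "concentration_uM": s.label,
                "f_d": r.f_d,
                "f_a": r.f_a,
                "e_pr": r.e_pr,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["construct", "concentration_uM"], kind="stable")
        .reset_index(drop=True)
    )


def relative_change(q_by_concentration: dict) -> pd.DataFrame:
    """delta(c) = (Q(c)/Q(0) - 1) x 100%, per concentration.

    Q(0) must be present and nonzero; delta(0) is 0 by definition.  The
    result is unit-invariant in Q.
    """
    if 0 not in q_by_concentration and 0.0 not in q_by_concentration:
        raise DnabowError("baseline Q(0) missing")
    q0 = q_by_concentration.get(0, q_by_concentration.get(0.0))
    if q0 == 0:
        raise DnabowError("baseline Q(0) is zero")
    rows = [
        {"concentration": c, "Q": q, "delta_percent": (q / q0 - 1.0) * 100.0}
        for c, q in sorted(q_by_concentration.items())
    ]
    return pd.DataFrame(rows)
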