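"""DNA melting-curve Tm extraction: derivative of A(T) plus a Gaussian peak fit.

The melting temperature is located as the centre of a Gaussian (with a
constant baseline term, since measured dA/dT has nonzero wings) fitted to
the derivative of the 260-nm absorbance-versus-temperature curve.  The
derivative uses central differences on interior points and one-sided
differences at the ends; no smoothing is applied before differentiation
unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import DnabowError

__all__ = [
    "MeltingCurve",
    "TmFit",
    "BoundaryPeakError",
    "derivative",
    "fit_tm",
    "tm_vs_condition",
    "read_melting_csv",
]


class BoundaryPeakError(DnabowError):
    """The derivative maximum sits on the grid boundary; no interior peak to fit."""


@dataclass
class MeltingCurve:
    """Absorbance vs temperature for one condition (e.g. one Mg2+ concentration, uM)."""

    temperatures: np.ndarray  # deg C, strictly increasing
    absorbance: np.ndarray  # arbitrary units
    label: str | float = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.temperatures.shape != self.absorbance.shape:
            raise ValueError("temperature and absorbance lengths differ")
        if self.temperatures.size < 10:
            raise ValueError("melting curve needs at least 10 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperatures[-1] - self.temperatures[0] < 10:
            raise ValueError("melting curve must span at least 10 deg C")


def derivative(curve: MeltingCurve) -> np.ndarray:
    """dA/dT: central differences inside, one-sided at the ends; length preserved."""
    if curve.temperatures.size < 3:
        raise DnabowError("derivative needs at least 3 points")
    return np.gradient(curve.absorbance, curve.temperatures)


@dataclass(frozen=True)
class TmFit:
    tm: float  # Gaussian centre, deg C
    width: float  # Gaussian sigma, deg C
    amplitude: float
    baseline: float
    rmse: float
    converged: bool
    multimodal: bool  # a second comparable peak was present


def _gauss_baseline(t, center, sigma, amp, base):
    return base + amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def fit_tm(
    temperatures: np.ndarray,
    dadt: np.ndarray,
    smoothing_window: int | None = None,
) -> TmFit:
    """Gaussian + constant-baseline least squares on the derivative peak.

    Initialized at the argmax of dA/dT.  A peak at the grid boundary raises
    :class:`BoundaryPeakError`; non-convergence is flagged, never silently
    replaced.  Curves with two comparable peaks report the global maximum
    with ``multimodal=True``.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(dadt, dtype=float)
    if smoothing_window:
        from .hbonds import smooth_series

        y = smooth_series(y, smoothing_window)
    imax = int(np.argmax(y))
    if imax in (0, t.size - 1):
        raise BoundaryPeakError(
            f"derivative maximum at grid boundary (T = {t[imax]:.1f} C)"
        )
    base0 = float(np.median(y))
    amp0 = float(y[imax] - base0)
    if amp0 <= 0:
        raise DnabowError("derivative has no positive interior peak")
    # width guess: half-max crossing distance, fall back to 1/10 span
    above = y - base0 > amp0 / 2
    sigma0 = max((t[above].max() - t[above].min()) / 2.355, (t[-1] - t[0]) / 20) if above.any() else (t[-1] - t[0]) / 10
    p0 = [t[imax], sigma0, amp0, base0]
    converged = True
    try:
        popt, _ = curve_fit(_gauss_baseline, t, y, p0=p0, maxfev=10000)
    except RuntimeError:
        converged = False
        popt = p0
    center, sigma, amp, base = popt
    sigma = abs(float(sigma))
    resid = y - _gauss_baseline(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if not t[0] <= center <= t[-1]:
        converged = False
    peaks, _ = find_peaks(y, height=base0 + 0.5 * amp0, prominence=0.5 * amp0)
    multimodal = len(peaks) > 1
    return TmFit(float(center), sigma, float(amp), float(base), rmse, converged, multimodal)


def tm_vs_condition(curves: list[MeltingCurve]) -> pd.DataFrame:
    """One fitted row per curve, sorted by condition label.

    Failed fits are reported per row (``error`` column) rather than aborting
    the table; duplicate condition labels are kept and flagged.
    """
    if not curves:
        raise DnabowError("no curves given")
    rows = []
    for c in curves:
        row = {"condition": c.label, "tm": np.nan, "width": np.nan, "rmse": np.nan,
               "converged": False, "multimodal": False, "error": ""}
        try:
            fit = fit_tm(c.temperatures, derivative(c))
            row.update(
                tm=fit.tm, width=fit.width, rmse=fit.rmse,
                converged=fit.converged, multimodal=fit.multimodal,
            )
        except DnabowError as exc:
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("condition", kind="stable").reset_index(drop=True)
    df["duplicate_condition"] = df["condition"].duplicated(keep=False)
    return df


def read_melting_csv(path, label=None) -> MeltingCurve:
    """Read a curve from CSV with columns temperature_C, absorbance."""
    df = pd.read_csv(path, comment="#")
    return MeltingCurve(
        df["temperature_C"].to_numpy(), df["absorbance"].to_numpy(),
        label if label is not None else str(path),
    )
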