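"""Plate-reader computations: doubling time, reporter normalization,
fluorogenic turn-on ratios.

All three operations are pure and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthCurve", "doubling_time", "normalized_reporter", "turn_on_ratio"]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 growth curve: strictly increasing times (min) and readings."""

    time_min: np.ndarray
    od: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_min", np.asarray(self.time_min, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if len(self.time_min) != len(self.od):
            raise ValueError("time and OD arrays must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.blank < 0:
            raise ValueError("blank must be non-negative")


def doubling_time(
    curve: GrowthCurve,
    od_min: float = 0.015,
    n_points: int = 10,
    nonlinear: bool = False,
) -> float:
    """Doubling time (min) from the early exponential phase.

    After blank subtraction, the first ``n_points`` consecutive readings
    starting at the first point with OD >= ``od_min`` are fitted; the
    default is a least-squares line on ln(OD) vs time (doubling time =
    ln 2 / slope), with a nonlinear exponential fit available as a
    cross-check.  Raises if fewer than ``n_points`` qualify or the
    fitted growth rate is not positive.
    """
    od = curve.od - curve.blank
    qual = np.nonzero(od >= od_min)[0]
    if len(qual) == 0 or qual[0] + n_points > len(od):
        raise ValueError(f"fewer than {n_points} readings at or above OD {od_min}")
    i0 = qual[0]
    t = curve.time_min[i0 : i0 + n_points]
    y = od[i0 : i0 + n_points]
    if np.any(y <= 0):
        raise ValueError("non-positive OD readings inside the fit window")
    if nonlinear:
        from scipy.optimize import curve_fit

        slope0 = np.polyfit(t, np.log(y), 1)[0]
        popt, _ = curve_fit(
            lambda tt, a, k: a * np.exp(k * tt), t, y, p0=(y[0] * np.exp(-slope0 * t[0]), slope0)
        )
        slope = popt[1]
    else:
        slope = np.polyfit(t, np.log(y), 1)[0]
    if slope < 1e-10:  # zero within round-off: flat or declining culture
        raise ValueError("non-positive growth rate: the culture is not growing")
    return float(np.log(2.0) / slope)


def normalized_reporter(fluorescence: float, od: float) -> float:
    """Reporter fluorescence normalized to cell density (F / OD600)."""
    if od <= 0:
        raise ValueError("OD must be positive")
    return float(fluorescence) / float(od)


def turn_on_ratio(f_plus: float, f_minus: float) -> float:
    """Fluorogenic turn-on: signal with the clickable amino acid over without."""
    if f_minus <= 0:
        raise ValueError("the reference fluorescence must be positive")
    return float(f_plus) / float(f_minus)
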