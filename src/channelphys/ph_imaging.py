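"""Ratiometric organelle-pH analysis (dual-excitation pHluorin-style).

A ratiometric pH sensor excited at 405 and 475 nm reports luminal pH
through the 405:475 intensity ratio.  A calibration curve fitted to
standards of known pH maps ratios to pH; the resting pH is the mean over
a pre-stimulus window, and the response to a weak-base (NH4Cl) pulse —
the luminal alkalinization magnitude — reflects the compartment's
buffering behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthgen import FluorTraces

__all__ = [
    "CalibCurve",
    "PhResult",
    "ratio_series",
    "fit_calibration",
    "ratio_to_ph",
    "buffering_response",
]


def _sigmoid_ph(ratio, ph_min, ph_max, ratio_half, slope):
    return ph_min + (ph_max - ph_min) / (1.0 + np.exp((ratio_half - ratio)
                                                      / slope))


@dataclass(frozen=True)
class CalibCurve:
    """Boltzmann-sigmoid calibration pH(ratio).

    ``pH(r) = pH_min + (pH_max - pH_min) / (1 + exp((r_half - r)/slope))``
    — monotone increasing in the ratio for ``slope > 0``, analytically
    invertible on the open pH interval (pH_min, pH_max).
    """

    ph_min: float
    ph_max: float
    ratio_half: float
    slope: float
    residual_sd: float = 0.0
    ratio_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if self.ph_max <= self.ph_min:
            raise ValueError("ph_max must exceed ph_min")
        if self.slope <= 0:
            raise ValueError("slope must be > 0 (monotone increasing)")

    def ph_of_ratio(self, ratio):
        return _sigmoid_ph(np.asarray(ratio, dtype=float), self.ph_min,
                           self.ph_max, self.ratio_half, self.slope)

    def ratio_of_ph(self, ph):
        """Analytic inverse; rejects pH outside (ph_min, ph_max)."""
        ph_arr = np.asarray(ph, dtype=float)
        if ((ph_arr <= self.ph_min) | (ph_arr >= self.ph_max)).any():
            raise ValueError(
                f"pH outside the invertible calibration domain "
                f"({self.ph_min}, {self.ph_max})")
        frac = (ph_arr - self.ph_min) / (self.ph_max - self.ph_min)
        return self.ratio_half - self.slope * np.log(1.0 / frac - 1.0)


@dataclass(frozen=True)
class PhResult:
    """Resting pH, post-stimulus pH and their difference."""

    resting_pH: float
    post_pH: float
    delta_pH: float


def ratio_series(traces: FluorTraces) -> np.ndarray:
    """Elementwise 405:475 intensity ratio."""
    bad = np.flatnonzero(traces.f475 <= 0)
    if len(bad):
        raise ValueError(f"non-positive 475 nm intensity at index {bad[0]}")
    return traces.f405 / traces.f475


def fit_calibration(standards, residual_tol: float = np.inf) -> CalibCurve:
    """Least-squares Boltzmann fit of (pH, ratio) calibration standards.

    Needs at least four standards spanning the pH range; the standards
    must be monotone (ratio increasing with pH).  The fitted curve's
    valid ratio range is the span of the standards.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need >= 4 (pH, ratio) standards")
    order = np.argsort(pts[:, 0])
    ph, ratio = pts[order, 0], pts[order, 1]
    if not (np.diff(ratio) > 0).all():
        raise ValueError("standards are not monotone in pH")
    span = ph.max() - ph.min()
    p0 = (ph.min() - 0.25 * span, ph.max() + 0.25 * span,
          float(np.median(ratio)), max(0.25 * np.ptp(ratio), 1e-3))
    popt, _ = curve_fit(
        _sigmoid_ph, ratio, ph, p0=p0, maxfev=20000,
        bounds=([-np.inf, -np.inf, -np.inf, 1e-9],
                [np.inf, np.inf, np.inf, np.inf]))
    resid = ph - _sigmoid_ph(ratio, *popt)
    rsd = float(np.sqrt(np.mean(resid ** 2)))
    if rsd > residual_tol:
        raise ValueError(f"calibration residual SD {rsd:.3g} exceeds "
                         f"tolerance {residual_tol:.3g}")
    return CalibCurve(*popt, residual_sd=rsd,
                      ratio_range=(float(ratio.min()), float(ratio.max())))


def ratio_to_ph(ratio, calib: CalibCurve):
    """Calibrated pH for ratios inside the curve's valid range."""
    r = np.asarray(ratio, dtype=float)
    lo, hi = calib.ratio_range
    if ((r < lo) | (r > hi)).any():
        raise ValueError(f"ratio outside the calibrated range [{lo}, {hi}]")
    out = calib.ph_of_ratio(r)
    return float(out) if np.isscalar(ratio) else out


def buffering_response(t_s: np.ndarray, ph: np.ndarray,
                       onset_s: float = 30.0, pre_window_s: float = 10.0,
                       post_offset_s: float = 10.0) -> PhResult:
    """Resting pH and weak-base response magnitude from a pH time series.

    Resting pH is the mean over ``[onset - pre_window, onset)``; the
    post-stimulus pH is read at ``onset + post_offset`` (nearest sample);
    delta is post minus resting.
    """
    t = np.asarray(t_s, dtype=float)
    p = np.asarray(ph, dtype=float)
    if t.shape != p.shape:
        raise ValueError("t_s and ph length mismatch")
    if not t[0] <= onset_s <= t[-1]:
        raise ValueError("stimulus onset outside the trace")
    if onset_s - pre_window_s < t[0]:
        raise ValueError("pre-stimulus window extends before the trace")
    t_post = onset_s + post_offset_s
    if t_post > t[-1]:
        raise ValueError("post-stimulus time extends beyond the trace")
    pre = (t >= onset_s - pre_window_s) & (t < onset_s)
    if not pre.any():
        raise ValueError("no samples in the pre-stimulus window")
    resting = float(p[pre].mean())
    post = float(p[np.argmin(np.abs(t - t_post))])
    return PhResult(resting, post, post - resting)
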