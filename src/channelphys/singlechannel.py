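"""Idealization and kinetic analysis of single-channel current traces.

Implements the standard analysis chain for stationary single-channel
records: half-amplitude threshold idealization (with hysteresis and a
fixed dead time), open probability, maximum-likelihood exponential
dwell-time fits, Gaussian-mixture amplitude histograms, polynomial
unitary I-V fits, and reconstruction of the macroscopic i x Po voltage
relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .synthgen import EventSequence, TraceRecord

__all__ = [
    "PoCurve",
    "DwellFit",
    "AmpHistFit",
    "UnitaryIV",
    "idealize",
    "open_probability",
    "fit_dwell_exponential",
    "amplitude_histogram_fit",
    "unitary_iv_fit",
    "reconstruct_macroscopic",
    "rectification_index",
]


@dataclass
class PoCurve:
    """Open probability vs holding potential with bookkeeping counts."""

    voltage_mV: np.ndarray
    po: np.ndarray
    n_events: np.ndarray | None = None
    n_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.po = np.asarray(self.po, dtype=float)
        if ((self.po < 0) | (self.po > 1)).any():
            raise ValueError("Po must lie in [0, 1]")


@dataclass
class DwellFit:
    """Single-exponential dwell-time fit (per state class)."""

    tau_ms: float
    n_events: int
    log_likelihood: float
    dead_time_ms: float = 0.0


@dataclass
class AmpHistFit:
    """Gaussian-mixture fit of the sample amplitude distribution."""

    means_pA: np.ndarray      # sorted ascending
    sds_pA: np.ndarray
    weights: np.ndarray       # sum to 1
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    peak_separation_sd: float  # |mean gap| / pooled SD, fit-quality metric


@dataclass
class UnitaryIV:
    """Polynomial fit of the unitary-current I-V relationship."""

    voltage_mV: np.ndarray
    amplitude_pA: np.ndarray
    coefficients: np.ndarray   # ascending powers
    degree: int
    residuals_pA: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __call__(self, v: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(v, self.coefficients)


# ---------------------------------------------------------------------------


def idealize(trace: TraceRecord, unitary_amp_pA: float,
             threshold_frac: float = 0.5, dead_time_ms: float = 0.0,
             hysteresis_frac: float = 0.1) -> EventSequence:
    """Half-amplitude threshold idealization of a binary open/closed trace.

    Samples are classified by crossing ``threshold_frac`` of the unitary
    amplitude, sign-aware, with a hysteresis band of ``hysteresis_frac``
    of the amplitude (opening and closing thresholds straddle the half
    level), then runs shorter than ``dead_time_ms`` are merged into their
    neighbors.  Returns the alternating closed/open event list.
    """
    if unitary_amp_pA == 0:
        raise ValueError("unitary_amp_pA must be nonzero")
    expected_sign = np.sign(trace.holding_mV) or 1.0
    if np.sign(unitary_amp_pA) not in (0.0, expected_sign):
        warnings.warn(
            "unitary amplitude sign inconsistent with the holding-voltage "
            "convention; proceeding on magnitude", stacklevel=2)
    # normalize so the open level sits near +1 regardless of polarity
    x = trace.i_pA * np.sign(unitary_amp_pA) / abs(unitary_amp_pA)
    hi = threshold_frac + 0.5 * hysteresis_frac
    lo = threshold_frac - 0.5 * hysteresis_frac
    above = x > hi
    below = x < lo
    decided = above | below
    idx = np.flatnonzero(decided)
    n = len(x)
    open_mask = np.zeros(n, dtype=bool)
    if len(idx):
        vals = above[idx]
        # forward-fill the last decided classification; closed before the
        # first decision point
        starts = np.concatenate([[0], idx + 1])
        seg_vals = np.concatenate([[False], vals])
        lengths = np.diff(np.concatenate([starts, [n]]))
        open_mask = np.repeat(seg_vals, lengths)
        open_mask[idx] = vals
    dt = 1.0 / trace.sampling_khz
    # runs -> (is_open, n_samples)
    change = np.flatnonzero(np.diff(open_mask.astype(np.int8)))
    bounds = np.concatenate([[0], change + 1, [n]])
    runs = [(bool(open_mask[b]), int(e - b))
            for b, e in zip(bounds[:-1], bounds[1:])]
    if dead_time_ms > 0:
        min_samples = int(np.ceil(dead_time_ms / dt))
        runs = _merge_short_runs(runs, min_samples)
    events = [("open" if is_open else "closed", k * dt) for is_open, k in runs]
    return EventSequence(events, n * dt)


def _merge_short_runs(runs: list[tuple[bool, int]], min_samples: int
                      ) -> list[tuple[bool, int]]:
    """Merge runs shorter than the dead time into their neighbors.

    Shortest-first merging; interior short runs are absorbed by their
    neighbors (which then coalesce), edge runs by their single neighbor.
    """
    runs = list(runs)
    while len(runs) > 1:
        lengths = [k for _, k in runs]
        j = int(np.argmin(lengths))
        if lengths[j] >= min_samples:
            break
        state, k = runs.pop(j)
        if 0 < j < len(runs):  # absorbed between two same-state neighbors
            s_prev, k_prev = runs[j - 1]
            s_next, k_next = runs.pop(j)
            runs[j - 1] = (s_prev, k_prev + k + k_next)
        elif j == 0:
            s_next, k_next = runs[0]
            runs[0] = (s_next, k_next + k)
        else:
            s_prev, k_prev = runs[-1]
            runs[-1] = (s_prev, k_prev + k)
    return runs


def open_probability(events: EventSequence) -> float:
    """Fraction of time in conducting states (subconductance counts as open)."""
    if not events.events:
        raise ValueError("empty event sequence")
    return events.time_in(("open", "sub")) / events.total_ms


def fit_dwell_exponential(durations_ms: np.ndarray,
                          dead_time_ms: float = 0.0) -> DwellFit:
    """Maximum-likelihood single-exponential fit of dwell durations.

    With left truncation at the dead time, memorylessness gives the MLE in
    closed form: ``tau_hat = mean(durations) - dead_time``.
    """
    d = np.asarray(durations_ms, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 dwell durations")
    if (d <= dead_time_ms).any():
        raise ValueError("all durations must exceed the dead time")
    tau = float(d.mean() - dead_time_ms)
    ll = float(np.sum(-np.log(tau) - (d - dead_time_ms) / tau))
    return DwellFit(tau, len(d), ll, dead_time_ms)


def amplitude_histogram_fit(trace: TraceRecord, n_components: int = 2,
                            n_restarts: int = 5, seed: int = 0,
                            n_bins: int = 100) -> AmpHistFit:
    """Gaussian-mixture fit of the all-points amplitude histogram.

    EM with k-means initialization and ``n_restarts`` seeded restarts;
    components are reported sorted by mean, and the separation of the two
    best-separated adjacent components in pooled-SD units is returned as
    a quality metric.
    """
    x = trace.i_pA.reshape(-1, 1)
    if len(x) < 10 * n_components:
        raise ValueError("trace too short for the requested mixture size")
    gm = GaussianMixture(n_components=n_components, n_init=n_restarts,
                         init_params="k-means++", random_state=seed,
                         reg_covar=1e-10)
    gm.fit(x)
    if not gm.converged_:
        raise RuntimeError(
            f"mixture fit failed to converge after {n_restarts} restarts "
            f"(lower bound {gm.lower_bound_:.3g})")
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    counts, edges = np.histogram(trace.i_pA, bins=n_bins)
    if n_components > 1:
        gaps = np.diff(means)
        pooled = np.sqrt(0.5 * (sds[:-1] ** 2 + sds[1:] ** 2))
        sep = float(np.max(gaps / pooled))
    else:
        sep = np.inf
    return AmpHistFit(means, sds, weights, edges, counts, sep)


def unitary_iv_fit(points, degree: int = 3) -> UnitaryIV:
    """Least-squares polynomial fit of unitary amplitudes vs voltage.

    ``points`` is a sequence of (voltage_mV, amplitude_pA) pairs; needs at
    least ``degree + 1`` distinct voltages.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (voltage, amplitude) pairs")
    v, a = pts[:, 0], pts[:, 1]
    if len(np.unique(v)) < degree + 1:
        raise ValueError(
            f"degree-{degree} fit needs >= {degree + 1} distinct voltages")
    coeffs = np.polynomial.polynomial.polyfit(v, a, degree)
    resid = a - np.polynomial.polynomial.polyval(v, coeffs)
    return UnitaryIV(v, a, coeffs, degree, resid)


def reconstruct_macroscopic(uiv: UnitaryIV, po: PoCurve,
                            v_neg: float = -150.0, v_pos: float = 100.0
                            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Macroscopic i x Po voltage relationship from unitary data.

    Evaluates the unitary polynomial on the Po voltage grid and multiplies
    elementwise; the Po grid must lie inside the fitted voltage range.
    Returns ``(voltage, i_times_po, rectification)`` where the
    rectification index of the product curve is evaluated at
    ``(v_neg, v_pos)`` when covered, else at the grid extremes.
    """
    v = po.voltage_mV
    vmin, vmax = uiv.voltage_mV.min(), uiv.voltage_mV.max()
    if v.min() > vmax or v.max() < vmin:
        raise ValueError("Po and unitary I-V voltage ranges are disjoint")
    product = np.asarray(uiv(v)) * po.po
    lo = v_neg if v.min() <= v_neg else v.min()
    hi = v_pos if v.max() >= v_pos else v.max()
    rect = rectification_index((v, product), v_neg=lo, v_pos=hi)
    return v, product, rect


def rectification_index(iv, v_neg: float = -150.0, v_pos: float = 100.0
                        ) -> float:
    """Inward-rectification index ``|I(v_neg)| / |I(v_pos)|``.

    Values above 1 indicate inward rectification.  ``iv`` is a
    ``(voltage, current)`` array pair; currents at the two probe voltages
    are linearly interpolated on the grid.
    """
    v, i = (np.asarray(a, dtype=float) for a in iv)
    order = np.argsort(v)
    v, i = v[order], i[order]
    for probe in (v_neg, v_pos):
        if probe < v[0] or probe > v[-1]:
            raise ValueError(f"{probe} mV outside the I-V voltage range")
    i_neg = np.interp(v_neg, v, i)
    i_pos = np.interp(v_pos, v, i)
    if i_pos == 0:
        raise ValueError("current at the positive probe voltage is zero; "
                         "rectification index undefined")
    return abs(i_neg) / abs(i_pos)
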