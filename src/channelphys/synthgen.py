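"""Synthetic-data generators with known ground truth.

Every input class the analysis modules consume can be generated here from
explicit model parameters, so that recovery tests can compare estimates
against the generating truth:

- continuous-time Markov gating realizations (:func:`simulate_gating`) and
  their rendering into noisy, filtered current traces (:func:`render_trace`);
- Hill-model dose-response tables (:func:`gen_dose_response`);
- Gaussian interaction-energy series for the LIE estimator
  (:func:`gen_energy_traces`);
- lipid axis-distance series plus matching 3-D coordinate frames
  (:func:`gen_lipid_frames`);
- two-channel ratiometric fluorescence traces with a weak-base pulse
  (:func:`gen_ph_traces`).

Gating is simulated event-driven (Gillespie), not on a fixed time step, so
dwell times are exactly exponential.  Units: pA, mV, ms, pS, kHz; inward
current negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .lipid_geometry import Axis, AxisDistanceSeries, CoordinateFrame

__all__ = [
    "GatingModel",
    "VoltageProtocol",
    "EventSequence",
    "TraceRecord",
    "DoseResponse",
    "FluorTraces",
    "two_state_model",
    "default_gating_model",
    "simulate_gating",
    "render_trace",
    "gen_dose_response",
    "gen_energy_traces",
    "gen_lipid_frames",
    "gen_ph_traces",
    "hill_response",
    "LIE_SUBSYSTEMS",
]

OPEN_CLASS = ("open", "sub")  # conducting state classes; "sub" = subconductance


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GatingModel:
    """Voltage-dependent Markov gating scheme for a single channel.

    Parameters
    ----------
    state_labels
        Ordered labels; each must start with one of ``closed``, ``open`` or
        ``sub`` (e.g. ``("closed", "open", "sub")``).
    conductance_pS
        Per-state conductance in pS; closed states must have exactly 0.
    rates
        Either a callable ``voltage_mV -> Q`` returning the transition-rate
        matrix in 1/ms (rows sum to zero, off-diagonals >= 0), or a mapping
        from discrete voltage levels to such matrices.
    erev_mV
        Reversal potential of the unitary current.
    """

    state_labels: tuple[str, ...]
    conductance_pS: tuple[float, ...]
    rates: Callable[[float], np.ndarray] | Mapping[float, np.ndarray]
    erev_mV: float = 0.0

    def __post_init__(self) -> None:
        if len(self.state_labels) != len(self.conductance_pS):
            raise ValueError("state_labels and conductance_pS length mismatch")
        for lab, g in zip(self.state_labels, self.conductance_pS):
            if not lab.startswith(("closed", "open", "sub")):
                raise ValueError(f"unknown state class for label {lab!r}")
            if lab.startswith("closed") and g != 0.0:
                raise ValueError("closed-state conductance must be exactly 0")
            if g < 0:
                raise ValueError("conductance must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def rate_matrix(self, voltage_mV: float) -> np.ndarray:
        """Validated transition-rate matrix (1/ms) at a holding potential."""
        if callable(self.rates):
            q = np.asarray(self.rates(voltage_mV), dtype=float)
        else:
            try:
                q = np.asarray(self.rates[voltage_mV], dtype=float)
            except KeyError:
                raise KeyError(
                    f"no rate matrix tabulated at {voltage_mV} mV; "
                    f"available: {sorted(self.rates)}"
                ) from None
        if q.shape != (self.n_states, self.n_states):
            raise ValueError(f"rate matrix shape {q.shape} != "
                             f"({self.n_states}, {self.n_states})")
        off = q - np.diag(np.diag(q))
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate-matrix rows must sum to zero")
        return q

    def is_open(self, label: str) -> bool:
        return label.startswith(OPEN_CLASS)

    def stationary_distribution(self, voltage_mV: float) -> np.ndarray:
        """Stationary distribution of the chain at one voltage.

        Solves pi Q = 0 with sum(pi) = 1 by least squares; for a reducible
        chain (e.g. opening rates all zero) the result is supported on the
        reachable closed class.
        """
        q = self.rate_matrix(voltage_mV)
        n = self.n_states
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def stationary_po(self, voltage_mV: float) -> float:
        """Stationary open probability (subconductance counted as open)."""
        pi = self.stationary_distribution(voltage_mV)
        mask = np.array([self.is_open(s) for s in self.state_labels])
        return float(pi[mask].sum())


@dataclass(frozen=True)
class VoltageProtocol:
    """Step or ramp command-voltage protocol.

    The default step family spans +90 to -150 mV in 30 mV decrements; the
    default ramp descends from +100 to -150 mV over 1000 ms.
    """

    kind: str = "step"
    levels_mV: tuple[float, ...] = tuple(np.arange(90.0, -151.0, -30.0))
    durations_ms: tuple[float, ...] | float = 1000.0
    ramp_from_mV: float = 100.0
    ramp_to_mV: float = -150.0
    ramp_ms: float = 1000.0
    sampling_khz: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp"):
            raise ValueError("kind must be 'step' or 'ramp'")
        if self.sampling_khz <= 0:
            raise ValueError("sampling_khz must be > 0")
        if self.kind == "step":
            dur = self.durations_ms
            durs = (dur,) * len(self.levels_mV) if np.isscalar(dur) else dur
            if any(d <= 0 for d in durs):
                raise ValueError("durations must be > 0")
        elif self.ramp_ms <= 0:
            raise ValueError("ramp_ms must be > 0")

    def ramp_voltage(self, t_ms: np.ndarray) -> np.ndarray:
        """Instantaneous command voltage at times within one ramp."""
        if self.kind != "ramp":
            raise ValueError("ramp_voltage is only defined for ramp protocols")
        frac = np.asarray(t_ms, dtype=float) / self.ramp_ms
        if ((frac < 0) | (frac > 1 + 1e-12)).any():
            raise ValueError("time outside the ramp duration")
        return self.ramp_from_mV + (self.ramp_to_mV - self.ramp_from_mV) * frac


@dataclass
class EventSequence:
    """Idealized record: ordered (state label, duration ms) pairs."""

    events: list[tuple[str, float]]
    total_ms: float

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.events):
            raise ValueError("event durations must be > 0")
        for (a, _), (b, _) in zip(self.events, self.events[1:]):
            if a == b:
                raise ValueError("adjacent events must have distinct states")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def durations(self, label_prefix: str | None = None) -> np.ndarray:
        """Durations (ms), optionally restricted to one state class."""
        if label_prefix is None:
            return np.array([d for _, d in self.events])
        return np.array([d for s, d in self.events if s.startswith(label_prefix)])

    def time_in(self, prefixes: Sequence[str]) -> float:
        return float(sum(d for s, d in self.events if s.startswith(tuple(prefixes))))


@dataclass
class TraceRecord:
    """Sampled current trace with acquisition metadata."""

    t_ms: np.ndarray
    i_pA: np.ndarray
    holding_mV: float
    sampling_khz: float
    filter_khz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        if self.t_ms.shape != self.i_pA.shape:
            raise ValueError("t_ms and i_pA must have equal length")
        if len(self.t_ms) > 1:
            dt = np.diff(self.t_ms)
            if (dt <= 0).any():
                raise ValueError("t_ms must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_khz, rtol=1e-6):
                raise ValueError("t_ms spacing inconsistent with sampling_khz")


@dataclass
class DoseResponse:
    """Inhibitor dose-response table: % of control current vs concentration."""

    concentration_uM: np.ndarray
    response_pct: np.ndarray
    replicate: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.concentration_uM = np.asarray(self.concentration_uM, dtype=float)
        self.response_pct = np.asarray(self.response_pct, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if (self.concentration_uM <= 0).any():
            raise ValueError("concentrations must be > 0")
        if not (len(self.concentration_uM) == len(self.response_pct)
                == len(self.replicate)):
            raise ValueError("column length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration_uM": self.concentration_uM,
            "response_pct": self.response_pct,
            "replicate": self.replicate,
        })


@dataclass
class FluorTraces:
    """Two-channel ratiometric fluorescence time series (405 and 475 nm)."""

    t_s: np.ndarray
    f405: np.ndarray
    f475: np.ndarray
    stimulus_onset_s: float | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        self.f475 = np.asarray(self.f475, dtype=float)
        if not (self.t_s.shape == self.f405.shape == self.f475.shape):
            raise ValueError("channel length mismatch")
        if (self.f405 <= 0).any() or (self.f475 <= 0).any():
            raise ValueError("fluorescence intensities must be > 0")


# ---------------------------------------------------------------------------
# gating models
# ---------------------------------------------------------------------------


def two_state_model(mean_open_ms: float, mean_closed_ms: float,
                    conductance_pS: float = 60.0,
                    erev_mV: float = 0.0) -> GatingModel:
    """Voltage-independent closed<->open model with given mean dwell times.

    The stationary open fraction is ``mean_open / (mean_open + mean_closed)``.
    """
    if mean_open_ms <= 0 or mean_closed_ms <= 0:
        raise ValueError("mean dwell times must be > 0")
    alpha = 1.0 / mean_closed_ms   # opening rate
    beta = 1.0 / mean_open_ms      # closing rate
    q = np.array([[-alpha, alpha], [beta, -beta]])
    return GatingModel(("closed", "open"), (0.0, conductance_pS),
                       lambda v, _q=q: _q, erev_mV)


def two_state_model_from_po(po: float, mean_open_ms: float,
                            conductance_pS: float = 60.0,
                            erev_mV: float = 0.0) -> GatingModel:
    """Two-state model pinned to a stationary open probability.

    Mean closed time is derived as ``mean_open * (1 - po) / po``.
    """
    if not 0 < po < 1:
        raise ValueError("po must be in (0, 1)")
    return two_state_model(mean_open_ms, mean_open_ms * (1 - po) / po,
                           conductance_pS, erev_mV)


# Default U-shaped voltage dependence: no openings at 0 mV, brief flickery
# openings at positive potentials (max Po 0.6 at +90 mV, with a 0.5x
# subconductance level), long sparse openings at negative potentials
# (Po 0.3 at -150 mV).  The stationary Po is pinned per voltage; mean open
# times are 26 ms (positive limb) and 421 ms (negative limb).
_DEFAULT_PO = {
    -150.0: 0.30, -120.0: 0.22, -90.0: 0.10, -60.0: 0.05, -30.0: 0.02,
    0.0: 0.0, 30.0: 0.15, 60.0: 0.40, 90.0: 0.60,
}
_SUB_RATIO = 0.25       # stationary Osub/O occupancy ratio on the positive limb
_SUB_EXIT_RATE = 0.1    # 1/ms, Osub -> O


def default_gating_model(conductance_pS: float = 60.0,
                         erev_mV: float = 0.0,
                         po_table: Mapping[float, float] | None = None
                         ) -> GatingModel:
    """Default three-state model C <-> O <-> Osub over the step family.

    The subconductance state (0.5x the full open conductance) is reachable
    only at positive potentials.  Opening rates are scaled so that the
    stationary conducting-class probability equals the tabulated Po at
    every voltage; ``Po = 0`` at 0 mV is enforced by a zero opening rate.
    """
    po_tab = dict(_DEFAULT_PO if po_table is None else po_table)
    matrices: dict[float, np.ndarray] = {}
    for v, po in po_tab.items():
        tau_open = 26.0 if v > 0 else 421.0
        beta = 1.0 / tau_open
        if v > 0:
            r = _SUB_RATIO
            k_so = _SUB_EXIT_RATE
            k_os = r * k_so
        else:
            r, k_so, k_os = 0.0, _SUB_EXIT_RATE, 0.0
        # pin stationary P(open)+P(sub) = po: pi_O/pi_C = alpha/beta,
        # pi_sub/pi_O = r  =>  alpha = beta * po / ((1 - po) (1 + r))
        alpha = 0.0 if po == 0 else beta * po / ((1.0 - po) * (1.0 + r))
        matrices[v] = np.array([
            [-alpha, alpha, 0.0],
            [beta, -(beta + k_os), k_os],
            [0.0, k_so, -k_so],
        ])
    return GatingModel(("closed", "open", "sub"),
                       (0.0, conductance_pS, 0.5 * conductance_pS),
                       matrices, erev_mV)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_gating(model: GatingModel, voltage_mV: float, duration_ms: float,
                    seed: int | np.random.Generator | None = None,
                    start_state: int | None = None) -> EventSequence:
    """Exact event-driven realization of the gating chain at one voltage.

    Holding times are sampled exponentially from each state's total exit
    rate and jumps categorically from the off-diagonal rates (Gillespie).
    A state with zero exit rate yields a single event spanning the whole
    duration.  Reproducible for a fixed seed.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be > 0")
    q = model.rate_matrix(voltage_mV)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if start_state is None:
        # start closed: the physical resting condition, and the convention
        # that makes an absorbing closed state a single full-length event
        start_state = next(
            (i for i, s in enumerate(model.state_labels)
             if s.startswith("closed")), 0)
    s = start_state
    t = 0.0
    events: list[tuple[str, float]] = []
    labels = model.state_labels
    while t < duration_ms:
        exit_rate = -q[s, s]
        if exit_rate <= 0:
            events.append((labels[s], duration_ms - t))
            t = duration_ms
            break
        dwell = rng.exponential(1.0 / exit_rate)
        if t + dwell >= duration_ms:
            events.append((labels[s], duration_ms - t))
            t = duration_ms
            break
        events.append((labels[s], dwell))
        t += dwell
        probs = q[s].copy()
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(model.n_states, p=probs))
    return EventSequence(events, duration_ms)


def render_trace(events: EventSequence, model: GatingModel, voltage_mV: float,
                 noise_sd_pA: float = 0.0, sampling_khz: float = 10.0,
                 filter_khz: float | None = None,
                 seed: int | np.random.Generator | None = None) -> TraceRecord:
    """Render an event sequence into a sampled current trace.

    Per-sample current is ``g(state) * (V - Erev) * 1e-3`` pA (pS x mV)
    plus independent Gaussian noise; an optional 4-pole Bessel-style
    low-pass is applied after the noise (zero-phase).
    """
    if noise_sd_pA < 0:
        raise ValueError("noise_sd_pA must be >= 0")
    if filter_khz is not None and sampling_khz < 2.0 * filter_khz:
        raise ValueError("sampling rate must be >= 2x the filter cutoff")
    g_by_label = dict(zip(model.state_labels, model.conductance_pS))
    levels = np.array([g_by_label[s] for s, _ in events.events])
    ends = np.cumsum([d for _, d in events.events])
    n = int(round(events.total_ms * sampling_khz))
    t = np.arange(n) / sampling_khz
    idx = np.minimum(np.searchsorted(ends, t, side="right"), len(levels) - 1)
    i = levels[idx] * (voltage_mV - model.erev_mV) * 1e-3
    if noise_sd_pA > 0:
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        i = i + rng.normal(0.0, noise_sd_pA, size=n)
    if filter_khz is not None:
        sos = signal.bessel(4, filter_khz / (sampling_khz / 2.0),
                            btype="low", output="sos", norm="mag")
        i = signal.sosfiltfilt(sos, i)
    return TraceRecord(t, i, voltage_mV, sampling_khz, filter_khz,
                       meta={"erev_mV": model.erev_mV,
                             "noise_sd_pA": noise_sd_pA})


def hill_response(x_uM: np.ndarray | float, ic50_uM: float, h: float
                  ) -> np.ndarray | float:
    """Hill inhibition curve ``Y = 100 / (1 + (IC50 / X)^h)`` in % of control.

    ``h`` is signed; the inhibition convention used throughout is h < 0
    (response falls from 100% toward 0 with increasing concentration).
    """
    x = np.asarray(x_uM, dtype=float)
    y = 100.0 / (1.0 + (ic50_uM / x) ** h)
    return float(y) if np.isscalar(x_uM) else y


def gen_dose_response(ic50_uM: float, h: float,
                      concentrations_uM: Sequence[float],
                      replicates: int = 1, noise_cv: float = 0.0,
                      seed: int | None = None) -> DoseResponse:
    """Dose-response table from the Hill model with multiplicative noise.

    Noise-free responses follow the Hill curve exactly; per-replicate noise
    is multiplicative Gaussian with coefficient of variation ``noise_cv``.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    if ic50_uM <= 0:
        raise ValueError("ic50_uM must be > 0")
    if (conc <= 0).any():
        raise ValueError("concentrations must be > 0")
    if h == 0:
        raise ValueError("h = 0 gives a degenerate flat curve")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    y0 = hill_response(conc, ic50_uM, h)
    concs = np.tile(conc, replicates)
    reps = np.repeat(np.arange(replicates), len(conc))
    y = np.tile(y0, replicates)
    if noise_cv > 0:
        y = y * rng.normal(1.0, noise_cv, size=y.shape)
    return DoseResponse(concs, y, reps, seed=seed)


LIE_SUBSYSTEMS = ("p-L", "p*", "L(g)", "m-L", "m*")


def gen_energy_traces(mean_q: Mapping[str, float] | float,
                      mean_vdw: Mapping[str, float] | float,
                      sd: float, n: int, seed: int | None = None
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Gaussian interaction-energy series per LIE subsystem.

    Returns ``{subsystem: (coulombic_series, vdw_series)}`` in kJ/mol for
    the five subsystems of the protein/membrane decomposition: the
    protein-lipid complex (p-L), the bare protein (p*), the isolated
    lipid (L(g)), the membrane-lipid system (m-L) and the bare membrane
    (m*).  Scalars are broadcast to all subsystems.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    for name in LIE_SUBSYSTEMS:
        mq = mean_q[name] if isinstance(mean_q, Mapping) else float(mean_q)
        mv = mean_vdw[name] if isinstance(mean_vdw, Mapping) else float(mean_vdw)
        eq = np.full(n, mq) + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)
        ev = np.full(n, mv) + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)
        out[name] = (eq, ev)
    return out


def _lipid_frame(dp: float, dr2: float, axis: Axis,
                 n_tmd_rings: int = 4, ring_radius: float = 9.0,
                 tmd_length: float = 36.0) -> CoordinateFrame:
    """Build one coordinate frame realizing prescribed axis distances.

    Transmembrane-domain atoms form a cylindrical cage whose long axis is
    the given axis; one phosphorus marker sits at perpendicular distance
    ``dp`` and a five-atom acyl chain has its center of mass at ``dr2``.
    """
    d = axis.direction
    # orthonormal frame (d, e1, e2)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, d)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, probe)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    xyz, masses, tags = [], [], []
    n_per_ring = 8
    for iz in range(n_tmd_rings):
        z = (iz / (n_tmd_rings - 1) - 0.5) * tmd_length
        for j in range(n_per_ring):
            phi = 2.0 * np.pi * j / n_per_ring
            p = (axis.anchor + z * d
                 + ring_radius * (np.cos(phi) * e1 + np.sin(phi) * e2))
            xyz.append(p)
            masses.append(12.011)
            tags.append("tmd")
    xyz.append(axis.anchor + 10.0 * d + dp * e1)
    masses.append(30.974)
    tags.append("phosphorus")
    for k in range(5):
        xyz.append(axis.anchor + (2.0 * k - 4.0) * d + dr2 * e1)
        masses.append(12.011)
        tags.append("r2_chain")
    return CoordinateFrame(
        atom_ids=np.arange(len(xyz)),
        xyz=np.array(xyz),
        masses=np.array(masses),
        tags=np.array(tags),
    )


def gen_lipid_frames(state_centers: Sequence[tuple[float, float]],
                     dwell_frames: int | Sequence[int], jitter_sd: float,
                     seed: int | None = None,
                     axis: Axis | None = None,
                     with_frames: bool = False
                     ) -> tuple[AxisDistanceSeries, list[CoordinateFrame]]:
    """Piecewise-stationary 2-D Gaussian (dP, dR2-Cent) emissions.

    The series visits the state centers in order, dwelling ``dwell_frames``
    frames at each, with isotropic Gaussian jitter.  When ``with_frames``
    is true, a matching synthetic coordinate frame is built per time point
    so that recomputing the distances from the geometry reproduces the
    emitted series exactly.
    """
    centers = np.asarray(state_centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 2:
        raise ValueError("state_centers must be a sequence of (dP, dR2) pairs")
    if len(np.unique(centers, axis=0)) != len(centers):
        raise ValueError("state centers must be distinct")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    dwells = (np.full(len(centers), dwell_frames, dtype=int)
              if np.isscalar(dwell_frames)
              else np.asarray(dwell_frames, dtype=int))
    if (dwells < 1).any():
        raise ValueError("dwell_frames must be >= 1")
    if len(dwells) != len(centers):
        raise ValueError("dwell_frames length must match state_centers")
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = Axis(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    pts = np.repeat(centers, dwells, axis=0)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    pts = np.abs(pts)  # distances are non-negative by definition
    series = AxisDistanceSeries(dP=pts[:, 0], dR2_cent=pts[:, 1])
    frames = ([_lipid_frame(dp, dr2, axis) for dp, dr2 in pts]
              if with_frames else [])
    return series, frames


def gen_ph_traces(resting_pH: float, calib, nh4cl_delta_pH: float,
                  onset_s: float = 30.0, noise_cv: float = 0.0,
                  seed: int | None = None, duration_s: float = 120.0,
                  sampling_hz: float = 1.0,
                  f475_base: float = 1000.0) -> FluorTraces:
    """Two-channel ratiometric fluorescence with a weak-base (NH4Cl) pulse.

    The luminal pH steps by ``nh4cl_delta_pH`` at ``onset_s`` (weak-base
    alkalinization); the pH time course is mapped through the inverse
    calibration to a 405:475 ratio and split into two positive channels
    with independent multiplicative Gaussian noise.

    ``calib`` is a :class:`channelphys.ph_imaging.CalibCurve`.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not 0 <= onset_s <= duration_s:
        raise ValueError("onset_s must lie within the trace")
    n = int(round(duration_s * sampling_hz))
    t = np.arange(n) / sampling_hz
    ph = np.full(n, resting_pH, dtype=float)
    ph[t >= onset_s] += nh4cl_delta_pH
    ratio = calib.ratio_of_ph(ph)  # raises if pH outside calibration domain
    rng = np.random.default_rng(seed)
    mult = (lambda: rng.normal(1.0, noise_cv, n)) if noise_cv > 0 else (
        lambda: np.ones(n))
    f475 = f475_base * mult()
    f405 = f475_base * ratio * mult()
    if (f475 <= 0).any() or (f405 <= 0).any():
        raise ValueError("noise level produced non-positive intensities")
    return FluorTraces(t, f405, f475, stimulus_onset_s=onset_s)
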