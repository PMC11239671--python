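"""Macroscopic (whole-cell) I-V analysis.

Covers the quantitative steps of a whole-cell voltage-clamp study of a
nonselective cation channel: conversion of ramp recordings into I-V
curves, reversal potentials, bi-ionic Goldman-Hodgkin-Katz permeability
ratios, Hill fits of inhibitor dose-response data, normalization of
pH-series currents, Henderson liquid-junction-potential corrections, and
current densities.

The GHK permeability ratio uses the bi-ionic reduction valid for an
equimolar external-substitution design (the entire external test cation
replaces Na+ at the same concentration, internal solution fixed):

    P_X / P_Na = exp(F * (E_rev,X - E_rev,Na) / (R T))

The general two-term form with internal-solution terms is also provided
for users supplying complete solution data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from lmfit import Model

from .synthgen import DoseResponse, TraceRecord, VoltageProtocol, hill_response

__all__ = [
    "SolutionSpec",
    "ThermoSettings",
    "IVCurve",
    "PermeabilityResult",
    "HillFit",
    "ramp_to_iv",
    "reversal_potential",
    "ghk_permeability_ratio",
    "bi_ionic_delta_erev",
    "ghk_delta_erev_full",
    "hill_fit",
    "normalize_ph_series",
    "henderson_ljp",
    "current_density",
    "load_mobility_table",
    "solution_from_salts",
]

# Faraday / gas constant ratio: RT/F in mV at T Kelvin
_RT_OVER_F_mV_PER_K = 1000.0 * 8.31446261815324 / 96485.33212


@dataclass(frozen=True)
class ThermoSettings:
    """Thermodynamic context; room temperature by default."""

    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if not 273.0 < self.temperature_K < 320.0:
            raise ValueError("temperature must be physiological-ish (273-320 K)")

    @property
    def rt_over_f_mV(self) -> float:
        return _RT_OVER_F_mV_PER_K * self.temperature_K


@dataclass
class SolutionSpec:
    """Electrolyte composition (mM per ion) for one compartment.

    ``ions`` maps ion names (as in the bundled mobility table) to
    concentrations in mM; ``role`` is ``bath`` or ``pipette``.
    """

    ions: dict[str, float]
    role: str = "bath"
    pH: float = 7.3

    def __post_init__(self) -> None:
        if self.role not in ("bath", "pipette"):
            raise ValueError("role must be 'bath' or 'pipette'")
        if any(c < 0 for c in self.ions.values()):
            raise ValueError("concentrations must be >= 0")


# Stoichiometries of the salts used in the standard recording solutions.
_SALTS: dict[str, dict[str, int]] = {
    "NaCl": {"Na": 1, "Cl": 1}, "KCl": {"K": 1, "Cl": 1},
    "CsCl": {"Cs": 1, "Cl": 1}, "LiCl": {"Li": 1, "Cl": 1},
    "MgCl2": {"Mg": 1, "Cl": 2}, "CaCl2": {"Ca": 1, "Cl": 2},
    "BaCl2": {"Ba": 1, "Cl": 2}, "NMDG-Cl": {"NMDG": 1, "Cl": 1},
    "K-gluconate": {"K": 1, "gluconate": 1},
    "Na-gluconate": {"Na": 1, "gluconate": 1},
    "Na-isethionate": {"Na": 1, "isethionate": 1},
    "Na-methanesulfonate": {"Na": 1, "methanesulfonate": 1},
    "NaOH": {"Na": 1, "OH": 1}, "KOH": {"K": 1, "OH": 1},
    "CsOH": {"Cs": 1, "OH": 1},
    "Na-HEPES": {"Na": 1, "HEPES": 1}, "K-HEPES": {"K": 1, "HEPES": 1},
}


def solution_from_salts(salts: dict[str, float], role: str = "bath",
                        pH: float = 7.3) -> SolutionSpec:
    """Build a SolutionSpec from salt concentrations (mM).

    Neutral osmolytes (glucose, sucrose) and buffers without a tabulated
    mobility should simply be omitted; only dissociated ions carry
    junction current.
    """
    ions: dict[str, float] = {}
    for salt, conc in salts.items():
        if salt not in _SALTS:
            raise KeyError(f"unknown salt {salt!r}; known: {sorted(_SALTS)}")
        for ion, stoich in _SALTS[salt].items():
            ions[ion] = ions.get(ion, 0.0) + stoich * conc
    return SolutionSpec(ions, role, pH)


@dataclass
class IVCurve:
    """Current-voltage relationship on a strictly monotone voltage grid."""

    voltage_mV: np.ndarray
    current: np.ndarray        # pA, or pA/pF if density
    units: str = "pA"
    ljp_corrected: bool = False

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage_mV.shape != self.current.shape:
            raise ValueError("voltage/current length mismatch")
        dv = np.diff(self.voltage_mV)
        if not ((dv > 0).all() or (dv < 0).all()):
            raise ValueError("voltage grid must be strictly monotone")

    def ascending(self) -> "IVCurve":
        if self.voltage_mV[0] < self.voltage_mV[-1]:
            return self
        return IVCurve(self.voltage_mV[::-1].copy(), self.current[::-1].copy(),
                       self.units, self.ljp_corrected)


@dataclass(frozen=True)
class PermeabilityResult:
    """Relative permeability from a bi-ionic reversal-potential shift."""

    ratio: float               # P_X / P_Na
    delta_erev_mV: float
    temperature_K: float


@dataclass
class HillFit:
    """Hill-model dose-response fit (IC50 in uM, signed slope h)."""

    ic50_uM: float
    h: float
    covariance: np.ndarray | None
    residual_sd: float
    n_points: int


# ---------------------------------------------------------------------------


def ramp_to_iv(trace: TraceRecord, protocol: VoltageProtocol) -> IVCurve:
    """Convert a ramp recording into an I-V curve.

    Each sample time maps to the instantaneous command voltage; repeated
    ramps are averaged.  The trace length must be an integer number of
    ramp sweeps.
    """
    if protocol.kind != "ramp":
        raise ValueError("ramp_to_iv requires a ramp protocol")
    n_ramp = int(round(protocol.ramp_ms * trace.sampling_khz))
    n = len(trace.i_pA)
    if n < n_ramp or n % n_ramp != 0:
        raise ValueError(
            f"trace length {n} is not a whole number of "
            f"{n_ramp}-sample ramps")
    sweeps = trace.i_pA.reshape(n // n_ramp, n_ramp)
    i_mean = sweeps.mean(axis=0)
    t_in_ramp = np.arange(n_ramp) / trace.sampling_khz
    v = protocol.ramp_voltage(t_in_ramp)
    return IVCurve(v, i_mean).ascending()


def reversal_potential(iv: IVCurve) -> float:
    """Zero-current crossing of an I-V curve, in mV.

    Linear interpolation between the samples bracketing each sign change;
    if several crossings exist, the one nearest 0 mV is returned with a
    warning.  Raises if the curve does not bracket zero current.
    """
    curve = iv.ascending()
    v, i = curve.voltage_mV, curve.current
    exact = np.flatnonzero(i == 0)
    roots = [float(v[k]) for k in exact]
    s = np.sign(i)
    flips = np.flatnonzero((s[:-1] * s[1:]) < 0)
    for k in flips:
        roots.append(float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k])))
    if not roots:
        raise ValueError("I-V curve does not bracket zero current; "
                         "no reversal potential in range")
    roots = sorted(set(roots), key=abs)
    if len(roots) > 1:
        warnings.warn(
            f"multiple zero crossings {roots}; returning the one nearest "
            "0 mV", stacklevel=2)
    return roots[0]


def ghk_permeability_ratio(erev_na_mV: float, erev_x_mV: float,
                           thermo: ThermoSettings | None = None
                           ) -> PermeabilityResult:
    """Bi-ionic GHK permeability ratio from two reversal potentials.

    Valid for the equimolar substitution design (the external test cation
    X fully replaces Na+ at the same concentration; internal solution
    unchanged), where the GHK voltage relation reduces to

        P_X / P_Na = exp(F * (E_rev,X - E_rev,Na) / (R T)).
    """
    thermo = thermo or ThermoSettings()
    delta = erev_x_mV - erev_na_mV
    ratio = float(np.exp(delta / thermo.rt_over_f_mV))
    return PermeabilityResult(ratio, delta, thermo.temperature_K)


def bi_ionic_delta_erev(ratio: float, thermo: ThermoSettings | None = None
                        ) -> float:
    """Inverse of :func:`ghk_permeability_ratio`: predicted shift in mV."""
    if ratio <= 0:
        raise ValueError("permeability ratio must be > 0")
    thermo = thermo or ThermoSettings()
    return float(thermo.rt_over_f_mV * np.log(ratio))


def ghk_delta_erev_full(p_na: float, p_x: float,
                        bath1: dict[str, float], bath2: dict[str, float],
                        internal: dict[str, float],
                        thermo: ThermoSettings | None = None,
                        na: str = "Na", x: str = "K") -> float:
    """Two-term GHK reversal-potential shift for full solution data.

    ``bath1``/``bath2`` are the external cation concentrations (mM) under
    the two conditions; ``internal`` is the (fixed) internal composition.
    Returns E_rev(bath2) - E_rev(bath1) in mV.  The internal-solution
    terms cancel when the internal composition is identical, recovering
    the bi-ionic reduction.
    """
    thermo = thermo or ThermoSettings()

    def lg(sol: dict[str, float]) -> float:
        return p_na * sol.get(na, 0.0) + p_x * sol.get(x, 0.0)

    denom = lg(internal)
    return float(thermo.rt_over_f_mV
                 * (np.log(lg(bath2) / denom) - np.log(lg(bath1) / denom)))


def hill_fit(data: DoseResponse, init: tuple[float, float] | None = None
             ) -> HillFit:
    """Nonlinear least-squares Hill fit of a dose-response table.

    Fits ``Y = 100 / (1 + (IC50/X)^h)`` with the slope ``h`` kept signed
    (negative for inhibition).  Multi-start over both slope signs and a
    concentration-spanning IC50 grid guards against the sign ambiguity of
    the Hill exponent; the best-chi-square start wins.
    """
    conc = data.concentration_uM
    if len(np.unique(conc)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    y = data.response_pct
    model = Model(lambda x, ic50, h: hill_response(x, ic50, h),
                  independent_vars=["x"])
    geo = float(np.exp(np.mean(np.log(conc))))
    starts = [(geo, -1.0), (geo, 1.0), (geo, -2.0), (geo, 2.0),
              (conc.min(), -1.0), (conc.max(), -1.0)]
    if init is not None:
        starts.insert(0, init)
    best = None
    for ic50_0, h0 in starts:
        params = model.make_params(ic50=ic50_0, h=h0)
        params["ic50"].set(min=1e-12)
        try:
            res = model.fit(y, params, x=conc)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError("Hill fit failed to converge from any start")
    dof = max(len(y) - 2, 1)
    return HillFit(float(best.params["ic50"].value),
                   float(best.params["h"].value),
                   best.covar, float(np.sqrt(best.chisqr / dof)), len(y))


def normalize_ph_series(currents_by_pH: dict[float, float],
                        ref_pH: float = 7.3) -> dict[float, float]:
    """Normalize a pH-series of currents to the reference-pH current."""
    if ref_pH not in currents_by_pH:
        raise KeyError(f"reference pH {ref_pH} not in series")
    ref = currents_by_pH[ref_pH]
    if ref == 0:
        raise ValueError("reference current is zero; cannot normalize")
    return {ph: i / ref for ph, i in currents_by_pH.items()}


def load_mobility_table() -> pd.DataFrame:
    """Bundled limiting-conductivity table (ion, valence, lambda0)."""
    ref = resources.files("channelphys").joinpath(
        "data/limiting_conductivities.csv")
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#").set_index("ion")


def henderson_ljp(pipette: SolutionSpec, bath: SolutionSpec,
                  mobility_table: pd.DataFrame | None = None,
                  thermo: ThermoSettings | None = None) -> float:
    """Henderson liquid-junction potential, bath relative to pipette (mV).

    Uses the Henderson mixture approximation with limiting ionic
    mobilities (u_i proportional to lambda0_i / |z_i|).  The sign follows
    the patch-clamp convention in which a slow pipette anion (e.g.
    gluconate) against a NaCl bath gives a positive LJP; the true
    membrane potential is the command potential minus this value.
    Antisymmetric under solution exchange, zero for identical solutions.
    """
    table = load_mobility_table() if mobility_table is None else mobility_table
    thermo = thermo or ThermoSettings()
    ions = sorted(set(pipette.ions) | set(bath.ions))
    missing = [i for i in ions if i not in table.index]
    if missing:
        raise KeyError(f"no mobility tabulated for ion(s): {missing}")
    z = table.loc[ions, "z"].to_numpy(dtype=float)
    lam = table.loc[ions, "lambda0_S_cm2_per_mol"].to_numpy(dtype=float)
    u = lam / np.abs(z)
    c_p = np.array([pipette.ions.get(i, 0.0) for i in ions])
    c_b = np.array([bath.ions.get(i, 0.0) for i in ions])
    for name, conc in (("pipette", c_p), ("bath", c_b)):
        net = abs(float(z @ conc))
        tot = float(np.abs(z) @ conc)
        if tot > 0 and net / tot > 0.01:
            warnings.warn(
                f"{name} solution violates electroneutrality by "
                f"{100 * net / tot:.1f}%", stacklevel=2)
    dc = c_b - c_p
    s1 = float((z * u) @ dc)
    s2 = float((z * z * u) @ dc)
    g_b = float((z * z * u) @ c_b)
    g_p = float((z * z * u) @ c_p)
    if g_b == 0 or g_p == 0:
        raise ValueError("a solution with no ions has no junction potential")
    if s2 == 0:  # identical ionic strength profile; limit of the formula
        return 0.0
    return float(-thermo.rt_over_f_mV * (s1 / s2) * np.log(g_b / g_p))


def current_density(current_pA, capacitance_pF: float):
    """Current density in pA/pF (elementwise for array input)."""
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be > 0")
    return np.asarray(current_pA, dtype=float) / capacitance_pF
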