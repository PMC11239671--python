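"""Boost-potential enhanced-sampling mechanics and LIE binding energetics.

Two desk-scale pieces of the molecular-modelling workflow:

1. The Gaussian-boost scheme used in accelerated MD: a harmonic boost
   ``dV = 1/2 k (E - V)^2`` added wherever the system potential drops
   below a reference energy E, with E and k chosen so that
   ``Vmax <= E <= Vmin + 1/k``.  A 1-D overdamped-Langevin demonstrator
   (:func:`run_toy_gamd`) shows the resulting acceleration of
   barrier crossings on a double-well potential.  Production-scale
   all-atom dynamics are out of scope; the toy applies a single boost
   term.

2. The linear-interaction-energy (LIE) estimator of the
   membrane-to-protein lipid transfer free energy from average coulombic
   and van der Waals interaction energies of five subsystems
   (protein-lipid complex p-L, bare protein p*, isolated lipid L(g),
   membrane-lipid m-L, bare membrane m*):

       dF_{m->p} = 0.5 <dE^Q_{m->p}> + 0.16 <dE^vdW_{m->p}>   (kJ/mol)

Boost parameters are carried in kcal/mol by convention (sigma0 defaults
to 6.0 kcal/mol); LIE energies in kJ/mol.  1 kcal = 4.184 kJ exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "KJ_PER_KCAL",
    "BoostParams",
    "PotentialSpec",
    "EnergyComponents",
    "LIEResult",
    "boost_potential",
    "select_boost_params",
    "run_toy_gamd",
    "count_barrier_crossings",
    "lie_free_energy",
]

KJ_PER_KCAL = 4.184

_SUBSYSTEMS = ("p-L", "p*", "L(g)", "m-L", "m*")


@dataclass(frozen=True)
class BoostParams:
    """Harmonic boost parameters (reference energy E, force constant k).

    ``E`` and ``1/k`` share the energy unit given by ``unit``; ``sigma0``
    is the upper limit imposed on the boost-potential standard deviation
    when the parameters are selected from potential statistics.
    """

    E: float
    k: float
    sigma0: float = 6.0
    bound_choice: str = "upper"
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.bound_choice not in ("lower", "upper"):
            raise ValueError("bound_choice must be 'lower' or 'upper'")

    def satisfies_bound(self, v_min: float, v_max: float) -> bool:
        """Check the selection inequality ``Vmax <= E <= Vmin + 1/k``."""
        eps = 1e-9 * max(1.0, abs(v_max - v_min))
        return (v_max - eps) <= self.E <= (v_min + 1.0 / self.k + eps)

    def to_unit(self, unit: str) -> "BoostParams":
        """Convert between kcal/mol and kJ/mol (exact factor 4.184)."""
        if unit == self.unit:
            return self
        if {unit, self.unit} != {"kcal/mol", "kJ/mol"}:
            raise ValueError(f"unsupported unit {unit!r}")
        f = KJ_PER_KCAL if unit == "kJ/mol" else 1.0 / KJ_PER_KCAL
        return BoostParams(self.E * f, self.k / f, self.sigma0 * f,
                           self.bound_choice, unit)


@dataclass(frozen=True)
class PotentialSpec:
    """Analytic 1-D potential for the toy dynamics.

    ``double-well``: V(x) = barrier * (x^2 - 1)^2, wells at x = +-1.
    ``harmonic``: V(x) = 0.5 * stiffness * x^2.
    Temperature in the same energy unit as the potential (kB folded in),
    friction in inverse time, timestep in the same time unit.
    """

    kind: str = "double-well"
    barrier: float = 5.0
    stiffness: float = 1.0
    temperature: float = 1.0
    friction: float = 1.0
    timestep: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in ("double-well", "harmonic"):
            raise ValueError("kind must be 'double-well' or 'harmonic'")
        if min(self.barrier, self.stiffness, self.temperature,
               self.friction, self.timestep) <= 0:
            raise ValueError("all physical parameters must be > 0")

    def energy(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "double-well":
            return self.barrier * (np.square(x) - 1.0) ** 2
        return 0.5 * self.stiffness * np.square(x)

    def gradient(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "double-well":
            return 4.0 * self.barrier * x * (np.square(x) - 1.0)
        return self.stiffness * x


@dataclass
class EnergyComponents:
    """Average interaction energies per LIE subsystem, kJ/mol.

    ``coulomb`` and ``vdw`` map each of ``p-L, p*, L(g), m-L, m*`` to its
    post-burn-in average coulombic / van der Waals interaction energy.
    """

    coulomb: dict[str, float]
    vdw: dict[str, float]
    n_burned: int = 0

    def __post_init__(self) -> None:
        for kind, d in (("coulomb", self.coulomb), ("vdw", self.vdw)):
            missing = [s for s in _SUBSYSTEMS if s not in d]
            if missing:
                raise ValueError(f"missing {kind} subsystem(s): {missing}")

    @classmethod
    def from_series(cls, series: Mapping[str, tuple[np.ndarray, np.ndarray]],
                    burn_in_frac: float = 0.0) -> "EnergyComponents":
        """Average raw per-frame (coulomb, vdW) series, discarding burn-in.

        ``burn_in_frac`` is the leading fraction of each series discarded
        before averaging (the equilibration transient).
        """
        if not 0.0 <= burn_in_frac < 1.0:
            raise ValueError("burn_in_frac must be in [0, 1)")
        coul, vdw = {}, {}
        n_burned = 0
        for name in _SUBSYSTEMS:
            if name not in series:
                raise ValueError(f"missing subsystem: {name}")
            eq, ev = (np.asarray(a, dtype=float) for a in series[name])
            k = int(np.floor(burn_in_frac * len(eq)))
            n_burned = max(n_burned, k)
            coul[name] = float(eq[k:].mean())
            vdw[name] = float(ev[k:].mean())
        return cls(coul, vdw, n_burned)


@dataclass(frozen=True)
class LIEResult:
    """LIE transfer energies (kJ/mol): component deltas and free energy."""

    delta_e_q: float      # <dE^Q_{m->p}>
    delta_e_vdw: float    # <dE^vdW_{m->p}>
    delta_f: float        # 0.5 * dE^Q + 0.16 * dE^vdW


# ---------------------------------------------------------------------------


def boost_potential(v: np.ndarray | float, params: BoostParams
                    ) -> np.ndarray | float:
    """Harmonic boost ``dV = 1/2 k (E - V)^2`` for V < E, else 0.

    The modified potential is ``V* = V + dV``; with the selection
    inequality satisfied, V* is non-decreasing in V, so the boost never
    reorders potential levels.
    """
    v_arr = np.asarray(v, dtype=float)
    dv = np.where(v_arr < params.E,
                  0.5 * params.k * (params.E - v_arr) ** 2, 0.0)
    return float(dv) if np.isscalar(v) else dv


def select_boost_params(v_max: float, v_min: float, v_avg: float,
                        sigma_v: float, sigma0: float = 6.0,
                        bound: str = "upper") -> BoostParams:
    """Choose (E, k) from potential statistics under a sigma0 cap.

    The effective force constant ``k0 = min(1, (sigma0/sigma_V) *
    (Vmax - Vmin) / (Vmax - Vavg))`` limits the boost SD to sigma0;
    ``k = k0 / (Vmax - Vmin)``.  The reference energy sits at the
    requested end of the allowed interval: ``E = Vmax`` (lower bound) or
    ``E = Vmin + 1/k`` (upper bound, the more aggressive choice).  The
    returned parameters always satisfy ``Vmax <= E <= Vmin + 1/k``.
    """
    if v_max <= v_min:
        raise ValueError("v_max must exceed v_min")
    if v_avg >= v_max:
        raise ValueError("v_avg must be below v_max")
    if sigma_v <= 0 or sigma0 <= 0:
        raise ValueError("sigma_v and sigma0 must be > 0")
    k0 = min(1.0, (sigma0 / sigma_v) * (v_max - v_min) / (v_max - v_avg))
    k = k0 / (v_max - v_min)
    e = v_max if bound == "lower" else v_min + 1.0 / k
    params = BoostParams(e, k, sigma0, bound)
    assert params.satisfies_bound(v_min, v_max)
    return params


def run_toy_gamd(potential: PotentialSpec,
                 params: BoostParams | None = None,
                 steps: int = 100_000, seed: int | None = None,
                 x0: float = -1.0) -> tuple[np.ndarray, np.ndarray]:
    """Overdamped Langevin dynamics on the (optionally boosted) potential.

    Euler-Maruyama integration of
    ``dx = -grad V*(x)/gamma dt + sqrt(2 T dt / gamma) xi``; with
    ``params`` given the force includes the boost contribution
    ``dV' = -k (E - V) V'`` wherever V < E.  Returns the position
    trajectory and the per-step boost energy (zeros when unboosted,
    non-negative always).  Raises on divergence, reporting the step.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    dt = potential.timestep
    gamma = potential.friction
    noise_scale = np.sqrt(2.0 * potential.temperature * dt / gamma)
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(steps)
    x = np.empty(steps + 1)
    dv = np.zeros(steps + 1)
    x[0] = x0
    if params is not None:
        dv[0] = boost_potential(potential.energy(x0), params)
    for n in range(steps):
        xn = x[n]
        grad = potential.gradient(xn)
        if params is not None:
            v = potential.energy(xn)
            if v < params.E:
                # chain rule: d(dV)/dx = -k (E - V) V'(x)
                grad = grad * (1.0 - params.k * (params.E - v))
        x[n + 1] = xn - grad / gamma * dt + noise_scale * xi[n]
        if not np.isfinite(x[n + 1]) or abs(x[n + 1]) > 1e6:
            raise FloatingPointError(
                f"trajectory diverged at step {n + 1}; reduce the timestep")
        if params is not None:
            dv[n + 1] = boost_potential(potential.energy(x[n + 1]), params)
    return x, dv


def count_barrier_crossings(x: np.ndarray, well_sep: float = 0.5) -> int:
    """Count well-to-well transitions of a double-well trajectory.

    A crossing is registered when the trajectory moves from beyond
    ``-well_sep`` to beyond ``+well_sep`` or vice versa (hysteresis
    suppresses barrier-top chatter).
    """
    side = 0
    crossings = 0
    for xi in x:
        if xi <= -well_sep:
            if side == 1:
                crossings += 1
            side = -1
        elif xi >= well_sep:
            if side == -1:
                crossings += 1
            side = 1
    return crossings


def lie_free_energy(components: EnergyComponents) -> LIEResult:
    """LIE membrane-to-protein transfer free energy, kJ/mol.

    From the five subsystem averages the lipid-to-protein and
    lipid-to-membrane interaction-energy changes are

        dE_{L->p} = E_{p-L} - E_{p*} - E_{L(g)}
        dE_{L->m} = E_{m-L} - E_{m*} - E_{L(g)}

    (per energy class Q / vdW); their difference gives dE_{m->p}, and

        dF_{m->p} = 0.5 dE^Q_{m->p} + 0.16 dE^vdW_{m->p}.
    """
    def transfer(d: dict[str, float]) -> float:
        d_lp = d["p-L"] - d["p*"] - d["L(g)"]
        d_lm = d["m-L"] - d["m*"] - d["L(g)"]
        return d_lp - d_lm

    dq = transfer(components.coulomb)
    dvdw = transfer(components.vdw)
    return LIEResult(dq, dvdw, 0.5 * dq + 0.16 * dvdw)
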