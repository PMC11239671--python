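"""Principal-axis distance analysis of lipid binding.

The binding of a phospholipid to the transmembrane domain (TMD) of a
membrane protein is summarized by two scalar coordinates per trajectory
frame: the perpendicular distance of the lipid phosphorus atom (dP) and
of the center of mass of its second acyl chain (dR2-Cent) from the
smallest-moment principal axis of the TMD.  A 2-D histogram of these
coordinates exposes the discrete binding states (labeled S1, S2, ... in
descending population), and per-frame classification yields visit order
and dwell statistics, e.g. the stepwise entry path through partially
bound intermediates into the fully bound state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CoordinateFrame",
    "Axis",
    "AxisDistanceSeries",
    "StateMap",
    "FrameClassification",
    "principal_axis_smallest_moment",
    "axis_distances",
    "state_histogram",
    "classify_frames",
]


@dataclass
class CoordinateFrame:
    """One set of atomic coordinates with masses and selection tags.

    Tags mark the selections used downstream: ``tmd`` (the transmembrane
    bundle defining the axis), ``phosphorus`` (the lipid head-group
    marker) and ``r2_chain`` (the second acyl chain).
    """

    atom_ids: np.ndarray
    xyz: np.ndarray          # (n, 3) Angstrom
    masses: np.ndarray
    tags: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.tags = np.asarray(self.tags)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")
        if len(self.masses) != len(self.xyz) or len(self.tags) != len(self.xyz):
            raise ValueError("masses/tags length mismatch")

    def select(self, tag: str) -> "CoordinateFrame":
        mask = self.tags == tag
        if not mask.any():
            raise ValueError(f"selection {tag!r} is empty")
        return CoordinateFrame(self.atom_ids[mask], self.xyz[mask],
                               self.masses[mask], self.tags[mask])

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.xyz / self.masses.sum()


@dataclass(frozen=True)
class Axis:
    """A line in space: unit direction plus an anchor point."""

    direction: np.ndarray
    anchor: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        a = np.asarray(self.anchor, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("direction must be non-zero")
        object.__setattr__(self, "direction", d / nrm)
        object.__setattr__(self, "anchor", a)


@dataclass
class AxisDistanceSeries:
    """Per-frame (dP, dR2-Cent) distances to the TMD principal axis (A)."""

    dP: np.ndarray
    dR2_cent: np.ndarray

    def __post_init__(self) -> None:
        self.dP = np.asarray(self.dP, dtype=float)
        self.dR2_cent = np.asarray(self.dR2_cent, dtype=float)
        if self.dP.shape != self.dR2_cent.shape:
            raise ValueError("dP and dR2_cent length mismatch")
        if (self.dP < 0).any() or (self.dR2_cent < 0).any():
            raise ValueError("distances must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.dP)

    def as_points(self) -> np.ndarray:
        return np.column_stack([self.dP, self.dR2_cent])


@dataclass
class StateMap:
    """2-D (dP, dR2-Cent) histogram with labeled modes S1...Sn.

    Modes are ranked by population: S1 is the most populated (in the
    entry pathway the fully bound state).
    """

    edges_dP: np.ndarray
    edges_dR2: np.ndarray
    counts: np.ndarray
    centers: np.ndarray       # (n_states, 2) mode centers
    populations: np.ndarray   # histogram count at each mode
    labels: list[str] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def center_of(self, label: str) -> np.ndarray:
        return self.centers[self.labels.index(label)]


@dataclass
class FrameClassification:
    """Per-frame state assignment with visit and dwell summaries."""

    labels: list[str]                 # per frame; "unassigned" beyond cutoff
    visit_order: list[str]            # distinct consecutive assigned states
    dwell_frames: dict[str, int]      # total frames per state incl. unassigned
    path_to_S1: list[str] | None      # first-passage visit path, if S1 reached


def principal_axis_smallest_moment(frame: CoordinateFrame,
                                   selection: str = "tmd",
                                   degeneracy_rtol: float = 1e-6) -> Axis:
    """Smallest-moment principal axis of a selection (its long axis).

    Diagonalizes the mass-weighted inertia tensor about the selection's
    center of mass and returns the eigenvector of the smallest eigenvalue,
    anchored at the center of mass.  For an elongated body this is the
    elongation axis.  The sign is fixed by a positive projection on +z
    (falling back to +x, then +y, for axes perpendicular to z).
    """
    sel = frame.select(selection) if selection is not None else frame
    if len(sel.xyz) < 3:
        raise ValueError("need at least 3 atoms to define an axis")
    com = sel.center_of_mass()
    r = sel.xyz - com
    m = sel.masses
    r2 = (r * r).sum(axis=1)
    # I = sum_i m_i (|r_i|^2 I3 - r_i r_i^T)
    inertia = np.eye(3) * (m * r2).sum() - np.einsum("i,ij,ik->jk", m, r, r)
    evals, evecs = np.linalg.eigh(inertia)
    if np.ptp(evals) <= degeneracy_rtol * max(abs(evals).max(), 1.0):
        raise ValueError("inertia tensor is degenerate (near-spherical body); "
                         "the principal axis is ambiguous")
    axis = evecs[:, np.argmin(evals)]
    for k in (2, 0, 1):  # prefer +z, then +x, +y
        if abs(axis[k]) > 1e-12:
            if axis[k] < 0:
                axis = -axis
            break
    return Axis(axis, com)


def _point_line_distance(points: np.ndarray, axis: Axis) -> np.ndarray:
    rel = np.atleast_2d(points) - axis.anchor
    proj = rel @ axis.direction
    perp = rel - np.outer(proj, axis.direction)
    return np.linalg.norm(perp, axis=1)


def axis_distances(frame: CoordinateFrame, axis: Axis) -> tuple[float, float]:
    """Perpendicular distances (dP, dR2-Cent) of the lipid markers.

    dP is the distance of the phosphorus atom from the axis line;
    dR2-Cent that of the mass-weighted center of the ``r2_chain``
    selection.
    """
    p = frame.select("phosphorus").xyz
    if len(p) != 1:
        raise ValueError(f"expected one phosphorus atom, found {len(p)}")
    r2_com = frame.select("r2_chain").center_of_mass()
    dp = _point_line_distance(p, axis)[0]
    dr2 = _point_line_distance(r2_com[None, :], axis)[0]
    return float(dp), float(dr2)


def state_histogram(series: AxisDistanceSeries, bin_width_A: float = 0.5,
                    min_count_frac: float = 0.01,
                    min_separation_bins: int = 2) -> StateMap:
    """Binding-state map from the 2-D (dP, dR2-Cent) histogram.

    States are local maxima of the histogram above ``min_count_frac`` of
    the total frame count, with non-maximum suppression within
    ``min_separation_bins``; they are labeled S1...Sn by descending
    population.
    """
    if series.n_frames < 100:
        raise ValueError("need >= 100 frames for a state histogram")
    if bin_width_A <= 0:
        raise ValueError("bin_width_A must be > 0")
    pts = series.as_points()
    lo = np.floor(pts.min(axis=0) / bin_width_A) * bin_width_A
    hi = np.ceil(pts.max(axis=0) / bin_width_A) * bin_width_A + bin_width_A
    edges_x = np.arange(lo[0], hi[0] + 0.5 * bin_width_A, bin_width_A)
    edges_y = np.arange(lo[1], hi[1] + 0.5 * bin_width_A, bin_width_A)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                  bins=(edges_x, edges_y))
    size = 2 * min_separation_bins + 1
    local_max = (counts == ndimage.maximum_filter(
        counts, size=size, mode="constant", cval=-1.0))
    thresh = min_count_frac * series.n_frames
    candidates = np.argwhere(local_max & (counts >= thresh))
    # greedy non-maximum suppression by descending count, Chebyshev radius
    order = np.argsort(-counts[candidates[:, 0], candidates[:, 1]],
                       kind="stable")
    kept: list[np.ndarray] = []
    for idx in candidates[order]:
        if all(np.abs(idx - k).max() > min_separation_bins for k in kept):
            kept.append(idx)
    if not kept:
        warnings.warn("no histogram mode above threshold; empty state list",
                      stacklevel=2)
        return StateMap(edges_x, edges_y, counts,
                        np.empty((0, 2)), np.empty(0, dtype=int), [])
    kept_arr = np.array(kept)
    pops = counts[kept_arr[:, 0], kept_arr[:, 1]].astype(int)
    centers = np.column_stack([
        0.5 * (edges_x[kept_arr[:, 0]] + edges_x[kept_arr[:, 0] + 1]),
        0.5 * (edges_y[kept_arr[:, 1]] + edges_y[kept_arr[:, 1] + 1]),
    ])
    labels = [f"S{i + 1}" for i in range(len(kept_arr))]
    return StateMap(edges_x, edges_y, counts, centers, pops, labels)


def classify_frames(series: AxisDistanceSeries, statemap: StateMap,
                    cutoff_A: float = 5.0) -> FrameClassification:
    """Nearest-mode assignment of each frame with dwell/visit summaries.

    Frames farther than ``cutoff_A`` from every mode center are labeled
    ``unassigned``.  The visit order lists distinct consecutive assigned
    states; the first-passage path to S1 is the visit order truncated at
    the first arrival in S1 (``None`` if S1 is never reached).
    """
    if statemap.n_states == 0:
        raise ValueError("state map is empty")
    pts = series.as_points()
    d = np.linalg.norm(pts[:, None, :] - statemap.centers[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    dmin = d[np.arange(len(pts)), nearest]
    labels = [statemap.labels[j] if dj <= cutoff_A else "unassigned"
              for j, dj in zip(nearest, dmin)]
    visit_order: list[str] = []
    for lab in labels:
        if lab != "unassigned" and (not visit_order or visit_order[-1] != lab):
            visit_order.append(lab)
    dwell: dict[str, int] = {}
    for lab in labels:
        dwell[lab] = dwell.get(lab, 0) + 1
    path = None
    if "S1" in visit_order:
        path = visit_order[: visit_order.index("S1") + 1]
    return FrameClassification(labels, visit_order, dwell, path)
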