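"""Solvent-accessible surface area by the Lee-Richards slice construction.

Each atom is inflated by the probe radius (default 0.14 nm, a water-sized
probe).  The inflated sphere is cut into z-slices of configurable thickness;
on each slice the atom contributes a circle, of which the arcs lying inside
any neighbour's circle are occluded.  The accessible arc angle phi on a
slice contributes phi * R_i * dz of area (the area of a spherical zone is
independent of latitude), so summing over slices yields the accessible area
per atom.  The computation is deterministic for fixed inputs and uses no
periodic images: the aggregate is expected to be made whole and isolated
first, mirroring the usual practice of stripping solvent before a surface
calculation.

Van der Waals radii default to the Bondi set and can be overridden
per element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import (Frame, Selection, SeriesStats, Topology, Trajectory,
                   trailing_window, whole_coords)

#: Bondi van der Waals radii (nm)
BONDI_RADII = {
    "H": 0.120, "He": 0.140, "C": 0.170, "N": 0.155, "O": 0.152,
    "F": 0.147, "Ne": 0.154, "Si": 0.210, "P": 0.180, "S": 0.180,
    "Cl": 0.175, "Ar": 0.188, "K": 0.275, "Na": 0.227, "Mg": 0.173,
    "Br": 0.185, "I": 0.198,
}

DEFAULT_PROBE = 0.14      # nm
DEFAULT_SLICE = 0.005     # nm


class UnknownElementError(KeyError):
    """Raised when an element has no van der Waals radius and no override."""


def element_radii(elements: list[str],
                  overrides: dict[str, float] | None = None) -> np.ndarray:
    table = dict(BONDI_RADII)
    if overrides:
        table.update(overrides)
    missing = sorted({e for e in elements if e not in table})
    if missing:
        raise UnknownElementError(
            f"no van der Waals radius for element(s) {missing}; "
            "supply radii overrides")
    return np.array([table[e] for e in elements])


def _accessible_angle(arcs: list[tuple[float, float]]) -> float:
    """Total angle of the unit circle not covered by the given arcs.

    Arcs are (center, half_width) in radians; the union is measured with
    wraparound handled by splitting at 0/2pi.
    """
    two_pi = 2.0 * np.pi
    intervals: list[tuple[float, float]] = []
    for c, hw in arcs:
        lo, hi = c - hw, c + hw
        if hi - lo >= two_pi:
            return 0.0
        lo_m = lo % two_pi
        hi_m = lo_m + (hi - lo)
        if hi_m <= two_pi:
            intervals.append((lo_m, hi_m))
        else:
            intervals.append((lo_m, two_pi))
            intervals.append((0.0, hi_m - two_pi))
    if not intervals:
        return two_pi
    intervals.sort()
    covered = 0.0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return max(0.0, two_pi - covered)


def sasa_areas(coords: np.ndarray, radii: np.ndarray,
               probe_radius: float = DEFAULT_PROBE,
               slice_width: float = DEFAULT_SLICE) -> np.ndarray:
    """Per-atom Lee-Richards accessible areas (nm^2) for one configuration."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    R = np.asarray(radii, dtype=float) + probe_radius
    n = len(R)
    if coords.shape[0] != n:
        raise ValueError("coords/radii length mismatch")
    tree = cKDTree(coords)
    rmax = R.max()
    areas = np.zeros(n)
    eps = 1e-12
    for i in range(n):
        buried = False
        neighbours: list[int] = []
        for j in tree.query_ball_point(coords[i], R[i] + rmax):
            if j == i:
                continue
            d3 = float(np.linalg.norm(coords[j] - coords[i]))
            if d3 >= R[i] + R[j]:
                continue
            duplicate = d3 < eps and abs(R[j] - R[i]) < eps
            if d3 + R[i] < R[j] - eps or (duplicate and j < i):
                buried = True      # fully inside j, or duplicate of earlier atom
                break
            if duplicate:
                continue           # later duplicate never occludes the kept atom
            neighbours.append(j)
        if buried:
            continue
        zi = coords[i, 2]
        nb = coords[neighbours] if neighbours else np.empty((0, 3))
        Rb = R[neighbours] if neighbours else np.empty(0)
        n_slices = max(1, int(np.ceil(2.0 * R[i] / slice_width)))
        dz = 2.0 * R[i] / n_slices
        area = 0.0
        for s in range(n_slices):
            z = zi - R[i] + (s + 0.5) * dz
            ai_sq = R[i] ** 2 - (z - zi) ** 2
            if ai_sq <= 0.0:
                continue
            ai = np.sqrt(ai_sq)
            arcs: list[tuple[float, float]] = []
            occluded = False
            for (xk, yk, zk), Rk in zip(nb, Rb):
                ak_sq = Rk ** 2 - (z - zk) ** 2
                if ak_sq <= 0.0:
                    continue
                ak = np.sqrt(ak_sq)
                dx, dy = xk - coords[i, 0], yk - coords[i, 1]
                d = np.hypot(dx, dy)
                if d >= ai + ak:
                    continue
                if d + ai <= ak:
                    occluded = True
                    break
                if d + ak <= ai:
                    continue
                half = np.arccos(np.clip((d * d + ai * ai - ak * ak)
                                         / (2.0 * d * ai), -1.0, 1.0))
                arcs.append((np.arctan2(dy, dx), half))
            if occluded:
                continue
            area += _accessible_angle(arcs) * R[i] * dz
        areas[i] = area
    return areas


@dataclass
class SasaResult:
    """Per-frame SASA totals with per-atom areas for the last frame analysed."""

    total: SeriesStats
    per_atom: np.ndarray
    probe_radius: float
    slice_width: float
    radius_set: str = "bondi"


def sasa_frame(sel: Selection, frame_or_coords, topology: Topology,
               probe_radius: float = DEFAULT_PROBE,
               slice_width: float = DEFAULT_SLICE,
               radii_overrides: dict[str, float] | None = None,
               include_hydrogens: bool = True) -> tuple[float, np.ndarray]:
    """SASA (total, per-atom) of a selection in one frame."""
    sel.validate(topology)
    coords = frame_or_coords.coords if isinstance(frame_or_coords, Frame) \
        else np.asarray(frame_or_coords)
    ix = [i for i in sel.indices
          if include_hydrogens or topology.elements[i] != "H"]
    radii = element_radii([topology.elements[i] for i in ix], radii_overrides)
    areas = sasa_areas(coords[ix], radii, probe_radius, slice_width)
    return float(areas.sum()), areas


def sasa_analysis(sel: Selection, trajectory: Trajectory,
                  probe_radius: float = DEFAULT_PROBE,
                  slice_width: float = DEFAULT_SLICE,
                  radii_overrides: dict[str, float] | None = None,
                  include_hydrogens: bool = True,
                  window_fraction: float = 0.1) -> SasaResult:
    """Per-frame micelle SASA over a trajectory (whole coordinates, no images)."""
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    totals, per_atom = [], None
    for fr in trajectory:
        coords = whole_coords(top, fr, cluster=True)
        total, per_atom = sasa_frame(sel, coords, top, probe_radius,
                                     slice_width, radii_overrides,
                                     include_hydrogens)
        totals.append(total)
    return SasaResult(total=SeriesStats(np.asarray(totals), win),
                      per_atom=per_atom, probe_radius=probe_radius,
                      slice_width=slice_width)
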