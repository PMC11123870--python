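"""Micelle size and shape metrics.

Size is measured by the mass-weighted radius of gyration

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i )

and the equivalent hard-sphere micelle radius Rs = sqrt(5/3) * Rg (the
relation between the gyration radius of a uniform solid sphere and its
geometric radius).  Shape is measured by the principal moments of inertia
(Imax/Imin ratio, eccentricity e = 1 - Imin/Iavg, zero for a perfect
sphere), by the sorted components of the diagonalised gyration tensor
(Rg11 >= Rg22 >= Rg33 and their ratios), and by the pairwise distances
between the fullerene-cage centres of mass of the aggregate.

All per-frame primitives assume coordinates have been made whole across the
periodic boundary (see :func:`micellekit.core.whole_coords`); the
trajectory-level wrappers do this for the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import (Frame, MicelleAssignment, Selection, SeriesStats, Topology,
                   Trajectory, center_of_mass, minimum_image_distance,
                   trailing_window, whole_coords)

RS_FACTOR = np.sqrt(5.0 / 3.0)


def radius_of_gyration(sel: Selection, coords_or_frame, topology: Topology) -> float:
    """Mass-weighted RMS distance of the selection from its own COM (nm)."""
    sel.validate(topology)
    coords = coords_or_frame.coords if isinstance(coords_or_frame, Frame) \
        else np.asarray(coords_or_frame)
    ix = sel.array()
    m = topology.masses[ix]
    r = coords[ix] - np.average(coords[ix], weights=m, axis=0)
    return float(np.sqrt(np.sum(m * np.sum(r * r, axis=1)) / m.sum()))


def micelle_radius(rg: float) -> float:
    """Equivalent hard-sphere micelle radius Rs = sqrt(5/3) * Rg (nm)."""
    if rg < 0:
        raise ValueError("radius of gyration must be >= 0")
    return RS_FACTOR * rg


@dataclass
class FrameInertia:
    """Principal moments of inertia for one frame (amu nm^2)."""

    moments: np.ndarray          # eigenvalues sorted descending
    degenerate: bool = False     # near-collinear geometry flag

    @property
    def imax(self) -> float:
        return float(self.moments[0])

    @property
    def imin(self) -> float:
        return float(self.moments[2])

    @property
    def iavg(self) -> float:
        return float(np.mean(self.moments))

    @property
    def ratio_max_min(self) -> float:
        return self.imax / self.imin

    @property
    def eccentricity(self) -> float:
        return eccentricity(self.imin, self.iavg)


def inertia_moments(sel: Selection, coords_or_frame, topology: Topology) -> FrameInertia:
    """Eigenvalues of the mass-weighted inertia tensor about the selection COM.

    Near-collinear geometry (smallest eigenvalue < 1e-10 of the largest) is
    flagged via ``degenerate``; eigenvalues are still returned.
    """
    sel.validate(topology)
    if len(sel) < 3:
        raise ValueError("inertia moments need at least 3 atoms")
    coords = coords_or_frame.coords if isinstance(coords_or_frame, Frame) \
        else np.asarray(coords_or_frame)
    ix = sel.array()
    m = topology.masses[ix]
    r = coords[ix] - np.average(coords[ix], weights=m, axis=0)
    r2 = np.sum(r * r, axis=1)
    tensor = np.diag([np.sum(m * (r2 - r[:, k] ** 2)) for k in range(3)])
    for a in range(3):
        for b in range(a + 1, 3):
            off = -np.sum(m * r[:, a] * r[:, b])
            tensor[a, b] = tensor[b, a] = off
    vals = np.linalg.eigvalsh(tensor)[::-1]
    degenerate = bool(vals[2] < 1e-10 * max(vals[0], 1e-300))
    return FrameInertia(moments=vals, degenerate=degenerate)


def eccentricity(imin: float, iavg: float) -> float:
    """e = 1 - Imin/Iavg; 0 for a perfect sphere."""
    if imin > iavg:
        raise ValueError("Imin must not exceed Iavg")
    if imin <= 0:
        raise ValueError("moments must be > 0")
    return 1.0 - imin / iavg


@dataclass
class FrameGyration:
    """Diagonalised gyration tensor for one frame."""

    eigenvalues: np.ndarray      # lambda1 >= lambda2 >= lambda3 (nm^2)
    degenerate: bool = False

    @property
    def components(self) -> np.ndarray:
        """Rg_kk = sqrt(lambda_k), sorted Rg11 >= Rg22 >= Rg33 (nm)."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def rg(self) -> float:
        return float(np.sqrt(np.sum(np.clip(self.eigenvalues, 0.0, None))))

    @property
    def ratio_12(self) -> float:
        c = self.components
        return float(c[0] / c[1])

    @property
    def ratio_23(self) -> float:
        c = self.components
        return float(c[1] / c[2])


def gyration_tensor(sel: Selection, coords_or_frame, topology: Topology) -> FrameGyration:
    """Mass-weighted second-moment (gyration) tensor eigenvalues, descending."""
    sel.validate(topology)
    if len(sel) < 3:
        raise ValueError("gyration tensor needs at least 3 atoms")
    coords = coords_or_frame.coords if isinstance(coords_or_frame, Frame) \
        else np.asarray(coords_or_frame)
    ix = sel.array()
    m = topology.masses[ix]
    r = coords[ix] - np.average(coords[ix], weights=m, axis=0)
    S = np.einsum("i,ia,ib->ab", m, r, r) / m.sum()
    vals = np.linalg.eigvalsh(S)[::-1]
    degenerate = bool(vals[2] < 1e-10 * max(vals[0], 1e-300))
    return FrameGyration(eigenvalues=vals, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Trajectory-level results
# ---------------------------------------------------------------------------

@dataclass
class GyrationResult:
    rg: SeriesStats
    rs: SeriesStats
    components: dict[str, SeriesStats]     # Rg11, Rg22, Rg33
    ratios: dict[str, SeriesStats]         # Rg11/Rg22, Rg22/Rg33


@dataclass
class InertiaResult:
    imax: SeriesStats
    imin: SeriesStats
    iavg: SeriesStats
    ratio_max_min: SeriesStats
    eccentricity: SeriesStats
    degenerate_frames: int = 0


@dataclass
class ComDistanceSeries:
    """Pairwise cage-COM minimum-image distance time series (nm)."""

    pair_labels: list[str]
    times: np.ndarray
    distances: np.ndarray          # (n_frames, n_pairs)
    stats: dict[str, SeriesStats] = field(default_factory=dict)


def gyration_analysis(sel: Selection, trajectory: Trajectory,
                      window_fraction: float = 0.1,
                      cluster: bool = True) -> GyrationResult:
    """Per-frame Rg/Rs and gyration-tensor components with window statistics."""
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    rgs, comps = [], []
    for fr in trajectory:
        coords = whole_coords(top, fr, cluster=cluster)
        g = gyration_tensor(sel, coords, top)
        rgs.append(g.rg)
        comps.append(g.components)
    rgs = np.asarray(rgs)
    comps = np.asarray(comps)
    return GyrationResult(
        rg=SeriesStats(rgs, win),
        rs=SeriesStats(RS_FACTOR * rgs, win),
        components={f"Rg{k + 1}{k + 1}": SeriesStats(comps[:, k], win)
                    for k in range(3)},
        ratios={"Rg11/Rg22": SeriesStats(comps[:, 0] / comps[:, 1], win),
                "Rg22/Rg33": SeriesStats(comps[:, 1] / comps[:, 2], win)},
    )


def inertia_analysis(sel: Selection, trajectory: Trajectory,
                     window_fraction: float = 0.1,
                     cluster: bool = True) -> InertiaResult:
    """Per-frame principal inertia moments, Imax/Imin and eccentricity."""
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    rows, ndeg = [], 0
    for fr in trajectory:
        coords = whole_coords(top, fr, cluster=cluster)
        fi = inertia_moments(sel, coords, top)
        ndeg += fi.degenerate
        rows.append([fi.imax, fi.imin, fi.iavg, fi.ratio_max_min, fi.eccentricity])
    arr = np.asarray(rows)
    return InertiaResult(
        imax=SeriesStats(arr[:, 0], win), imin=SeriesStats(arr[:, 1], win),
        iavg=SeriesStats(arr[:, 2], win), ratio_max_min=SeriesStats(arr[:, 3], win),
        eccentricity=SeriesStats(arr[:, 4], win), degenerate_frames=ndeg)


def cage_com_distances(assignment: MicelleAssignment, trajectory: Trajectory,
                       window_fraction: float = 0.1) -> ComDistanceSeries:
    """Per-frame minimum-image distances between all fullerene-cage COM pairs.

    For the usual tetrameric aggregate this yields six distance series.
    """
    top = trajectory.topology
    mols = assignment.molecule_ids
    pairs = list(combinations(range(len(mols)), 2))
    if not pairs:
        import warnings
        warnings.warn("fewer than two cage selections; empty distance series")
        return ComDistanceSeries([], trajectory.times(),
                                 np.empty((trajectory.n_frames, 0)))
    labels = [f"{mols[a]}-{mols[b]}" for a, b in pairs]
    win = trailing_window(trajectory.n_frames, window_fraction)
    out = np.empty((trajectory.n_frames, len(pairs)))
    for k, fr in enumerate(trajectory):
        coords = whole_coords(top, fr, cluster=False)
        coms = np.array([center_of_mass(assignment.cages[m], coords, top)
                         for m in mols])
        for p, (a, b) in enumerate(pairs):
            out[k, p] = minimum_image_distance(coms[a], coms[b], fr.box)
    stats = {lab: SeriesStats(out[:, p], win) for p, lab in enumerate(labels)}
    return ComDistanceSeries(labels, trajectory.times(), out, stats)
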