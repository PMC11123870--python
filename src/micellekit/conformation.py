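"""Alkyl-chain conformation metrics: gauche defects and orientation angles.

Dihedral angles follow the IUPAC convention (cis = 0 deg, trans = 180 deg)
and are reported in [0, 360).  A *gauche defect* is a dihedral displaced by
more than a threshold (default 60 deg) from the trans conformation,
measured as circular distance.  The orientation angle theta measures how
far a surfactant's molecular axis (fullerene-cage COM -> head-group
centroid) tilts away from the outward radial direction (micelle COM ->
cage COM); theta = 0 when the cage points at the micelle centre and the
polar heads point into solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (MicelleAssignment, Selection, Topology, Trajectory,
                   center_of_mass, trailing_window, whole_coords)

GAUCHE_THRESHOLD = 60.0   # deg from trans
TRANS = 180.0


class DegenerateDihedralError(ValueError):
    """Raised when three consecutive dihedral atoms are collinear."""


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Dihedral angle of four points, degrees in [0, 360), cis = 0, trans = 180."""
    phi = dihedral_angles(np.asarray([p1]), np.asarray([p2]),
                          np.asarray([p3]), np.asarray([p4]))
    return float(phi[0])


def dihedral_angles(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised dihedral angles for stacked quadruples, degrees in [0, 360)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(b2n < 1e-12) or np.any(norm1 < 1e-12) or np.any(norm2 < 1e-12):
        raise DegenerateDihedralError(
            "collinear or coincident atoms give an undefined dihedral")
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2 / b2n[..., None])
    phi = np.degrees(np.arctan2(y, x))
    return np.mod(phi, 360.0)


def distance_from_trans(phi) -> np.ndarray:
    """Circular distance (deg) between dihedral phi and the trans state (180)."""
    delta = np.mod(np.asarray(phi, dtype=float) - TRANS, 360.0)
    return np.minimum(delta, 360.0 - delta)


@dataclass(frozen=True)
class DihedralSpec:
    """A labelled dihedral: label (1-based position along the chain) and the
    ordered atom quadruple of one chain instance."""

    label: int
    atoms: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError("dihedral atoms must be four distinct indices")


def chain_dihedral_specs(chain_atom_ids: list[list[int]]) -> list[DihedralSpec]:
    """Consecutive dihedral specs for chains given as ordered atom-id lists.

    Chain atoms are ordered head -> cage; the quadruple (i, i+1, i+2, i+3)
    gets label i+1, matching the usual 1..10 labelling of a 13-atom chain.
    """
    specs = []
    for chain in chain_atom_ids:
        for i in range(len(chain) - 3):
            specs.append(DihedralSpec(i + 1, tuple(chain[i:i + 4])))
    return specs


@dataclass
class GaucheProfile:
    """Per-dihedral-label gauche probabilities with sample counts."""

    labels: list[int]
    probabilities: dict[int, float]
    counts: dict[int, int]                 # frames x chain instances per label
    threshold: float = GAUCHE_THRESHOLD


def gauche_profile(specs: list[DihedralSpec], trajectory: Trajectory,
                   threshold: float = GAUCHE_THRESHOLD,
                   window_fraction: float = 1.0) -> GaucheProfile:
    """Fraction of (frame, chain-instance) samples in a gauche-defect state.

    By default the whole trajectory is used (conformational statistics are
    usually wanted over all sampled frames); pass a window fraction to
    restrict to the trailing window.
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames")
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    quad = np.array([s.atoms for s in specs])
    labels = np.array([s.label for s in specs])
    defects = np.zeros(len(specs), dtype=int)
    n_frames = 0
    for fr in trajectory.frames[win]:
        coords = whole_coords(top, fr, cluster=False)
        phi = dihedral_angles(coords[quad[:, 0]], coords[quad[:, 1]],
                              coords[quad[:, 2]], coords[quad[:, 3]])
        defects += (distance_from_trans(phi) > threshold).astype(int)
        n_frames += 1
    uniq = sorted(set(labels.tolist()))
    probs, counts = {}, {}
    for lab in uniq:
        mask = labels == lab
        n = int(mask.sum()) * n_frames
        probs[lab] = float(defects[mask].sum()) / n
        counts[lab] = n
    return GaucheProfile(uniq, probs, counts, threshold)


@dataclass
class ThetaDistribution:
    """Per-molecule orientation-deviation angle series and pooled histogram."""

    per_molecule: dict[int, np.ndarray]    # theta series, degrees
    bin_edges: np.ndarray
    histogram: np.ndarray                  # normalised, sums to 1
    flagged_inverted: int                  # samples with theta > 90 deg
    skipped_frames: int = 0


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero-length vector has no direction")
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv),
                                              -1.0, 1.0))))


def theta_distribution(assignment: MicelleAssignment, trajectory: Trajectory,
                       bin_width: float = 5.0,
                       window_fraction: float = 1.0,
                       micelle_com_mode: str = "all") -> ThetaDistribution:
    """Orientation angle theta per molecule per frame, with pooled histogram.

    micelle_com_mode: "all" uses every surfactant atom for the micelle COM
    (default), "cages" uses cage atoms only.
    """
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    if micelle_com_mode == "all":
        micelle_sel = assignment.surfactant_selection()
    elif micelle_com_mode == "cages":
        ix: list[int] = []
        for m in assignment.molecule_ids:
            ix.extend(assignment.cages[m].indices)
        micelle_sel = Selection(tuple(sorted(ix)), "cages")
    else:
        raise ValueError("micelle_com_mode must be 'all' or 'cages'")
    series: dict[int, list[float]] = {m: [] for m in assignment.molecule_ids}
    skipped = 0
    for fr in trajectory.frames[win]:
        coords = whole_coords(top, fr, cluster=True)
        mcom = center_of_mass(micelle_sel, coords, top)
        for m in assignment.molecule_ids:
            cage_com = center_of_mass(assignment.cages[m], coords, top)
            head_ix = assignment.heads[m].array()
            head_centroid = coords[head_ix].mean(axis=0)
            radial = cage_com - mcom
            axis = head_centroid - cage_com
            if np.linalg.norm(radial) < 1e-9:
                warnings.warn(f"molecule {m}: cage at micelle COM, frame skipped")
                skipped += 1
                continue
            series[m].append(angle_between(axis, radial))
    pooled = np.concatenate([np.asarray(v) for v in series.values()]) \
        if any(series.values()) else np.empty(0)
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    hist, _ = np.histogram(pooled, bins=edges)
    total = hist.sum()
    return ThetaDistribution(
        per_molecule={m: np.asarray(v) for m, v in series.items()},
        bin_edges=edges,
        histogram=hist / total if total else hist.astype(float),
        flagged_inverted=int(np.sum(pooled > 90.0)),
        skipped_frames=skipped)
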