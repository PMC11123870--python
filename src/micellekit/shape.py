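"""Planar-vs-tetrahedral classification of four-cage micelles.

For each of the four leave-one-out triples of cage centres of mass, a plane
is put through the triple; the *angle vector* runs from the triple's
centroid to the fourth cage COM, and beta is the angle between that vector
and its orthogonal projection onto the plane (equivalently 90 deg minus the
angle to the plane normal), folded to [0, 90].  All four beta are ~0 for a
planar quadrilateral and 90 for a regular tetrahedron (the apex sits on
the face-centroid normal).  The procedure is tetramer-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (MicelleAssignment, Trajectory, center_of_mass,
                   trailing_window, whole_coords)

PLANAR_MAX = 10.0     # deg: all four beta at or below -> planar quadrilateral
TETRA_MIN = 60.0      # deg: all four beta at or above -> tetrahedral


class DegenerateTripleError(ValueError):
    """Raised for collinear or coincident leave-one-out triples."""


def beta_angles(cage_coms: np.ndarray, strict: bool = True) -> np.ndarray:
    """The four leave-one-out beta angles (deg) of a cage-COM quadruple.

    With ``strict=False`` a collinear triple yields NaN for that case
    instead of raising.
    """
    pts = np.asarray(cage_coms, dtype=float).reshape(4, 3)
    for a in range(4):
        for b in range(a + 1, 4):
            if np.linalg.norm(pts[a] - pts[b]) < 1e-12:
                raise DegenerateTripleError("coincident cage centres")
    betas = np.empty(4)
    for leave in range(4):
        triple = pts[[i for i in range(4) if i != leave]]
        normal = np.cross(triple[1] - triple[0], triple[2] - triple[0])
        nn = np.linalg.norm(normal)
        scale = np.linalg.norm(triple[1] - triple[0]) * \
            np.linalg.norm(triple[2] - triple[0])
        if nn < 1e-9 * max(scale, 1e-300):
            if strict:
                raise DegenerateTripleError(
                    f"collinear triple (leave-out {leave})")
            betas[leave] = np.nan
            continue
        v = pts[leave] - triple.mean(axis=0)
        sin_beta = abs(np.dot(v, normal / nn)) / np.linalg.norm(v)
        betas[leave] = np.degrees(np.arcsin(np.clip(sin_beta, 0.0, 1.0)))
    return betas


@dataclass
class BetaDistribution:
    """Per-frame beta quadruples, pooled histogram and frame-class fractions."""

    betas: np.ndarray              # (n_frames, 4), deg
    bin_edges: np.ndarray
    histogram: np.ndarray          # normalised over pooled angles
    class_fractions: dict[str, float]
    frame_classes: list[str]
    planar_max: float = PLANAR_MAX
    tetra_min: float = TETRA_MIN


def classify_beta_series(betas: np.ndarray, planar_max: float = PLANAR_MAX,
                         tetra_min: float = TETRA_MIN,
                         bin_width: float = 10.0) -> BetaDistribution:
    """Histogram + frame classification from an (n_frames, 4) beta array.

    A frame is *planar* when all four angles are <= planar_max,
    *tetrahedral* when all four are >= tetra_min, else *intermediate*.
    """
    betas = np.asarray(betas, dtype=float).reshape(-1, 4)
    classes = []
    for row in betas:
        if np.all(row <= planar_max):
            classes.append("planar")
        elif np.all(row >= tetra_min):
            classes.append("tetrahedral")
        else:
            classes.append("intermediate")
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    hist, _ = np.histogram(betas[~np.isnan(betas)], bins=edges)
    total = hist.sum()
    n = len(classes)
    fractions = {c: classes.count(c) / n
                 for c in ("planar", "tetrahedral", "intermediate")}
    return BetaDistribution(betas, edges,
                            hist / total if total else hist.astype(float),
                            fractions, classes, planar_max, tetra_min)


def classify_frames(trajectory: Trajectory, assignment: MicelleAssignment,
                    planar_max: float = PLANAR_MAX,
                    tetra_min: float = TETRA_MIN,
                    bin_width: float = 10.0,
                    window_fraction: float = 1.0) -> BetaDistribution:
    """Beta-angle classification of a four-cage micelle trajectory."""
    if len(assignment.molecule_ids) != 4:
        raise ValueError("beta-angle classification requires exactly four "
                         "cage selections (the procedure is tetramer-specific)")
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    rows = []
    for fr in trajectory.frames[win]:
        coords = whole_coords(top, fr, cluster=True)
        coms = np.array([center_of_mass(assignment.cages[m], coords, top)
                         for m in assignment.molecule_ids])
        rows.append(beta_angles(coms, strict=False))
    return classify_beta_series(np.asarray(rows), planar_max, tetra_min,
                                bin_width)
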