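"""Per-molecule dipole moments from fixed partial charges.

mu = sum_i q_i (r_i - r_ref), reported as |mu| in Debye
(1 e nm = 48.0321 D).  The surfactants studied are net-charged, so |mu|
depends on the reference point; the reference used (selection centre of
mass by default) is stamped into every result.  Embedded species (an ion or
water inside the fullerene cavity) can be included or excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (Frame, MicelleAssignment, Selection, SeriesStats, Topology,
                   Trajectory, center_of_mass, trailing_window, whole_coords)

E_NM_TO_DEBYE = 48.0321


def dipole_moment(sel: Selection, frame_or_coords, topology: Topology,
                  reference: str | np.ndarray = "com") -> float:
    """|mu| of a selection in Debye.

    reference: "com" (mass centre), "geometric" (unweighted centroid) or an
    explicit 3-vector (nm).  Coordinates are assumed whole.
    """
    sel.validate(topology)
    coords = frame_or_coords.coords if isinstance(frame_or_coords, Frame) \
        else np.asarray(frame_or_coords)
    ix = sel.array()
    q = topology.charges[ix]
    if np.all(q == 0):
        warnings.warn(f"selection {sel.label!r} has all-zero charges")
        return 0.0
    if isinstance(reference, str):
        if reference == "com":
            ref = center_of_mass(sel, coords, topology)
        elif reference == "geometric":
            ref = coords[ix].mean(axis=0)
        else:
            raise ValueError("reference must be 'com', 'geometric' or a point")
    else:
        ref = np.asarray(reference, dtype=float)
    mu = np.sum(q[:, None] * (coords[ix] - ref), axis=0)
    return float(np.linalg.norm(mu) * E_NM_TO_DEBYE)


@dataclass
class DipoleResult:
    """Per-molecule |mu| series (Debye) plus the across-molecule mean."""

    per_molecule: dict[int, SeriesStats]
    mean_over_molecules: SeriesStats
    mode: str                      # "pure_surfactant" or "with_embedded"
    reference: str


def dipole_analysis(assignment: MicelleAssignment, trajectory: Trajectory,
                    mode: str = "pure_surfactant",
                    reference: str = "com",
                    window_fraction: float = 0.1) -> DipoleResult:
    """Per-molecule dipole magnitudes over a trajectory.

    mode "pure_surfactant" uses cage+chain+head atoms; "with_embedded" adds
    any species embedded in the cavity.
    """
    if mode not in ("pure_surfactant", "with_embedded"):
        raise ValueError("mode must be pure_surfactant or with_embedded")
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    mols = assignment.molecule_ids
    series = np.empty((trajectory.n_frames, len(mols)))
    sels = [assignment.molecule_selection(m, with_embedded=(mode == "with_embedded"))
            for m in mols]
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for k, fr in enumerate(trajectory):
            coords = whole_coords(top, fr, cluster=False)
            for j, sel in enumerate(sels):
                series[k, j] = dipole_moment(sel, coords, top, reference)
    return DipoleResult(
        per_molecule={m: SeriesStats(series[:, j], win)
                      for j, m in enumerate(mols)},
        mean_over_molecules=SeriesStats(series.mean(axis=1), win),
        mode=mode, reference=reference)
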