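"""Solvation structure and hydrogen-bond dynamics.

* Radial distribution function g(r): minimum-image pair histogram normalised
  by spherical-shell volume and the mean target density over the box,
  averaged over frames and reference atoms.
* Hydration number: mean count of water oxygens within a cutoff (default
  0.35 nm) of a tagged atom; equivalent to the RDF integral to that cutoff
  up to binning.
* Geometric hydrogen-bond detection: donor-acceptor distance within
  0.35 nm and an angle criterion, by default the donor-H...acceptor angle
  at the hydrogen >= 120 deg (the common literature reading of a "120 deg"
  threshold); an equivalent H-D...A <= 60 deg convention is selectable.
* Intermittent hydrogen-bond time correlation C_HB(t) = <h(0)h(t)> averaged
  over time origins and pairs, normalised so C_HB(0) = 1; h(t) is the bond
  presence indicator and re-formed bonds count (intermittent, not
  continuous, definition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (Frame, Selection, Topology, Trajectory,
                   minimum_image_vector, trailing_window, wrap_coords)


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RdfResult:
    bin_centers: np.ndarray        # nm
    g: np.ndarray
    bin_width: float
    reference_label: str
    target_label: str
    n_frames: int
    density: float                 # mean target density, nm^-3

    def peak_position(self) -> float:
        """Bin centre of the global maximum of g(r)."""
        return float(self.bin_centers[int(np.argmax(self.g))])

    def integral(self, r_max: float) -> float:
        """Coordination number: integral of rho * g * 4 pi r^2 dr to r_max."""
        mask = self.bin_centers <= r_max
        edges_lo = self.bin_centers[mask] - self.bin_width / 2
        edges_hi = self.bin_centers[mask] + self.bin_width / 2
        shell = 4.0 / 3.0 * np.pi * (edges_hi ** 3 - edges_lo ** 3)
        return float(np.sum(self.density * self.g[mask] * shell))


def _pair_distances(ref: np.ndarray, tgt: np.ndarray, box: np.ndarray,
                    exclude_same_index: np.ndarray | None = None) -> np.ndarray:
    """Minimum-image distances for all (ref, tgt) pairs, flattened."""
    d = minimum_image_vector(ref[:, None, :], tgt[None, :, :], box)
    dist = np.linalg.norm(d, axis=-1)
    if exclude_same_index is not None:
        dist[exclude_same_index] = np.inf
    return dist.ravel()


def rdf(reference_sel: Selection, target_sel: Selection, trajectory: Trajectory,
        bin_width: float = 0.01, r_max: float | None = None,
        window_fraction: float = 1.0) -> RdfResult:
    """g(r) between two selections, averaged over frames and reference atoms."""
    top = trajectory.topology
    reference_sel.validate(top)
    target_sel.validate(top)
    win = trailing_window(trajectory.n_frames, window_fraction)
    frames = trajectory.frames[win]
    min_edge = min(float(fr.box.min()) for fr in frames)
    limit = min_edge / 2.0
    if r_max is None:
        r_max = limit
    elif r_max > limit:
        warnings.warn(f"r_max {r_max} nm exceeds half the box edge; "
                      f"clipped to {limit:.3f} nm")
        r_max = limit
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centers))
    ref_ix = reference_sel.array()
    tgt_ix = target_sel.array()
    same = ref_ix[:, None] == tgt_ix[None, :]
    density_sum = 0.0
    for fr in frames:
        dist = _pair_distances(fr.coords[ref_ix], fr.coords[tgt_ix], fr.box,
                               exclude_same_index=same if same.any() else None)
        h, _ = np.histogram(dist, bins=edges)
        hist += h
        vol = float(np.prod(fr.box))
        n_tgt_eff = len(tgt_ix) - (1 if same.any() else 0)
        density_sum += n_tgt_eff / vol
    n_frames = len(frames)
    density = density_sum / n_frames
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = n_frames * len(ref_ix) * density * shell
    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    return RdfResult(centers, g, bin_width, reference_sel.label,
                     target_sel.label, n_frames, density)


# ---------------------------------------------------------------------------
# Hydration numbers
# ---------------------------------------------------------------------------

@dataclass
class HydrationResult:
    atom_indices: np.ndarray
    mean_counts: np.ndarray        # per reference atom
    sd_counts: np.ndarray
    cutoff: float


def hydration_number(atom_sel: Selection, water_oxygen_sel: Selection,
                     trajectory: Trajectory, cutoff: float = 0.35,
                     window_fraction: float = 1.0) -> HydrationResult:
    """Mean number of water oxygens within ``cutoff`` of each tagged atom."""
    top = trajectory.topology
    atom_sel.validate(top)
    water_oxygen_sel.validate(top)
    win = trailing_window(trajectory.n_frames, window_fraction)
    frames = trajectory.frames[win]
    ref_ix = atom_sel.array()
    wat_ix = water_oxygen_sel.array()
    counts = np.zeros((len(frames), len(ref_ix)))
    for k, fr in enumerate(frames):
        box = fr.box
        wat = wrap_coords(fr.coords[wat_ix], box)
        ref = wrap_coords(fr.coords[ref_ix], box)
        # cKDTree periodic boxes need coords strictly inside [0, box)
        wat = np.where(wat >= box, 0.0, wat)
        ref = np.where(ref >= box, 0.0, ref)
        tree = cKDTree(wat, boxsize=box)
        counts[k] = [len(tree.query_ball_point(r, cutoff)) for r in ref]
    return HydrationResult(ref_ix, counts.mean(axis=0), counts.std(axis=0),
                           cutoff)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HbondCriteria:
    """Geometric hydrogen-bond criteria.

    ``angle_convention`` selects the measured angle:
      * "dha": donor-H...acceptor angle at the hydrogen; accept >= cutoff
        (default cutoff 120 deg).
      * "hda": H-donor...acceptor angle at the donor; accept <= cutoff
        (default cutoff 60 deg).
    """

    distance_cutoff: float = 0.35          # nm, donor-acceptor
    angle_convention: str = "dha"
    angle_cutoff: float | None = None      # deg; default set by convention

    def __post_init__(self) -> None:
        if self.angle_convention not in ("dha", "hda"):
            raise ValueError("angle_convention must be 'dha' or 'hda'")
        if self.angle_cutoff is None:
            self.angle_cutoff = 120.0 if self.angle_convention == "dha" else 60.0
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")

    def accepts(self, d_pos, h_pos, a_pos, box) -> bool:
        """Apply distance + angle tests to one D, H, A geometry (minimum image)."""
        da = minimum_image_vector(d_pos, a_pos, box)
        if np.linalg.norm(da) > self.distance_cutoff:
            return False
        if self.angle_convention == "dha":
            hd = minimum_image_vector(h_pos, d_pos, box)
            ha = minimum_image_vector(h_pos, a_pos, box)
            cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            return bool(angle >= self.angle_cutoff)
        dh = minimum_image_vector(d_pos, h_pos, box)
        cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return bool(angle <= self.angle_cutoff)


def detect_hbonds(criteria: HbondCriteria, donor_sel: Selection,
                  acceptor_sel: Selection, frame: Frame, topology: Topology
                  ) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the criteria."""
    donor_sel.validate(topology)
    acceptor_sel.validate(topology)
    box = frame.box
    acc_ix = acceptor_sel.array()
    acc = wrap_coords(frame.coords[acc_ix], box)
    acc = np.where(acc >= box, 0.0, acc)
    tree = cKDTree(acc, boxsize=box)
    bonds: list[tuple[int, int, int]] = []
    for d in donor_sel.indices:
        hydrogens = topology.bonded_hydrogens(d)
        if not hydrogens:
            warnings.warn(f"donor atom {d} has no bonded hydrogen; skipped")
            continue
        dpos = wrap_coords(frame.coords[d], box)
        dpos = np.where(dpos >= box, 0.0, dpos)
        for k in tree.query_ball_point(dpos, criteria.distance_cutoff):
            a = int(acc_ix[k])
            if a == d:
                continue
            for h in hydrogens:
                if criteria.accepts(frame.coords[d], frame.coords[h],
                                    frame.coords[a], box):
                    bonds.append((d, h, a))
    return bonds


@dataclass
class HbondSeries:
    """Per-frame hydrogen-bond lists plus per-site mean counts."""

    frames: list[list[tuple[int, int, int]]]
    site_indices: np.ndarray
    mean_counts: np.ndarray        # bonds per site per frame
    sd_counts: np.ndarray
    mode: str                      # "donor", "acceptor" or "both"


def hbond_series(criteria: HbondCriteria, donor_sel: Selection,
                 acceptor_sel: Selection, trajectory: Trajectory,
                 sites: Selection, mode: str = "both",
                 window_fraction: float = 1.0) -> HbondSeries:
    """Per-frame detection with per-site statistics over the analysis window.

    ``sites`` are the atoms whose bond counts are tabulated; ``mode``
    counts bonds where the site acts as donor, acceptor, or either.
    """
    if mode not in ("donor", "acceptor", "both"):
        raise ValueError("mode must be donor/acceptor/both")
    top = trajectory.topology
    win = trailing_window(trajectory.n_frames, window_fraction)
    frames = trajectory.frames[win]
    site_ix = sites.array()
    pos = {int(a): i for i, a in enumerate(site_ix)}
    counts = np.zeros((len(frames), len(site_ix)))
    all_bonds = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for k, fr in enumerate(frames):
            bonds = detect_hbonds(criteria, donor_sel, acceptor_sel, fr, top)
            all_bonds.append(bonds)
            for d, h, a in bonds:
                if mode in ("donor", "both") and d in pos:
                    counts[k, pos[d]] += 1
                if mode in ("acceptor", "both") and a in pos:
                    counts[k, pos[a]] += 1
    return HbondSeries(all_bonds, site_ix, counts.mean(axis=0),
                       counts.std(axis=0), mode)


# ---------------------------------------------------------------------------
# Hydrogen-bond time correlation
# ---------------------------------------------------------------------------

@dataclass
class HbondTcf:
    lags: np.ndarray               # ps
    c: np.ndarray                  # C_HB(t), C(0) = 1


def presence_matrix(frame_bonds: list[list[tuple[int, int, int]]]
                    ) -> np.ndarray:
    """Build the (n_pairs, n_frames) 0/1 presence matrix of donor-acceptor
    pairs from per-frame bond lists (hydrogen identity is ignored: a pair is
    bonded if any of its hydrogens satisfies the criteria)."""
    pairs: dict[tuple[int, int], int] = {}
    for bonds in frame_bonds:
        for d, _h, a in bonds:
            pairs.setdefault((d, a), len(pairs))
    h = np.zeros((len(pairs), len(frame_bonds)), dtype=bool)
    for t, bonds in enumerate(frame_bonds):
        for d, _hh, a in bonds:
            h[pairs[(d, a)], t] = True
    return h


def hbond_tcf(h: np.ndarray, max_lag: int | None = None,
              dt: float = 1.0) -> HbondTcf:
    """Intermittent C_HB(t) from a (n_pairs, n_frames) presence matrix.

    Time origins are every frame up to T - max_lag (default max_lag: 20% of
    the series).  Normalised by <h(0)h(0)> over the same origins, so
    C_HB(0) = 1 whenever any bond exists.
    """
    h = np.atleast_2d(np.asarray(h, dtype=float))
    n_pairs, T = h.shape
    if T < 2:
        raise ValueError("need at least 2 frames")
    if max_lag is None:
        max_lag = max(1, int(0.2 * T))
    max_lag = min(max_lag, T - 1)
    origins = T - max_lag
    num = np.empty(max_lag + 1)
    base = h[:, :origins]
    for lag in range(max_lag + 1):
        num[lag] = np.sum(base * h[:, lag:lag + origins])
    if num[0] == 0:
        raise ValueError("no hydrogen bonds to correlate")
    return HbondTcf(lags=np.arange(max_lag + 1) * dt, c=num / num[0])
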