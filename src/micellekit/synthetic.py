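"""Seeded generator of toy fullerene-amphiphile micelle trajectories.

The generator emulates the statistical structure of a four-cage surfactant
micelle in water so that every analysis stage can be verified against known
ground truth: cage pseudo-atom shells at tetrahedral / planar-square /
interpolated arrangements with per-frame Gaussian jitter, alkyl chains
grown with fixed bond length (0.153 nm) and angle (111 deg) whose dihedrals
are sampled trans/gauche per a prescribed probability vector, water placed
uniformly at a given density plus optional planted first-shell counts at
exact radii, ions on prescribed shells or in bulk, and optional embedded
species at the cage centres.

Frames are statistically, not dynamically, realistic: there are no forces
or thermostats, and successive frames are independent samples.  All
randomness flows through one seeded generator; the same seed reproduces
the trajectory bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import (Frame, MicelleAssignment, Topology, Trajectory,
                   assignment_from_roles)
from .conformation import DihedralSpec, chain_dihedral_specs
from .io import ELEMENT_MASSES, write_gro, write_topology_csv, write_xyz

BOND_CC = 0.153       # nm
ANGLE_CCC = 111.0     # deg
GAUCHE_STATES = (60.0, 300.0)   # deg, +/- gauche
TRANS_STATE = 180.0

#: per-dihedral gauche probabilities shaped like a real amphiphile chain:
#: ring-locked dihedrals pinned at 0 or 1, flexible ones intermediate
DEFAULT_GAUCHE_PROBS = (0.6, 0.3, 0.6, 0.8, 0.0, 1.0, 0.0, 0.6, 0.0, 1.0)

#: chain atom element pattern (head -> cage): positions 2, 6, 7, 8 are N
CHAIN_ELEMENTS = tuple("N" if i in (2, 6, 7, 8) else "C" for i in range(1, 14))

ION_CHARGES = {"Cl": -1.0, "Na": 1.0}


@dataclass(frozen=True)
class PlantedShell:
    """Exactly ``count`` water oxygens at distance ``radius`` (nm) around one
    tagged chain atom, with bulk water excluded near that atom."""

    label: int                # chain atom label 1..13
    count: int
    radius: float
    molecule: int = 0
    chain: int = 0


@dataclass(frozen=True)
class IonShell:
    """``count`` ions of ``element`` at distance ``radius`` around one tagged
    chain atom."""

    element: str
    count: int
    radius: float
    label: int = 2
    molecule: int = 0
    chain: int = 0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic micelle trajectory.

    Defaults mirror the studied systems at desk scale: a tetramer with cage
    COM spacing ~1.0 nm (the C60 crystal contact distance), C60-like
    60-pseudo-atom cages of radius 0.35 nm, five 13-atom chains per cage
    with the characteristic gauche-probability profile, in a cubic box.
    The box (6 nm) and water density (0.3 nm^-3) are reduced from the
    production-scale 10 nm / 33 nm^-3 system so that a full analysis run
    takes seconds; both are plain fields for callers who want more.
    """

    arrangement: str = "tetrahedral"     # tetrahedral | planar_square | interpolated
    interpolation: float = 0.5           # lambda for "interpolated"
    edge: float = 1.0                    # nm, cage-COM spacing
    com_jitter: float = 0.02             # nm, per-frame Gaussian sigma
    n_frames: int = 50
    dt: float = 1.0                      # ps
    box: tuple[float, float, float] = (6.0, 6.0, 6.0)
    n_molecules: int = 4
    n_cage_atoms: int = 60
    cage_radius: float = 0.35            # nm
    chains_per_cage: int = 5
    chain_length: int = 13
    gauche_probs: tuple[float, ...] = DEFAULT_GAUCHE_PROBS
    water_density: float = 0.3           # nm^-3 (oxygen count density)
    water_model: str = "O"               # "O" (oxygen-only) | "tip3p"
    water_exclusion_radius: float | None = None   # default cage_radius + 0.25
    planted_shells: tuple[PlantedShell, ...] = ()
    planted_guard: float = 0.45          # nm, bulk-water keep-out around targets
    ion_shells: tuple[IonShell, ...] = ()
    n_bulk_ions: int | None = None       # None -> neutralise net charge with Cl-
    embedded: tuple[str | None, ...] | str | None = None   # per-molecule or one
    charged: bool = True                 # +1 e on each chain's N2 head atom
    wrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrangement not in ("tetrahedral", "planar_square", "interpolated"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if len(self.gauche_probs) != self.chain_length - 3:
            raise ValueError("gauche_probs must have chain_length - 3 entries")
        if any(not 0 <= p <= 1 for p in self.gauche_probs):
            raise ValueError("gauche probabilities must lie in [0, 1]")
        if min(self.edge, self.cage_radius, *self.box) <= 0:
            raise ValueError("all lengths must be > 0")
        chain_reach = (self.chain_length + 1) * BOND_CC \
            if self.chains_per_cage else 0.0
        reach = self.edge + 2 * (self.cage_radius + chain_reach)
        if reach > min(self.box):
            raise ValueError(
                f"box {self.box} too small for solute (needs ~{reach:.2f} nm)")


@dataclass
class GroundTruth:
    """Exact generating quantities for a synthetic trajectory."""

    arrangement: list[str]                       # per-frame label
    cage_centers: np.ndarray                     # (T, n_mol, 3), nm
    dihedral_specs: list[DihedralSpec]
    dihedral_states: np.ndarray                  # (T, n_chains, n_dih) gauche?
    chain_atom_ids: list[list[int]]              # head -> cage order
    planted: list[dict]                          # atom_index, count, radius
    ion_info: list[dict]
    surfactant_molecules: list[int]

    def to_dict(self) -> dict:
        return {
            "arrangement": self.arrangement,
            "cage_centers": self.cage_centers.tolist(),
            "dihedral_specs": [{"label": s.label, "atoms": list(s.atoms)}
                               for s in self.dihedral_specs],
            "dihedral_states": self.dihedral_states.astype(int).tolist(),
            "chain_atom_ids": self.chain_atom_ids,
            "planted": self.planted,
            "ion_info": self.ion_info,
            "surfactant_molecules": self.surfactant_molecules,
        }


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral construction)."""
    if n == 1:
        return np.zeros((1, 3))
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def arrangement_vertices(arrangement: str, edge: float,
                         interpolation: float = 0.5,
                         n: int = 4) -> np.ndarray:
    """Base cage-COM positions centred at the origin."""
    if n != 4 and arrangement != "planar_square":
        raise ValueError("non-square arrangements are defined for tetramers")
    s = edge / np.sqrt(8.0)
    tetra = s * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float)
    if arrangement == "tetrahedral":
        return tetra
    if arrangement == "planar_square":
        h = edge / 2.0
        sq = np.array([[h, h, 0], [h, -h, 0], [-h, h, 0], [-h, -h, 0]],
                      dtype=float)
        return sq[:n]
    out = tetra.copy()
    out[:, 2] *= interpolation        # lambda=0 planar, 1 tetrahedral
    return out


def _rotation_to(u: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +x to the unit vector u."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, u)
    c = float(np.dot(x, u))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
          angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place the next chain atom from bond length, bond angle and dihedral."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(dihedrals_deg: np.ndarray, bond: float = BOND_CC,
                angle_deg: float = ANGLE_CCC) -> np.ndarray:
    """Chain coordinates in a local frame growing along +x.

    Returns (len(dihedrals) + 3, 3); atom 0 is the first (cage-side) atom.
    """
    n = len(dihedrals_deg) + 3
    pos = np.zeros((n, 3))
    pos[1] = [bond, 0.0, 0.0]
    back = np.radians(180.0 - angle_deg)
    pos[2] = pos[1] + bond * np.array([np.cos(back), np.sin(back), 0.0])
    for i in range(3, n):
        pos[i] = _nerf(pos[i - 3], pos[i - 2], pos[i - 1], bond, angle_deg,
                       dihedrals_deg[i - 3])
    return pos


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory and its ground truth from a SyntheticSpec."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    center = box / 2.0
    n_mol = spec.n_molecules
    base = arrangement_vertices(spec.arrangement, spec.edge,
                                spec.interpolation, n_mol) + center
    shell = fibonacci_sphere(spec.n_cage_atoms) * spec.cage_radius
    n_dih = spec.chain_length - 3

    embedded = spec.embedded
    if embedded is None or isinstance(embedded, str):
        embedded = tuple([embedded] * n_mol)  # type: ignore[list-item]
    if len(embedded) != n_mol:
        raise ValueError("embedded must be one species or one per molecule")

    # --- static topology -------------------------------------------------
    names: list[str] = []
    elements: list[str] = []
    charges: list[float] = []
    mol_ids: list[int] = []
    roles: list[str] = []
    bonds: list[tuple[int, int]] = []
    chain_atom_ids: list[list[int]] = []       # head -> cage order
    cage_atom_ix: list[np.ndarray] = []
    chain_dirs: list[list[np.ndarray]] = []    # per molecule, per chain
    chain_rolls: list[list[float]] = []
    embedded_ix: dict[int, int] = {}

    for m in range(n_mol):
        ix0 = len(names)
        for k in range(spec.n_cage_atoms):
            names.append("CC")
            elements.append("C")
            charges.append(0.0)
            mol_ids.append(m)
            roles.append("cage")
            if k > 0:      # connectivity so molecules unwrap across boundaries
                bonds.append((ix0 + k - 1, ix0 + k))
        cage_atom_ix.append(np.arange(ix0, ix0 + spec.n_cage_atoms))
        outward = base[m] - base.mean(axis=0)
        if np.linalg.norm(outward) < 1e-9:
            outward = np.array([0.0, 0.0, 1.0])
        outward = outward / np.linalg.norm(outward)
        R_out = _rotation_to(outward)
        dirs, rolls = [], []
        for c in range(spec.chains_per_cage):
            if spec.chains_per_cage == 1:
                u = outward
            else:
                az = 2.0 * np.pi * c / spec.chains_per_cage
                tilt = np.radians(40.0)
                u = R_out @ np.array([np.cos(tilt),
                                      np.sin(tilt) * np.cos(az),
                                      np.sin(tilt) * np.sin(az)])
            dirs.append(u)
            rolls.append(float(rng.uniform(0.0, 2.0 * np.pi)))
            start = len(names)
            ids = list(range(start, start + spec.chain_length))
            chain_atom_ids.append(ids[::-1])   # stored cage->head; flip to head->cage
            for j in range(spec.chain_length):          # j=0 cage side
                label = spec.chain_length - j           # 13..1 head-numbering
                el = CHAIN_ELEMENTS[label - 1]
                names.append(f"{el}{label}")
                elements.append(el)
                charges.append(1.0 if (spec.charged and label == 2) else 0.0)
                mol_ids.append(m)
                roles.append("head" if label <= 2 else "chain")
                if j > 0:
                    bonds.append((start + j - 1, start + j))
            anchor_atom = ix0 + int(np.argmax(shell @ u))
            bonds.append((anchor_atom, start))   # graft chain onto the cage
        chain_dirs.append(dirs)
        chain_rolls.append(rolls)
        if embedded[m] is not None:
            sp = embedded[m]
            embedded_ix[m] = len(names)
            if sp == "H2O":
                names.append("OW")
                elements.append("O")
                charges.append(0.0)
            else:
                names.append(sp.upper())
                elements.append(sp)
                charges.append(ION_CHARGES.get(sp, 0.0))
            mol_ids.append(m)
            roles.append("embedded")
            bonds.append((ix0, embedded_ix[m]))   # unwrap with the host cage

    # shell ions, then bulk ions
    ion_info: list[dict] = []
    shell_ion_ix: list[tuple[IonShell, np.ndarray, int]] = []
    next_mol = n_mol
    for ish in spec.ion_shells:
        chain_idx = ish.molecule * spec.chains_per_cage + ish.chain
        target = chain_atom_ids[chain_idx][ish.label - 1]
        ids = []
        for _ in range(ish.count):
            ids.append(len(names))
            names.append(ish.element.upper())
            elements.append(ish.element)
            charges.append(ION_CHARGES.get(ish.element, 0.0) if spec.charged else 0.0)
            mol_ids.append(next_mol)
            roles.append("ion")
            next_mol += 1
        shell_ion_ix.append((ish, np.asarray(ids), target))
        ion_info.append({"element": ish.element, "count": ish.count,
                         "radius": ish.radius, "atom_index": int(target)})
    net = sum(charges)
    n_bulk = spec.n_bulk_ions
    if n_bulk is None:
        n_bulk = int(round(net)) if spec.charged and net > 0 else 0
    bulk_ion_ix = []
    for _ in range(n_bulk):
        bulk_ion_ix.append(len(names))
        names.append("CL")
        elements.append("Cl")
        charges.append(-1.0 if spec.charged else 0.0)
        mol_ids.append(next_mol)
        roles.append("ion")
        next_mol += 1
    bulk_ion_ix = np.asarray(bulk_ion_ix, dtype=int)

    # planted-shell targets
    planted: list[dict] = []
    planted_targets: list[tuple[int, int, float]] = []
    for ps in spec.planted_shells:
        chain_idx = ps.molecule * spec.chains_per_cage + ps.chain
        target = chain_atom_ids[chain_idx][ps.label - 1]
        planted_targets.append((target, ps.count, ps.radius))
        planted.append({"atom_index": int(target), "count": ps.count,
                        "radius": ps.radius})

    # waters: count drawn once, positions per frame
    vol = float(np.prod(box))
    n_water = int(rng.poisson(spec.water_density * vol))
    n_planted = sum(ps.count for ps in spec.planted_shells)
    water_ix: list[np.ndarray] = []
    site_per_water = 3 if spec.water_model == "tip3p" else 1
    for _ in range(n_water + n_planted):
        ids = []
        for s in range(site_per_water):
            ids.append(len(names))
            if s == 0:
                names.append("OW")
                elements.append("O")
                charges.append(-0.834 if spec.water_model == "tip3p" else 0.0)
            else:
                names.append(f"HW{s}")
                elements.append("H")
                charges.append(0.417)
            mol_ids.append(next_mol)
            roles.append("water")
        if site_per_water == 3:
            bonds.append((ids[0], ids[1]))
            bonds.append((ids[0], ids[2]))
        water_ix.append(np.asarray(ids))
        next_mol += 1

    masses = np.array([ELEMENT_MASSES[e] for e in elements])
    topology = Topology(names=names, elements=elements, masses=masses,
                        charges=np.asarray(charges), molecule_ids=np.asarray(mol_ids),
                        roles=roles, bonds=bonds)
    n_atoms = topology.n_atoms

    # --- per-frame coordinates -------------------------------------------
    excl = spec.water_exclusion_radius
    if excl is None:
        excl = spec.cage_radius + 0.25
    n_chains_total = n_mol * spec.chains_per_cage
    frames: list[Frame] = []
    centers_out = np.empty((spec.n_frames, n_mol, 3))
    states_out = np.zeros((spec.n_frames, n_chains_total, n_dih), dtype=bool)
    probs = np.asarray(spec.gauche_probs)

    for t in range(spec.n_frames):
        coords = np.zeros((n_atoms, 3))
        centers = base + rng.normal(0.0, spec.com_jitter, size=(n_mol, 3))
        centers_out[t] = centers
        for m in range(n_mol):
            coords[cage_atom_ix[m]] = centers[m] + shell
            if m in embedded_ix:
                coords[embedded_ix[m]] = centers[m]
            for c in range(spec.chains_per_cage):
                chain_idx = m * spec.chains_per_cage + c
                # built cage->head: build-position j has head-label L-j,
                # i.e. dihedral j (atoms j..j+3) carries label L-3-j
                gauche = rng.random(n_dih) < probs[::-1]
                states_out[t, chain_idx] = gauche[::-1]
                which = rng.integers(0, 2, size=n_dih)
                dihedrals = np.where(gauche,
                                     np.asarray(GAUCHE_STATES)[which],
                                     TRANS_STATE)
                local = build_chain(dihedrals)
                u = chain_dirs[m][c]
                roll = chain_rolls[m][c]
                cr, sr = np.cos(roll), np.sin(roll)
                R_roll = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
                R = _rotation_to(u) @ R_roll
                anchor = centers[m] + u * (spec.cage_radius + BOND_CC)
                ids = chain_atom_ids[chain_idx][::-1]    # cage -> head order
                coords[ids] = anchor + local @ R.T
        for ish, ids, target in shell_ion_ix:
            dirs = fibonacci_sphere(max(len(ids), 2))[:len(ids)] if len(ids) > 1 \
                else rng.normal(size=(1, 3))
            dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
            coords[ids] = coords[target] + ish.radius * dirs
        if len(bulk_ion_ix):
            coords[bulk_ion_ix] = _place_uniform(rng, len(bulk_ion_ix), box,
                                                 centers, excl, [])
        # planted first-shell waters, then bulk waters
        w = 0
        for target, count, radius in planted_targets:
            for _ in range(count):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                _set_water(coords, water_ix[w], coords[target] + radius * d,
                           rng, spec.water_model)
                w += 1
        guard = [(coords[tg], spec.planted_guard) for tg, _c, _r in planted_targets]
        if n_water:
            opos = _place_uniform(rng, n_water, box, centers, excl, guard)
            for i in range(n_water):
                _set_water(coords, water_ix[w + i], opos[i], rng, spec.water_model)
        if spec.wrap:
            coords = np.mod(coords, box)
        frames.append(Frame(time=t * spec.dt, coords=coords, box=box.copy()))

    truth = GroundTruth(
        arrangement=[spec.arrangement] * spec.n_frames,
        cage_centers=centers_out,
        dihedral_specs=chain_dihedral_specs(chain_atom_ids),
        dihedral_states=states_out,
        chain_atom_ids=chain_atom_ids,
        planted=planted,
        ion_info=ion_info,
        surfactant_molecules=list(range(n_mol)),
    )
    return Trajectory(topology, frames), truth


def _place_uniform(rng, n: int, box: np.ndarray, centers: np.ndarray,
                   excl: float, guards: list[tuple[np.ndarray, float]]
                   ) -> np.ndarray:
    """Uniform positions in the box, outside cage/guard exclusion spheres."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 1.0, size=(max(2 * (n - filled), 16), 3)) * box
        ok = np.ones(len(cand), dtype=bool)
        if excl > 0:
            for ctr in centers:
                ok &= np.linalg.norm(cand - ctr, axis=1) > excl
        for gpos, grad in guards:
            ok &= np.linalg.norm(cand - gpos, axis=1) > grad
        good = cand[ok]
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def _set_water(coords: np.ndarray, ids: np.ndarray, opos: np.ndarray,
               rng, model: str) -> None:
    coords[ids[0]] = opos
    if model == "tip3p" and len(ids) == 3:
        # rigid 3-site water, OH 0.09572 nm, HOH 104.52 deg, random orientation
        half = np.radians(104.52 / 2.0)
        local = 0.09572 * np.array([[np.cos(half), np.sin(half), 0.0],
                                    [np.cos(half), -np.sin(half), 0.0]])
        # random rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        coords[ids[1]] = opos + local[0] @ q.T
        coords[ids[2]] = opos + local[1] @ q.T


def micelle_assignment(topology: Topology) -> MicelleAssignment:
    """Assignment of the generated surfactants into one micelle."""
    return assignment_from_roles(topology)


def write_synthetic(spec: SyntheticSpec, outdir: str | Path
                    ) -> tuple[Trajectory, GroundTruth]:
    """Generate and write traj.xyz, frame0.gro, topology.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, truth = generate(spec)
    write_xyz(outdir / "traj.xyz", traj)
    write_gro(outdir / "frame0.gro", traj.topology, traj.frames[0])
    write_topology_csv(outdir / "topology.csv", traj.topology)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh)
    with open(outdir / "spec.json", "w") as fh:
        d = asdict(spec)
        json.dump(d, fh, default=list)
    return traj, truth
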