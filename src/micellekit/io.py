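"""Readers and writers for coordinate/trajectory files and topology sidecars.

Supported formats
-----------------
GRO, PDB (single- or multi-frame; PDB/XYZ coordinates in Angstrom are
converted to nm on read), a multi-frame XYZ dialect whose comment line may
carry ``box=Lx,Ly,Lz`` (nm) and ``time=T`` (ps) tokens, and XTC/DCD behind
the same Trajectory contract.  GRO, PDB and XTC/DCD parsing is delegated to
MDAnalysis; the XYZ dialect and the topology CSV sidecar are parsed here.

The topology sidecar is a CSV with columns
``atom_id,name,element,mass,charge,molecule_id,role`` and an optional
``bonds`` column listing bonded partner atom_ids separated by ``;``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory, TriclinicBoxError

A_TO_NM = 0.1

#: default atomic masses (amu) used when no sidecar supplies them
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ca": 40.078, "Br": 79.904, "I": 126.904,
}

_TWO_LETTER = {"CL": "Cl", "NA": "Na", "BR": "Br", "MG": "Mg", "CA": "Ca"}


class ParseError(ValueError):
    """Raised for malformed coordinate-file records; names the offending line."""


def guess_element(name: str) -> str:
    """Guess an element symbol from an atom name (GRO/PDB style)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot guess element from atom name {name!r}")
    if stripped[:2].upper() in _TWO_LETTER:
        return _TWO_LETTER[stripped[:2].upper()]
    return stripped[0].upper()


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    return Path(path).suffix.lstrip(".").lower()


def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise ParseError("file carries no box information")
    dims = np.asarray(dimensions, dtype=float)
    if dims.shape[-1] >= 6 and not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise TriclinicBoxError(
            f"triclinic box (angles {dims[3:6]}) is not supported")
    return dims[:3] * A_TO_NM


def _topology_from_universe(u) -> Topology:
    names = [str(n) for n in u.atoms.names]
    elements = [guess_element(n) for n in names]
    masses = np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements])
    try:
        mol_ids = np.asarray(u.atoms.resids, dtype=int)
    except Exception:
        mol_ids = np.zeros(len(names), dtype=int)
    return Topology(names=names, elements=elements, masses=masses,
                    charges=np.zeros(len(names)), molecule_ids=mol_ids,
                    roles=["other"] * len(names))


def read_structure(path: str | Path, fmt: str | None = None,
                   box: tuple[float, float, float] | None = None
                   ) -> tuple[Topology, Frame]:
    """Read a single-frame structure file (GRO/PDB/XYZ) -> (Topology, Frame).

    Coordinates are normalised to nm.  ``box`` (nm) overrides/supplies the
    cell when the file carries none.
    """
    fmt = _detect_format(path, fmt)
    if fmt == "xyz":
        traj = read_xyz(path, box=box)
        return traj.topology, traj.frames[0]
    if fmt not in ("gro", "pdb"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # surface MDAnalysis parse failures with context
            raise ParseError(f"cannot parse {path}: {exc}") from exc
    top = _topology_from_universe(u)
    try:
        box_nm = _check_orthorhombic(u.dimensions)
    except ParseError:
        if box is None:
            raise ParseError(f"{path}: no box in file and none supplied")
        box_nm = np.asarray(box, dtype=float)
    coords = u.atoms.positions * A_TO_NM
    return top, Frame(time=0.0, coords=coords, box=box_nm)


def read_trajectory(path: str | Path, fmt: str | None = None,
                    topology: Topology | None = None,
                    box: tuple[float, float, float] | None = None,
                    dt: float = 1.0) -> Trajectory:
    """Read a multi-frame trajectory (XYZ/GRO/PDB/XTC/DCD) -> Trajectory.

    For XTC/DCD a ``topology`` must be supplied (binary trajectories carry no
    atom table).  ``dt`` (ps) is the frame stride used when the file states
    no times.
    """
    fmt = _detect_format(path, fmt)
    if fmt == "xyz":
        traj = read_xyz(path, box=box, dt=dt)
        if topology is not None:
            traj = Trajectory(topology, traj.frames)
        return traj
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt in ("gro", "pdb"):
            u = mda.Universe(str(path))
            top = topology or _topology_from_universe(u)
        elif fmt in ("xtc", "dcd"):
            if topology is None:
                raise ValueError(f"{fmt} input requires a topology sidecar")
            u = mda.Universe.empty(topology.n_atoms, trajectory=True)
            u.load_new(str(path))
            top = topology
        else:
            raise ValueError(f"unsupported trajectory format {fmt!r}")
        frames = []
        last_t = -np.inf
        for k, ts in enumerate(u.trajectory):
            try:
                box_nm = _check_orthorhombic(ts.dimensions)
            except ParseError:
                if box is None:
                    raise ParseError(f"{path}: frame {k} has no box and none supplied")
                box_nm = np.asarray(box, dtype=float)
            t = float(ts.time) if ts.time is not None else k * dt
            if t <= last_t:
                t = last_t + dt
            last_t = t
            frames.append(Frame(time=t, coords=ts.positions * A_TO_NM, box=box_nm))
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# XYZ dialect
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, box: tuple[float, float, float] | None = None,
             dt: float = 1.0) -> Trajectory:
    """Read a (multi-frame) XYZ file; coordinates in Angstrom -> nm.

    The comment line may carry ``box=Lx,Ly,Lz`` (nm) and ``time=T`` (ps)
    tokens; otherwise ``box`` must be supplied and times run 0, dt, 2*dt...
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    names: list[str] | None = None
    pos = 0
    k = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError:
            raise ParseError(f"{path}:{pos + 1}: expected atom count, got "
                             f"{lines[pos]!r}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        meta = {}
        for tok in comment.replace(",", " ").split():
            if "=" in tok:
                key, _, val = tok.partition("=")
                meta.setdefault(key, []).append(val)
        if "box" in meta:
            vals = [float(v) for v in meta["box"]]
            frame_box = np.asarray(vals[:3] if len(vals) >= 3 else vals * 3)
        elif box is not None:
            frame_box = np.asarray(box, dtype=float)
        else:
            raise ParseError(f"{path}:{pos + 2}: no box= in comment and none supplied")
        t = float(meta["time"][0]) if "time" in meta else k * dt
        atoms = lines[pos + 2: pos + 2 + n]
        if len(atoms) < n:
            raise ParseError(f"{path}:{pos + 1}: frame declares {n} atoms, "
                             f"file ends early")
        frame_names: list[str] = []
        coords = np.empty((n, 3))
        for i, line in enumerate(atoms):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{pos + 3 + i}: malformed atom record "
                                 f"{line!r}")
            frame_names.append(parts[0])
            try:
                coords[i] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise ParseError(f"{path}:{pos + 3 + i}: non-numeric coordinate in "
                                 f"{line!r}")
        if names is None:
            names = frame_names
        frames.append(Frame(time=t, coords=coords * A_TO_NM, box=frame_box))
        pos += 2 + n
        k += 1
    if not frames:
        raise ParseError(f"{path}: empty XYZ file")
    elements = [guess_element(nm) for nm in names]
    masses = np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements])
    top = Topology(names=names, elements=elements, masses=masses,
                   charges=np.zeros(len(names)),
                   molecule_ids=np.zeros(len(names), dtype=int),
                   roles=["other"] * len(names))
    return Trajectory(top, frames)


def write_xyz(path: str | Path, trajectory: Trajectory) -> None:
    """Write a multi-frame XYZ file (Angstrom) with box=/time= comment tokens."""
    top = trajectory.topology
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            bx = ",".join(f"{v:.6f}" for v in fr.box)
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"time={fr.time:.6f} box={bx}\n")
            for name, (x, y, z) in zip(top.names, fr.coords / A_TO_NM):
                fh.write(f"{name:<6s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def write_gro(path: str | Path, topology: Topology, frame: Frame,
              title: str = "micellekit") -> None:
    """Write a single-frame GRO file (nm, fixed columns)."""
    with open(path, "w") as fh:
        fh.write(f"{title}\n{topology.n_atoms:5d}\n")
        for i in range(topology.n_atoms):
            res = int(topology.molecule_ids[i]) % 100000
            x, y, z = frame.coords[i]
            fh.write(f"{res:5d}{'MOL':<5s}{topology.names[i][:5]:>5s}"
                     f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# Topology sidecar CSV
# ---------------------------------------------------------------------------

def read_topology_csv(path: str | Path) -> Topology:
    """Read the topology sidecar CSV (see module docstring for columns)."""
    df = pd.read_csv(path, dtype={"bonds": str})
    required = ["atom_id", "name", "element", "mass", "charge",
                "molecule_id", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df.sort_values("atom_id").reset_index(drop=True)
    if not np.array_equal(df["atom_id"].to_numpy(), np.arange(len(df))):
        raise ParseError(f"{path}: atom_id must be 0..N-1 without gaps")
    bonds: list[tuple[int, int]] = []
    if "bonds" in df.columns:
        for i, cell in enumerate(df["bonds"]):
            if isinstance(cell, str) and cell.strip():
                for part in cell.split(";"):
                    j = int(part)
                    if j > i:
                        bonds.append((i, j))
                    elif j < i:
                        bonds.append((j, i))
    bonds = sorted(set(bonds))
    return Topology(names=[str(n) for n in df["name"]],
                    elements=[str(e) for e in df["element"]],
                    masses=df["mass"].to_numpy(float),
                    charges=df["charge"].to_numpy(float),
                    molecule_ids=df["molecule_id"].to_numpy(int),
                    roles=[str(r) for r in df["role"]],
                    bonds=bonds)


def write_topology_csv(path: str | Path, topology: Topology) -> None:
    adj = topology.adjacency()
    df = pd.DataFrame({
        "atom_id": np.arange(topology.n_atoms),
        "name": topology.names,
        "element": topology.elements,
        "mass": topology.masses,
        "charge": topology.charges,
        "molecule_id": topology.molecule_ids,
        "role": topology.roles,
        "bonds": [";".join(str(j) for j in sorted(adj[i]))
                  for i in range(topology.n_atoms)],
    })
    df.to_csv(path, index=False)
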