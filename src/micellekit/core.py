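"""Core data model for micelle trajectory analysis.

Internal units throughout the package: nm (length), ps (time), amu (mass),
elementary charge (charge), degrees (angles).  These match the GRO file
conventions and the units the analyses report.

Only orthorhombic boxes are supported; triclinic input raises
:class:`TriclinicBoxError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

ROLES = ("cage", "chain", "head", "water", "ion", "embedded", "other")


class TriclinicBoxError(ValueError):
    """Raised when a non-orthorhombic box is encountered."""


class SelectionError(ValueError):
    """Raised for empty or out-of-range atom selections."""


@dataclass
class Topology:
    """Static atom table: names, elements, masses, charges, molecules, roles, bonds.

    Parameters
    ----------
    names, elements : sequences of str, one per atom
    masses : amu, all > 0
    charges : elementary charge units
    molecule_ids : integer molecule membership, one per atom
    roles : per-atom role label, one of ``ROLES``
    bonds : iterable of (i, j) atom-index pairs
    """

    names: list[str]
    elements: list[str]
    masses: np.ndarray
    charges: np.ndarray
    molecule_ids: np.ndarray
    roles: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        n = len(self.names)
        for attr in ("elements", "roles"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length != number of atoms ({n})")
        for arr, label in ((self.masses, "masses"), (self.charges, "charges"),
                           (self.molecule_ids, "molecule_ids")):
            if arr.shape != (n,):
                raise ValueError(f"{label} shape {arr.shape} != ({n},)")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be > 0")
        bad = [r for r in self.roles if r not in ROLES]
        if bad:
            raise ValueError(f"unknown roles: {sorted(set(bad))}")
        self.bonds = [(int(i), int(j)) for i, j in self.bonds]
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references missing atom")
        self._adjacency: dict[int, list[int]] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def molecules(self) -> dict[int, np.ndarray]:
        """Map molecule_id -> sorted array of member atom indices."""
        out: dict[int, list[int]] = {}
        for i, mol in enumerate(self.molecule_ids):
            out.setdefault(int(mol), []).append(i)
        return {m: np.asarray(ix, dtype=int) for m, ix in out.items()}

    def adjacency(self) -> dict[int, list[int]]:
        if self._adjacency is None:
            adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
            for i, j in self.bonds:
                adj[i].append(j)
                adj[j].append(i)
            self._adjacency = adj
        return self._adjacency

    def bonded_hydrogens(self, i: int) -> list[int]:
        """Indices of hydrogen atoms bonded to atom *i*."""
        return [j for j in self.adjacency()[i] if self.elements[j] == "H"]

    def select(self, *, role: str | Sequence[str] | None = None,
               element: str | Sequence[str] | None = None,
               name: str | Sequence[str] | None = None,
               molecule_id: int | Sequence[int] | None = None,
               indices: Sequence[int] | None = None,
               label: str = "") -> "Selection":
        """Resolve a conjunctive selection over the atom table."""
        mask = np.ones(self.n_atoms, dtype=bool)

        def as_set(v):
            return {v} if isinstance(v, (str, int)) else set(v)

        if role is not None:
            want = as_set(role)
            mask &= np.array([r in want for r in self.roles])
        if element is not None:
            want = as_set(element)
            mask &= np.array([e in want for e in self.elements])
        if name is not None:
            want = as_set(name)
            mask &= np.array([nm in want for nm in self.names])
        if molecule_id is not None:
            want = as_set(molecule_id)
            mask &= np.array([int(m) in want for m in self.molecule_ids])
        if indices is not None:
            m2 = np.zeros(self.n_atoms, dtype=bool)
            m2[np.asarray(indices, dtype=int)] = True
            mask &= m2
        return Selection(tuple(int(i) for i in np.nonzero(mask)[0]), label=label)


@dataclass
class Frame:
    """One trajectory frame: time (ps), coords (N,3) in nm, orthorhombic box (nm)."""

    time: float
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be > 0, got {self.box}")


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise ValueError(
                    f"frame {k} has {fr.coords.shape[0]} atoms, topology has {n}")
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]

    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])


@dataclass(frozen=True)
class Selection:
    """An ordered, unique set of 0-based atom indices with a provenance label."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError(f"duplicate indices in selection {self.label!r}")

    def __len__(self) -> int:
        return len(self.indices)

    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def validate(self, topology: Topology) -> None:
        if not self.indices:
            raise SelectionError(f"selection {self.label!r} is empty")
        if max(self.indices) >= topology.n_atoms or min(self.indices) < 0:
            raise SelectionError(f"selection {self.label!r} out of topology range")


@dataclass
class MicelleAssignment:
    """Mapping of surfactant molecules into one micelle.

    ``cages``/``chains``/``heads`` map molecule_id -> Selection; ``embedded``
    is optional per molecule.  The studied aggregates are tetramers, but the
    container does not enforce an aggregation number (the beta-angle
    classifier does, because that procedure is tetramer-specific).
    """

    molecule_ids: list[int]
    cages: dict[int, Selection]
    chains: dict[int, Selection]
    heads: dict[int, Selection]
    embedded: dict[int, Selection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.molecule_ids:
            groups = [set(self.cages[m].indices), set(self.chains[m].indices),
                      set(self.heads[m].indices)]
            for a in range(3):
                for b in range(a + 1, 3):
                    if groups[a] & groups[b]:
                        raise ValueError(
                            f"cage/chain/head selections overlap in molecule {m}")

    def surfactant_selection(self, label: str = "surfactant") -> Selection:
        """All cage+chain+head atoms across the micelle, in index order."""
        ix: set[int] = set()
        for m in self.molecule_ids:
            ix |= set(self.cages[m].indices) | set(self.chains[m].indices) \
                | set(self.heads[m].indices)
        return Selection(tuple(sorted(ix)), label=label)

    def molecule_selection(self, m: int, with_embedded: bool = False) -> Selection:
        ix = set(self.cages[m].indices) | set(self.chains[m].indices) \
            | set(self.heads[m].indices)
        if with_embedded and m in self.embedded:
            ix |= set(self.embedded[m].indices)
        return Selection(tuple(sorted(ix)), label=f"molecule {m}")


def assignment_from_roles(topology: Topology) -> MicelleAssignment:
    """Build a MicelleAssignment from role labels.

    Surfactant molecules are those containing at least one ``cage`` atom;
    ``embedded`` atoms inside such a molecule are attached to it.
    """
    cages: dict[int, Selection] = {}
    chains: dict[int, Selection] = {}
    heads: dict[int, Selection] = {}
    embedded: dict[int, Selection] = {}
    for m, ix in topology.molecules().items():
        roles = [topology.roles[i] for i in ix]
        if "cage" not in roles:
            continue
        by_role: dict[str, list[int]] = {}
        for i, r in zip(ix, roles):
            by_role.setdefault(r, []).append(int(i))
        cages[m] = Selection(tuple(by_role.get("cage", [])), f"cage:{m}")
        chains[m] = Selection(tuple(by_role.get("chain", [])), f"chain:{m}")
        heads[m] = Selection(tuple(by_role.get("head", [])), f"head:{m}")
        if by_role.get("embedded"):
            embedded[m] = Selection(tuple(by_role["embedded"]), f"embedded:{m}")
    mols = sorted(cages)
    if not mols:
        raise SelectionError("no molecules with cage atoms found")
    return MicelleAssignment(mols, cages, chains, heads, embedded)


# ---------------------------------------------------------------------------
# Periodic boundary utilities (orthorhombic)
# ---------------------------------------------------------------------------

def minimum_image_vector(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shortest periodic-image displacement b - a (broadcasting over leading axes)."""
    box = np.asarray(box, dtype=float)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)

def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shortest periodic-image distance between points a and b (nm)."""
    d = minimum_image_vector(a, b, box)
    return np.linalg.norm(d, axis=-1)


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box)."""
    return np.mod(coords, np.asarray(box, dtype=float))


def make_whole(topology: Topology, frame: Frame) -> np.ndarray:
    """Unwrap every molecule across periodic boundaries by bond-graph traversal.

    Each bonded neighbour is placed at its minimum image relative to the atom
    it was reached from; atoms without bonds are left untouched.  Returns a
    new (N,3) coordinate array.
    """
    coords = frame.coords.copy()
    box = frame.box
    adj = topology.adjacency()
    seen = np.zeros(topology.n_atoms, dtype=bool)
    for start in range(topology.n_atoms):
        if seen[start]:
            continue
        seen[start] = True
        stack = [start]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if seen[j]:
                    continue
                seen[j] = True
                coords[j] = coords[i] + minimum_image_vector(coords[i], coords[j], box)
                stack.append(j)
    return coords


def cluster_molecules(topology: Topology, coords: np.ndarray, box: np.ndarray,
                      molecule_ids: Iterable[int] | None = None,
                      reference: int | None = None) -> np.ndarray:
    """Re-center whole molecules so a cluster is contiguous across the boundary.

    Each molecule is translated by a whole number of box lengths so that its
    center of mass sits at the minimum image relative to the reference
    molecule (default: the heaviest one).  ``coords`` must already be whole
    per molecule (see :func:`make_whole`).
    """
    coords = coords.copy()
    mols = topology.molecules()
    ids = list(mols) if molecule_ids is None else list(molecule_ids)
    masses = topology.masses
    if reference is None:
        reference = max(ids, key=lambda m: masses[mols[m]].sum())
    ref_ix = mols[reference]
    ref_com = np.average(coords[ref_ix], weights=masses[ref_ix], axis=0)
    for m in ids:
        if m == reference:
            continue
        ix = mols[m]
        com = np.average(coords[ix], weights=masses[ix], axis=0)
        shift = minimum_image_vector(ref_com, com, box) - (com - ref_com)
        coords[ix] += shift
    return coords


def whole_coords(topology: Topology, frame: Frame,
                 cluster: bool = True,
                 molecule_ids: Iterable[int] | None = None) -> np.ndarray:
    """Convenience: unwrap molecules, then re-center the cluster."""
    coords = make_whole(topology, frame)
    if cluster:
        coords = cluster_molecules(topology, coords, frame.box, molecule_ids)
    return coords


def center_of_mass(sel: Selection, coords_or_frame, topology: Topology) -> np.ndarray:
    """Mass-weighted centre of the selection (nm).

    The selection is assumed to be whole (unwrapped) already; see
    :func:`make_whole` / :func:`whole_coords`.
    """
    sel.validate(topology)
    coords = coords_or_frame.coords if isinstance(coords_or_frame, Frame) \
        else np.asarray(coords_or_frame)
    ix = sel.array()
    return np.average(coords[ix], weights=topology.masses[ix], axis=0)


def trailing_window(n_frames: int, fraction: float = 0.1) -> slice:
    """Frame slice of the trailing analysis window (default final 10%)."""
    if not 0 < fraction <= 1:
        raise ValueError("window fraction must be in (0, 1]")
    start = n_frames - max(1, int(round(fraction * n_frames)))
    return slice(max(0, start), n_frames)


@dataclass
class SeriesStats:
    """A per-frame series with mean +/- sd over the trailing analysis window."""

    series: np.ndarray
    window: slice
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        win = self.series[self.window]
        self.mean = float(np.mean(win))
        self.sd = float(np.std(win))
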