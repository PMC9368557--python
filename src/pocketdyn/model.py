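"""Core in-memory data model: atoms, topology, trajectory, selections.

All coordinates are stored in nanometres and all times in picoseconds,
regardless of the units of the file they were read from. Atom indices are
0-based and contiguous; residue indices follow the author numbering of the
input structure (e.g. I35 keeps index 35).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class AtomRecord:
    """One atom with topology and nonbonded parameters.

    ``partial_charge`` (elementary charge), ``lj_sigma`` (nm) and
    ``lj_epsilon`` (kJ/mol) come from an external parameter table; atoms
    missing from the table get zeros and ``has_params=False``.
    """

    index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    mass: float = 0.0
    partial_charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    has_params: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def __post_init__(self) -> None:
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise InputError(
                f"atom {self.name}: Lennard-Jones parameters must be >= 0"
            )


@dataclass(frozen=True)
class Residue:
    name: str
    index: int
    chain_id: str
    first_atom: int
    last_atom: int  # exclusive

    @property
    def atom_indices(self) -> np.ndarray:
        return np.arange(self.first_atom, self.last_atom)


@dataclass(frozen=True)
class Selection:
    """A named, sorted, duplicate-free set of atom indices."""

    label: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=np.intp)
        if idx.ndim != 1:
            raise InputError("selection indices must be a flat array")
        if idx.size and (np.any(np.diff(idx) <= 0)):
            idx = np.unique(idx)
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return int(self.atom_indices.size)

    def union(self, other: "Selection", label: str | None = None) -> "Selection":
        return Selection(
            label or f"({self.label} or {other.label})",
            np.union1d(self.atom_indices, other.atom_indices),
        )

    def intersection(self, other: "Selection", label: str | None = None) -> "Selection":
        return Selection(
            label or f"({self.label} and {other.label})",
            np.intersect1d(self.atom_indices, other.atom_indices),
        )

    def complement(self, n_atoms: int, label: str | None = None) -> "Selection":
        mask = np.ones(n_atoms, dtype=bool)
        mask[self.atom_indices] = False
        return Selection(label or f"(not {self.label})", np.nonzero(mask)[0])


@dataclass
class Topology:
    """Ordered atoms grouped into residues, plus the ligand selection.

    ``bonds`` is optional connectivity (pairs of atom indices); nothing in
    the analysis stack requires it, but readers preserve CONECT records
    when present.
    """

    atoms: list[AtomRecord]
    residues: list[Residue] = field(default_factory=list)
    ligand_selection: Selection | None = None
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise InputError(
                    f"atom indices must be contiguous from 0; got {a.index} at {i}"
                )
        if not self.residues:
            self.residues = _group_residues(self.atoms)
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise InputError(f"bond ({i},{j}) references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue(self, residue_index: int, chain_id: str | None = None) -> Residue:
        for r in self.residues:
            if r.index == residue_index and (chain_id is None or r.chain_id == chain_id):
                return r
        raise InputError(f"no residue with index {residue_index}")

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if a.is_heavy], dtype=np.intp
        )

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        r = self.residue(residue_index)
        for i in range(r.first_atom, r.last_atom):
            if self.atoms[i].name == atom_name:
                return i
        raise InputError(
            f"residue {residue_index} has no atom named {atom_name!r}"
        )

    def protein_indices(self) -> np.ndarray:
        """All atoms outside the ligand selection."""
        if self.ligand_selection is None or len(self.ligand_selection) == 0:
            return np.arange(self.n_atoms, dtype=np.intp)
        mask = np.ones(self.n_atoms, dtype=bool)
        mask[self.ligand_selection.atom_indices] = False
        return np.nonzero(mask)[0]


def _group_residues(atoms: list[AtomRecord]) -> list[Residue]:
    residues: list[Residue] = []
    start = 0
    for i in range(1, len(atoms) + 1):
        if i == len(atoms) or (
            (atoms[i].residue_index, atoms[i].chain_id, atoms[i].residue_name)
            != (atoms[start].residue_index, atoms[start].chain_id, atoms[start].residue_name)
        ):
            a = atoms[start]
            residues.append(Residue(a.residue_name, a.residue_index, a.chain_id, start, i))
            start = i
    return residues


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates in nm with per-frame times in ps.

    ``synthetic_times`` flags a 0,1,2,... time axis fabricated because the
    source format carried no time information.
    """

    coordinates: np.ndarray
    times: np.ndarray | None = None
    box: np.ndarray | None = None
    synthetic_times: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=np.float64)
        if c.ndim != 3 or c.shape[2] != 3:
            raise InputError("coordinates must have shape (frames, atoms, 3)")
        if c.shape[0] < 1:
            raise InputError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(c)):
            raise InputError("coordinates contain non-finite values")
        self.coordinates = c
        if self.times is None:
            self.times = np.arange(c.shape[0], dtype=np.float64)
            self.synthetic_times = True
        else:
            t = np.asarray(self.times, dtype=np.float64)
            if t.shape != (c.shape[0],):
                raise InputError("times length must equal frame count")
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise InputError("times must be strictly increasing")
            self.times = t
        if self.box is not None:
            b = np.asarray(self.box, dtype=np.float64)
            if b.shape != (c.shape[0], 3):
                raise InputError("box must have shape (frames, 3)")
            self.box = b

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[1])

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def subset(self, frame_indices: np.ndarray) -> "Trajectory":
        """New trajectory restricted to the given frames (order preserved)."""
        idx = np.asarray(frame_indices)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return Trajectory(
            self.coordinates[idx],
            self.times[idx],
            None if self.box is None else self.box[idx],
            synthetic_times=self.synthetic_times,
        )


def concat(a: Trajectory, b: Trajectory) -> Trajectory:
    """Concatenate two trajectories of the same topology; times are re-laid
    on a synthetic 0,1,2,... axis because the joined time axes need not be
    monotone."""
    if a.n_atoms != b.n_atoms:
        raise InputError("cannot concatenate trajectories with different atom counts")
    coords = np.concatenate([a.coordinates, b.coordinates], axis=0)
    return Trajectory(coords)
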