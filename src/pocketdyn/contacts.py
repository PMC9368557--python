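"""Heavy-atom contact detection and per-state contact-probability maps.

A ligand group and a protein residue are in contact in a frame when the
minimum distance over all heavy-atom cross pairs is at or below the cutoff
(default 0.45 nm, a common heavy-atom convention; the value is recorded on
every map). Probabilities are exact frame counts over the frames selected
by a mask, so per-state maps follow directly from state-label masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError
from .model import Selection, Topology, Trajectory

DEFAULT_CONTACT_CUTOFF = 0.45  # nm


@dataclass(frozen=True)
class GroupDefinition:
    """A named heavy-atom group of the ligand."""

    name: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=np.intp)
        if idx.size == 0:
            raise InputError(f"group {self.name}: no atoms")
        object.__setattr__(self, "atom_indices", idx)

    @classmethod
    def from_selection(cls, topology: Topology, sel: Selection) -> "GroupDefinition":
        heavy = [i for i in sel.atom_indices if topology.atoms[i].is_heavy]
        return cls(sel.label, np.asarray(heavy))


@dataclass
class ContactMap:
    """Groups x residues contact probabilities on a fixed frame set."""

    groups: list[str]
    residues: list[tuple[str, int]]  # (residue_name, residue_index)
    values: np.ndarray  # (G, R) in [0, 1]
    n_frames: int
    cutoff: float

    def probability(self, group: str, residue_index: int) -> float:
        g = self.groups.index(group)
        r = next(i for i, (_, ri) in enumerate(self.residues) if ri == residue_index)
        return float(self.values[g, r])


def contact_frame(
    frame: np.ndarray,
    group: GroupDefinition,
    residue: Selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> bool:
    """True iff the closest group/residue heavy-atom pair is within cutoff."""
    if len(residue) == 0:
        raise InputError("residue selection is empty")
    return bool(
        cdist(frame[group.atom_indices], frame[residue.atom_indices]).min() <= cutoff
    )


def residue_heavy_selections(
    topology: Topology,
    residue_indices: list[int] | None = None,
    side_chain_only: bool = False,
) -> list[tuple[tuple[str, int], Selection]]:
    """Heavy-atom selection per protein residue (optionally side chain only,
    i.e. excluding N/CA/C/O backbone atoms)."""
    backbone = {"N", "CA", "C", "O"}
    ligand = set()
    if topology.ligand_selection is not None:
        ligand = set(topology.ligand_selection.atom_indices.tolist())
    out = []
    for res in topology.residues:
        if residue_indices is not None and res.index not in residue_indices:
            continue
        idx = [
            i
            for i in range(res.first_atom, res.last_atom)
            if i not in ligand
            and topology.atoms[i].is_heavy
            and not (side_chain_only and topology.atoms[i].name in backbone)
        ]
        if idx:
            out.append(((res.name, res.index), Selection(f"{res.name}{res.index}", np.asarray(idx))))
    return out


def contact_probability(
    trajectory: Trajectory,
    frame_mask: np.ndarray,
    groups: list[GroupDefinition],
    residues: list[tuple[tuple[str, int], Selection]],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactMap:
    """Fraction of masked frames in which each (group, residue) is in contact."""
    mask = np.asarray(frame_mask, dtype=bool)
    if mask.shape != (trajectory.n_frames,):
        raise InputError("frame mask length must equal the frame count")
    frames = np.nonzero(mask)[0]
    if frames.size == 0:
        raise InputError("frame mask selects no frames")
    values = np.zeros((len(groups), len(residues)))
    for gi, g in enumerate(groups):
        for ri, (_, rsel) in enumerate(residues):
            hits = 0
            for f in frames:
                xg = trajectory.coordinates[f, g.atom_indices]
                xr = trajectory.coordinates[f, rsel.atom_indices]
                if cdist(xg, xr).min() <= cutoff:
                    hits += 1
            values[gi, ri] = hits / frames.size
    return ContactMap(
        [g.name for g in groups], [key for key, _ in residues], values, int(frames.size), cutoff
    )


def top_contacts(cmap: ContactMap, n: int) -> list[tuple[str, tuple[str, int], float]]:
    """The n most probable contacts, descending; ties break by residue
    index then group name."""
    if n < 1:
        raise InputError("n must be >= 1")
    entries = [
        (g, cmap.residues[ri], float(cmap.values[gi, ri]))
        for gi, g in enumerate(cmap.groups)
        for ri in range(len(cmap.residues))
    ]
    entries.sort(key=lambda e: (-e[2], e[1][1], e[0]))
    return entries[:n]
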