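"""Seeded generators of toy complexes and trajectories with planted structure.

Three kinds of ground truth can be planted:

* **Binding states** — a toy pocket/ligand complex whose five named
  hydrogen-bond pair distances switch between templates for state 0
  (carboxylate bonded to the I33/G34/I35 backbone), state 1 (ketone bonded
  to I37), state 2 (carboxylate bonded to I37), an unassigned pose (all
  pairs broken but the ligand still in the pocket) and a dissociated pose
  (ligand far outside). Gaussian jitter of a chosen scale is added to every
  coordinate.
* **Displacement correlations** — trajectories whose Calpha-displacement
  cross-correlation matrix converges to a prescribed target.
* **Community structure** — stochastic-block-model graphs.

The pocket geometry is fabricated: only residue names, ligand group names
and interaction roles mimic a real PDZ pocket, which is all the analysis
stages read. Templates are fixed constants; every generator is a pure
function of its arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .model import AtomRecord, Selection, Topology, Trajectory

STATE_LABELS = ("state0", "state1", "state2", "unassigned", "dissociated")

#: ligand heavy-atom groups and their H-bond-capable atoms
LIGAND_GROUPS = (
    "carboxyl",
    "ketone",
    "cyclopentyl",
    "bromophenyl",
    "piperidine",
    "pyrrolidine",
    "tertbutyl",
)

# Protein residues: (name, author resid, anchor of backbone N, nm).
_RESIDUES = [
    ("LEU", 32, (-0.35, -0.25, 0.05)),
    ("ILE", 33, (0.00, 0.00, 0.00)),
    ("GLY", 34, (0.35, 0.00, 0.00)),
    ("ILE", 35, (0.175, 0.30, 0.00)),
    ("ILE", 37, (1.40, 0.15, 0.00)),
    ("PHE", 53, (0.00, -0.75, 0.35)),
    ("ALA", 58, (0.30, -1.05, 0.60)),
    ("LYS", 83, (1.15, -0.35, 0.10)),
    ("VAL", 84, (1.40, -0.55, 0.25)),
    ("VAL", 86, (1.20, 0.45, -0.10)),
    ("ALA", 87, (1.10, 0.60, 0.00)),
    ("ILE", 90, (1.30, 0.85, 0.15)),
]

#: secondary-structure element per residue of the toy pocket
SS_MAP = {
    32: "betaB", 33: "betaB", 34: "betaB", 35: "betaB", 37: "betaB",
    53: "betaC",
    58: "alphaA",
    83: "alphaB", 84: "alphaB", 86: "alphaB", 87: "alphaB", 90: "alphaB",
}

# backbone offsets from the residue anchor (side chains sit below the
# ligand plane so pocket contacts are dominated by the intended groups)
_BACKBONE = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("CA", "C", (0.08, 0.06, -0.05)),
    ("C", "C", (0.16, 0.01, -0.09)),
    ("O", "O", (0.20, 0.09, -0.12)),
]
_CB = ("CB", "C", (0.10, 0.14, -0.10))
_LYS_SIDE = [
    ("CB", "C", (0.03, 0.07, 0.08)),
    ("CG", "C", (0.06, 0.14, 0.15)),
    ("CD", "C", (0.08, 0.21, 0.20)),
    ("CE", "C", (0.09, 0.27, 0.24)),
    ("NZ", "N", (0.10, 0.30, 0.25)),
]


def _ring(n: int, radius: float, z: float = 0.0) -> list[tuple[float, float, float]]:
    ang = 2 * np.pi * np.arange(n) / n
    return [
        (radius * float(np.cos(a)), radius * float(np.sin(a)), z + 0.01 * (i % 2))
        for i, a in enumerate(ang)
    ]


def _ligand_atoms() -> list[tuple[str, str, str, tuple[float, float, float]]]:
    """(group, atom name, element, offset from group anchor)."""
    atoms: list[tuple[str, str, str, tuple[float, float, float]]] = []
    atoms += [
        ("carboxyl", "C11", "C", (0.00, -0.02, 0.09)),
        ("carboxyl", "O11", "O", (0.06, 0.00, 0.00)),
        ("carboxyl", "O12", "O", (-0.06, 0.02, 0.02)),
        ("ketone", "C21", "C", (0.05, -0.04, 0.10)),
        ("ketone", "O21", "O", (0.00, 0.00, 0.00)),
    ]
    for i, off in enumerate(_ring(5, 0.07)):
        atoms.append(("cyclopentyl", f"C3{i + 1}", "C", off))
    for i, off in enumerate(_ring(6, 0.08)):
        atoms.append(("bromophenyl", f"C4{i + 1}", "C", off))
    atoms.append(("bromophenyl", "BR1", "Br", (0.18, 0.00, 0.02)))
    atoms.append(("piperidine", "N51", "N", (0.08, 0.00, 0.00)))
    for i, off in enumerate(_ring(5, 0.08, 0.02)):
        atoms.append(("piperidine", f"C5{i + 2}", "C", off))
    atoms.append(("pyrrolidine", "N61", "N", (0.07, 0.00, 0.00)))
    for i, off in enumerate(_ring(4, 0.07, 0.02)):
        atoms.append(("pyrrolidine", f"C6{i + 2}", "C", off))
    atoms.append(("tertbutyl", "C71", "C", (0.00, 0.00, 0.00)))
    for i, off in enumerate(_ring(3, 0.08, 0.05)):
        atoms.append(("tertbutyl", f"C7{i + 2}", "C", off))
    return atoms


# Per-state anchor of each ligand group (nm). Distances between the
# H-bond-capable atoms (carboxylate O11/O12, ketone O21) and the backbone
# N of I33/G34/I35/I37 encode the planted hydrogen-bond pattern.
_STATE_ANCHORS: dict[str, dict[str, tuple[float, float, float]]] = {
    "state0": {
        "carboxyl": (0.175, 0.10, 0.22),
        "ketone": (0.45, 0.50, 0.30),
        "cyclopentyl": (0.25, 0.58, 0.20),
        "bromophenyl": (0.88, -0.30, 0.50),
        "piperidine": (0.60, 0.20, 0.35),
        "pyrrolidine": (0.40, 0.05, 0.45),
        "tertbutyl": (0.70, 0.60, 0.40),
    },
    "state1": {
        "carboxyl": (0.60, 0.95, 0.35),
        "ketone": (1.40, 0.15, 0.28),
        "cyclopentyl": (0.55, 0.65, 0.55),
        "bromophenyl": (1.08, 0.50, 0.22),
        "piperidine": (0.90, -0.25, 0.45),
        "pyrrolidine": (1.30, 0.40, 0.30),
        "tertbutyl": (0.32, 0.48, 0.25),
    },
    "state2": {
        "carboxyl": (1.40, 0.15, 0.30),
        "ketone": (0.55, 0.80, 0.30),
        "cyclopentyl": (0.30, 0.62, 0.22),
        "bromophenyl": (1.08, 0.50, 0.28),
        "piperidine": (0.70, 0.30, 0.40),
        "pyrrolidine": (0.90, 0.10, 0.40),
        "tertbutyl": (0.60, 0.55, 0.50),
    },
    "unassigned": {
        "carboxyl": (0.80, 0.80, 0.50),
        "ketone": (1.30, 0.30, 0.60),
        "cyclopentyl": (0.50, 0.70, 0.60),
        "bromophenyl": (1.10, 0.00, 0.60),
        "piperidine": (0.80, 0.30, 0.65),
        "pyrrolidine": (0.95, 0.50, 0.60),
        "tertbutyl": (0.65, 0.50, 0.70),
    },
}
_DISSOCIATION_SHIFT = np.array([3.0, 3.0, 3.0])

# nonbonded parameters (mass amu, charge e, sigma nm, epsilon kJ/mol);
# the ammonium charge sits entirely on NZ because the toy model has no
# hydrogens, and the carboxylate charge is split over C11/O11/O12
_PROTEIN_PARAMS = {
    "N": (14.007, -0.47, 0.325, 0.71),
    "CA": (12.011, 0.07, 0.400, 0.23),
    "C": (12.011, 0.51, 0.356, 0.46),
    "O": (15.999, -0.51, 0.302, 0.50),
    "CB": (12.011, 0.00, 0.400, 0.23),
    "CG": (12.011, 0.00, 0.400, 0.23),
    "CD": (12.011, 0.00, 0.400, 0.23),
    "CE": (12.011, 0.21, 0.400, 0.23),
    "NZ": (14.007, 1.00, 0.325, 0.71),
}
_LIGAND_ELEMENT_PARAMS = {
    "C": (12.011, 0.00, 0.360, 0.29),
    "O": (15.999, -0.51, 0.300, 0.61),
    "N": (14.007, -0.30, 0.325, 0.71),
    "Br": (79.904, -0.10, 0.390, 1.00),
}
_LIGAND_CHARGES = {"O11": -0.76, "O12": -0.76, "C11": 0.62, "O21": -0.51, "C21": 0.51}


@dataclass
class ToyComplex:
    """A fabricated pocket-ligand system plus its bookkeeping."""

    topology: Topology
    reference: Trajectory  # one frame, the state-0 template
    groups: dict[str, Selection]
    param_table: pd.DataFrame
    ss_map: dict[int, str]

    @property
    def ligand(self) -> Selection:
        return self.topology.ligand_selection


def gen_toy_complex(seed: int = 0) -> ToyComplex:
    """Build the toy pocket-ligand complex (deterministic; seed kept for
    interface symmetry with the other generators)."""
    del seed
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    rows = []
    idx = 0
    for resname, resid, anchor in _RESIDUES:
        entries = list(_BACKBONE)
        if resname == "LYS":
            entries += _LYS_SIDE
        elif resname != "GLY":
            entries.append(_CB)
        for name, element, off in entries:
            mass, q, sig, eps = _PROTEIN_PARAMS[name]
            atoms.append(
                AtomRecord(idx, name, element, resname, resid, "A",
                           mass, q, sig, eps, has_params=True)
            )
            coords.append(tuple(np.add(anchor, off)))
            rows.append((resname, name, mass, q, sig, eps))
            idx += 1

    groups_idx: dict[str, list[int]] = {g: [] for g in LIGAND_GROUPS}
    lig_atoms = _ligand_atoms()
    anchors0 = _STATE_ANCHORS["state0"]
    for group, name, element, off in lig_atoms:
        mass, q, sig, eps = _LIGAND_ELEMENT_PARAMS[element]
        q = _LIGAND_CHARGES.get(name, q if element != "O" else 0.0)
        if element == "N":
            q = _LIGAND_CHARGES.get(name, -0.30)
        atoms.append(
            AtomRecord(idx, name, element, "BIO", 124, "L",
                       mass, q, sig, eps, has_params=True)
        )
        coords.append(tuple(np.add(anchors0[group], off)))
        rows.append(("BIO", name, mass, q, sig, eps))
        groups_idx[group].append(idx)
        idx += 1

    topo = Topology(atoms=atoms)
    n_prot = idx - len(lig_atoms)
    topo.ligand_selection = Selection("ligand", np.arange(n_prot, idx))
    groups = {g: Selection(g, np.asarray(v)) for g, v in groups_idx.items()}
    table = pd.DataFrame(
        rows, columns=["residue_name", "atom_name", "mass", "charge", "sigma", "epsilon"]
    ).drop_duplicates(subset=["residue_name", "atom_name"])
    ref = Trajectory(np.asarray(coords, dtype=np.float64)[None])
    return ToyComplex(topo, ref, groups, table, dict(SS_MAP))


#: H-bond acceptor atom(s) of each bond-forming ligand group
HBOND_GROUP_ATOMS = {"carboxyl": ("O11", "O12"), "ketone": ("O21",)}

#: planted bond pattern per state: which of the five canonical pairs are formed
PLANTED_PATTERN = {
    "state0": {"I33-carboxyl", "G34-carboxyl", "I35-carboxyl"},
    "state1": {"I37-ketone"},
    "state2": {"I37-carboxyl"},
    "unassigned": set(),
    "dissociated": set(),
}
CANONICAL_PAIRS = (
    ("I33-carboxyl", 33, "carboxyl"),
    ("G34-carboxyl", 34, "carboxyl"),
    ("I35-carboxyl", 35, "carboxyl"),
    ("I37-carboxyl", 37, "carboxyl"),
    ("I37-ketone", 37, "ketone"),
)


def _ligand_template(toy: ToyComplex, state: str) -> np.ndarray:
    anchors = _STATE_ANCHORS["state0" if state == "dissociated" else state]
    out = np.empty((len(toy.ligand), 3))
    base = toy.ligand.atom_indices[0]
    for group, name, _el, off in _ligand_atoms():
        i = toy.topology.atom_index(124, name) - base
        out[i] = np.add(anchors[group], off)
    if state == "dissociated":
        out += _DISSOCIATION_SHIFT
    return out


def _check_margin(toy: ToyComplex, margin: float) -> None:
    """Planted templates must clear the 0.5 nm rule by ``margin`` on both
    sides; the fixed geometry supports margins up to ~0.12 nm."""
    for state in ("state0", "state1", "state2", "unassigned"):
        lig = _ligand_template(toy, state)
        base = toy.ligand.atom_indices[0]
        for label, resid, group in CANONICAL_PAIRS:
            n_idx = toy.topology.atom_index(resid, "N")
            n_pos = toy.reference.coordinates[0, n_idx]
            d = min(
                float(np.linalg.norm(lig[toy.topology.atom_index(124, a) - base] - n_pos))
                for a in HBOND_GROUP_ATOMS[group]
            )
            if label in PLANTED_PATTERN[state]:
                if d > 0.5 - margin:
                    raise InputError(
                        f"margin {margin} too large: {state}/{label} template "
                        f"distance {d:.3f} exceeds {0.5 - margin:.3f} nm"
                    )
            elif d < 0.5 + margin:
                raise InputError(
                    f"margin {margin} too large: {state}/{label} template "
                    f"distance {d:.3f} is below {0.5 + margin:.3f} nm"
                )


def gen_state_switching_trajectory(
    toy: ToyComplex,
    schedule: list[str],
    margin: float = 0.1,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> Trajectory:
    """Trajectory whose per-frame ligand pose follows a planted state schedule.

    In each frame the five canonical pair distances respect the planted
    bond pattern of the scheduled state with at least ``margin`` nm of
    clearance around the 0.5 nm break threshold (before jitter);
    dissociated frames put every pair beyond 1.5 nm. Gaussian jitter of
    scale ``noise_sigma`` (nm, per coordinate) is added everywhere.
    """
    if len(schedule) == 0:
        raise InputError("schedule must contain at least one frame")
    bad = set(schedule) - set(STATE_LABELS)
    if bad:
        raise InputError(f"unknown state labels in schedule: {sorted(bad)}")
    if margin <= 0:
        raise InputError("margin must be positive")
    if noise_sigma >= margin / 4:
        raise InputError("noise_sigma must be below margin/4 for separation")
    _check_margin(toy, margin)

    rng = np.random.default_rng(seed)
    n_atoms = toy.topology.n_atoms
    lig_idx = toy.ligand.atom_indices
    protein = toy.reference.coordinates[0].copy()
    templates = {s: _ligand_template(toy, s) for s in set(schedule)}
    coords = np.empty((len(schedule), n_atoms, 3))
    for f, state in enumerate(schedule):
        frame = protein.copy()
        frame[lig_idx] = templates[state]
        coords[f] = frame
    if noise_sigma > 0:
        coords += rng.normal(0.0, noise_sigma, coords.shape)
    return Trajectory(coords, times=np.arange(len(schedule)) * 100.0)


@dataclass(frozen=True)
class PlantedCovariance:
    """Target node-displacement correlation matrix for planting."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.matrix, dtype=np.float64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InputError("correlation matrix must be square")
        if not np.allclose(c, c.T, atol=1e-12):
            raise InputError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise InputError("correlation matrix must have unit diagonal")
        if np.any(np.abs(c) > 1 + 1e-12):
            raise InputError("correlation entries must lie in [-1, 1]")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-8:
            raise InputError(
                f"correlation matrix is not positive semidefinite (min eig {w.min():.3g})"
            )
        object.__setattr__(self, "matrix", c)

    @property
    def n_nodes(self) -> int:
        return int(self.matrix.shape[0])


def gen_correlated_trajectory(
    base: Trajectory | np.ndarray,
    planted: PlantedCovariance,
    n_frames: int,
    displacement_scale: float = 0.05,
    seed: int = 0,
    node_indices: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory whose node-displacement correlation matrix converges to
    the planted target.

    Each Cartesian component of the node displacements is an independent
    zero-mean Gaussian vector with covariance ``planted.matrix`` (isotropic
    construction), so the displacement-vector cross-correlation equals the
    planted correlation exactly in expectation and the sample estimate
    converges at the usual 1/sqrt(n_frames) rate. Atoms outside
    ``node_indices`` keep their base positions.
    """
    if n_frames < 2:
        raise InputError("need at least 2 frames")
    base_xyz = base.coordinates[0] if isinstance(base, Trajectory) else np.asarray(base, float)
    n_atoms = base_xyz.shape[0]
    if node_indices is None:
        node_indices = np.arange(n_atoms)
    node_indices = np.asarray(node_indices, dtype=np.intp)
    k = planted.n_nodes
    if node_indices.size != k:
        raise InputError(
            f"planted matrix has {k} nodes but {node_indices.size} node atoms given"
        )
    w, v = np.linalg.eigh(planted.matrix)
    factor = v * np.sqrt(np.clip(w, 0.0, None))  # C* = factor @ factor.T
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_frames, 3, k)) @ factor.T  # (F, 3, k)
    coords = np.broadcast_to(base_xyz, (n_frames, n_atoms, 3)).copy()
    coords[:, node_indices, :] += displacement_scale * np.swapaxes(latent, 1, 2)
    return Trajectory(coords)


def gen_planted_graph(
    sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[nx.Graph, list[int]]:
    """Stochastic block model with unit edge weights and its planted labels."""
    if any(s < 2 for s in sizes):
        raise InputError("every block must have at least 2 nodes")
    if not (0 <= p_out < p_in <= 1):
        raise InputError("need 0 <= p_out < p_in <= 1")
    b = len(sizes)
    probs = [[p_in if i == j else p_out for j in range(b)] for i in range(b)]
    g = nx.stochastic_block_model(sizes, probs, seed=int(seed))
    graph = nx.Graph()
    graph.add_nodes_from(range(sum(sizes)))
    graph.add_weighted_edges_from((u, v, 1.0) for u, v in g.edges())
    labels = [block for block, s in enumerate(sizes) for _ in range(s)]
    return graph, labels


def write_simulation_bundle(
    outdir: str | Path,
    toy: ToyComplex,
    trajectory: Trajectory,
    schedule: list[str],
) -> dict[str, str]:
    """Write a simulated system: multi-model PDB, parameter TSV and the
    planted-truth JSON. Returns the file map."""
    from .io import write_pdb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "structure": str(outdir / "structure.pdb"),
        "trajectory": str(outdir / "trajectory.pdb"),
        "parameters": str(outdir / "parameters.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_pdb(toy.topology, toy.reference, files["structure"])
    write_pdb(toy.topology, trajectory, files["trajectory"])
    toy.param_table.to_csv(files["parameters"], sep="\t", index=False)
    with open(files["truth"], "w") as fh:
        json.dump({"schedule": list(schedule)}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return files
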