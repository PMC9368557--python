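"""Pairwise nonbonded forces and per-residue punctual stress.

Punctual stress on a residue at a time point is the sum of the magnitudes
of the individual pairwise nonbonded forces (Lennard-Jones + Coulomb) the
ligand exerts on its atoms — absolute pairwise contributions, not the norm
of the net force, so opposing pulls do not cancel. Only protein-ligand
pairs contribute; bonded terms and protein-protein interactions are out of
scope, which also means no 1-4 exclusions are needed.

Units are the MD convention throughout: nm, elementary charges, kJ/mol,
forces in kJ mol^-1 nm^-1, with the Coulomb constant
ke = 138.935458 kJ mol^-1 nm e^-2. Lorentz-Berthelot combination rules;
plain cutoff (default 1.2 nm), no reaction field or mesh electrostatics —
the supported outputs are comparative rankings, not engine-grade absolute
forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError
from .model import Selection, Topology, Trajectory

log = logging.getLogger(__name__)

COULOMB_KE = 138.935458  # kJ mol^-1 nm e^-2
DEFAULT_CUTOFF = 1.2  # nm


@dataclass
class NonbondedParams:
    """Per-atom charge/sigma/epsilon arrays plus the interaction cutoff."""

    charge: np.ndarray  # e
    sigma: np.ndarray  # nm
    epsilon: np.ndarray  # kJ/mol
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        q = np.asarray(self.charge, dtype=np.float64)
        s = np.asarray(self.sigma, dtype=np.float64)
        e = np.asarray(self.epsilon, dtype=np.float64)
        if not (q.shape == s.shape == e.shape):
            raise InputError("charge/sigma/epsilon must have equal lengths")
        if np.any(s < 0) or np.any(e < 0):
            raise InputError("sigma and epsilon must be >= 0")
        if self.cutoff <= 0:
            raise InputError("cutoff must be positive")
        self.charge, self.sigma, self.epsilon = q, s, e

    @classmethod
    def from_topology(cls, topology: Topology, cutoff: float = DEFAULT_CUTOFF) -> "NonbondedParams":
        return cls(
            np.array([a.partial_charge for a in topology.atoms]),
            np.array([a.lj_sigma for a in topology.atoms]),
            np.array([a.lj_epsilon for a in topology.atoms]),
            cutoff,
        )


def pair_force(
    ri: np.ndarray,
    rj: np.ndarray,
    qi: float,
    qj: float,
    sigma_i: float,
    sigma_j: float,
    eps_i: float,
    eps_j: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Force on atom i from atom j (kJ mol^-1 nm^-1, 3-vector).

    F = [24 eps (2 (s/r)^12 - (s/r)^6) / r + ke qi qj / r^2] rhat, with
    rhat pointing from j to i, so a positive scalar is repulsion pushing i
    away from j. Lorentz-Berthelot: s = (si+sj)/2, eps = sqrt(ei ej).
    Zero beyond the cutoff.
    """
    rij = np.asarray(ri, float) - np.asarray(rj, float)
    r = float(np.linalg.norm(rij))
    if r == 0.0:
        raise InputError("coincident atoms: pair force is singular")
    if r > cutoff:
        return np.zeros(3)
    sig = 0.5 * (sigma_i + sigma_j)
    eps = np.sqrt(eps_i * eps_j)
    sr6 = (sig / r) ** 6
    # qi*qj is grouped so the scalar is bit-identical under i<->j exchange
    scalar = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r + COULOMB_KE * (qi * qj) / r**2
    return scalar * rij / r


def punctual_stress_frame(
    frame: np.ndarray,
    residue: Selection,
    ligand: Selection,
    params: NonbondedParams,
) -> float:
    """Sum of pairwise force magnitudes between a residue and the ligand."""
    if len(residue) == 0 or len(ligand) == 0:
        raise InputError("selections must be non-empty")
    if np.intersect1d(residue.atom_indices, ligand.atom_indices).size:
        raise InputError("residue and ligand selections overlap")
    ir = residue.atom_indices
    il = ligand.atom_indices
    d = cdist(frame[ir], frame[il])
    if np.any(d == 0):
        raise InputError("coincident atoms: pair force is singular")
    within = d <= params.cutoff
    if not np.any(within):
        return 0.0
    sig = 0.5 * (params.sigma[ir][:, None] + params.sigma[il][None, :])
    eps = np.sqrt(params.epsilon[ir][:, None] * params.epsilon[il][None, :])
    qq = params.charge[ir][:, None] * params.charge[il][None, :]
    sr6 = (sig / d) ** 6
    scalar = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d + COULOMB_KE * qq / d**2
    return float(np.abs(scalar[within]).sum())


@dataclass
class StressProfile:
    """Per-residue punctual stress: full time series and the aggregate
    (mean over masked frames per trajectory, summed across trajectories)."""

    residues: list[tuple[str, int]]
    per_frame: list[np.ndarray]  # one (F_t, R) array per trajectory
    aggregate: np.ndarray  # (R,)
    masks: list[np.ndarray] = field(default_factory=list)

    def as_dict(self) -> dict[int, float]:
        return {ri: float(self.aggregate[i]) for i, (_, ri) in enumerate(self.residues)}


def stress_profile(
    trajectories: list[Trajectory],
    topology: Topology,
    params: NonbondedParams,
    frame_masks: list[np.ndarray] | None = None,
    residue_indices: list[int] | None = None,
) -> StressProfile:
    """Per-residue punctual stress profiles from ligand interactions.

    For each trajectory the per-residue stress is averaged over the masked
    frames; the aggregate sums those per-trajectory means. A trajectory
    whose mask selects no frames is skipped with a warning.
    """
    ligand = topology.ligand_selection
    if ligand is None or len(ligand) == 0:
        raise InputError("topology has no ligand selection")
    lig_set = set(ligand.atom_indices.tolist())
    res_sels: list[tuple[tuple[str, int], Selection]] = []
    for res in topology.residues:
        if residue_indices is not None and res.index not in residue_indices:
            continue
        idx = [i for i in range(res.first_atom, res.last_atom) if i not in lig_set]
        if idx:
            res_sels.append(((res.name, res.index), Selection(f"{res.name}{res.index}", np.asarray(idx))))
    if frame_masks is None:
        frame_masks = [np.ones(t.n_frames, dtype=bool) for t in trajectories]
    if len(frame_masks) != len(trajectories):
        raise InputError("one frame mask per trajectory required")

    n_res = len(res_sels)
    per_frame: list[np.ndarray] = []
    aggregate = np.zeros(n_res)
    used_masks: list[np.ndarray] = []
    for t, (traj, mask) in enumerate(zip(trajectories, frame_masks)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (traj.n_frames,):
            raise InputError(f"trajectory {t}: mask length mismatch")
        frames = np.nonzero(mask)[0]
        if frames.size == 0:
            log.warning("trajectory %d: empty frame mask, skipped", t)
            continue
        series = np.zeros((frames.size, n_res))
        for k, f in enumerate(frames):
            x = traj.coordinates[f]
            for r, (_, sel) in enumerate(res_sels):
                series[k, r] = punctual_stress_frame(x, sel, ligand, params)
        per_frame.append(series)
        used_masks.append(mask)
        aggregate += series.mean(axis=0)
    return StressProfile([key for key, _ in res_sels], per_frame, aggregate, used_masks)


def top_stressed(profile: StressProfile, n: int = 10) -> list[tuple[tuple[str, int], float]]:
    """The n residues with the greatest aggregate stress, descending;
    ties break by residue index."""
    if n < 1:
        raise InputError("n must be >= 1")
    entries = list(zip(profile.residues, profile.aggregate))
    entries.sort(key=lambda e: (-e[1], e[0][1]))
    return [(res, float(s)) for res, s in entries[:n]]
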