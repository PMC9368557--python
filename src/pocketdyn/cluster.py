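"""Superposition, RMSD and ligand-pose clustering.

The quantity of interest is the ligand pose within the pocket frame of
reference, so the conventional protocol is: rigid-body fit every frame on
the protein Calpha atoms, then measure and cluster on ligand heavy-atom
RMSD. Two clustering schemes are provided: the Daura/GROMOS iterative
neighbor-count scheme with a distance cutoff (the de-facto trajectory
standard for "top N clusters") and seeded k-medoids on the pairwise-RMSD
matrix for analyses with a fixed cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateSelectionError, InputError
from .model import Selection, Trajectory


def _fit_indices(sel) -> np.ndarray:
    return sel.atom_indices if isinstance(sel, Selection) else np.asarray(sel, dtype=np.intp)


def superpose(
    trajectory: Trajectory,
    reference: np.ndarray,
    fit_selection: Selection | np.ndarray,
) -> Trajectory:
    """Least-squares rigid-body fit of every frame onto the reference.

    The optimal proper rotation (Kabsch) and translation are computed on
    ``fit_selection`` and applied to all atoms.
    """
    idx = _fit_indices(fit_selection)
    if idx.size < 3:
        raise DegenerateSelectionError("fit selection needs at least 3 atoms")
    ref = np.asarray(reference, dtype=np.float64)
    if ref.ndim != 2:
        raise InputError("reference must be a single frame (atoms, 3)")
    ref_fit = ref[idx]
    ref_cm = ref_fit.mean(axis=0)
    ref_c = ref_fit - ref_cm
    # collinearity check: centered fit coordinates must span a plane
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise DegenerateSelectionError("fit selection is collinear or degenerate")
    out = np.empty_like(trajectory.coordinates)
    for f in range(trajectory.n_frames):
        mob = trajectory.coordinates[f]
        mob_fit = mob[idx]
        mob_cm = mob_fit.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob_fit - mob_cm)
        out[f] = rot.apply(mob - mob_cm) + ref_cm
    return Trajectory(out, times=trajectory.times.copy(),
                      synthetic_times=trajectory.synthetic_times)


def rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    selection: Selection | np.ndarray | None = None,
) -> float:
    """Plain RMSD over a selection, without refitting."""
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputError("frames have mismatched shapes")
    if selection is not None:
        idx = _fit_indices(selection)
        a, b = a[idx], b[idx]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_rmsd(trajectory: Trajectory, selection: Selection | np.ndarray) -> np.ndarray:
    """All-frame-pairs RMSD matrix over a selection (no refit)."""
    idx = _fit_indices(selection)
    x = trajectory.coordinates[:, idx, :].reshape(trajectory.n_frames, -1)
    sq = np.einsum("ij,ij->i", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2 / idx.size)


@dataclass
class ClusterResult:
    """Size-ranked partition of frames into pose clusters."""

    labels: np.ndarray  # per-frame cluster id, 0 = largest
    sizes: list[int]
    fractions: list[float]
    medoids: list[int]  # representative frame per cluster

    def __post_init__(self) -> None:
        if any(self.sizes[i] < self.sizes[i + 1] for i in range(len(self.sizes) - 1)):
            raise InputError("cluster sizes must be sorted non-increasing")


def _rank_clusters(members: list[list[int]], medoids: list[int], n_frames: int) -> ClusterResult:
    order = sorted(
        range(len(members)), key=lambda c: (-len(members[c]), min(members[c]))
    )
    labels = np.empty(n_frames, dtype=int)
    sizes, fracs, meds = [], [], []
    for rank, c in enumerate(order):
        for f in members[c]:
            labels[f] = rank
        sizes.append(len(members[c]))
        fracs.append(len(members[c]) / n_frames)
        meds.append(medoids[c])
    return ClusterResult(labels, sizes, fracs, meds)


def gromos_cluster(
    trajectory: Trajectory,
    cluster_selection: Selection | np.ndarray,
    cutoff: float = 0.2,
) -> ClusterResult:
    """Daura/GROMOS clustering: repeatedly take the frame with the most
    neighbors within ``cutoff`` as a cluster center (ties to the lowest
    frame index), remove it with its neighbors, and repeat."""
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    d = pairwise_rmsd(trajectory, cluster_selection)
    n = d.shape[0]
    alive = np.ones(n, dtype=bool)
    members: list[list[int]] = []
    medoids: list[int] = []
    while alive.any():
        neigh = (d <= cutoff) & alive[None, :] & alive[:, None]
        counts = neigh.sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        group = np.nonzero(neigh[center])[0]
        members.append(group.tolist())
        medoids.append(center)
        alive[group] = False
    return _rank_clusters(members, medoids, n)


def k_medoid_cluster(
    trajectory: Trajectory,
    cluster_selection: Selection | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """k-medoids (PAM-style alternation) on the pairwise-RMSD matrix.

    Runs ``n_restarts`` seeded random initializations and keeps the
    partition with the lowest total within-cluster distance to medoids.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if k > trajectory.n_frames:
        raise InputError("k cannot exceed the frame count")
    d = pairwise_rmsd(trajectory, cluster_selection)
    n = d.shape[0]
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_medoids: np.ndarray | None = None
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k, replace=False)
        for _it in range(100):
            assign = np.argmin(d[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                cluster = np.nonzero(assign == c)[0]
                if cluster.size == 0:
                    continue
                within = d[np.ix_(cluster, cluster)].sum(axis=1)
                new_medoids[c] = cluster[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        assign = np.argmin(d[:, medoids], axis=1)
        cost = d[np.arange(n), medoids[assign]].sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_medoids = np.sort(medoids)
    assign = np.argmin(d[:, best_medoids], axis=1)
    members = [np.nonzero(assign == c)[0].tolist() for c in range(k)]
    members = [m for m in members if m]
    medoids = [int(best_medoids[c]) for c in range(k) if np.any(assign == c)]
    return _rank_clusters(members, medoids, n)
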