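"""Hydrogen-bond pair distances, the 0.5 nm break rule, and binding states.

A binding state is a recurring ligand pose defined by which of five named
hydrogen-bond pairs are simultaneously formed between the ligand and the
pocket backbone:

* state 0 — carboxylate bonded to at least two of the I33/G34/I35 backbone
  amides, with both I37 pairs broken (the crystal-like pose);
* state 1 — the central ketone bonded to I37;
* state 2 — the carboxylate bonded to I37.

A pair is *broken* when its donor-acceptor heavy-atom distance exceeds the
break threshold (default 0.5 nm, strictly: exactly 0.5 counts as formed).
Carboxylate distances take the minimum over both equivalent oxygens.

No hydrogen positions or donor-angle criteria enter the state rule: the
classification is a pure heavy-atom distance pattern. A conventional
geometric H-bond detector (0.35 nm / 30 degrees) is provided separately as
a candidate-pair discovery aid only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde

from .errors import InputError
from .model import Selection, Topology, Trajectory

CANONICAL_LABELS = (
    "I33-carboxyl",
    "G34-carboxyl",
    "I35-carboxyl",
    "I37-carboxyl",
    "I37-ketone",
)
STATE0_PAIRS = ("I33-carboxyl", "G34-carboxyl", "I35-carboxyl")
DEFAULT_BREAK_THRESHOLD = 0.5  # nm


@dataclass(frozen=True)
class HBondPair:
    """A tracked protein-backbone / ligand-group hydrogen-bond pair."""

    label: str
    protein_atom: int
    ligand_atoms: np.ndarray
    break_threshold: float = DEFAULT_BREAK_THRESHOLD

    def __post_init__(self) -> None:
        la = np.asarray(self.ligand_atoms, dtype=np.intp)
        if la.size == 0:
            raise InputError(f"pair {self.label}: ligand atom set is empty")
        if self.break_threshold <= 0:
            raise InputError(f"pair {self.label}: threshold must be positive")
        object.__setattr__(self, "ligand_atoms", la)


@dataclass
class BondStateSeries:
    label: str
    distances: np.ndarray  # nm, per frame
    formed: np.ndarray  # bool, per frame
    break_threshold: float


@dataclass
class StateAssignment:
    labels: list[str]
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not self.fractions:
            from .synthetic import STATE_LABELS

            self.fractions = {
                s: self.labels.count(s) / n for s in STATE_LABELS
            }

    def mask(self, state: str) -> np.ndarray:
        return np.array([lab == state for lab in self.labels])


def build_canonical_pairs(
    topology: Topology,
    groups: dict[str, Selection],
    break_threshold: float = DEFAULT_BREAK_THRESHOLD,
) -> list[HBondPair]:
    """The five canonical pairs, built from backbone N donors and the
    carboxylate/ketone oxygens of the ligand group map."""
    oxy = {
        g: np.array(
            [i for i in groups[g].atom_indices if topology.atoms[i].element == "O"]
        )
        for g in ("carboxyl", "ketone")
    }
    pairs = []
    for label in CANONICAL_LABELS:
        resid = int("".join(ch for ch in label.split("-")[0] if ch.isdigit()))
        group = label.split("-")[1]
        pairs.append(
            HBondPair(label, topology.atom_index(resid, "N"), oxy[group], break_threshold)
        )
    return pairs


def classify_bond(distance: float, threshold: float = DEFAULT_BREAK_THRESHOLD) -> str:
    """'formed' or 'broken' by the break rule: broken iff distance > threshold."""
    if distance < 0:
        raise InputError("distance cannot be negative")
    return "broken" if distance > threshold else "formed"


def pair_distance_series(trajectory: Trajectory, pair: HBondPair) -> BondStateSeries:
    """Per-frame min distance from the protein atom to the pair's ligand
    atoms, with the formed/broken flag applied."""
    if trajectory.n_frames == 0:
        raise InputError("empty trajectory")
    p = trajectory.coordinates[:, pair.protein_atom, :]  # (F, 3)
    l = trajectory.coordinates[:, pair.ligand_atoms, :]  # (F, k, 3)
    d = np.linalg.norm(l - p[:, None, :], axis=2).min(axis=1)
    return BondStateSeries(pair.label, d, d <= pair.break_threshold, pair.break_threshold)


def assign_states(
    series: list[BondStateSeries],
    dissociation: np.ndarray | None = None,
) -> StateAssignment:
    """Classify each frame from the canonical bond pattern.

    Precedence: dissociated, then state 0 (>=2 of the three carboxylate
    pairs formed and both I37 pairs broken), then state 1 (I37-ketone
    formed), then state 2 (I37-carboxyl formed), else unassigned.
    """
    by_label = {s.label: s for s in series}
    for lab in CANONICAL_LABELS:
        if lab not in by_label:
            raise InputError(f"missing canonical pair: {lab}")
    n = len(series[0].formed)
    if any(len(s.formed) != n for s in series):
        raise InputError("bond series have inconsistent frame counts")
    if dissociation is None:
        dissociation = np.zeros(n, dtype=bool)
    elif len(dissociation) != n:
        raise InputError("dissociation flags length mismatch")

    n_carboxyl = sum(by_label[lab].formed.astype(int) for lab in STATE0_PAIRS)
    i37c = by_label["I37-carboxyl"].formed
    i37k = by_label["I37-ketone"].formed
    labels = []
    for f in range(n):
        if dissociation[f]:
            labels.append("dissociated")
        elif n_carboxyl[f] >= 2 and not i37c[f] and not i37k[f]:
            labels.append("state0")
        elif i37k[f]:
            labels.append("state1")
        elif i37c[f]:
            labels.append("state2")
        else:
            labels.append("unassigned")
    return StateAssignment(labels)


def min_distance_series(
    trajectory: Trajectory, sel_a: Selection, sel_b: Selection
) -> np.ndarray:
    """Per-frame shortest distance between any atom of A and any atom of B."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise InputError("selections must be non-empty")
    if np.intersect1d(sel_a.atom_indices, sel_b.atom_indices).size:
        raise InputError("selections overlap")
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        xa = trajectory.coordinates[f, sel_a.atom_indices]
        xb = trajectory.coordinates[f, sel_b.atom_indices]
        out[f] = cdist(xa, xb).min()
    return out


def dissociation_scan(
    trajectory: Trajectory,
    ligand: Selection,
    pocket_residue: Selection,
    cutoff: float = 0.8,
    window: int = 50,
) -> tuple[np.ndarray, int | None]:
    """Sustained-exit detector on the ligand/pocket min-distance series.

    The ligand counts as dissociated from the first frame of a run of
    ``window`` consecutive frames beyond ``cutoff``, and as re-entered from
    the first frame of a ``window``-long run back inside. Returns the
    per-frame dissociated flag and the first sustained-exit frame (None if
    the ligand never leaves).
    """
    if window < 1:
        raise InputError("window must be >= 1")
    d = min_distance_series(trajectory, ligand, pocket_residue)
    out = d > cutoff
    n = len(out)
    run_out = _run_lengths(out)
    run_in = _run_lengths(~out)
    flags = np.zeros(n, dtype=bool)
    dissociated = False
    first_exit: int | None = None
    f = 0
    while f < n:
        if not dissociated and out[f] and run_out[f] >= window:
            dissociated = True
            if first_exit is None:
                first_exit = f
        elif dissociated and not out[f] and run_in[f] >= window:
            dissociated = False
        flags[f] = dissociated
        f += 1
    return flags, first_exit


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """run_lengths[i] = length of the run of True starting at i (0 if False)."""
    n = len(mask)
    out = np.zeros(n, dtype=int)
    run = 0
    for i in range(n - 1, -1, -1):
        run = run + 1 if mask[i] else 0
        out[i] = run
    return out


@dataclass
class DistanceDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    gaussian_mu: float
    gaussian_sigma: float
    n_modes: int
    unimodal: bool | None  # None when too few samples for mode estimation


def distance_distribution(
    values: np.ndarray, n_bins: int = 50, min_samples: int = 30
) -> DistanceDistribution:
    """Histogram plus Gaussian fit and kernel-density mode count.

    The Gaussian fit is the sample mean/SD; modes are local maxima of a
    Gaussian KDE with Silverman's bandwidth evaluated on a fine grid,
    counted only when their prominence exceeds 5% of the peak density.
    With fewer than ``min_samples`` values the mode count is not estimated
    and ``unimodal`` is None.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise InputError("values must be a non-empty 1-D array")
    counts, edges = np.histogram(v, bins=n_bins)
    mu = float(v.mean())
    sigma = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if v.size < min_samples:
        return DistanceDistribution(edges, counts, mu, sigma, 1, None)
    if sigma <= max(abs(mu), 1.0) * 1e-12:  # degenerate: all values identical
        return DistanceDistribution(edges, counts, mu, sigma, 1, True)
    kde = gaussian_kde(v, bw_method="silverman")
    h = kde.factor * sigma
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, 512)
    dens = kde(grid)
    # a mode must stand out by >=5% of the peak density, otherwise KDE
    # sampling wiggles register as spurious modes
    peaks, _ = find_peaks(dens, prominence=0.05 * dens.max())
    n_modes = max(int(peaks.size), 1)
    return DistanceDistribution(edges, counts, mu, sigma, n_modes, n_modes == 1)


def detect_hbond_candidates(
    trajectory: Trajectory,
    topology: Topology,
    donors: Selection,
    acceptors: Selection,
    distance_cutoff: float = 0.35,
    min_occupancy: float = 0.1,
) -> list[tuple[int, int, float]]:
    """Discovery aid: donor/acceptor heavy-atom pairs within a conventional
    geometric H-bond distance in at least ``min_occupancy`` of frames.

    This is *not* the state rule (which uses the 0.5 nm break threshold on
    named pairs); it only suggests pairs worth tracking. Without explicit
    hydrogens an angle test is not applicable, so the criterion is distance
    only.
    """
    counts: dict[tuple[int, int], int] = {}
    for f in range(trajectory.n_frames):
        xd = trajectory.coordinates[f, donors.atom_indices]
        xa = trajectory.coordinates[f, acceptors.atom_indices]
        close = cdist(xd, xa) <= distance_cutoff
        for i, j in zip(*np.nonzero(close)):
            key = (int(donors.atom_indices[i]), int(acceptors.atom_indices[j]))
            counts[key] = counts.get(key, 0) + 1
    out = []
    for (i, j), c in sorted(counts.items()):
        occ = c / trajectory.n_frames
        if occ >= min_occupancy and i != j:
            out.append((i, j, occ))
    out.sort(key=lambda t: -t[2])
    return out
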