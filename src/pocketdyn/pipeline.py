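"""Full per-state analysis pipeline with a single config and seeded,
reproducible outputs.

Stage order: dissociation scan -> frame retention (frames from the first
sustained exit onward are excluded) -> hydrogen-bond distance series ->
state assignment -> per-state distance distributions -> pose clustering ->
per-state contact maps -> per-state correlation networks -> per-state
stress profiles. Identical config + seed gives a byte-identical JSON
bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cluster as _cluster
from . import contacts as _contacts
from . import forces as _forces
from . import hbonds as _hbonds
from . import network as _network
from .errors import InputError, PocketDynError
from .io import read_structure, read_trajectory, write_pdb
from .model import Selection, Topology, Trajectory
from .select import select


class StageError(PocketDynError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs; thresholds default to the package's
    standard values (H-bond break 0.5 nm, contacts 0.45 nm, dissociation
    0.8 nm over a 50-frame window, force cutoff 1.2 nm)."""

    structure: str | None = None
    trajectories: list[str] = field(default_factory=list)
    parameters: str | None = None
    ligand_resname: str | None = None
    groups: dict[str, list[str]] | None = None  # group -> ligand atom names
    ss_map: dict[int, str] | None = None
    hbond_threshold: float = 0.5
    contact_cutoff: float = 0.45
    dissociation_cutoff: float = 0.8
    dissociation_window: int = 50
    pocket_residue: int = 37
    n_clusters: int = 3
    cluster_restarts: int = 10
    network_f_min: float = 0.75
    force_cutoff: float = 1.2
    min_state_frames: int = 100
    min_network_frames: int = 10
    distribution_bins: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "ss_map" in raw and raw["ss_map"]:
            raw["ss_map"] = _expand_ss_map(raw["ss_map"])
        return cls(**raw)


def _expand_ss_map(spec: dict) -> dict[int, str]:
    """Accept {"56-63": "alphaA", 35: "betaB"} style maps."""
    out: dict[int, str] = {}
    for key, element in spec.items():
        s = str(key)
        if "-" in s.lstrip("-")[0:]:
            lo, hi = s.split("-", 1) if not s.startswith("-") else (s, s)
            try:
                lo_i, hi_i = int(lo), int(hi)
            except ValueError:
                raise InputError(f"bad ss_map range {key!r}")
            for r in range(lo_i, hi_i + 1):
                out[r] = str(element)
        else:
            out[int(s)] = str(element)
    return out


def resolve_groups(
    topology: Topology, groups: dict[str, list[str]] | None
) -> dict[str, Selection]:
    """Group name -> ligand Selection, from atom-name lists or (fallback)
    the synthetic naming convention."""
    lig = topology.ligand_selection
    if lig is None or len(lig) == 0:
        raise InputError("topology has no ligand")
    if groups is None:
        from .synthetic import LIGAND_GROUPS

        prefix_map = {
            "C1": "carboxyl", "O1": "carboxyl",
            "C2": "ketone", "O2": "ketone",
            "C3": "cyclopentyl",
            "C4": "bromophenyl", "BR": "bromophenyl",
            "C5": "piperidine", "N5": "piperidine",
            "C6": "pyrrolidine", "N6": "pyrrolidine",
            "C7": "tertbutyl",
        }
        idx: dict[str, list[int]] = {g: [] for g in LIGAND_GROUPS}
        for i in lig.atom_indices:
            name = topology.atoms[i].name
            g = prefix_map.get(name[:2].upper())
            if g is not None:
                idx[g].append(int(i))
        return {g: Selection(g, np.asarray(v)) for g, v in idx.items() if v}
    by_name = {}
    lig_set = set(lig.atom_indices.tolist())
    for g, names in groups.items():
        chosen = [
            i for i in lig.atom_indices if topology.atoms[i].name in set(names)
        ]
        if not chosen:
            raise InputError(f"group {g!r}: no matching ligand atoms")
        if any(i not in lig_set for i in chosen):
            raise InputError(f"group {g!r}: atoms outside the ligand")
        by_name[g] = Selection(g, np.asarray(chosen))
    return by_name


@dataclass
class ReportBundle:
    """All pipeline outputs as JSON-serializable sections, each recording
    the parameters that produced it."""

    sections: dict

    def to_json(self) -> str:
        return json.dumps(self.sections, indent=1, sort_keys=True) + "\n"

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle_path = outdir / "bundle.json"
        bundle_path.write_text(self.to_json())
        manifest = {
            "files": {"bundle": "bundle.json"},
            "parameters": self.sections.get("config", {}),
            "seed": self.sections.get("config", {}).get("seed"),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        return {"bundle": str(bundle_path), "manifest": str(outdir / "manifest.json")}


def run_full_analysis(
    config: AnalysisConfig,
    topology: Topology | None = None,
    trajectories: list[Trajectory] | None = None,
    groups: dict[str, Selection] | None = None,
) -> ReportBundle:
    """Execute every stage; pass topology/trajectories/groups directly to
    skip file loading (the file paths in the config are then ignored)."""
    stage = "load"
    try:
        if topology is None:
            if config.structure is None:
                raise InputError("no structure path configured")
            topology, _frame = read_structure(
                config.structure, config.parameters, config.ligand_resname
            )
            trajectories = [read_trajectory(p, topology) for p in config.trajectories]
        if not trajectories:
            raise InputError("no trajectories to analyse")
        if groups is None:
            groups = resolve_groups(topology, config.groups)
        ligand = topology.ligand_selection
        pocket = _residue_heavy(topology, config.pocket_residue)

        stage = "dissociation_scan"
        retained: list[Trajectory] = []
        retention = []
        for t, traj in enumerate(trajectories):
            flags, first_exit = _hbonds.dissociation_scan(
                traj, ligand, pocket, config.dissociation_cutoff, config.dissociation_window
            )
            keep = traj.n_frames if first_exit is None else first_exit
            retained.append(traj.subset(np.arange(keep)))
            retention.append(
                {
                    "trajectory": t,
                    "total_frames": traj.n_frames,
                    "retained_frames": keep,
                    "excluded_frames": traj.n_frames - keep,
                    "first_exit_frame": first_exit,
                }
            )

        stage = "hbond_series"
        pairs = _hbonds.build_canonical_pairs(topology, groups, config.hbond_threshold)
        per_traj_series = [
            [_hbonds.pair_distance_series(tr, p) for p in pairs] for tr in retained
        ]
        occupancy = {
            p.label: float(
                np.concatenate(
                    [s[i].formed for s in per_traj_series]
                ).mean()
            )
            for i, p in enumerate(pairs)
        }

        stage = "state_assignment"
        per_traj_states = [_hbonds.assign_states(series) for series in per_traj_series]
        pooled_labels = [lab for a in per_traj_states for lab in a.labels]
        pooled = _hbonds.StateAssignment(pooled_labels)
        n_retained = len(pooled_labels)

        stage = "distance_distributions"
        distributions = {}
        for state in ("state0", "state1", "state2"):
            mask = pooled.mask(state)
            if mask.sum() == 0:
                continue
            sec = {}
            for i, p in enumerate(pairs):
                pooled_d = np.concatenate([s[i].distances for s in per_traj_series])
                dist = _hbonds.distance_distribution(
                    pooled_d[mask], n_bins=config.distribution_bins
                )
                sec[p.label] = {
                    "mean_nm": dist.gaussian_mu,
                    "sd_nm": dist.gaussian_sigma,
                    "n_modes": dist.n_modes,
                    "unimodal": dist.unimodal,
                }
            distributions[state] = {
                "n_frames": int(mask.sum()),
                "low_confidence": bool(mask.sum() < config.min_state_frames),
                "pairs": sec,
            }

        stage = "clustering"
        pooled_traj = Trajectory(
            np.concatenate([tr.coordinates for tr in retained], axis=0)
        )
        ca = select(topology, "name CA and not ligand")
        lig_heavy = Selection(
            "ligand-heavy",
            np.array([i for i in ligand.atom_indices if topology.atoms[i].is_heavy]),
        )
        fitted = _cluster.superpose(pooled_traj, pooled_traj.coordinates[0], ca)
        kres = _cluster.k_medoid_cluster(
            fitted, lig_heavy, config.n_clusters,
            seed=config.seed, n_restarts=config.cluster_restarts,
        )
        clustering = {
            "method": "k-medoids",
            "k": config.n_clusters,
            "sizes": kres.sizes,
            "fractions": kres.fractions,
            "medoid_frames": kres.medoids,
            "labels": kres.labels.tolist(),
        }

        stage = "contacts"
        res_sels = _contacts.residue_heavy_selections(topology)
        group_defs = [
            _contacts.GroupDefinition.from_selection(topology, sel)
            for sel in groups.values()
        ]
        contact_maps = {}
        for state in ("state0", "state1", "state2"):
            mask = pooled.mask(state)
            if mask.sum() == 0:
                continue
            cmap = _contacts.contact_probability(
                pooled_traj, mask, group_defs, res_sels, config.contact_cutoff
            )
            contact_maps[state] = {
                "cutoff_nm": config.contact_cutoff,
                "n_frames": cmap.n_frames,
                "low_confidence": bool(mask.sum() < config.min_state_frames),
                "top_contacts": [
                    {"group": g, "residue": f"{rn}{ri}", "probability": p}
                    for g, (rn, ri), p in _contacts.top_contacts(cmap, 10)
                ],
            }

        stage = "networks"
        node_residues = [r.index for r in topology.residues if r.name != _ligand_resname(topology)]
        ca_labels = [
            f"{r.name}{r.index}" for r in topology.residues if r.name != _ligand_resname(topology)
        ]
        networks = {}
        for state in ("state0", "state1", "state2"):
            mask = pooled.mask(state)
            if mask.sum() < config.min_network_frames:
                if mask.sum() > 0:
                    networks[state] = {"skipped": True, "n_frames": int(mask.sum())}
                continue
            st_traj = pooled_traj.subset(mask)
            dccm = _network.compute_dccm(
                st_traj, ca, node_labels=ca_labels, fit_selection=ca, ligand=lig_heavy
            )
            elig = _network.contact_eligibility(
                st_traj, topology, node_residues, lig_heavy,
                f_min=config.network_f_min, cutoff=config.contact_cutoff,
            )
            graph = _network.build_network(dccm, elig)
            part = _network.girvan_newman(graph)
            coupling = _network.ligand_coupling(part, ss_map=config.ss_map)
            networks[state] = {
                "n_frames": int(mask.sum()),
                "modularity": part.q,
                "n_communities": len(set(part.mapping.values())),
                "ligand_coupling": coupling,
                "edge_rule": {
                    "f_min": config.network_f_min,
                    "contact_cutoff_nm": config.contact_cutoff,
                    "weight": "-log|Cij|",
                },
            }

        stage = "stress"
        params = _forces.NonbondedParams.from_topology(topology, config.force_cutoff)
        stress = {}
        for state in ("state0", "state1", "state2"):
            masks = [a.mask(state) for a in per_traj_states]
            if sum(m.sum() for m in masks) == 0:
                continue
            profile = _forces.stress_profile(retained, topology, params, masks)
            stress[state] = {
                "cutoff_nm": config.force_cutoff,
                "top10": [
                    {"residue": f"{rn}{ri}", "stress": s}
                    for (rn, ri), s in _forces.top_stressed(profile, 10)
                ],
            }

        sections = {
            "config": _config_dict(config),
            "retention": retention,
            "frame_accounting": {
                "total_input_frames": int(sum(t.n_frames for t in trajectories)),
                "retained_frames": n_retained,
                "excluded_frames": int(
                    sum(t.n_frames for t in trajectories) - n_retained
                ),
                "per_state": {s: int(pooled.mask(s).sum()) for s in
                              ("state0", "state1", "state2", "unassigned", "dissociated")},
            },
            "hbond_occupancy": occupancy,
            "state_fractions": pooled.fractions,
            "state_labels": pooled.labels,
            "distributions": distributions,
            "clustering": clustering,
            "contacts": contact_maps,
            "networks": networks,
            "stress": stress,
        }
        return ReportBundle(sections)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _ligand_resname(topology: Topology) -> str | None:
    lig = topology.ligand_selection
    if lig is None or len(lig) == 0:
        return None
    return topology.atoms[int(lig.atom_indices[0])].residue_name


def _residue_heavy(topology: Topology, resid: int) -> Selection:
    res = topology.residue(resid)
    idx = [i for i in range(res.first_atom, res.last_atom) if topology.atoms[i].is_heavy]
    return Selection(f"res{resid}", np.asarray(idx))


def _config_dict(config: AnalysisConfig) -> dict:
    d = asdict(config)
    if d.get("ss_map"):
        d["ss_map"] = {str(k): v for k, v in d["ss_map"].items()}
    return d


def write_medoid_frames(
    topology: Topology,
    trajectory: Trajectory,
    medoid_frames: list[int],
    path: str | Path,
) -> None:
    """Write cluster-representative frames as a multi-model PDB."""
    write_pdb(topology, trajectory.subset(np.asarray(medoid_frames)), path)
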