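"""Readers and writers.

Structures and trajectories are read through MDAnalysis, which gives us the
PDB dialect used by the test fixtures (multi-model PDB) plus, for free, the
common binary trajectory formats (XTC/DCD/TRR) behind the same
:class:`~pocketdyn.model.Trajectory` contract. PDB coordinates arrive in
Angstrom and are converted to nm at read time.

Nonbonded parameters are not part of PDB; they come from a TSV table keyed
by (residue_name, atom_name). Atoms missing from the table get zero
charge/sigma/epsilon and ``has_params=False`` — the force module then simply
contributes nothing for them.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .model import AtomRecord, Selection, Topology, Trajectory

log = logging.getLogger(__name__)

ANGSTROM_TO_NM = 0.1

#: Residue names never treated as the ligand when auto-detecting HETATMs.
_SOLVENT = {"HOH", "WAT", "SOL", "TIP3", "NA", "CL", "SOD", "CLA", "K", "MG"}


def _prescan_pdb(path: Path) -> None:
    """Cheap structural validation of a (possibly multi-model) PDB file.

    Raises :class:`FormatError` for duplicate atom serials within a model
    (with the line number) and for per-MODEL atom-count mismatches (naming
    the model), which the downstream reader does not report in those terms.
    """
    counts: list[int] = []
    model_ids: list[str] = []
    serials: set[str] = set()
    n = 0
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model:
                    counts.append(n)
                in_model = True
                n = 0
                serials = set()
                model_ids.append(line[6:].strip() or str(len(model_ids) + 1))
            elif rec == "ENDMDL":
                counts.append(n)
                in_model = False
                n = 0
                serials = set()
            elif rec in ("ATOM  ", "HETATM"):
                serial = line[6:11].strip()
                if serial and serial in serials:
                    raise FormatError(
                        f"{path}: duplicate atom serial {serial} at line {lineno}"
                    )
                serials.add(serial)
                n += 1
    if in_model:
        counts.append(n)
    if not counts and n:
        counts.append(n)  # single implicit model
    if counts and len(set(counts)) > 1:
        bad = next(
            (i for i, c in enumerate(counts) if c != counts[0]),
        )
        name = model_ids[bad] if bad < len(model_ids) else str(bad + 1)
        raise FormatError(
            f"{path}: MODEL {name} has {counts[bad]} atoms, expected {counts[0]}"
        )


def read_param_table(path: str | Path) -> pd.DataFrame:
    """Read a nonbonded parameter table.

    TSV with columns residue_name, atom_name, mass, charge, sigma, epsilon
    (mass in amu, charge in e, sigma in nm, epsilon in kJ/mol).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"residue_name", "atom_name", "mass", "charge", "sigma", "epsilon"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"parameter table missing columns: {sorted(missing)}")
    return df


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if stripped[:2].upper() in ("BR", "CL", "NA", "MG", "ZN", "FE"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


def _universe(path: Path):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path))
    except (OSError, FileNotFoundError) as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    except FormatError:
        raise
    except Exception as exc:  # mda raises assorted parser errors
        raise FormatError(f"{path}: not a parseable structure file ({exc})") from exc


def read_structure(
    path: str | Path,
    parameter_table: str | Path | pd.DataFrame | None = None,
    ligand_resname: str | None = None,
) -> tuple[Topology, Trajectory]:
    """Read a structure file into a Topology plus its first frame.

    The ligand is the set of atoms whose residue name equals
    ``ligand_resname``; when not given, any non-solvent HETATM residue name
    starting with "BIO" (else the unique non-solvent HETATM residue) is used.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in (".pdb", ".ent"):
        _prescan_pdb(path)
    u = _universe(path)

    params: pd.DataFrame | None
    if parameter_table is None:
        params = None
    elif isinstance(parameter_table, pd.DataFrame):
        params = parameter_table
    else:
        params = read_param_table(parameter_table)
    lookup = {}
    if params is not None:
        for row in params.itertuples(index=False):
            lookup[(row.residue_name, row.atom_name)] = row

    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        elements = [_element_from_name(a.name) for a in u.atoms]

    atoms: list[AtomRecord] = []
    n_missing = 0
    for i, a in enumerate(u.atoms):
        resname = str(a.resname).strip()
        chain = str(getattr(a, "chainID", "") or getattr(a, "segid", "") or "A").strip() or "A"
        row = lookup.get((resname, str(a.name).strip()))
        if params is not None and row is None:
            n_missing += 1
        atoms.append(
            AtomRecord(
                index=i,
                name=str(a.name).strip(),
                element=elements[i].strip() or _element_from_name(a.name),
                residue_name=resname,
                residue_index=int(a.resid),
                chain_id=chain,
                mass=float(row.mass) if row is not None else float(getattr(a, "mass", 0.0) or 0.0),
                partial_charge=float(row.charge) if row is not None else 0.0,
                lj_sigma=float(row.sigma) if row is not None else 0.0,
                lj_epsilon=float(row.epsilon) if row is not None else 0.0,
                has_params=row is not None,
            )
        )
    if n_missing:
        log.warning(
            "%d atoms absent from the parameter table; their charges and LJ "
            "parameters default to zero",
            n_missing,
        )

    topo = Topology(atoms=atoms)
    topo.ligand_selection = _detect_ligand(topo, u, ligand_resname)

    coords = u.atoms.positions.astype(np.float64) * ANGSTROM_TO_NM
    frame = Trajectory(coords[None, :, :])
    return topo, frame


def _detect_ligand(topo: Topology, u, ligand_resname: str | None) -> Selection:
    if ligand_resname is not None:
        idx = [a.index for a in topo.atoms if a.residue_name == ligand_resname]
        return Selection("ligand", np.asarray(idx, dtype=np.intp))
    try:
        record_types = u.atoms.record_types
        het_res = {
            topo.atoms[i].residue_name
            for i in range(topo.n_atoms)
            if str(record_types[i]).upper().startswith("HETATM")
        } - _SOLVENT
    except Exception:
        het_res = set()
    name = None
    bio = sorted(r for r in het_res if r.startswith("BIO"))
    if bio:
        name = bio[0]
    elif len(het_res) == 1:
        name = next(iter(het_res))
    if name is None:
        return Selection("ligand", np.array([], dtype=np.intp))
    idx = [a.index for a in topo.atoms if a.residue_name == name]
    return Selection("ligand", np.asarray(idx, dtype=np.intp))


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a multi-frame trajectory matching ``topology``.

    Multi-model PDB is the reference dialect; binary formats supported by
    the underlying reader work the same way. PDB carries no time axis, so
    frames get synthetic times 0,1,2,... flagged on the result.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    is_pdb = path.suffix.lower() in (".pdb", ".ent")
    if is_pdb:
        _prescan_pdb(path)
        u = _universe(path)
    else:
        import MDAnalysis as mda

        ref = np.zeros((topology.n_atoms, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(topology.n_atoms, trajectory=True)
            u.load_new(str(path))
        del ref
    if u.atoms.n_atoms != topology.n_atoms:
        raise FormatError(
            f"{path}: trajectory has {u.atoms.n_atoms} atoms per frame, "
            f"topology has {topology.n_atoms}"
        )
    coords = []
    times = []
    boxes = []
    have_box = True
    for ts in u.trajectory:
        coords.append(ts.positions.astype(np.float64) * ANGSTROM_TO_NM)
        times.append(float(ts.time))
        if ts.dimensions is None or not np.any(ts.dimensions[:3]):
            have_box = False
        else:
            boxes.append(np.asarray(ts.dimensions[:3], dtype=np.float64) * ANGSTROM_TO_NM)
    arr = np.stack(coords, axis=0)
    t = np.asarray(times)
    synthetic = is_pdb or t.size < 2 or np.any(np.diff(t) <= 0)
    return Trajectory(
        arr,
        times=None if synthetic else t,
        box=np.stack(boxes) if (have_box and boxes) else None,
        synthetic_times=synthetic,
    )


def write_pdb(
    topology: Topology,
    trajectory: Trajectory | np.ndarray,
    path: str | Path,
) -> None:
    """Write coordinates as a (multi-model) PDB file; input nm, output A."""
    if isinstance(trajectory, np.ndarray):
        trajectory = Trajectory(trajectory[None] if trajectory.ndim == 2 else trajectory)
    if trajectory.n_atoms != topology.n_atoms:
        raise InputError("coordinate atom count does not match topology")
    lig = set()
    if topology.ligand_selection is not None:
        lig = set(topology.ligand_selection.atom_indices.tolist())
    with open(path, "w") as fh:
        multi = trajectory.n_frames > 1
        for f in range(trajectory.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            xyz = trajectory.coordinates[f] / ANGSTROM_TO_NM
            for a in topology.atoms:
                rec = "HETATM" if a.index in lig else "ATOM  "
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                x, y, z = xyz[a.index]
                fh.write(
                    f"{rec}{a.index + 1:5d} {name:<4.4s} {a.residue_name:<4.4s}"
                    f"{a.chain_id[:1]}{a.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_report(
    table: list[dict] | pd.DataFrame,
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write a homogeneous table of named values as CSV or JSON.

    Numeric values round-trip at full precision (17 significant digits for
    CSV; native JSON numbers otherwise).
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        records = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise InputError(f"unknown report format: {format!r}")


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path)
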