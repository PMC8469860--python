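"""Readers and writers: PDB/XYZ structures (via MDAnalysis), JSON system
state and manifests, CSV trajectories, weight records and load curves."""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .sorption import WeightRecord
from .system import ParticleSystem


# ---------------------------------------------------------------------------
# structures

def _to_universe(system: ParticleSystem):
    import MDAnalysis as mda

    mol = system.molecule_id
    uniq, resindex = np.unique(mol, return_inverse=True)
    n_res = len(uniq)
    u = mda.Universe.empty(system.n_atoms, n_residues=max(n_res, 1),
                           atom_resindex=resindex,
                           residue_segindex=np.zeros(max(n_res, 1), int),
                           trajectory=True)
    u.add_TopologyAttr("names", list(system.names))
    u.add_TopologyAttr("elements", list(system.elements))
    u.add_TopologyAttr("masses", system.masses)
    u.add_TopologyAttr("charges", system.charges)
    u.add_TopologyAttr("resids", (np.arange(n_res) + 1).tolist() or [1])
    resnames = []
    for m in uniq:
        sp = system.species[mol == m][0]
        resnames.append("GEL" if sp == "gelatin" else "PVA")
    u.add_TopologyAttr("resnames", resnames or ["GEL"])
    if len(system.bonds):
        u.add_bonds([tuple(b) for b in system.bonds])
    u.atoms.positions = system.positions.astype(np.float32)
    if system.cell is not None:
        lx, ly, lz = system.box_lengths
        u.dimensions = [lx, ly, lz, 90.0, 90.0, 90.0]
    return u


def write_pdb(system: ParticleSystem, path):
    """PDB with CONECT records carrying the bonded topology."""
    u = _to_universe(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path), bonds="all")


def write_xyz(system: ParticleSystem, path, frames=None):
    """Single- or multi-frame XYZ (frames must carry positions)."""
    import MDAnalysis as mda

    u = _to_universe(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if frames is None:
            u.atoms.write(str(path))
            return
        with mda.Writer(str(path), u.atoms.n_atoms) as w:
            for fr in frames:
                if fr.positions is None:
                    raise DataError("frame without stored positions")
                u.atoms.positions = fr.positions.astype(np.float32)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# JSON system state (restart)

_ARRAY_FIELDS = ("positions", "masses", "charges", "bonds", "bond_k",
                 "bond_r0", "angles", "angle_k", "angle_theta0", "dihedrals",
                 "dihedral_k", "dihedral_n", "dihedral_phi0", "velocities")
_STR_FIELDS = ("elements", "names", "species")


def system_to_dict(system: ParticleSystem) -> dict:
    out = {}
    for f in _ARRAY_FIELDS:
        out[f] = np.asarray(getattr(system, f)).tolist()
    for f in _STR_FIELDS:
        out[f] = [str(x) for x in getattr(system, f)]
    out["molecule_id"] = system.molecule_id.tolist()
    out["cell"] = None if system.cell is None else system.cell.tolist()
    return out


def system_from_dict(d: dict) -> ParticleSystem:
    kw = {}
    for f in _ARRAY_FIELDS:
        kw[f] = np.asarray(d[f], float)
    for f in ("bonds", "angles", "dihedrals"):
        kw[f] = np.asarray(d[f], int).reshape(-1, {"bonds": 2, "angles": 3,
                                                   "dihedrals": 4}[f])
    kw["dihedral_n"] = np.asarray(d["dihedral_n"], int)
    for f in _STR_FIELDS:
        kw[f] = np.asarray(d[f], dtype=object)
    kw["molecule_id"] = np.asarray(d["molecule_id"], int)
    kw["cell"] = None if d["cell"] is None else np.asarray(d["cell"], float)
    return ParticleSystem(**kw)


def save_system(system: ParticleSystem, path):
    with open(path, "w") as fh:
        json.dump(system_to_dict(system), fh)


def load_system(path) -> ParticleSystem:
    with open(path) as fh:
        return system_from_dict(json.load(fh))


def write_manifest(manifest: dict, path):
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# trajectory CSV

def frames_to_dataframe(frames) -> pd.DataFrame:
    rows = []
    for fr in frames:
        rows.append({
            "time_fs": fr.time,
            "box_x_A": fr.box_lengths[0], "box_y_A": fr.box_lengths[1],
            "box_z_A": fr.box_lengths[2],
            "e_bonded": fr.energies["bonded"],
            "e_vdw": fr.energies["vdw"],
            "e_electrostatic": fr.energies["electrostatic"],
            "e_total": fr.total,
            "volume_A3": fr.volume,
            "kinetic": fr.kinetic,
            "temperature_K": fr.temperature,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experimental CSV formats

WEIGHT_COLUMNS = ("hydrogel_type", "temperature_c", "initial_wet_g",
                  "initial_dry_g", "swollen_wet_g", "swollen_dry_g")


def write_weight_records(records: list[WeightRecord], path):
    rows = [{
        "hydrogel_type": r.hydrogel_type, "temperature_c": r.temperature_c,
        "initial_wet_g": r.initial_wet, "initial_dry_g": r.initial_dry,
        "swollen_wet_g": r.swollen_wet, "swollen_dry_g": r.swollen_dry,
    } for r in records]
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(path, index=False)


def read_weight_records(path) -> list[WeightRecord]:
    df = pd.read_csv(path)
    missing = [c for c in WEIGHT_COLUMNS[2:] if c not in df.columns]
    if missing:
        raise DataError(f"weight CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        def _get(col):
            v = row.get(col)
            return None if pd.isna(v) else float(v)
        records.append(WeightRecord(
            initial_wet=_get("initial_wet_g"),
            initial_dry=_get("initial_dry_g"),
            swollen_wet=_get("swollen_wet_g"),
            swollen_dry=_get("swollen_dry_g"),
            temperature_c=_get("temperature_c"),
            hydrogel_type=(None if pd.isna(row.get("hydrogel_type"))
                           else str(row.get("hydrogel_type")))))
    return records


def write_load_curve(load_n, displacement_mm, path):
    pd.DataFrame({"load_n": load_n,
                  "displacement_mm": displacement_mm}).to_csv(path,
                                                              index=False)


def read_load_curve(path):
    df = pd.read_csv(path)
    for col in ("load_n", "displacement_mm"):
        if col not in df.columns:
            raise DataError(f"curve CSV missing column {col!r}")
    return df["load_n"].to_numpy(), df["displacement_mm"].to_numpy()
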