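"""Readers and writers for the pipeline's plain-text formats.

Tables travel as CSV/TSV; trajectories as multi-model PDB (MODEL/ENDMDL
records, via biotite) plus an atom-annotation CSV carrying residue ids,
labels, generic (Ballesteros–Weinstein) numbers, loop membership and
the ligand/receptor segment split. Concentrations are log10 molar
everywhere inside the package; any conversion from molar happens at
this boundary.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, stack
from biotite.structure.io.pdb import PDBFile

from .doseresponse import ConcentrationResponse
from .errors import SchemaError
from .gtpgs import GtpGammaCondition
from .trajcontacts import ATOM_COLUMNS, Trajectory

__all__ = [
    "load_concentration_response",
    "write_concentration_response",
    "load_gtpgs_conditions",
    "write_trajectory",
    "load_trajectory",
    "load_bret_reference",
    "load_gtpgs_reference",
]

CR_COLUMNS = ["ligand", "pathway", "replicate", "log10_conc_M", "response"]


def load_concentration_response(path) -> dict[tuple[str, str], ConcentrationResponse]:
    """Read a long-format concentration–response CSV, one dataset per
    (ligand, pathway). Malformed rows are reported with their row index."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("log10_conc_M", "response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise SchemaError(
                f"{path}: non-numeric {col} in rows {[i + 2 for i in bad]} "
                "(1-based, counting the header)")
        df[col] = vals
    out: dict[tuple[str, str], ConcentrationResponse] = {}
    for (lig, path_id), grp in df.groupby(["ligand", "pathway"], sort=True):
        points = [
            (str(r.replicate), float(r.log10_conc_M), float(r.response))
            for r in grp.itertuples()
        ]
        out[(lig, path_id)] = ConcentrationResponse(lig, path_id, points)
    return out


def write_concentration_response(
    datasets: dict[tuple[str, str], ConcentrationResponse] | list[ConcentrationResponse],
    path,
) -> None:
    if isinstance(datasets, dict):
        datasets = list(datasets.values())
    rows = []
    for ds in datasets:
        for rep, x, y in ds.points:
            rows.append((ds.ligand_id, ds.pathway_id, rep, x, y))
    pd.DataFrame(rows, columns=CR_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )


def load_gtpgs_conditions(path) -> list[GtpGammaCondition]:
    """Read a GTPγS CSV, replicate-level (a ``value`` column, one row per
    replicate) or summary-level (``mean``, ``sem``, ``n`` columns)."""
    df = pd.read_csv(path)
    base = ["subunit", "drug", "arm", "genotype"]
    missing = [c for c in base if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    conditions: list[GtpGammaCondition] = []
    if "value" in df.columns:
        for key, grp in df.groupby(base, sort=True):
            conditions.append(GtpGammaCondition(
                *key, replicates=[float(v) for v in grp["value"]]))
    elif {"mean", "sem", "n"} <= set(df.columns):
        for r in df.itertuples():
            conditions.append(GtpGammaCondition(
                r.subunit, r.drug, r.arm, r.genotype,
                mean=float(r.mean), sem=float(r.sem), n=int(r.n)))
    else:
        raise SchemaError(f"{path}: need either a value column or mean/sem/n")
    return conditions


def _trajectory_to_stack(traj: Trajectory):
    n_atoms = traj.coords.shape[1]
    template = AtomArray(n_atoms)
    template.coord = traj.coords[0].astype(np.float32)
    template.chain_id = np.where(traj.atoms["segment"] == "ligand", "L", "R")
    template.res_id = traj.atoms["residue_id"].to_numpy()
    template.res_name = [str(s)[:3].upper().ljust(3) for s in traj.atoms["residue_label"]]
    template.atom_name = [f"{e}{i+1}" for i, e in enumerate(traj.atoms["element"])]
    template.element = traj.atoms["element"].to_numpy(dtype="U2")
    template.hetero = np.full(n_atoms, True)
    arrays = []
    for f in range(traj.n_frames):
        arr = template.copy()
        arr.coord = traj.coords[f].astype(np.float32)
        arrays.append(arr)
    return stack(arrays)


def write_trajectory(traj: Trajectory, pdb_path, annotation_path) -> None:
    """Write frames as a multi-model PDB plus the annotation CSV."""
    pdb = PDBFile()
    pdb.set_structure(_trajectory_to_stack(traj))
    pdb.write(str(pdb_path))
    traj.atoms[ATOM_COLUMNS].to_csv(annotation_path, index=False)


def load_trajectory(pdb_path, annotation_path) -> Trajectory:
    """Read a multi-model PDB plus annotation CSV back into a Trajectory.

    Atom order in the PDB must match the annotation row order.
    PDB coordinates carry 3 decimals, so round-trips are exact to 1e-3 Å.
    """
    pdb = PDBFile.read(str(pdb_path))
    coords = pdb.get_coord(model=None).astype(float)
    atoms = pd.read_csv(annotation_path, keep_default_na=False)
    missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
    if missing:
        raise SchemaError(f"{annotation_path}: missing columns {missing}")
    return Trajectory(coords, atoms)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("gpcrbias") / "data" / name)


def load_bret_reference() -> pd.DataFrame:
    """Bundled literature-reported BRET functional-selectivity panel for
    the 5-HT2A receptor: pEC50, Emax (% of 5-HT) and transduction
    coefficient log(τ/K_A), each with SEM, for 5-HT and four tryptamine
    analogs across ten Gα pathways and both β-arrestins. Inactive
    (ligand, pathway) cells carry NaN."""
    return pd.read_csv(_data_path("bret_functional_selectivity.csv"))


def load_gtpgs_reference() -> pd.DataFrame:
    """Bundled literature-reported [35S]GTPγS percent-of-basal summary
    table (human prefrontal cortex): mean, SEM, n per drug/subunit/arm
    plus the published one-sample and between-condition p values
    (rendered strings; 'ns' = non-significant). ``n_alt`` records an
    alternative replicate-count parse where the published layout is
    ambiguous."""
    return pd.read_csv(_data_path("gtpgs_percent_basal.csv"), keep_default_na=False)
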