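import numpy as np
import pandas as pd
import pytest

from gpcrbias.trajcontacts import Trajectory


def make_atoms(n_ligand: int, receptor_spec: list[tuple[int, str, str]]) -> pd.DataFrame:
    """Annotation table: n_ligand ligand atoms plus one receptor atom per
    (residue_id, residue_label, loop_tag) entry."""
    rows = []
    for i in range(n_ligand):
        rows.append((i + 1, "C", 1000, "LIG", "", "", "ligand"))
    for rid, label, loop in receptor_spec:
        rows.append((len(rows) + 1, "C", rid, label, "", loop, "receptor"))
    return pd.DataFrame(
        rows,
        columns=["atom_id", "element", "residue_id", "residue_label",
                 "generic_number", "loop_tag", "segment"],
    )


def make_trajectory(lig_frames: np.ndarray, receptor_coords: np.ndarray,
                    receptor_spec: list[tuple[int, str, str]]) -> Trajectory:
    """Trajectory with per-frame ligand coordinates and a receptor that is
    identical in every frame (alignment is then the identity)."""
    lig_frames = np.asarray(lig_frames, dtype=float)
    n_frames = lig_frames.shape[0]
    rec = np.broadcast_to(receptor_coords, (n_frames, *receptor_coords.shape))
    coords = np.concatenate([lig_frames, rec], axis=1)
    return Trajectory(coords, make_atoms(lig_frames.shape[1], receptor_spec))


@pytest.fixture
def square_receptor():
    """Four rigid receptor atoms far from the origin, enough to align on."""
    spec = [(1, "R1", ""), (2, "R2", ""), (3, "R3", ""), (4, "R4", "")]
    coords = np.array([[20.0, 0, 0], [0, 20.0, 0], [-20.0, 0, 0], [0, -20.0, 5.0]])
    return coords, spec
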