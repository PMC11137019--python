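"""Ligand-pose clustering and residue contact fingerprints for MD frames.

Post-processing chain for ligand–receptor trajectories:

1. superpose every frame onto frame 0 using receptor atoms, so ligand
   motion is measured in the receptor frame of reference;
2. pairwise ligand heavy-atom RMSD matrix across frames;
3. agglomerative average-linkage clustering of frames, cut at a fixed
   RMSD distance (default 5 Å); the *main cluster* is the largest one;
4. per-residue contact frequencies over main-cluster frames — a residue
   is in contact in a frame when any of its heavy atoms lies strictly
   within the cutoff (default 3 Å) of any ligand heavy atom;
5. a reported set filtered at a frequency threshold (strictly above
   50% by default) and the accumulated frequency over second
   extracellular loop (ECL2) residues, the structural correlate used to
   compare ligand engagement of the loop.

Generic (Ballesteros–Weinstein) numbers and loop membership are
caller-supplied annotation; nothing here computes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .errors import (
    ContractError,
    MalformedTrajectoryError,
    MissingAnnotationError,
)

__all__ = [
    "Trajectory",
    "RmsdMatrix",
    "Clustering",
    "ContactFingerprint",
    "superpose",
    "ligand_rmsd_matrix",
    "average_linkage_cluster",
    "contact_frequency",
    "report_contacts",
    "ecl2_accumulated",
]

ATOM_COLUMNS = ["atom_id", "element", "residue_id", "residue_label",
                "generic_number", "loop_tag", "segment"]


@dataclass
class Trajectory:
    """Cartesian frames plus an atom annotation table.

    ``coords`` has shape (frames, atoms, 3) in Å; ``atoms`` carries one
    row per atom with at least the columns in ``ATOM_COLUMNS``
    (generic_number and loop_tag may be empty strings).
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise MalformedTrajectoryError(
                f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise MalformedTrajectoryError("need at least one frame")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise MalformedTrajectoryError(f"annotation lacks columns {missing}")
        if len(self.atoms) != self.coords.shape[1]:
            raise MalformedTrajectoryError(
                f"{len(self.atoms)} annotation rows vs "
                f"{self.coords.shape[1]} atoms per frame")
        if not np.all(np.isfinite(self.coords)):
            raise MalformedTrajectoryError("non-finite coordinates")
        seg = set(self.atoms["segment"])
        if "ligand" not in seg or "receptor" not in seg:
            raise MalformedTrajectoryError(
                "need at least one ligand and one receptor atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def mask(self, segment: str | None = None, heavy: bool = True) -> np.ndarray:
        m = np.ones(len(self.atoms), dtype=bool)
        if segment is not None:
            m &= (self.atoms["segment"] == segment).to_numpy()
        if heavy:
            m &= (self.atoms["element"].astype(str).str.upper() != "H").to_numpy()
        return m


@dataclass
class RmsdMatrix:
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        self.values = v


@dataclass
class Clustering:
    labels: np.ndarray          # frame -> cluster id (1-based)
    linkage: str
    cutoff: float
    main_cluster: int

    def frames_of(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_id)[0]

    @property
    def main_frames(self) -> np.ndarray:
        return self.frames_of(self.main_cluster)


@dataclass
class ContactFingerprint:
    per_residue: dict[int, float] = field(default_factory=dict)  # % of frames
    residue_labels: dict[int, str] = field(default_factory=dict)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_mask: np.ndarray) -> np.ndarray:
    """Rigid-body (Kabsch) superposition of one frame onto a reference.

    The rotation/translation is determined on ``fit_mask`` atoms and
    applied to all atoms of ``mobile``.
    """
    mob_fit = mobile[fit_mask]
    ref_fit = reference[fit_mask]
    mob_c = mob_fit.mean(axis=0)
    ref_c = ref_fit.mean(axis=0)
    H = (mob_fit - mob_c).T @ (ref_fit - ref_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return (mobile - mob_c) @ R.T + ref_c


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    # coords: (frames, atoms, 3) already in a common frame of reference
    diff = coords[:, None, :, :] - coords[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))


def ligand_rmsd_matrix(
    traj: Trajectory,
    align_selection: np.ndarray | None = None,
    best_fit: bool = False,
) -> RmsdMatrix:
    """Pairwise ligand heavy-atom RMSD across frames.

    Default convention: one shared superposition of every frame onto
    frame 0 using ``align_selection`` (receptor heavy atoms when not
    given), then *unfitted* ligand RMSD — ligand movement relative to
    the receptor. ``best_fit=True`` instead optimally superposes the
    ligand atoms of each frame pair (internal pose change only).
    """
    fit_mask = traj.mask("receptor") if align_selection is None else align_selection
    if np.count_nonzero(fit_mask) < 3:
        raise ContractError("alignment selection must contain >= 3 atoms")
    lig = traj.mask("ligand")
    aligned = np.empty_like(traj.coords)
    aligned[0] = traj.coords[0]
    for i in range(1, traj.n_frames):
        aligned[i] = superpose(traj.coords[i], traj.coords[0], fit_mask)
    ligc = aligned[:, lig, :]
    if not best_fit:
        return RmsdMatrix(_pairwise_rmsd(ligc))
    n = traj.n_frames
    m = np.zeros((n, n))
    all_mask = np.ones(ligc.shape[1], dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            fitted = superpose(ligc[j], ligc[i], all_mask)
            d = ligc[i] - fitted
            m[i, j] = m[j, i] = np.sqrt(np.mean(np.sum(d * d, axis=-1)))
    return RmsdMatrix(m)


def average_linkage_cluster(m: RmsdMatrix, cutoff: float = 5.0) -> Clustering:
    """Unweighted average-linkage clustering cut at an RMSD distance.

    Frames end up in the same cluster while the average inter-cluster
    RMSD of a merge stays at or below ``cutoff``; the cluster count is
    emergent, not fixed. Main cluster = largest; ties broken by the
    smallest mean intra-cluster RMSD, then by lowest label.
    """
    n = m.values.shape[0]
    if n == 1:
        return Clustering(np.array([1]), "average", cutoff, 1)
    condensed = squareform(m.values, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")

    def key(cid: int) -> tuple:
        idx = np.nonzero(labels == cid)[0]
        if idx.size == 1:
            mean_intra = 0.0
        else:
            sub = m.values[np.ix_(idx, idx)]
            mean_intra = float(sub[np.triu_indices(idx.size, 1)].mean())
        return (-idx.size, mean_intra, cid)

    main = min(np.unique(labels), key=key)
    return Clustering(labels, "average", cutoff, int(main))


def contact_frequency(
    traj: Trajectory,
    frames: np.ndarray | list[int],
    distance: float = 3.0,
) -> ContactFingerprint:
    """Per-residue ligand contact frequency over a set of frames.

    A receptor residue is in contact in a frame iff the minimum heavy-
    atom distance to any ligand heavy atom is strictly below
    ``distance``. Frequencies are % of the supplied frames. Contacts are
    intra-frame distances, so no alignment is involved.
    """
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ContractError("empty frame set")
    lig = traj.mask("ligand")
    rec = traj.mask("receptor")
    res_ids = traj.atoms.loc[rec, "residue_id"].to_numpy()
    labels = dict(
        zip(traj.atoms.loc[rec, "residue_id"], traj.atoms.loc[rec, "residue_label"])
    )
    unique_res = np.unique(res_ids)
    counts = {int(r): 0 for r in unique_res}
    for f in frames:
        d = cdist(traj.coords[f][rec], traj.coords[f][lig])
        min_per_atom = d.min(axis=1)
        for r in unique_res:
            if np.min(min_per_atom[res_ids == r]) < distance:
                counts[int(r)] += 1
    per_res = {r: 100.0 * c / frames.size for r, c in counts.items()}
    return ContactFingerprint(per_res, {int(k): str(v) for k, v in labels.items()})


def report_contacts(fp: ContactFingerprint, threshold: float = 50.0) -> list[tuple[int, float]]:
    """Residues with contact frequency strictly above the threshold,
    ordered by descending frequency (ties by residue id)."""
    kept = [(r, f) for r, f in fp.per_residue.items() if f > threshold]
    return sorted(kept, key=lambda rf: (-rf[1], rf[0]))


def ecl2_accumulated(fp: ContactFingerprint, atoms: pd.DataFrame) -> float:
    """Accumulated (summed, unthresholded) contact frequency over ECL2
    residues, as annotated in the atom table's loop_tag column."""
    tagged = atoms.loc[atoms["loop_tag"] == "ECL2", "residue_id"].unique()
    if tagged.size == 0:
        raise MissingAnnotationError("no atoms tagged ECL2 in annotation")
    return float(sum(fp.per_residue.get(int(r), 0.0) for r in tagged))
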