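"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, one per downstream stage:

* concentration–response curves drawn from the operational model with
  additive homoscedastic Gaussian replicate noise (triplicates by
  default, mirroring typical BRET panel designs);
* [35S]GTPγS percent-of-basal replicate sets as i.i.d. Gaussian draws
  at a designed mean/SD/n;
* ligand–receptor trajectories with designed pose clusters (well
  separated relative to the downstream clustering cutoff) and designed
  per-residue contact frequencies, realized exactly by construction.

Every generator takes an explicit integer seed (documented default 42)
and is bitwise reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .doseresponse import ConcentrationResponse
from .errors import ConstructionError, InvalidParameterError, InvalidSpecError
from .operational import OperationalParams, operational_response
from .trajcontacts import Trajectory

__all__ = [
    "ReplicateSpec",
    "GtpSimSpec",
    "TrajectorySpec",
    "default_log_grid",
    "default_pose_centers",
    "simulate_concentration_response",
    "simulate_gtpgs",
    "simulate_trajectory",
]

DEFAULT_SEED = 42


def default_log_grid() -> np.ndarray:
    """Half-log concentration grid from 1e-12 to 10^-4.5 M (16 points),
    wide enough to bracket potencies from pEC50 ~ 5 to ~ 10.5."""
    return np.linspace(-12.0, -4.5, 16)


@dataclass(frozen=True)
class ReplicateSpec:
    """Replicate structure of a simulated concentration–response dataset.

    noise_sd is the SD of additive Gaussian noise in %-of-reference-max
    units (i.e. on the response scale, not relative).
    """

    n_reps: int = 3
    noise_sd: float = 5.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InvalidSpecError(f"n_reps must be >= 1, got {self.n_reps}")
        if not (math.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise InvalidSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class GtpSimSpec:
    """Design of one simulated GTPγS condition (% of basal scale)."""

    true_mean: float
    true_sd: float
    n: int
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidSpecError(f"n must be >= 2, got {self.n}")
        if not (math.isfinite(self.true_sd) and self.true_sd > 0):
            raise InvalidSpecError(f"true_sd must be > 0, got {self.true_sd}")


def simulate_concentration_response(
    params: OperationalParams,
    grid: np.ndarray | None = None,
    spec: ReplicateSpec = ReplicateSpec(),
    ligand_id: str = "ligand",
    pathway_id: str = "pathway",
) -> ConcentrationResponse:
    """Draw replicate responses from the operational forward model.

    With noise_sd = 0 the points lie exactly on the curve.
    """
    if grid is None:
        grid = default_log_grid()
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise InvalidParameterError("non-finite concentration grid")
    if np.unique(grid).size < 4:
        raise InvalidSpecError("grid needs >= 4 distinct concentrations")
    if np.ptp(grid) < 3.0:
        raise InvalidSpecError("grid must span >= 3 log units")
    curve = operational_response(
        grid, params.Em, params.basal, params.logKA, params.logTau, params.n_slope
    )
    rng = np.random.default_rng(spec.seed)
    points = []
    for rep in range(1, spec.n_reps + 1):
        noise = rng.normal(0.0, spec.noise_sd, size=grid.size) if spec.noise_sd > 0 \
            else np.zeros(grid.size)
        for x, y in zip(grid, curve + noise):
            points.append((f"r{rep}", float(x), float(y)))
    return ConcentrationResponse(ligand_id, pathway_id, points)


def simulate_gtpgs(spec: GtpSimSpec) -> np.ndarray:
    """n i.i.d. Gaussian draws on the % of basal scale."""
    rng = np.random.default_rng(spec.seed)
    return rng.normal(spec.true_mean, spec.true_sd, size=spec.n)


@dataclass(frozen=True)
class TrajectorySpec:
    """Design of a synthetic ligand–receptor trajectory.

    pose_centers are per-pose ligand coordinate templates (same atom
    count and ordering); pose_weights are frame fractions summing to 1.
    designed_contacts maps residue label -> target contact frequency
    (fraction of main-cluster frames); each designed residue's contact
    atom is placed 2 Å from a ligand atom in exactly round(f * n_main)
    main-pose frames and far otherwise. loop_tags assigns loop
    membership (e.g. ECL2) to designed residues.
    """

    n_frames: int
    pose_centers: tuple
    pose_weights: tuple
    jitter_sd: float = 0.1
    designed_contacts: dict = field(default_factory=dict)
    loop_tags: dict = field(default_factory=dict)
    n_background_residues: int = 24
    rigid_motion: bool = True
    min_pose_separation: float = 5.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")
        if len(self.pose_centers) != len(self.pose_weights):
            raise InvalidSpecError("one weight per pose template required")
        if abs(sum(self.pose_weights) - 1.0) > 1e-9:
            raise InvalidSpecError("pose_weights must sum to 1 (±1e-9)")
        if not (math.isfinite(self.jitter_sd) and self.jitter_sd >= 0):
            raise InvalidSpecError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        shapes = {np.asarray(c).shape for c in self.pose_centers}
        if len(shapes) != 1 or next(iter(shapes))[1] != 3:
            raise InvalidSpecError("pose templates must share atom count/ordering")
        for label, f in self.designed_contacts.items():
            if not (0.0 <= f <= 1.0):
                raise ConstructionError(
                    f"designed contact frequency for {label!r} outside [0, 1]: {f}")
        centers = [np.asarray(c, dtype=float) for c in self.pose_centers]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                rmsd = float(np.sqrt(np.mean(
                    np.sum((centers[i] - centers[j]) ** 2, axis=-1))))
                if rmsd <= self.min_pose_separation:
                    raise ConstructionError(
                        f"pose centers {i} and {j} are {rmsd:.2f} Å apart "
                        f"(RMSD), not above the clustering cutoff "
                        f"{self.min_pose_separation} Å")


def default_pose_centers(n_poses: int, n_atoms: int = 5,
                         separation: float = 12.0) -> tuple:
    """Well-separated ligand pose templates: a small cross-shaped ligand
    translated by ``separation`` Å between poses (pairwise pose RMSD =
    ``separation`` for adjacent poses)."""
    base = np.array(
        [[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [-1.4, 0.0, 0.0],
         [0.0, 1.4, 0.0], [0.0, 0.0, 1.4]]
    )[:n_atoms]
    dirs = [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
            np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, 0.0]) / np.sqrt(2)]
    out = []
    for k in range(n_poses):
        shift = np.zeros(3) if k == 0 else separation * dirs[(k - 1) % len(dirs)] * \
            (1 + (k - 1) // len(dirs))
        out.append(base + shift)
    return tuple(out)


def _pose_frame_counts(weights, n_frames: int) -> list[int]:
    """Largest-remainder apportionment of frames to poses."""
    raw = [w * n_frames for w in weights]
    counts = [int(math.floor(r)) for r in raw]
    rem = n_frames - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def simulate_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Build a trajectory realizing the designed poses and contacts.

    Geometry (in the receptor frame of reference): ligand poses sit near
    the origin; a rigid scaffold of background residues (one CA-like
    atom each) surrounds them far outside contact range and provides the
    alignment frame; each designed-contact residue has a fixed scaffold
    atom plus a side-chain atom that is placed 2 Å from the ligand in
    its designated main-pose frames and at the scaffold otherwise. An
    optional per-frame global rigid motion (default on) is applied to
    all atoms, which downstream superposition must undo.
    """
    rng = np.random.default_rng(spec.seed)
    centers = [np.asarray(c, dtype=float) for c in spec.pose_centers]
    n_lig = centers[0].shape[0]
    counts = _pose_frame_counts(spec.pose_weights, spec.n_frames)
    main_pose = int(np.argmax(spec.pose_weights))
    n_main = counts[main_pose]
    if n_main == 0 and spec.designed_contacts:
        raise ConstructionError("main pose received no frames; contacts "
                                "cannot be realized")

    # scaffold radius: well outside contact range of any pose
    extent = max(float(np.abs(c).max()) for c in centers)
    radius = extent + 12.0

    designed = list(spec.designed_contacts)
    n_scaffold = spec.n_background_residues + len(designed)
    angles = np.linspace(0.0, 2.0 * np.pi, n_scaffold, endpoint=False)
    z_lev = np.tile([-8.0, 0.0, 8.0], n_scaffold)[:n_scaffold]
    scaffold = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), z_lev]
    )

    # annotation table: ligand atoms, then one CA per residue, then one
    # side-chain contact atom per designed residue
    rows = []
    for a in range(n_lig):
        rows.append((len(rows) + 1, "C", 1000, "LIG", "", "", "ligand"))
    for r in range(n_scaffold):
        label = designed[r] if r < len(designed) else f"BG{r + 1}"
        rows.append((len(rows) + 1, "C", r + 1, label,
                     "", spec.loop_tags.get(label, ""), "receptor"))
    contact_atom_row = {}
    for k, label in enumerate(designed):
        contact_atom_row[label] = len(rows)
        rows.append((len(rows) + 1, "O", k + 1, label,
                     "", spec.loop_tags.get(label, ""), "receptor"))
    atoms = pd.DataFrame(
        rows,
        columns=["atom_id", "element", "residue_id", "residue_label",
                 "generic_number", "loop_tag", "segment"],
    )
    n_atoms = len(rows)

    # frame plan: frames grouped pose by pose; within the main pose the
    # first round(f * n_main) frames carry each designed contact
    pose_of_frame = np.concatenate(
        [np.full(c, p, dtype=int) for p, c in enumerate(counts)]
    ) if spec.n_frames else np.empty(0, dtype=int)
    main_frame_rank = {}  # frame index -> 0-based rank within main pose
    rank = 0
    for f, p in enumerate(pose_of_frame):
        if p == main_pose:
            main_frame_rank[f] = rank
            rank += 1
    contact_frames = {
        label: int(round(f * n_main)) for label, f in spec.designed_contacts.items()
    }

    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        p = pose_of_frame[f]
        lig = centers[p].copy()
        if spec.jitter_sd > 0:
            lig = lig + rng.normal(0.0, spec.jitter_sd, size=lig.shape)
        frame = np.empty((n_atoms, 3))
        frame[:n_lig] = lig
        frame[n_lig:n_lig + n_scaffold] = scaffold
        for label in designed:
            row = contact_atom_row[label]
            in_contact = (
                p == main_pose and main_frame_rank[f] < contact_frames[label]
            )
            if in_contact:
                frame[row] = lig[0] + np.array([0.0, 0.0, 2.0])
            else:
                res_idx = designed.index(label)
                frame[row] = scaffold[res_idx] + np.array([0.0, 0.0, 1.5])
        if spec.rigid_motion:
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-5.0, 5.0, size=3)
            frame = frame @ R.T + t
        coords[f] = frame
    return Trajectory(coords, atoms)
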