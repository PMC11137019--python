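#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream drivers.

Writes, under results/inputs/:
  bret_panel.csv        two-pathway concentration-response panel for the
                        reference agonist (5-HT-like, tau ~ 1e4 as implied
                        by logR ~ 9.5 with micromolar binding) and a test
                        ligand that is full on P1 and partial on P2
                        (triplicates, 5%-of-Em Gaussian noise)
  gtpgs_replicates.csv  replicate-level percent-of-basal sets emulating an
                        agonist, an inverse agonist and a null condition
  ligand_traj.pdb/.csv  a 20-frame trajectory with two designed ligand
                        poses (70/30) and designed residue contacts,
                        including two ECL2 residues
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from gpcrbias.io import write_concentration_response, write_trajectory
from gpcrbias.operational import OperationalParams
from gpcrbias.synth import (
    GtpSimSpec,
    ReplicateSpec,
    TrajectorySpec,
    default_pose_centers,
    simulate_concentration_response,
    simulate_gtpgs,
    simulate_trajectory,
)

PANEL = {
    ("5-HT", "P1"): OperationalParams(100, 0, -5.5, 4.0, 1),           # logR 9.5
    ("5-HT", "P2"): OperationalParams(100, 0, -5.0, 4.0, 1),           # logR 9.0
    ("drugA", "P1"): OperationalParams(100, 0, -6.0, 3.7, 1),          # logR 9.7
    ("drugA", "P2"): OperationalParams(100, 0, -6.0, np.log10(0.8), 1),  # logR 5.9
}

GTPGS = {
    ("Gi1", "drugB", "drug"): (114.9, 8.6, 6),       # agonist-like
    ("Gi1", "drugB", "drug+antagonist"): (100.5, 5.0, 6),
    ("Gi1", "drugC", "drug"): (88.0, 4.0, 6),        # inverse-agonist-like
    ("Gi1", "drugC", "drug+antagonist"): (99.0, 4.5, 6),
    ("Gi2", "drugB", "drug"): (100.8, 6.0, 6),       # null
    ("Gi2", "drugB", "drug+antagonist"): (99.5, 6.0, 6),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    datasets = {}
    for i, (key, params) in enumerate(PANEL.items()):
        datasets[key] = simulate_concentration_response(
            params, spec=ReplicateSpec(3, 5.0, args.seed + i),
            ligand_id=key[0], pathway_id=key[1])
    write_concentration_response(datasets, args.out / "bret_panel.csv")
    print(f"bret_panel.csv: {len(datasets)} ligand/pathway datasets, "
          "3 replicates x 16 concentrations each")

    rows = []
    for i, ((subunit, drug, arm), (mean, sd, n)) in enumerate(GTPGS.items()):
        for v in simulate_gtpgs(GtpSimSpec(mean, sd, n, seed=args.seed + 100 + i)):
            rows.append((subunit, drug, arm, "human", v))
    pd.DataFrame(rows, columns=["subunit", "drug", "arm", "genotype", "value"]) \
        .to_csv(args.out / "gtpgs_replicates.csv", index=False, float_format="%.6f")
    print(f"gtpgs_replicates.csv: {len(rows)} replicate values over "
          f"{len(GTPGS)} conditions")

    traj = simulate_trajectory(TrajectorySpec(
        20, default_pose_centers(2), (0.7, 0.3),
        designed_contacts={"D155": 1.0, "V156": 0.9, "F339": 0.8,
                           "L228": 0.75, "L229": 0.6, "W336": 0.4},
        loop_tags={"L228": "ECL2", "L229": "ECL2"},
        seed=args.seed))
    write_trajectory(traj, args.out / "ligand_traj.pdb",
                     args.out / "ligand_traj.csv")
    print(f"ligand_traj.pdb: {traj.n_frames} frames, "
          f"{traj.coords.shape[1]} atoms, designed 14/6 pose split")


if __name__ == "__main__":
    main()
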