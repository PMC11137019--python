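#!/usr/bin/env python
"""Logistic concentration-response fits and activity calls.

Reads results/inputs/bret_panel.csv, fits the four-parameter logistic per
(ligand, pathway), calls activity, and writes
results/dose_response/dose_response.tsv. Expected behavior on the
simulated panel: the reference and the P1 curves fit as potent full
agonists; drugA on P2 shows a partial plateau near 44% of the reference
maximum (tau = 0.8 -> plateau tau/(1+tau)).
"""

import argparse
from pathlib import Path

from gpcrbias.doseresponse import detect_activity, fit_logistic
from gpcrbias.io import load_concentration_response


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results/dose_response"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    datasets = load_concentration_response(args.inputs / "bret_panel.csv")
    lines = ["ligand\tpathway\tpec50\tpec50_se\temax\temax_se\thill\tactive\treason"]
    for (lig, pathway), ds in sorted(datasets.items()):
        f = fit_logistic(ds)
        call = detect_activity(ds, f)
        lines.append(f"{lig}\t{pathway}\t{f.pEC50:.3f}\t{f.pEC50_se:.3f}\t"
                     f"{f.Emax:.2f}\t{f.Emax_se:.2f}\t{f.hill:.3f}\t"
                     f"{call.active}\t{call.reason}")
        print(f"{lig}/{pathway}: pEC50 {f.pEC50:.2f} ± {f.pEC50_se:.2f}, "
              f"Emax {f.Emax:.1f}%, active={call.active}")
    (args.out / "dose_response.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
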