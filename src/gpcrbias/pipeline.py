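"""Report assembly: runs the requested stages and writes the bundle.

Stage order: normalize → logistic fits + activity calls → operational
fits → bias matrix, and/or GTPγS classification, and/or trajectory
clustering + contact fingerprints. All results are computed in memory
first and written at the end, so a failing stage never leaves a partial
bundle behind. Output is deterministic given (inputs, config, seed):
rows are sorted, floats use a fixed format, and the manifest records
config, seed, versions and SHA-256 checksums of every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .doseresponse import ConcentrationResponse, detect_activity, fit_logistic
from .errors import ConfigError
from .gtpgs import GtpGammaCondition, classify_effect, format_p, one_sample_t, two_sample_t
from .trajcontacts import (
    Trajectory,
    average_linkage_cluster,
    contact_frequency,
    ecl2_accumulated,
    ligand_rmsd_matrix,
    report_contacts,
)
from .transduction import TransductionTable, bias_matrix, fit_operational

log = logging.getLogger("gpcrbias")

__all__ = ["PipelineInputs", "run_pipeline", "FULL_AGONIST_FRACTION"]

FULL_AGONIST_FRACTION = 0.9  # plateau >= 90% of reference Em -> full-agonist mode
FMT = "%.6g"


@dataclass
class PipelineInputs:
    concentration_response: dict[tuple[str, str], ConcentrationResponse] | None = None
    gtpgs: list[GtpGammaCondition] | None = None
    trajectory: Trajectory | None = None
    trajectory_label: str = "ligand"


@dataclass
class ReportBundle:
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "NA"
    if isinstance(v, float):
        return FMT % v
    return str(v)


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _dose_response_stage(cfg: RunConfig, datasets):
    """Logistic fits, activity calls, then operational fits and the
    transduction table referenced to the configured agonist."""
    keys = sorted(datasets)
    ligands = sorted({k[0] for k in keys})
    pathways = sorted({k[1] for k in keys})
    if cfg.reference_ligand not in ligands:
        raise ConfigError(
            f"reference ligand {cfg.reference_ligand!r} absent from the data")
    fits, activity = {}, {}
    for key in keys:
        f = fit_logistic(datasets[key])
        fits[key] = f
        activity[key] = detect_activity(datasets[key], f, cfg.emax_floor, cfg.alpha)
        log.info("logistic %s/%s pEC50=%.3g active=%s", key[0], key[1],
                 f.pEC50, activity[key].active)

    ref_rec = cfg.ligand(cfg.reference_ligand)
    ref_logka = -ref_rec.pKi if (ref_rec and ref_rec.pKi is not None) else None
    table = TransductionTable(cfg.reference_ligand)
    op_fits = {}
    ref_em = {}
    for p in pathways:
        key = (cfg.reference_ligand, p)
        if key not in datasets or not activity[key].active:
            continue
        op = fit_operational(datasets[key], "full-agonist", logka_fixed=ref_logka)
        op_fits[key] = op
        ref_em[p] = op.Em
        table.set_cell(*key, op.logR, op.logR_se, True)
    for key in keys:
        lig, p = key
        if lig == cfg.reference_ligand or p not in ref_em:
            continue
        if not activity[key].active:
            table.set_cell(lig, p, active=False)
            continue
        plateau = fits[key].span
        rec = cfg.ligand(lig)
        if plateau >= FULL_AGONIST_FRACTION * ref_em[p]:
            op = fit_operational(
                datasets[key], "full-agonist",
                logka_fixed=-rec.pKi if (rec and rec.pKi is not None) else None)
        else:
            op = fit_operational(datasets[key], "partial-agonist",
                                 em_shared=ref_em[p])
        op_fits[key] = op
        table.set_cell(lig, p, op.logR, op.logR_se, True)

    dr_rows = []
    for key in keys:
        f, a = fits[key], activity[key]
        op = op_fits.get(key)
        dr_rows.append((
            key[0], key[1],
            f.pEC50 if a.active else None, f.pEC50_se if a.active else None,
            f.Emax if a.active else None, f.Emax_se if a.active else None,
            "yes" if a.active else "NA", a.reason,
            op.logR if op else None, op.logR_se if op else None,
        ))
    grid = bias_matrix(table, confidence=cfg.confidence)
    bias_rows = []
    for (lig, p1, p2) in sorted(grid):
        b = grid[(lig, p1, p2)]
        bias_rows.append((
            lig, p1, p2,
            b.deltadelta.value if b.defined else None,
            b.deltadelta.se if b.defined else None,
            b.bias_factor if b.defined else None,
            "yes" if b.defined else "no", b.direction,
        ))
    return dr_rows, bias_rows


def _gtpgs_stage(cfg: RunConfig, conditions):
    by_key = {}
    for c in conditions:
        by_key.setdefault((c.drug, c.subunit, c.genotype), {})[c.arm] = c
    rows = []
    for (drug, subunit, genotype) in sorted(by_key):
        arms = by_key[(drug, subunit, genotype)]
        base = arms.get("drug")
        if base is None:
            continue
        vs_basal = one_sample_t(*base.summary)
        blocked = arms.get("drug+antagonist")
        blocked_t = one_sample_t(*blocked.summary) if blocked else None
        between = two_sample_t(base, blocked, cfg.t_variant) if blocked else None
        call = classify_effect(vs_basal, blocked_t, between, cfg.alpha)
        rows.append((
            drug, subunit, genotype,
            base.mean, base.sem, base.n, format_p(vs_basal.p, cfg.alpha),
            blocked.mean if blocked else None,
            blocked.sem if blocked else None,
            blocked.n if blocked else None,
            format_p(blocked_t.p, cfg.alpha) if blocked_t else "NA",
            format_p(between.p, cfg.alpha) if between else "NA",
            call.effect, call.mediation,
        ))
    return rows


def _trajectory_stage(cfg: RunConfig, traj: Trajectory, label: str):
    m = ligand_rmsd_matrix(traj)
    clustering = average_linkage_cluster(m, cfg.rmsd_cutoff)
    fp = contact_frequency(traj, clustering.main_frames, cfg.contact_distance)
    reported = report_contacts(fp, cfg.frequency_threshold)
    try:
        ecl2 = ecl2_accumulated(fp, traj.atoms)
    except Exception:
        ecl2 = None
    fp_rows = [
        (label, rid, fp.residue_labels.get(rid, ""), freq)
        for rid, freq in reported
    ]
    n_clusters = int(np.unique(clustering.labels).size)
    summary = (label, n_clusters, int(clustering.main_frames.size),
               traj.n_frames, ecl2)
    return fp_rows, summary


def run_pipeline(config: RunConfig, inputs: PipelineInputs, out_dir) -> ReportBundle:
    """Execute the configured stages and write the report bundle."""
    out_dir = Path(out_dir)
    outputs: dict[str, tuple[list[str], list[tuple]]] = {}

    if inputs.concentration_response:
        dr_rows, bias_rows = _dose_response_stage(config, inputs.concentration_response)
        outputs["dose_response.tsv"] = (
            ["ligand", "pathway", "pec50", "pec50_se", "emax", "emax_se",
             "active", "reason", "logr", "logr_se"], dr_rows)
        outputs["bias_factors.tsv"] = (
            ["ligand", "pathway1", "pathway2", "deltadelta", "se", "factor",
             "defined", "direction"], bias_rows)
    if inputs.gtpgs:
        outputs["gtpgs_classification.tsv"] = (
            ["drug", "subunit", "genotype", "mean", "sem", "n", "p_vs_basal",
             "blocked_mean", "blocked_sem", "blocked_n", "blocked_p_vs_basal",
             "p_between", "effect", "mediation"],
            _gtpgs_stage(config, inputs.gtpgs))
    if inputs.trajectory is not None:
        fp_rows, summary = _trajectory_stage(config, inputs.trajectory,
                                             inputs.trajectory_label)
        outputs["contact_fingerprint.tsv"] = (
            ["ligand", "residue_id", "residue_label", "frequency_pct"], fp_rows)
        outputs["cluster_summary.tsv"] = (
            ["ligand", "n_clusters", "main_cluster_frames", "total_frames",
             "ecl2_accumulated_pct"], [summary])
    if not outputs:
        raise ConfigError("no inputs supplied to the pipeline")

    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir)
    checksums = {}
    for name, (header, rows) in sorted(outputs.items()):
        path = out_dir / name
        _write_tsv(path, header, rows)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        bundle.files[name] = path
    manifest = {
        "package": "gpcrbias",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "checksums": checksums,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle.files["manifest.json"] = mpath
    return bundle
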