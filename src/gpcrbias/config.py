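"""Run configuration and ligand metadata."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError

__all__ = ["LigandRecord", "RunConfig"]


@dataclass(frozen=True)
class LigandRecord:
    """Ligand metadata carried through reports.

    pKi is binding-affinity metadata (−log10 molar); when present it
    anchors the fixed K_A of full-agonist operational fits.
    """

    ligand_id: str
    display_name: str = ""
    pKi: float | None = None
    is_reference: bool = False


@dataclass
class RunConfig:
    """Thresholds and knobs for one analysis run.

    Defaults: clustering cut 5 Å, contact cut 3 Å, reporting threshold
    50%, significance 0.05, pooled two-sample t, seed 42.
    """

    reference_ligand: str = "5-HT"
    alpha: float = 0.05
    emax_floor: float = 10.0
    rmsd_cutoff: float = 5.0
    contact_distance: float = 3.0
    frequency_threshold: float = 50.0
    t_variant: str = "pooled"
    confidence: float = 0.95
    seed: int = 42
    ligands: list[LigandRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("emax_floor", "rmsd_cutoff", "contact_distance",
                     "frequency_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.t_variant not in ("pooled", "welch"):
            raise ConfigError(f"t_variant must be pooled or welch, got {self.t_variant}")
        refs = [l for l in self.ligands if l.is_reference]
        if self.ligands:
            if len(refs) != 1:
                raise ConfigError(
                    f"exactly one reference ligand required, found {len(refs)}")
            if refs[0].ligand_id != self.reference_ligand:
                raise ConfigError(
                    f"reference_ligand {self.reference_ligand!r} does not match "
                    f"the flagged record {refs[0].ligand_id!r}")

    def ligand(self, ligand_id: str) -> LigandRecord | None:
        for l in self.ligands:
            if l.ligand_id == ligand_id:
                return l
        return None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ligands = [LigandRecord(**l) for l in raw.pop("ligands", [])]
        return cls(ligands=ligands, **raw)
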