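"""Transduction coefficients and ligand bias factors.

The chain implemented here is the standard operational-model bias
workflow for a multi-pathway agonist panel:

1. fit the operational model per ligand/pathway to obtain the
   transduction coefficient ``logR = log10(tau / K_A)`` with its
   standard error;
2. reference each pathway to the endogenous agonist,
   ``Δlog(τ/K_A) = logR_ligand - logR_reference`` (system and
   observation bias cancel in this difference);
3. compare two pathways for one ligand,
   ``ΔΔlog(τ/K_A) = Δ(pathway1) - Δ(pathway2)``;
4. report the bias factor ``10^ΔΔ`` with a normal-approximation CI.

A pathway on which a ligand shows no measurable activity propagates as
an *undefined* bias cell rather than a number — no formal bias factor
exists without activation on both pathways.

Identifiability: for a full agonist (plateau at the system maximum)
``tau`` and ``K_A`` cannot be separated; ``logKA`` is then fixed (at the
ligand's binding pKi when known, else -6) and only ``logR`` is reported.
``logR`` itself is insensitive to that choice, which is why referenced
differences are the quantity of record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .doseresponse import ActivityCall, ConcentrationResponse
from .errors import ContractError, InactiveInputError
from .operational import operational_response

__all__ = [
    "Estimate",
    "OperationalFit",
    "TransductionTable",
    "BiasResult",
    "fit_operational",
    "delta_log",
    "delta_delta_log",
    "bias_factor",
    "bias_matrix",
]

DEFAULT_LOGKA_FULL = -6.0
N_STARTS = 5


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its standard error."""

    value: float
    se: float

    def __sub__(self, other: "Estimate") -> "Estimate":
        return Estimate(self.value - other.value,
                        math.hypot(self.se, other.se))


@dataclass
class OperationalFit:
    """Operational-model fit for one ligand/pathway dataset."""

    logR: float
    logR_se: float
    logKA: float
    Em: float
    basal: float
    n_slope: float
    converged: bool
    constraint_mode: str  # full-agonist | partial-agonist
    rss: float = np.nan
    ligand_id: str | None = None
    pathway_id: str | None = None

    @property
    def logTau(self) -> float:
        return self.logR + self.logKA

    @property
    def estimate(self) -> Estimate:
        return Estimate(self.logR, self.logR_se)


@dataclass
class TransductionTable:
    """Per-(ligand, pathway) grid of transduction coefficients."""

    reference_ligand: str
    grid: dict[tuple[str, str], tuple[float, float, bool]] = field(default_factory=dict)
    # (ligand, pathway) -> (logR, se, active)

    def set_cell(self, ligand: str, pathway: str,
                 logR: float = np.nan, se: float = np.nan,
                 active: bool = True) -> None:
        if not active:
            logR, se = np.nan, np.nan  # inactive cells carry no coefficient
        self.grid[(ligand, pathway)] = (logR, se, active)

    def pathways(self) -> list[str]:
        return sorted({p for (_, p) in self.grid})

    def ligands(self) -> list[str]:
        return sorted({l for (l, _) in self.grid})

    def cell(self, ligand: str, pathway: str) -> tuple[float, float, bool]:
        return self.grid[(ligand, pathway)]


@dataclass
class BiasResult:
    """Bias of one ligand between two pathways, relative to the reference."""

    ligand: str
    pathway_pair: tuple[str, str]
    delta1: Estimate | None
    delta2: Estimate | None
    deltadelta: Estimate | None
    bias_factor: float
    ci_low: float
    ci_high: float
    defined: bool
    direction: str  # toward-p1 | toward-p2 | unbiased | undefined


def _fit_once(x, y, params, n_slope):
    model = lmfit.Model(
        lambda x, logR, logKA, Em, basal: operational_response(
            x, Em, basal, logKA, logR + logKA, n_slope
        )
    )
    return model.fit(y, params, x=x)


def fit_operational(
    data: ConcentrationResponse,
    mode: str = "full-agonist",
    em_shared: float | None = None,
    logka_fixed: float | None = None,
    n_slope: float = 1.0,
    basal_fixed: float = 0.0,
    activity: ActivityCall | None = None,
) -> OperationalFit:
    """Fit the operational model, parameterized directly in logR.

    full-agonist mode: ``logKA`` is fixed (``logka_fixed`` — the ligand's
    binding pKi when available — else -6) and ``logR`` and ``Em`` are
    fitted; the potency of the curve is absorbed into ``logR``.

    partial-agonist mode: ``Em`` is fixed at the reference curve's system
    maximum (``em_shared``, required) and ``logR`` and ``logKA`` are
    jointly fitted — both are identifiable from plateau plus potency.
    """
    if activity is not None and not activity.active:
        raise InactiveInputError(
            f"{data.ligand_id}/{data.pathway_id}: refusing operational fit on "
            f"data called inactive ({activity.reason})"
        )
    if mode not in ("full-agonist", "partial-agonist"):
        raise ContractError(f"unknown constraint mode {mode!r}")
    if mode == "partial-agonist" and em_shared is None:
        raise ContractError("partial-agonist mode requires em_shared from the "
                            "reference curve")
    data.require_fittable()
    x, y = data.log_conc, data.response

    # crude potency guess: concentration where the response crosses half-range
    half = (np.min(y) + np.max(y)) / 2.0
    order = np.argsort(x)
    xo, yo = x[order], y[order]
    above = np.nonzero(yo >= half)[0]
    pec50_guess = -float(xo[above[0]]) if above.size else -float(np.median(xo))

    logka0 = DEFAULT_LOGKA_FULL if logka_fixed is None else logka_fixed
    best = None
    for offset in np.linspace(-2.0, 2.0, N_STARTS):
        params = lmfit.Parameters()
        params.add("logR", value=pec50_guess + offset, min=-5, max=25)
        if mode == "full-agonist":
            params.add("logKA", value=logka0, vary=False)
            params.add("Em", value=float(np.max(y)), min=1e-6,
                       max=4 * float(np.max(np.abs(y))) + 100)
        else:
            params.add("logKA", value=-6.0 + offset / 2.0, min=-14, max=0)
            params.add("Em", value=em_shared, vary=False)
        params.add("basal", value=basal_fixed, vary=False)
        try:
            res = _fit_once(x, y, params, n_slope)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return OperationalFit(np.nan, np.nan, logka0, np.nan, basal_fixed, n_slope,
                              False, mode, np.nan, data.ligand_id, data.pathway_id)
    p = best.params
    se = p["logR"].stderr
    return OperationalFit(
        logR=float(p["logR"].value),
        logR_se=float(se) if se else np.nan,
        logKA=float(p["logKA"].value),
        Em=float(p["Em"].value),
        basal=float(p["basal"].value),
        n_slope=n_slope,
        converged=bool(best.success),
        constraint_mode=mode,
        rss=float(best.chisqr),
        ligand_id=data.ligand_id,
        pathway_id=data.pathway_id,
    )


def delta_log(ligand_fit: OperationalFit, reference_fit: OperationalFit) -> Estimate:
    """Δlog(τ/K_A) of a ligand vs the reference agonist on one pathway."""
    if (
        ligand_fit.pathway_id is not None
        and reference_fit.pathway_id is not None
        and ligand_fit.pathway_id != reference_fit.pathway_id
    ):
        raise ContractError(
            f"pathway mismatch: {ligand_fit.pathway_id} vs {reference_fit.pathway_id}"
        )
    return ligand_fit.estimate - reference_fit.estimate


def delta_delta_log(d1: Estimate, d2: Estimate,
                    pathway1: str | None = None,
                    pathway2: str | None = None) -> Estimate:
    """ΔΔlog(τ/K_A) between two pathways; antisymmetric under swap."""
    if pathway1 is not None and pathway1 == pathway2:
        raise ContractError(f"identical pathways: {pathway1}")
    return d1 - d2


def bias_factor(
    dd: Estimate,
    confidence: float = 0.95,
    ligand: str = "",
    pathway_pair: tuple[str, str] = ("", ""),
    delta1: Estimate | None = None,
    delta2: Estimate | None = None,
) -> BiasResult:
    """Bias factor 10^ΔΔ with a normal-approximation confidence interval.

    The call is 'unbiased' when the CI spans 1 (ΔΔ indistinguishable from
    zero), else toward whichever pathway the factor favors.
    """
    if not math.isfinite(dd.value):
        raise ContractError("ΔΔlog(τ/K_A) must be finite")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    factor = 10.0 ** dd.value
    if math.isfinite(dd.se):
        lo, hi = 10.0 ** (dd.value - z * dd.se), 10.0 ** (dd.value + z * dd.se)
    else:
        lo, hi = np.nan, np.nan
    if not math.isfinite(lo) or (lo <= 1.0 <= hi):
        direction = "unbiased"
    elif factor > 1.0:
        direction = "toward-p1"
    else:
        direction = "toward-p2"
    return BiasResult(ligand, pathway_pair, delta1, delta2, dd,
                      factor, lo, hi, True, direction)


def _undefined(ligand: str, pair: tuple[str, str]) -> BiasResult:
    return BiasResult(ligand, pair, None, None, None,
                      np.nan, np.nan, np.nan, False, "undefined")


def bias_matrix(
    table: TransductionTable, reference: str | None = None, confidence: float = 0.95
) -> dict[tuple[str, str, str], BiasResult]:
    """All-pairs bias grid: (ligand, pathway1, pathway2) -> BiasResult.

    Cells touching a pathway on which the ligand is inactive come back
    defined=False (the 'no formal bias factor' state). The reference
    ligand must be active on every pathway present in the grid.
    """
    ref = table.reference_ligand if reference is None else reference
    pathways = table.pathways()
    for p in pathways:
        if (ref, p) not in table.grid:
            raise ContractError(f"reference ligand {ref!r} has no cell on {p!r}")
        if not table.grid[(ref, p)][2]:
            raise ContractError(f"reference ligand {ref!r} inactive on {p!r}")
    out: dict[tuple[str, str, str], BiasResult] = {}
    for ligand in table.ligands():
        for p1 in pathways:
            for p2 in pathways:
                if p1 == p2:
                    continue
                key = (ligand, p1, p2)
                c1 = table.grid.get((ligand, p1))
                c2 = table.grid.get((ligand, p2))
                if c1 is None or c2 is None or not (c1[2] and c2[2]):
                    out[key] = _undefined(ligand, (p1, p2))
                    continue
                r1 = table.grid[(ref, p1)]
                r2 = table.grid[(ref, p2)]
                d1 = Estimate(c1[0], c1[1]) - Estimate(r1[0], r1[1])
                d2 = Estimate(c2[0], c2[1]) - Estimate(r2[0], r2[1])
                dd = delta_delta_log(d1, d2, p1, p2)
                out[key] = bias_factor(dd, confidence, ligand, (p1, p2), d1, d2)
    return out
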