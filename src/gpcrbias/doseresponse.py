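"""Four-parameter logistic concentration–response analysis.

Responses are expressed as % of the reference agonist's maximal response
(for a serotonin-receptor panel, 5-HT defines 100%). Each ligand/pathway
dataset is fitted with the four-parameter logistic

    E(x) = basal + (Emax - basal) / (1 + 10^((logEC50 - x) * hill))

where ``x`` is log10 molar concentration, yielding the pEC50/Emax pair
reported in functional-selectivity tables, plus an activity call that
reproduces the "no activity" (NA) bookkeeping for flat or negligible
curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidReferenceError

__all__ = [
    "ConcentrationResponse",
    "LogisticFit",
    "ActivityCall",
    "logistic_response",
    "normalize_to_reference",
    "fit_logistic",
    "detect_activity",
]

HILL_BOUNDS = (0.3, 5.0)
N_STARTS = 5


@dataclass
class ConcentrationResponse:
    """Replicate-level dose–response points for one ligand on one pathway.

    ``points`` rows are (replicate_id, log10_conc_M, response_pct).
    """

    ligand_id: str
    pathway_id: str
    points: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        x = self.log_conc
        y = self.response
        if x.size and not np.all(np.isfinite(y)):
            raise ValueError(f"{self.ligand_id}/{self.pathway_id}: non-finite responses")
        if x.size and np.any(x >= 0):
            warnings.warn(
                f"{self.ligand_id}/{self.pathway_id}: concentrations at or above 1 M "
                "on the log10-molar scale look unphysiological",
                stacklevel=2,
            )

    @property
    def log_conc(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    @property
    def response(self) -> np.ndarray:
        return np.array([p[2] for p in self.points], dtype=float)

    @property
    def n_distinct_conc(self) -> int:
        return np.unique(self.log_conc).size

    def require_fittable(self) -> None:
        if self.n_distinct_conc < 4:
            raise InsufficientDataError(
                f"{self.ligand_id}/{self.pathway_id}: need >= 4 distinct "
                f"concentrations, got {self.n_distinct_conc}"
            )


@dataclass
class LogisticFit:
    """Result of a four-parameter logistic fit."""

    pEC50: float
    pEC50_se: float
    Emax: float
    Emax_se: float
    basal: float
    hill: float
    converged: bool
    rss: float
    n_points: int
    extrapolated: bool = False

    @property
    def span(self) -> float:
        return self.Emax - self.basal


@dataclass
class ActivityCall:
    """Whether a ligand measurably activates a pathway, and why not."""

    active: bool
    reason: str  # converged-fit | flat-curve | below-floor

    def __post_init__(self) -> None:
        if self.active != (self.reason == "converged-fit"):
            raise ValueError("active flag inconsistent with reason")


def logistic_response(x, basal, emax, pec50, hill):
    """Four-parameter logistic at log10 molar concentration x."""
    x = np.asarray(x, dtype=float)
    return basal + (emax - basal) / (1.0 + 10.0 ** ((-pec50 - x) * hill))


def normalize_to_reference(raw: np.ndarray, reference_max: float) -> np.ndarray:
    """Rescale raw responses to % of the reference agonist's maximum."""
    if not (math.isfinite(reference_max) and reference_max > 0):
        raise InvalidReferenceError(f"reference_max must be > 0, got {reference_max}")
    return 100.0 * np.asarray(raw, dtype=float) / reference_max


def _start_points(x: np.ndarray, y: np.ndarray) -> list[dict]:
    """Multi-start initial guesses: pEC50 at quantiles of the sampled range."""
    quantiles = np.quantile(-x, np.linspace(0.1, 0.9, N_STARTS))
    lo, hi = float(np.min(y)), float(np.max(y))
    return [
        {"basal": lo, "emax": hi, "pec50": float(q), "hill": 1.0} for q in quantiles
    ]


def fit_logistic(
    data: ConcentrationResponse, hill_fixed: float | None = None
) -> LogisticFit:
    """Fit the four-parameter logistic to pooled replicate points.

    Five quantile-spaced pEC50 starts are tried and the lowest-RSS solution
    kept, so the converged flag reflects genuine convergence rather than a
    lucky start. Standard errors come from the fit covariance; a singular
    covariance leaves the estimates in place with NaN standard errors.
    """
    data.require_fittable()
    x, y = data.log_conc, data.response
    yspan = max(float(np.ptp(y)), 1e-12)
    ylo, yhi = float(np.min(y)), float(np.max(y))

    model = lmfit.Model(logistic_response)
    best = None
    for start in _start_points(x, y):
        params = model.make_params(**start)
        # plateau bounds scale with the data so the fit is scale-equivariant
        params["basal"].set(min=ylo - 2 * yspan, max=yhi + 2 * yspan)
        params["emax"].set(min=ylo - 2 * yspan, max=yhi + 2 * yspan)
        params["pec50"].set(min=float(np.min(-x)) - 3.0, max=float(np.max(-x)) + 3.0)
        if hill_fixed is not None:
            params["hill"].set(value=hill_fixed, vary=False)
        else:
            params["hill"].set(min=HILL_BOUNDS[0], max=HILL_BOUNDS[1])
        try:
            res = model.fit(y, params, x=x)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False,
                           np.nan, len(y))

    p = best.params
    pec50 = float(p["pec50"].value)
    lo_edge, hi_edge = float(np.min(-x)), float(np.max(-x))
    extrapolated = not (lo_edge - 1.0 <= pec50 <= hi_edge + 1.0)
    return LogisticFit(
        pEC50=pec50,
        pEC50_se=float(p["pec50"].stderr) if p["pec50"].stderr else np.nan,
        Emax=float(p["emax"].value),
        Emax_se=float(p["emax"].stderr) if p["emax"].stderr else np.nan,
        basal=float(p["basal"].value),
        hill=float(p["hill"].value),
        converged=bool(best.success),
        rss=float(best.chisqr),
        n_points=len(y),
        extrapolated=extrapolated,
    )


def detect_activity(
    data: ConcentrationResponse,
    fit: LogisticFit,
    emax_floor: float = 10.0,
    alpha: float = 0.05,
) -> ActivityCall:
    """Call a ligand/pathway pair active or not (the NA bookkeeping).

    Inactive when (a) an F-test of the logistic against a constant-mean
    model is non-significant at ``alpha`` (flat-curve), or (b) the fitted
    span Emax - basal falls below ``emax_floor`` % of the reference
    maximum (below-floor).
    """
    y = data.response
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = fit.rss
    k1 = 4  # logistic parameter count
    if not fit.converged or not math.isfinite(rss1):
        return ActivityCall(False, "flat-curve")
    dof = n - k1
    if dof <= 0:
        return ActivityCall(False, "flat-curve")
    if rss1 <= 1e-300:
        p_flat = 0.0
    else:
        f = ((rss0 - rss1) / (k1 - 1)) / (rss1 / dof)
        p_flat = float(stats.f.sf(max(f, 0.0), k1 - 1, dof))
    if p_flat >= alpha:
        return ActivityCall(False, "flat-curve")
    if fit.span < emax_floor:
        return ActivityCall(False, "below-floor")
    return ActivityCall(True, "converged-fit")
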