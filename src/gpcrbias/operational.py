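"""Black–Leff operational model of agonism.

The operational model separates what a ligand *is* at a receptor (its
functional affinity ``K_A``) from what it *does* (its efficacy ``tau``,
the ratio of receptor density to the receptor occupancy producing
half-maximal system response):

    E = basal + (Em - basal) * tau^n A^n / ((A + K_A)^n + tau^n A^n)

with ``A`` the agonist concentration (molar), ``Em`` the maximal response
the system can produce, and ``n`` the slope of the transducer function.
The single-number summary used for bias work is the transduction
coefficient ``log10(tau / K_A)``.

This module holds the forward model and its closed-form observables;
:mod:`gpcrbias.synth` uses it to generate data and
:mod:`gpcrbias.transduction` to fit it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "OperationalParams",
    "operational_response",
    "observed_emax",
    "observed_ec50",
    "observed_pec50",
]


@dataclass(frozen=True)
class OperationalParams:
    """Parameters of one ligand/pathway operational curve.

    Em and basal are on the normalized response scale (% of the reference
    agonist maximum); logKA is log10 molar; logTau is dimensionless.
    """

    Em: float
    basal: float
    logKA: float
    logTau: float
    n_slope: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.Em, self.basal, self.logKA, self.logTau, self.n_slope)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite operational parameters: {vals}")
        if self.Em <= self.basal:
            raise InvalidParameterError(
                f"Em ({self.Em}) must exceed basal ({self.basal})"
            )
        if self.n_slope <= 0:
            raise InvalidParameterError(f"n_slope must be > 0, got {self.n_slope}")

    @property
    def logR(self) -> float:
        """Transduction coefficient log10(tau / K_A)."""
        return self.logTau - self.logKA

    @property
    def tau(self) -> float:
        return 10.0 ** self.logTau

    @property
    def KA(self) -> float:
        return 10.0 ** self.logKA


def operational_response(
    log10_conc: np.ndarray | float,
    Em: float,
    basal: float,
    logKA: float,
    logTau: float,
    n_slope: float = 1.0,
) -> np.ndarray | float:
    """Evaluate the operational curve at log10 molar concentration(s)."""
    A = np.power(10.0, np.asarray(log10_conc, dtype=float))
    tau = 10.0 ** logTau
    KA = 10.0 ** logKA
    stim = (tau * A) ** n_slope
    out = basal + (Em - basal) * stim / ((A + KA) ** n_slope + stim)
    if np.ndim(log10_conc) == 0:
        return float(out)
    return out


def observed_emax(Em: float, basal: float, logTau: float, n_slope: float = 1.0) -> float:
    """Asymptotic plateau: basal + (Em - basal) * tau^n / (1 + tau^n)."""
    tn = (10.0 ** logTau) ** n_slope
    return basal + (Em - basal) * tn / (1.0 + tn)


def observed_ec50(logKA: float, logTau: float, n_slope: float = 1.0) -> float:
    """Half-plateau concentration (molar): K_A / ((2 + tau^n)^(1/n) - 1)."""
    tn = (10.0 ** logTau) ** n_slope
    return (10.0 ** logKA) / ((2.0 + tn) ** (1.0 / n_slope) - 1.0)


def observed_pec50(logKA: float, logTau: float, n_slope: float = 1.0) -> float:
    return -math.log10(observed_ec50(logKA, logTau, n_slope))
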