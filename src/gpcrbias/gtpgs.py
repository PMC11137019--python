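"""[35S]GTPγS percent-of-basal statistics and pharmacological calls.

In the antibody-capture [35S]GTPγS scintillation proximity assay, basal
nucleotide loading onto each immunocaptured Gα subunit defines 100%; a
drug is an *agonist* on a subunit if it significantly raises loading
above basal, an *inverse agonist* if it significantly lowers it, and
without a significant change it has *no effect*. Receptor mediation is
probed by co-incubation with a selective neutral antagonist (or by
receptor-knockout tissue): a significant drug-vs-blocked difference with
the blocked arm back at basal is *complete* mediation, with the blocked
arm still shifted it is *partial*, and no drug-vs-blocked difference
means the effect is *not* mediated by the blocked receptor.

Because each subunit is captured with its own antibody and GDP
conditions, the approach is semiquantitative across subunits: no
operation here accepts two different subunits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ContractError, InvalidBasalError, InvalidDispersionError

__all__ = [
    "GtpGammaCondition",
    "TTestResult",
    "EffectCall",
    "percent_of_basal",
    "one_sample_t",
    "two_sample_t",
    "classify_effect",
    "format_p",
]


@dataclass
class GtpGammaCondition:
    """One drug/arm/genotype condition on one Gα subunit.

    Data may be replicate-level (% of basal values) or summary-level
    (mean, SEM, n). When replicates are given the summary is derived
    from them; a supplied summary must then agree to 1e-9.
    """

    subunit: str
    drug: str
    arm: str = "drug"            # drug | drug+antagonist
    genotype: str = "human"      # WT | KO | human
    replicates: list[float] | None = None
    mean: float | None = None
    sem: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.replicates is not None:
            reps = np.asarray(self.replicates, dtype=float)
            if reps.size < 2:
                raise InvalidDispersionError("need n >= 2 replicates")
            m = float(reps.mean())
            s = float(reps.std(ddof=1) / math.sqrt(reps.size))
            for given, derived, name in ((self.mean, m, "mean"),
                                         (self.sem, s, "sem"),
                                         (self.n, reps.size, "n")):
                if given is not None and abs(given - derived) > 1e-9:
                    raise ContractError(
                        f"supplied {name} ({given}) disagrees with replicate-"
                        f"derived value ({derived})")
            self.mean, self.sem, self.n = m, s, int(reps.size)
        if self.n is None or self.n < 2:
            raise InvalidDispersionError(f"need n >= 2, got {self.n}")
        if self.sem is None or self.sem <= 0:
            raise InvalidDispersionError(f"SEM must be > 0, got {self.sem}")

    @property
    def summary(self) -> tuple[float, float, int]:
        return float(self.mean), float(self.sem), int(self.n)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    direction: str  # increase | decrease | none

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


def _direction(t: float) -> str:
    if t > 0:
        return "increase"
    if t < 0:
        return "decrease"
    return "none"


def percent_of_basal(raw: np.ndarray, basal_mean: float) -> np.ndarray:
    """Express raw binding values as % of the basal mean (basal = 100%)."""
    if not (math.isfinite(basal_mean) and basal_mean > 0):
        raise InvalidBasalError(f"basal mean must be > 0, got {basal_mean}")
    return 100.0 * np.asarray(raw, dtype=float) / basal_mean


def one_sample_t(mean: float, sem: float, n: int, mu0: float = 100.0) -> TTestResult:
    """Two-tailed one-sample Student t-test against basal from summary stats."""
    if sem <= 0:
        raise InvalidDispersionError(f"SEM must be > 0, got {sem}")
    if n < 2:
        raise InvalidDispersionError(f"need n >= 2, got {n}")
    t = (mean - mu0) / sem
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t, df, p, _direction(t))


def two_sample_t(
    a: GtpGammaCondition | tuple[float, float, int],
    b: GtpGammaCondition | tuple[float, float, int],
    variant: str = "pooled",
) -> TTestResult:
    """Two-tailed two-sample t-test between conditions from summary stats.

    ``pooled`` is classic Student (equal-variance, df = n_a + n_b - 2);
    ``welch`` uses the Welch–Satterthwaite correction. Both operands must
    concern the same Gα subunit when that metadata is present.
    """
    if isinstance(a, GtpGammaCondition) and isinstance(b, GtpGammaCondition):
        if a.subunit != b.subunit:
            raise ContractError(
                f"cross-subunit comparison disallowed: {a.subunit} vs {b.subunit}")
    ma, sa, na = a.summary if isinstance(a, GtpGammaCondition) else a
    mb, sb, nb = b.summary if isinstance(b, GtpGammaCondition) else b
    if sa <= 0 or sb <= 0:
        raise InvalidDispersionError("SEMs must be > 0")
    if variant not in ("pooled", "welch"):
        raise ContractError(f"unknown t-test variant {variant!r}")
    sd_a, sd_b = sa * math.sqrt(na), sb * math.sqrt(nb)
    res = stats.ttest_ind_from_stats(
        ma, sd_a, na, mb, sd_b, nb, equal_var=(variant == "pooled")
    )
    t = float(res.statistic)
    va, vb = sa * sa, sb * sb  # variances of the two means
    if variant == "pooled":
        df = float(na + nb - 2)
    else:
        df = (va + vb) ** 2 / (va * va / (na - 1) + vb * vb / (nb - 1))
    return TTestResult(t, df, float(res.pvalue), _direction(t))


@dataclass
class EffectCall:
    effect: str      # agonist | inverse-agonist | no-effect
    mediation: str   # complete | partial | none | undetermined
    alpha: float

    def __post_init__(self) -> None:
        if self.effect == "no-effect" and self.mediation != "undetermined":
            raise ValueError("no-effect implies undetermined mediation")


def classify_effect(
    vs_basal: TTestResult,
    blocked_vs_basal: TTestResult | None = None,
    between: TTestResult | None = None,
    alpha: float = 0.05,
) -> EffectCall:
    """Pharmacological call from the three t-tests of one subunit/drug.

    Effect: the drug-alone arm vs basal (increase -> agonist, decrease ->
    inverse agonist, non-significant -> no effect). Mediation, from the
    antagonist-blocked (or knockout) arm: complete when the between-arm
    difference is significant and the blocked arm no longer differs from
    basal; partial when both are significant; none when the arms do not
    differ. With no blocked arm supplied, mediation is undetermined.
    """
    if vs_basal.p >= alpha or vs_basal.direction == "none":
        return EffectCall("no-effect", "undetermined", alpha)
    effect = "agonist" if vs_basal.direction == "increase" else "inverse-agonist"
    if between is None or blocked_vs_basal is None:
        return EffectCall(effect, "undetermined", alpha)
    if between.p >= alpha:
        mediation = "none"
    elif blocked_vs_basal.p >= alpha:
        mediation = "complete"
    else:
        mediation = "partial"
    return EffectCall(effect, mediation, alpha)


def format_p(p: float, alpha: float = 0.05, ns_label: bool = True) -> str:
    """Render a p value in report style: 3 decimals, '<0.0001' tail, 'ns'."""
    if ns_label and p >= alpha:
        return "ns"
    if p < 1e-4:
        return "<0.0001"
    if round(p, 3) == 0.0:
        return "<0.001"
    return f"{p:.3f}"
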