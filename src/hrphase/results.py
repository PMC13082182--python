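"""Shared result containers for single-model fits."""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AssociationResult:
    """One regression association (SNV, condition or exposure).

    ``beta`` is on the reported scale: minutes of phase per alternate
    allele for genotype-phase fits, log-odds per unit exposure for
    logistic fits.  ``p_adjusted`` is Bonferroni: min(1, p * m).
    """

    target: str
    beta: float
    se: float
    p: float
    p_adjusted: float
    n: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    converged: bool = True
    flag: str = ""

    @property
    def odds_ratio(self) -> float:
        import math
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        import math
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class GroupComparison:
    """Two-group comparison: Cohen's d with CI plus the rank/t test.

    Sign convention: d = (mean of group 1 - mean of group 2) / pooled SD.
    """

    cohens_d: float
    ci_low: float
    ci_high: float
    test: str           # "welch_t" or "mann_whitney"
    statistic: float
    p: float
    n1: int
    n2: int
    flag: str = ""
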