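"""Result containers shared across the estimator, MVMR and mediation layers.

All causal effects for a binary outcome are on the log-odds scale per
1-unit increase of the exposure; ``odds_ratio`` fields carry the
exponentiated estimate. Confidence intervals use the conventional
``theta ± 1.96·se`` normal interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

Z95 = 1.96  # conventional 95% normal multiplier


def wald_pvalue(theta: float, se: float) -> float:
    """Two-sided normal p-value for a Wald test of theta = 0."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2 * stats.norm.sf(abs(theta) / se))


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Recover the standard error from a reported 95% normal interval."""
    if ci_high <= ci_low:
        raise ValueError("ci_high must exceed ci_low")
    return (ci_high - ci_low) / (2 * Z95)


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty.

    ``theta`` is on the log-odds (or trait-unit) scale; ``odds_ratio``
    and its CI are populated when the outcome is binary.
    """

    method: str
    theta: float
    se: float
    pvalue: float
    n_snp: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        self.ci_low = self.theta - Z95 * self.se
        self.ci_high = self.theta + Z95 * self.se

    def with_or_scale(self) -> "MREstimate":
        """Populate the odds-ratio fields (binary outcome)."""
        self.odds_ratio = math.exp(self.theta)
        self.or_ci_low = math.exp(self.ci_low)
        self.or_ci_high = math.exp(self.ci_high)
        return self

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snp": self.n_snp,
        }
        if self.odds_ratio is not None:
            d.update(
                odds_ratio=self.odds_ratio,
                or_ci_low=self.or_ci_low,
                or_ci_high=self.or_ci_high,
            )
        return d


@dataclass
class HeterogeneityResult:
    """Cochran Q heterogeneity summary with per-variant contributions."""

    q: float
    df: int
    pvalue: float
    per_snp_q: dict[str, float]
    i2_gx: float | None = None

    @classmethod
    def from_q(
        cls,
        q: float,
        df: int,
        per_snp_q: dict[str, float] | None = None,
        i2_gx: float | None = None,
    ) -> "HeterogeneityResult":
        """Build from Q and df, computing the upper-tail χ²_df probability."""
        return cls(q, df, float(stats.chi2.sf(q, df)), per_snp_q or {}, i2_gx)

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "df": self.df,
            "pvalue": self.pvalue,
            "i2_gx": self.i2_gx,
        }


@dataclass
class EggerResult:
    """MR-Egger slope plus the directional-pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    heterogeneity: HeterogeneityResult


@dataclass
class PressoResult:
    """MR-PRESSO global test, outlier calls and outlier-corrected estimate."""

    global_rss: float
    global_p: float
    outlier_ids: list[str]
    outlier_p: dict[str, float]
    corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int


@dataclass
class MVMRResult:
    """Conditional (direct) effects from multivariable MR."""

    estimates: dict[str, MREstimate]  # exposure name -> conditional effect
    heterogeneity: HeterogeneityResult
    conditional_f: dict[str, float]
    n_snp: int


@dataclass
class MediationResult:
    """Two-step MR decomposition of a total effect into indirect and direct.

    ``indirect = alpha * beta`` with a product delta-method SE;
    ``direct = total - indirect``; ``proportion_mediated = indirect/total``
    with a ratio delta-method SE. The decomposition identities hold exactly
    by construction.
    """

    total: MREstimate
    alpha: MREstimate
    beta: MREstimate
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    direct: float
    direct_ci: tuple[float, float]
    proportion_mediated: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    inconsistent_mediation: bool

    def to_dict(self) -> dict:
        return {
            "total": self.total.to_dict(),
            "alpha": self.alpha.to_dict(),
            "beta": self.beta.to_dict(),
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "indirect_ci": list(self.indirect_ci),
            "direct": self.direct,
            "direct_ci": list(self.direct_ci),
            "proportion_mediated": self.proportion_mediated,
            "proportion_se": self.proportion_se,
            "proportion_ci": list(self.proportion_ci),
            "inconsistent_mediation": self.inconsistent_mediation,
        }
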