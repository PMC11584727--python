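"""Two-step MR mediation: decompose a total effect into indirect and direct.

The two-step design estimates the exposure→mediator path α by
univariable MR, the mediator→outcome path β by multivariable MR adjusted
for the exposure, and combines them: indirect = α·β, direct = total −
α·β, proportion mediated = α·β / total. Because the two steps use
disjoint instrument sets (and step 1 a different outcome GWAS), α̂ and β̂
are treated as uncorrelated and first-order delta-method standard errors
apply: the product and ratio formulas below.

All effects are on the log-odds scale of the outcome per unit of
exposure; for a binary mediator, α is on the mediator's log-odds scale
and β per log-odds unit, so the "proportion mediated" is the ratio of
log-odds-scale path products — an approximation for non-collapsible
binary mediators, flagged in the pipeline report.
"""

from __future__ import annotations

import math

from .results import Z95, MediationResult, MREstimate


def indirect_effect(
    alpha: tuple[float, float],
    beta: tuple[float, float],
    second_order: bool = False,
) -> tuple[float, float]:
    """Product-of-coefficients indirect effect α·β with delta-method SE.

    ``alpha`` and ``beta`` are (estimate, se) pairs assumed independent.
    First-order: se = √(α²·se_β² + β²·se_α²). The exact-product
    (second-order) variant adds the se_α²·se_β² cross term.
    """
    a, sa = alpha
    b, sb = beta
    if sa <= 0 or sb <= 0:
        raise ValueError("standard errors must be positive")
    var = a * a * sb * sb + b * b * sa * sa
    if second_order:
        var += sa * sa * sb * sb
    return a * b, math.sqrt(var)


def proportion_mediated(
    indirect: tuple[float, float],
    total: tuple[float, float],
) -> tuple[float, float, tuple[float, float]]:
    """Ratio indirect/total with an independence delta-method SE and CI.

    Values outside [0,1] are returned as-is; callers flag them as
    inconsistent mediation (e.g. opposite-sign direct and indirect
    paths, or a near-null total effect).
    """
    ind, se_ind = indirect
    tot, se_tot = total
    if tot == 0:
        raise ZeroDivisionError("proportion mediated undefined: total effect is zero")
    est = ind / tot
    var = se_ind**2 / tot**2 + ind**2 * se_tot**2 / tot**4
    se = math.sqrt(var)
    return est, se, (est - Z95 * se, est + Z95 * se)


def run_mediation(
    alpha: MREstimate,
    beta: MREstimate,
    total: MREstimate,
    second_order: bool = False,
) -> MediationResult:
    """Assemble the full decomposition from the three path estimates.

    ``alpha`` should come from univariable IVW of exposure on mediator,
    ``beta`` from MVMR of the outcome on (exposure, mediator), and
    ``total`` from univariable IVW of exposure on outcome. The
    identities indirect + direct = total and proportion =
    indirect/total hold exactly by construction.
    """
    for name, est in (("alpha", alpha), ("beta", beta), ("total", total)):
        if est is None:
            raise ValueError(f"missing mediation input: {name}")
    ind, se_ind = indirect_effect((alpha.theta, alpha.se), (beta.theta, beta.se), second_order)
    direct = total.theta - ind
    # direct-effect SE by independence of the total and indirect components
    se_dir = math.sqrt(total.se**2 + se_ind**2)
    prop, se_prop, ci_prop = proportion_mediated((ind, se_ind), (total.theta, total.se))
    return MediationResult(
        total=total,
        alpha=alpha,
        beta=beta,
        indirect=ind,
        indirect_se=se_ind,
        indirect_ci=(ind - Z95 * se_ind, ind + Z95 * se_ind),
        direct=direct,
        direct_ci=(direct - Z95 * se_dir, direct + Z95 * se_dir),
        proportion_mediated=prop,
        proportion_se=se_prop,
        proportion_ci=ci_prop,
        inconsistent_mediation=not (0.0 <= prop <= 1.0),
    )
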