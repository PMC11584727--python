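"""Univariable two-sample MR estimators over a harmonized variant set.

Per-variant causal-effect estimates are Wald ratios θⱼ = Γⱼ/γⱼ with
first-order standard errors σ_Yj/|γⱼ|. The pooled inverse-variance
weighted (IVW) estimate is their precision-weighted mean; under the
multiplicative random-effects model its SE is inflated by
max(1, √(Q/df)) when Cochran's Q exceeds its expectation.

The sensitivity suite targets horizontal pleiotropy: MR-Egger regression
(a nonzero intercept indicates directional pleiotropy; I²GX measures
instrument-strength adequacy for the slope), the (penalized) weighted
median (consistent while ≥50% of weight is valid), radial IVW with
per-variant Q outlier statistics, MR-PRESSO (simulation-based global,
outlier and distortion tests), and leave-one-out re-estimation.

All estimators accept either a :class:`~mrmediate.harmonize.HarmonizedSet`
or plain arrays via the ``*_arrays`` variants used in simulation loops.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet
from .results import EggerResult, HeterogeneityResult, MREstimate, PressoResult

logger = logging.getLogger(__name__)


class InsufficientInstrumentsError(ValueError):
    pass


def _extract(hset: HarmonizedSet) -> tuple[np.ndarray, ...]:
    df = hset.df
    return (
        np.asarray(df["gamma"], dtype=float),
        np.asarray(df["se_x"], dtype=float),
        np.asarray(df["Gamma"], dtype=float),
        np.asarray(df["se_y"], dtype=float),
        np.asarray(df["variant_id"], dtype=object),
    )


def wald_ratio(gamma: float, se_x: float, Gamma: float, se_y: float) -> tuple[float, float]:
    """Single-variant causal effect Γ/γ with first-order SE σ_Y/|γ|."""
    if gamma == 0:
        raise ZeroDivisionError("degenerate instrument: gamma is zero")
    return Gamma / gamma, se_y / abs(gamma)


def wald_ratios(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    gamma, _, Gamma, se_y, _ = _extract(hset)
    if np.any(gamma == 0):
        raise ZeroDivisionError("degenerate instrument: gamma is zero")
    return Gamma / gamma, se_y / np.abs(gamma)


def ivw_arrays(
    theta: np.ndarray,
    se: np.ndarray,
    model: str = "multiplicative_random",
    ids: np.ndarray | None = None,
) -> tuple[MREstimate, HeterogeneityResult]:
    """IVW meta-analysis of Wald ratios (fixed or multiplicative random effects)."""
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = theta.size
    if n == 0:
        raise InsufficientInstrumentsError("empty instrument set")
    w = se**-2
    est = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    per_q = w * (theta - est) ** 2
    q = float(np.sum(per_q))
    df = n - 1
    if n == 1:
        logger.warning("single instrument: IVW falls back to the Wald ratio")
        se_out = float(se[0])
        het = HeterogeneityResult(0.0, 0, 1.0, {})
    else:
        if model == "fixed":
            se_out = se_fixed
        elif model == "multiplicative_random":
            se_out = se_fixed * max(1.0, np.sqrt(q / df))
        else:
            raise ValueError(f"unknown IVW model {model!r}")
        keys = ids if ids is not None else np.arange(n)
        het = HeterogeneityResult.from_q(q, df, dict(zip(keys, per_q)))
    p = float(2 * stats.norm.sf(abs(est) / se_out))
    label = "IVW" if model == "multiplicative_random" else "IVW (fixed)"
    return MREstimate(label, est, se_out, max(p, np.finfo(float).tiny), n), het


def ivw(
    hset: HarmonizedSet, model: str = "multiplicative_random"
) -> tuple[MREstimate, HeterogeneityResult]:
    theta, se = wald_ratios(hset)
    _, _, _, _, ids = _extract(hset)
    return ivw_arrays(theta, se, model, ids)


def _orient_positive(gamma, se_x, Gamma):
    """Flip (γ, Γ) pairs so every γ is positive (Egger orientation)."""
    sign = np.where(gamma < 0, -1.0, 1.0)
    return gamma * sign, se_x, Gamma * sign


def i2_gx(gamma: np.ndarray, se_x: np.ndarray) -> float:
    """Instrument-strength adequacy for MR-Egger (NOME violation measure).

    I²GX = (Q_GX − df)/Q_GX with Q_GX the Cochran Q of the γⱼ under
    weights σ_Xj⁻²; values near 1 mean Egger dilution is negligible.
    """
    w = np.asarray(se_x, dtype=float) ** -2
    g = np.abs(np.asarray(gamma, dtype=float))
    gbar = np.sum(w * g) / np.sum(w)
    q_gx = float(np.sum(w * (g - gbar) ** 2))
    if q_gx == 0:
        return float("-inf")
    return (q_gx - (g.size - 1)) / q_gx


def egger_arrays(
    gamma: np.ndarray,
    se_x: np.ndarray,
    Gamma: np.ndarray,
    se_y: np.ndarray,
    ids: np.ndarray | None = None,
) -> EggerResult:
    """MR-Egger: weighted regression of Γⱼ on γⱼ with an intercept.

    Variants are oriented so γⱼ > 0; weights are σ_Yj⁻²; both SEs carry
    multiplicative overdispersion scaling max(1, √(Q/(n−2))).
    """
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = gamma.size
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    g, sx, G = _orient_positive(gamma, se_x, Gamma)
    w = se_y**-2
    sw = np.sum(w)
    gbar = np.sum(w * g) / sw
    Gbar = np.sum(w * G) / sw
    sxx = np.sum(w * (g - gbar) ** 2)
    sxy = np.sum(w * (g - gbar) * (G - Gbar))
    slope = float(sxy / sxx)
    intercept = float(Gbar - slope * gbar)
    resid = G - intercept - slope * g
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (n - 2)))
    se_slope = float(np.sqrt(1.0 / sxx)) * scale
    se_int = float(np.sqrt(1.0 / sw + gbar**2 / sxx)) * scale
    p_slope = float(2 * stats.norm.sf(abs(slope) / se_slope))
    p_int = float(2 * stats.norm.sf(abs(intercept) / se_int))
    keys = ids if ids is not None else np.arange(n)
    het = HeterogeneityResult.from_q(
        q, n - 2, dict(zip(keys, w * resid**2)), i2_gx=i2_gx(gamma, se_x)
    )
    return EggerResult(
        MREstimate("MR-Egger", slope, se_slope, max(p_slope, np.finfo(float).tiny), n),
        intercept,
        se_int,
        max(p_int, np.finfo(float).tiny),
        het,
    )


def egger(hset: HarmonizedSet) -> EggerResult:
    gamma, se_x, Gamma, se_y, ids = _extract(hset)
    return egger_arrays(gamma, se_x, Gamma, se_y, ids)


def _weighted_median_interp(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation over cumulative
    standardized weights sⱼ = (cumⱼ − wⱼ/2)/Σw."""
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    ww = w[order]
    cum = np.cumsum(ww)
    s = (cum - ww / 2) / cum[-1]
    return float(np.interp(0.5, s, t))


def _weighted_median_rows(thetas: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median (shared weights w)."""
    order = np.argsort(thetas, axis=1, kind="stable")
    t = np.take_along_axis(thetas, order, axis=1)
    ww = w[order]
    cum = np.cumsum(ww, axis=1)
    s = (cum - ww / 2) / cum[:, -1:]
    # vectorized 1-D interpolation at 0.5 per row
    idx = (s < 0.5).sum(axis=1)
    idx = np.clip(idx, 1, s.shape[1] - 1)
    rows = np.arange(s.shape[0])
    s0, s1 = s[rows, idx - 1], s[rows, idx]
    t0, t1 = t[rows, idx - 1], t[rows, idx]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    out = t0 + frac * (t1 - t0)
    # clamp when 0.5 falls outside the s grid
    out = np.where(s[rows, 0] >= 0.5, t[rows, 0], out)
    out = np.where(s[rows, -1] <= 0.5, t[rows, -1], out)
    return out


def _penalized_weights(theta: np.ndarray, w: np.ndarray, penalty: float = 20.0) -> np.ndarray:
    """Down-weight variants heterogeneous at the unpenalized median.

    wⱼ′ = wⱼ·min(1, k·qⱼ) with qⱼ the upper-tail χ²₁ probability of
    variant j's Q contribution; k = 20 is the method's published default.
    """
    est0 = _weighted_median_interp(theta, w)
    qj = w * (theta - est0) ** 2
    pj = stats.chi2.sf(qj, 1)
    return w * np.minimum(1.0, penalty * pj)


def weighted_median_arrays(
    theta: np.ndarray,
    se: np.ndarray,
    penalized: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """(Penalized) weighted-median estimate with parametric-bootstrap SE."""
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = theta.size
    if n < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap SE will be noisy", n_boot)
    w = se**-2
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("nonpositive or non-finite weights")
    # penalty weights are computed once from the observed ratios and held
    # fixed across bootstrap replicates: the SE is conditional on the
    # selected down-weighting, which keeps the interval calibrated under
    # homogeneity (re-penalizing each replicate double-counts dispersion)
    weights = _penalized_weights(theta, w) if penalized else w
    est = _weighted_median_interp(theta, weights)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(n_boot, n))
    boots = _weighted_median_rows(draws, weights)
    se_est = float(np.std(boots, ddof=1))
    p = float(2 * stats.norm.sf(abs(est) / se_est))
    label = "Penalized weighted median" if penalized else "Weighted median"
    return MREstimate(label, est, se_est, max(p, np.finfo(float).tiny), n)


def weighted_median(
    hset: HarmonizedSet,
    penalized: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    theta, se = wald_ratios(hset)
    return weighted_median_arrays(theta, se, penalized, n_boot, seed)


def radial_ivw_arrays(
    theta: np.ndarray,
    se: np.ndarray,
    ids: np.ndarray | None = None,
) -> tuple[MREstimate, HeterogeneityResult]:
    """Radial IVW: regression of θⱼ√wⱼ on √wⱼ through the origin.

    Algebraically identical to fixed-effect IVW for the slope; the value
    of the radial form is its per-variant Q contributions, whose χ²₁
    p-values flag outliers (Bonferroni threshold 0.05/n via
    :func:`radial_outliers`).
    """
    est, het = ivw_arrays(theta, se, model="multiplicative_random", ids=ids)
    est = MREstimate("Radial IVW", est.theta, est.se, est.pvalue, est.n_snp)
    return est, het


def radial_ivw(hset: HarmonizedSet) -> tuple[MREstimate, HeterogeneityResult]:
    theta, se = wald_ratios(hset)
    _, _, _, _, ids = _extract(hset)
    return radial_ivw_arrays(theta, se, ids)


def radial_outliers(het: HeterogeneityResult, alpha: float = 0.05) -> list:
    """Variants whose radial Q contribution exceeds the Bonferroni χ²₁ bound."""
    n = len(het.per_snp_q)
    if n == 0:
        return []
    thresh = alpha / n
    return [k for k, qj in het.per_snp_q.items() if stats.chi2.sf(qj, 1) < thresh]


def _loo_slopes(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized."""
    sw = np.sum(w)
    swt = np.sum(w * theta)
    return (swt - w * theta) / (sw - w)


def mr_presso_arrays(
    gamma: np.ndarray,
    se_x: np.ndarray,
    Gamma: np.ndarray,
    se_y: np.ndarray,
    ids: np.ndarray | None = None,
    n_sim: int = 5000,
    sig: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares uses leave-one-out IVW slopes
    (each variant's residual is judged against a fit that excludes it);
    its null distribution comes from parametric simulation of both the
    variant–exposure and variant–outcome associations. P-values use the
    add-one estimator (1+#{≥obs})/(n_sim+1), so they are never zero.
    """
    gamma = np.asarray(gamma, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = gamma.size
    if n < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 instruments")
    ids = ids if ids is not None else np.arange(n)
    theta = Gamma / gamma
    se_ratio = se_y / np.abs(gamma)
    w_ratio = se_ratio**-2
    loo = _loo_slopes(theta, w_ratio)
    wy = se_y**-2
    obs_res2 = wy * (Gamma - gamma * loo) ** 2
    rss_obs = float(np.sum(obs_res2))

    rng = np.random.default_rng(seed)
    g_sim = rng.normal(gamma, se_x, size=(n_sim, n))
    G_sim = rng.normal(gamma * loo, se_y, size=(n_sim, n))
    theta_sim = G_sim / g_sim
    w_sim = (se_y / np.abs(g_sim)) ** -2
    sw = np.sum(w_sim, axis=1, keepdims=True)
    swt = np.sum(w_sim * theta_sim, axis=1, keepdims=True)
    loo_sim = (swt - w_sim * theta_sim) / (sw - w_sim)
    res2_sim = wy * (G_sim - g_sim * loo_sim) ** 2
    rss_sim = np.sum(res2_sim, axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_p = {}
    outlier_ids = []
    for j in range(n):
        pj = float((1 + np.sum(res2_sim[:, j] >= obs_res2[j])) / (n_sim + 1))
        outlier_p[ids[j]] = pj
        if pj < sig / n:  # Bonferroni
            outlier_ids.append(ids[j])

    corrected = None
    distortion_p = None
    if outlier_ids:
        mask = ~np.isin(ids, outlier_ids)
        if mask.sum() >= 2:
            corrected, _ = ivw_arrays(theta[mask], se_ratio[mask], ids=ids[mask])
            corrected = MREstimate(
                "MR-PRESSO (outlier-corrected)",
                corrected.theta,
                corrected.se,
                corrected.pvalue,
                corrected.n_snp,
            )
            # distortion: compare observed shift against shifts from random
            # same-size exclusions
            full, _ = ivw_arrays(theta, se_ratio)
            obs_dist = abs(corrected.theta - full.theta)
            k = len(outlier_ids)
            n_dist = min(n_sim, 1000)
            shifts = np.empty(n_dist)
            for i in range(n_dist):
                drop = rng.choice(n, size=k, replace=False)
                m = np.ones(n, bool)
                m[drop] = False
                sub, _ = ivw_arrays(theta[m], se_ratio[m])
                shifts[i] = abs(sub.theta - full.theta)
            distortion_p = float((1 + np.sum(shifts >= obs_dist)) / (n_dist + 1))
        else:
            logger.warning("MR-PRESSO flagged all but <2 instruments; no corrected estimate")
    return PressoResult(
        rss_obs, global_p, list(outlier_ids), outlier_p, corrected, distortion_p,
        n_sim, seed,
    )


def mr_presso(
    hset: HarmonizedSet, n_sim: int = 5000, sig: float = 0.05, seed: int = 0
) -> PressoResult:
    gamma, se_x, Gamma, se_y, ids = _extract(hset)
    return mr_presso_arrays(gamma, se_x, Gamma, se_y, ids, n_sim, sig, seed)


def leave_one_out(hset: HarmonizedSet) -> list[tuple[str, MREstimate]]:
    """Multiplicative random-effects IVW excluding each variant in turn."""
    theta, se = wald_ratios(hset)
    _, _, _, _, ids = _extract(hset)
    n = theta.size
    if n < 3:
        raise InsufficientInstrumentsError("leave-one-out requires at least 3 instruments")
    out = []
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[j] = False
        est, _ = ivw_arrays(theta[mask], se[mask], "multiplicative_random", ids[mask])
        out.append((ids[j], est))
        mask[j] = True
    return out
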