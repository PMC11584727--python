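"""Multivariable MR: joint regression of outcome associations on two
exposures' associations.

With instruments drawn from both exposures' clumped sets (standard MVMR
practice), weighted least squares of Γⱼ on (γ₁ⱼ, γ₂ⱼ) without intercept
and weights σ_Yj⁻² yields each exposure's direct effect conditional on
the other. In the mediation pipeline, exposure 2 is the mediator and its
conditional coefficient is the mediator→outcome path β.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import DEFAULT_FREQ_WINDOW, orient_to_frame
from .results import HeterogeneityResult, MREstimate, MVMRResult
from .sumstats import SummaryStatTable

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    pass


@dataclass
class MVMRSet:
    """Instrument union with associations for two exposures and the outcome.

    ``df`` columns: variant_id, gamma_1, se_1, gamma_2, se_2, Gamma,
    se_y — all expressed in exposure 1's GWAS effect-allele frame.
    """

    df: pd.DataFrame
    exposure_names: tuple[str, str]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)


def _aligned_beta(ref_row: pd.Series, other: SummaryStatTable, vid: str,
                  freq_window) -> tuple[float, float] | None:
    """Beta/SE of ``vid`` in ``other`` re-expressed in ``ref_row``'s frame."""
    try:
        row = other.lookup(vid)
    except KeyError:
        return None
    action, sign = orient_to_frame(
        ref_row["effect_allele"], ref_row["other_allele"],
        row["effect_allele"], row["other_allele"],
        ref_row.get("eaf"), row.get("eaf"), freq_window,
    )
    if sign == 0:
        return None
    return sign * row["beta"], row["se"]


def build_mvmr_set(
    exp1_instruments: list[str],
    exp2_instruments: list[str],
    gwas_1: SummaryStatTable,
    gwas_2: SummaryStatTable,
    gwas_out: SummaryStatTable,
    freq_window=DEFAULT_FREQ_WINDOW,
) -> MVMRSet:
    """Assemble the MVMR design over the union of both instrument sets.

    Each variant's associations are looked up in all three tables and
    harmonized to exposure 1's allele frame (falling back to exposure 2's
    frame for variants absent from exposure 1's GWAS). Variants missing
    from any table, or with irreconcilable alleles, are dropped and
    counted.
    """
    ids = list(dict.fromkeys(list(exp1_instruments) + list(exp2_instruments)))
    records = []
    n_dropped = 0
    for vid in ids:
        ref = None
        for table in (gwas_1, gwas_2):
            try:
                ref = table.lookup(vid)
                break
            except KeyError:
                continue
        if ref is None:
            n_dropped += 1
            continue
        vals = {}
        ok = True
        for name, table in (("1", gwas_1), ("2", gwas_2), ("y", gwas_out)):
            res = _aligned_beta(ref, table, vid, freq_window)
            if res is None:
                ok = False
                break
            vals[name] = res
        if not ok:
            n_dropped += 1
            continue
        records.append(
            {
                "variant_id": vid,
                "gamma_1": vals["1"][0],
                "se_1": vals["1"][1],
                "gamma_2": vals["2"][0],
                "se_2": vals["2"][1],
                "Gamma": vals["y"][0],
                "se_y": vals["y"][1],
            }
        )
    if n_dropped:
        logger.info("MVMR set: dropped %d variant(s) missing/incompatible", n_dropped)
    if len(records) < 3:
        raise ValueError(
            f"only {len(records)} instruments survive MVMR assembly; need ≥ 3"
        )
    df = pd.DataFrame(records)
    return MVMRSet(df, (gwas_1.trait_name, gwas_2.trait_name), n_dropped)


def mvmr_fit_arrays(
    gamma_1: np.ndarray,
    gamma_2: np.ndarray,
    Gamma: np.ndarray,
    se_y: np.ndarray,
    names: tuple[str, str] = ("exposure_1", "exposure_2"),
    ids: np.ndarray | None = None,
    se_1: np.ndarray | None = None,
    se_2: np.ndarray | None = None,
) -> MVMRResult:
    """No-intercept WLS of Γⱼ on (γ₁ⱼ, γ₂ⱼ), weights σ_Yj⁻².

    SEs carry multiplicative overdispersion scaling max(1, √(Q/(n−2))).
    Conditional F-statistics (each exposure's instrument strength given
    the other) are reported as diagnostics.
    """
    X = np.column_stack([np.asarray(gamma_1, float), np.asarray(gamma_2, float)])
    y = np.asarray(Gamma, float)
    se_y = np.asarray(se_y, float)
    n = y.size
    if n < 3:
        raise ValueError("MVMR requires at least 3 instruments")
    w = se_y**-2
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < 2 or np.linalg.cond(xtx) > 1e12:
        raise SingularDesignError("collinear or degenerate instrument effects")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (Xw.T @ yw)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    df = n - 2
    scale = max(1.0, np.sqrt(q / df))
    ses = np.sqrt(np.diag(xtx_inv)) * scale
    keys = ids if ids is not None else np.arange(n)
    het = HeterogeneityResult.from_q(q, df, dict(zip(keys, w * resid**2)))
    estimates = {}
    for k, name in enumerate(names):
        p = float(2 * stats.norm.sf(abs(coef[k]) / ses[k]))
        estimates[name] = MREstimate(
            f"MVMR ({name})", float(coef[k]), float(ses[k]),
            max(p, np.finfo(float).tiny), n,
        )
    # conditional instrument strength: mean per-variant F of each exposure's
    # instrument effects after projecting out the other exposure's effects
    # (diagnostic only; no hard threshold is enforced)
    cond_f = {}
    inst_se = {0: se_1, 1: se_2}
    for k, name in enumerate(names):
        if inst_se[k] is None:
            cond_f[name] = float("nan")
            continue
        target = X[:, k]
        other = X[:, 1 - k]
        denom = np.sum(w * other**2)
        b = np.sum(w * other * target) / denom if denom > 0 else 0.0
        res = target - b * other
        cond_f[name] = float(np.mean((res / np.asarray(inst_se[k], float)) ** 2))
    return MVMRResult(estimates, het, cond_f, n)


def mvmr_fit(mset: MVMRSet) -> MVMRResult:
    df = mset.df
    return mvmr_fit_arrays(
        df["gamma_1"], df["gamma_2"], df["Gamma"], df["se_y"],
        names=mset.exposure_names,
        ids=np.asarray(df["variant_id"], dtype=object),
        se_1=np.asarray(df["se_1"], float),
        se_2=np.asarray(df["se_2"], float),
    )
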