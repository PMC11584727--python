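"""Instrument selection and diagnostics.

Selection follows the standard two-sample MR recipe: keep genome-wide
significant variants (p < 5e-8) with minor-allele frequency above 1%,
prune them to approximate independence by greedy LD clumping
(r² < 0.001 within a 10 Mb window), and orient causality with Steiger
filtering (a valid instrument must explain more variance in the exposure
than in the outcome). Instrument strength is summarised per variant by
the F-statistic (β/se)² and in aggregate by the summed coefficient of
determination R².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet
from .sumstats import LDTable, SummaryStatTable

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_MAF_MIN = 0.01
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_BP = 10_000_000


@dataclass
class InstrumentDiagnostics:
    """Per-variant strength/directionality diagnostics and their summary."""

    per_variant: dict[str, dict] = field(default_factory=dict)

    @property
    def total_r2(self) -> float:
        return float(
            sum(v["r2_exposure"] for v in self.per_variant.values() if v["steiger_keep"])
        )

    @property
    def min_f(self) -> float:
        kept = [v["f_stat"] for v in self.per_variant.values() if v["steiger_keep"]]
        return float(min(kept)) if kept else float("nan")


def filter_significant(
    table: SummaryStatTable,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    maf_min: float = DEFAULT_MAF_MIN,
) -> SummaryStatTable:
    """Keep records with p < p_threshold (strict) and MAF > maf_min (strict)."""
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0,1)")
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0,0.5)")
    df = table.df
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    keep = (df["pvalue"] < p_threshold) & (maf > maf_min)
    out = df[keep].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("%s: no variants pass significance/MAF filters", table.trait_name)
    return SummaryStatTable(out, table.trait_name, table.trait_type)


def ld_clump(
    table: SummaryStatTable,
    ld: LDTable,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> SummaryStatTable:
    """Greedy p-value-ordered LD clumping.

    Repeatedly take the most significant remaining variant as an index
    and discard every remaining same-chromosome variant within
    ``window_bp`` whose r² with it is ≥ ``r2_threshold``. P-value ties
    break by variant_id. Index variants are returned in genomic order.
    Pairs absent from ``ld`` count as r² = 0 (unlinked).
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0,1]")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = table.df
    order = df.sort_values(["pvalue", "variant_id"], kind="mergesort")
    remaining = list(order.itertuples(index=False))
    kept_ids = []
    while remaining:
        index = remaining.pop(0)
        kept_ids.append(index.variant_id)
        survivors = []
        for cand in remaining:
            if (
                cand.chrom == index.chrom
                and abs(int(cand.pos) - int(index.pos)) <= window_bp
                and ld.r2(cand.variant_id, index.variant_id) >= r2_threshold
            ):
                continue
            survivors.append(cand)
        remaining = survivors
    out = df[df["variant_id"].isin(kept_ids)]
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SummaryStatTable(out, table.trait_name, table.trait_type)


def per_snp_r2(beta: float, se: float, n: float) -> float:
    """Variance explained by one variant, from its t-statistic.

    r² = t²/(t² + n − 2) with t = beta/se — needs no assumption about
    the phenotype variance and applies on the observed (log-odds)
    scale for binary traits.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if n <= 2:
        raise ValueError("n must exceed 2")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def f_statistic(beta: float, se: float) -> float:
    """Per-instrument strength, (β/se)²."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def _steiger_p(r2x: float, r2y: float, nx: float, ny: float) -> float:
    """Two-sided z-test comparing two independent correlations."""
    rx = np.sqrt(r2x)
    ry = np.sqrt(r2y)
    # atanh is unbounded as r→1; clip for numerical safety
    zx = np.arctanh(min(rx, 1 - 1e-12))
    zy = np.arctanh(min(ry, 1 - 1e-12))
    se = np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    z = (zx - zy) / se
    return float(2 * stats.norm.sf(abs(z)))


def steiger_filter(
    hset: HarmonizedSet,
) -> tuple[HarmonizedSet, InstrumentDiagnostics]:
    """Remove variants explaining more variance in the outcome than the exposure.

    Records missing either sample size are excluded with a warning.
    """
    diag = InstrumentDiagnostics()
    keep_ids = []
    for row in hset.df.itertuples(index=False):
        if pd.isna(row.n_x) or pd.isna(row.n_y):
            logger.warning("%s: missing sample size; excluded from Steiger", row.variant_id)
            continue
        r2x = per_snp_r2(row.gamma, row.se_x, row.n_x)
        r2y = per_snp_r2(row.Gamma, row.se_y, row.n_y)
        keep = r2x > r2y
        diag.per_variant[row.variant_id] = {
            "r2_exposure": r2x,
            "r2_outcome": r2y,
            "f_stat": f_statistic(row.gamma, row.se_x),
            "steiger_keep": keep,
            "steiger_p": _steiger_p(r2x, r2y, row.n_x, row.n_y),
        }
        if keep:
            keep_ids.append(row.variant_id)
    return hset.subset(keep_ids), diag


def enforce_disjoint(
    exposure_ids: set[str],
    mediator_ids: set[str],
    ld: LDTable,
    r2_threshold: float = DEFAULT_CLUMP_R2,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Make the mediator instrument set disjoint from (and unlinked to) the
    exposure set.

    Mediation requires independent instrument sets for exposure and
    mediator; the exposure set has priority (it is upstream in the path
    diagram), so shared or correlated variants are removed from the
    mediator side. Returns both sets plus a report of removals.
    """
    exposure_ids = set(exposure_ids)
    mediator_ids = set(mediator_ids)
    removals = []
    for mid in sorted(mediator_ids):
        if mid in exposure_ids:
            removals.append({"variant_id": mid, "reason": "shared", "partner": mid, "r2": 1.0})
            continue
        for eid in sorted(exposure_ids):
            r2 = ld.r2(mid, eid)
            if r2 >= r2_threshold:
                removals.append({"variant_id": mid, "reason": "ld", "partner": eid, "r2": r2})
                break
    removed = {r["variant_id"] for r in removals}
    report = pd.DataFrame(removals, columns=["variant_id", "reason", "partner", "r2"])
    return exposure_ids, mediator_ids - removed, report
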