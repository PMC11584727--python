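"""End-to-end orchestration: selection → harmonization → MR → mediation.

The pipeline reproduces the standard two-step MR mediation workflow:

1. instrument selection on the exposure and mediator GWAS (genome-wide
   significance, MAF, greedy LD clumping);
2. harmonization of each instrument panel against the outcome (and the
   mediator/exposure cross-tables for MVMR);
3. Steiger directionality filtering;
4. disjointness of exposure and mediator instrument sets;
5. univariable IVW for the total effect and the exposure→mediator path
   α, plus the pleiotropy sensitivity suite (Egger, weighted medians,
   radial IVW, MR-PRESSO, leave-one-out);
6. multivariable MR for the mediator→outcome path β adjusted for the
   exposure;
7. the mediation decomposition with delta-method intervals;
8. a local annotation screen standing in for a PhenoScanner confounder
   lookup: instruments annotated to non-mediator traits are reported
   with a recommendation to adjust by MVMR (never auto-executed).

Everything is deterministic given the config's master seed, which fans
out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import estimators, instruments, mediation, mvmr
from .harmonize import DEFAULT_FREQ_WINDOW, HarmonizedSet, harmonize_tables
from .results import MediationResult, MREstimate
from .sumstats import (
    LDTable,
    SummaryStatTable,
    read_annotation_table,
    read_ld_table,
    read_sumstats,
    read_whitelist,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-level configuration for one pipeline run."""

    exposure_path: str
    mediator_path: str
    outcome_path: str
    exposure_columns: dict = field(default_factory=dict)
    mediator_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    ld_path: str | None = None
    annotation_path: str | None = None
    whitelist_path: str | None = None
    p_threshold: float = instruments.DEFAULT_P_THRESHOLD
    maf_min: float = instruments.DEFAULT_MAF_MIN
    clump_r2: float = instruments.DEFAULT_CLUMP_R2
    clump_window_bp: int = instruments.DEFAULT_CLUMP_WINDOW_BP
    freq_window: tuple[float, float] = DEFAULT_FREQ_WINDOW
    steiger: bool = True
    n_boot: int = 1000
    n_sim: int = 5000
    seed: int = 0
    sensitivity: bool = True
    second_order_delta: bool = False
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("exposure_path", "mediator_path", "outcome_path"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")
        return cfg


@dataclass
class ReportBundle:
    """Machine-readable results of one full run."""

    instrument_diagnostics: dict
    harmonization_audit: dict
    univariable: dict[str, MREstimate]
    heterogeneity: dict
    egger_intercept: dict
    presso: dict | None
    leave_one_out: list
    mvmr_block: dict
    mediation_result: MediationResult
    annotation_hits: list
    warnings: list
    config_summary: dict

    def to_dict(self) -> dict:
        return {
            "instrument_diagnostics": self.instrument_diagnostics,
            "harmonization_audit": self.harmonization_audit,
            "univariable": {k: v.to_dict() for k, v in self.univariable.items()},
            "heterogeneity": self.heterogeneity,
            "egger_intercept": self.egger_intercept,
            "mr_presso": self.presso,
            "leave_one_out": self.leave_one_out,
            "mvmr": self.mvmr_block,
            "mediation": self.mediation_result.to_dict(),
            "annotation_hits": self.annotation_hits,
            "warnings": self.warnings,
            "config": self.config_summary,
        }

    def to_json(self) -> str:
        return json.dumps(_sanitize(self.to_dict()), indent=1, sort_keys=True,
                          allow_nan=False, default=_jsonable)

    def univariable_table(self) -> pd.DataFrame:
        rows = [est.to_dict() for est in self.univariable.values()]
        return pd.DataFrame(rows)


def _jsonable(obj: Any):
    try:
        return float(obj)
    except (TypeError, ValueError):
        return str(obj)


def _sanitize(obj: Any) -> Any:
    """Replace non-finite numerics with null so the report stays valid JSON."""
    import math

    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _select_instruments(
    table: SummaryStatTable,
    ld: LDTable,
    cfg: PipelineConfig,
) -> SummaryStatTable:
    sig = instruments.filter_significant(table, cfg.p_threshold, cfg.maf_min)
    return instruments.ld_clump(sig, ld, cfg.clump_r2, cfg.clump_window_bp)


def run_analysis(
    exposure: SummaryStatTable,
    mediator: SummaryStatTable,
    outcome: SummaryStatTable,
    ld: LDTable | None = None,
    annotation: pd.DataFrame | None = None,
    whitelist: set[str] | None = None,
    cfg: PipelineConfig | None = None,
) -> ReportBundle:
    """Run the whole analysis on in-memory tables (the library entry point)."""
    cfg = cfg or PipelineConfig("", "", "")
    ld = ld or LDTable()
    warnings: list[str] = []

    # 1. selection on each upstream GWAS
    exp_sel = _select_instruments(exposure, ld, cfg)
    med_sel = _select_instruments(mediator, ld, cfg)

    # 2-3. harmonize exposure instruments against the outcome, then Steiger
    hset_xy = harmonize_tables(exp_sel, outcome, cfg.freq_window, whitelist)
    diag = instruments.InstrumentDiagnostics()
    if cfg.steiger:
        hset_xy, diag = instruments.steiger_filter(hset_xy)
    exp_ids = hset_xy.variant_ids
    if len(exp_ids) == 0:
        raise estimators.InsufficientInstrumentsError(
            "selection: no exposure instruments survive harmonization/Steiger"
        )

    # exposure→mediator set for the α path (same instrument panel)
    hset_xm = harmonize_tables(exp_sel.subset(exp_ids), mediator, cfg.freq_window, whitelist)
    if cfg.steiger:
        hset_xm, _ = instruments.steiger_filter(hset_xm)

    # 4. disjoint mediator instruments
    exp_id_set, med_id_set, overlap_report = instruments.enforce_disjoint(
        set(exp_ids), med_sel.variant_ids, ld, cfg.clump_r2
    )
    if len(overlap_report):
        warnings.append(
            f"disjointness: removed {len(overlap_report)} mediator instrument(s)"
        )

    # 5. univariable estimates
    total, het = estimators.ivw(hset_xy, model="multiplicative_random")
    total.with_or_scale()
    alpha, _ = estimators.ivw(hset_xm, model="multiplicative_random")
    alpha = MREstimate("IVW (exposure→mediator)", alpha.theta, alpha.se,
                       alpha.pvalue, alpha.n_snp)

    univariable: dict[str, MREstimate] = {"IVW": total}
    egger_block: dict = {}
    presso_block = None
    loo_rows: list = []
    het_block = {"q": het.q, "df": het.df, "pvalue": het.pvalue, "i2_gx": None}
    if cfg.sensitivity and len(hset_xy) >= 3:
        egg = estimators.egger(hset_xy)
        univariable["MR-Egger"] = egg.slope.with_or_scale()
        het_block["i2_gx"] = egg.heterogeneity.i2_gx
        egger_block = {
            "intercept": egg.intercept,
            "se": egg.intercept_se,
            "pvalue": egg.intercept_pvalue,
        }
        univariable["Weighted median"] = estimators.weighted_median(
            hset_xy, penalized=False, n_boot=cfg.n_boot, seed=cfg.seed + 1
        ).with_or_scale()
        univariable["Penalized weighted median"] = estimators.weighted_median(
            hset_xy, penalized=True, n_boot=cfg.n_boot, seed=cfg.seed + 2
        ).with_or_scale()
        radial_est, radial_het = estimators.radial_ivw(hset_xy)
        univariable["Radial IVW"] = radial_est.with_or_scale()
        flagged = estimators.radial_outliers(radial_het)
        if flagged:
            warnings.append(f"radial IVW flags outlier(s): {sorted(map(str, flagged))}")
        if len(hset_xy) >= 4:
            presso = estimators.mr_presso(
                hset_xy, n_sim=cfg.n_sim, seed=cfg.seed + 3
            )
            presso_block = {
                "global_rss": presso.global_rss,
                "global_p": presso.global_p,
                "outlier_ids": list(map(str, presso.outlier_ids)),
                "distortion_p": presso.distortion_p,
                "n_sim": presso.n_sim,
            }
            if presso.corrected is not None:
                univariable["MR-PRESSO (corrected)"] = presso.corrected.with_or_scale()
        loo_rows = [
            {"excluded": str(vid), **est.to_dict()}
            for vid, est in estimators.leave_one_out(hset_xy)
        ]

    # 6. MVMR for the mediator→outcome path adjusted for the exposure
    mset = mvmr.build_mvmr_set(
        sorted(exp_id_set), sorted(med_id_set), exposure, mediator, outcome,
        cfg.freq_window,
    )
    mv = mvmr.mvmr_fit(mset)
    beta = mv.estimates[mediator.trait_name]
    beta = MREstimate("MVMR (mediator→outcome | exposure)", beta.theta, beta.se,
                      beta.pvalue, beta.n_snp)

    # 7. mediation decomposition
    med_result = mediation.run_mediation(alpha, beta, total, cfg.second_order_delta)
    if abs(total.theta) < 2 * total.se:
        warnings.append(
            "mediation: total effect indistinguishable from zero; the "
            "proportion mediated is unstable"
        )
    if med_result.inconsistent_mediation:
        warnings.append("mediation: proportion outside [0,1] (inconsistent mediation)")

    # 8. annotation screen (local stand-in for a PhenoScanner lookup)
    annotation_hits = []
    if annotation is not None and len(annotation):
        hits = annotation[annotation["variant_id"].isin(set(map(str, exp_ids)))]
        for row in hits.itertuples(index=False):
            annotation_hits.append({"variant_id": row.variant_id, "trait": row.trait})
        non_mediator = {h["trait"] for h in annotation_hits} - {mediator.trait_name}
        if non_mediator:
            warnings.append(
                "annotation screen: instruments associated with "
                f"{sorted(non_mediator)}; consider multivariable adjustment"
            )

    diagnostics = {
        "n_exposure_selected": len(exp_id_set),
        "n_mediator_selected": len(med_id_set),
        "total_r2": diag.total_r2,
        "min_f": diag.min_f,
        "n_steiger_excluded": sum(
            1 for v in diag.per_variant.values() if not v["steiger_keep"]
        ),
        "conditional_f": mv.conditional_f,
    }
    return ReportBundle(
        instrument_diagnostics=diagnostics,
        harmonization_audit=dict(hset_xy.audit),
        univariable=univariable,
        heterogeneity=het_block,
        egger_intercept=egger_block,
        presso=presso_block,
        leave_one_out=loo_rows,
        mvmr_block={
            "n_snp": mv.n_snp,
            "q": mv.heterogeneity.q,
            "q_pvalue": mv.heterogeneity.pvalue,
            "estimates": {k: v.to_dict() for k, v in mv.estimates.items()},
        },
        mediation_result=med_result,
        annotation_hits=annotation_hits,
        warnings=warnings,
        config_summary={
            "p_threshold": cfg.p_threshold,
            "maf_min": cfg.maf_min,
            "clump_r2": cfg.clump_r2,
            "clump_window_bp": cfg.clump_window_bp,
            "freq_window": list(cfg.freq_window),
            "steiger": cfg.steiger,
            "seed": cfg.seed,
        },
    )


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """File-driven entry point: read inputs, run, write report + log."""
    t0 = time.time()
    exposure = read_sumstats(cfg.exposure_path, cfg.exposure_columns, "continuous")
    mediator = read_sumstats(cfg.mediator_path, cfg.mediator_columns, "binary")
    outcome = read_sumstats(cfg.outcome_path, cfg.outcome_columns, "binary")
    ld = read_ld_table(cfg.ld_path) if cfg.ld_path else LDTable()
    annotation = read_annotation_table(cfg.annotation_path) if cfg.annotation_path else None
    whitelist = read_whitelist(cfg.whitelist_path) if cfg.whitelist_path else None

    report = run_analysis(exposure, mediator, outcome, ld, annotation, whitelist, cfg)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        report.univariable_table().to_csv(out / "report.tsv", sep="\t", index=False)
        elapsed = time.time() - t0
        lines = [f"pipeline completed in {elapsed:.1f} s"]
        lines += [f"audit.{k} = {v}" for k, v in sorted(report.harmonization_audit.items())]
        lines += [f"warning: {w}" for w in report.warnings]
        (out / "run.log").write_text("\n".join(lines) + "\n")
    return report
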