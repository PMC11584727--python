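"""Synthetic GWAS summary statistics with a known mediation structure.

The generator emulates the three-cohort design the pipeline targets: a
continuous exposure GWAS (intraocular pressure-like), a binary mediator
GWAS (glaucoma-like case/control meta-analysis), and a rare binary
outcome GWAS (retinal-vein-occlusion-like). True per-variant effects
follow the path diagram

    exposure --α--> mediator --β--> outcome,   exposure --τ--> outcome

so an exposure instrument with effect γⱼ has marginal effect γⱼ·α on the
mediator and γⱼ·(τ + α·β) on the outcome, and a mediator instrument with
effect δₖ has marginal effect δₖ·β on the outcome. Invalid exposure
instruments receive an additive pleiotropic path to the outcome,
oriented to the exposure-increasing allele (balanced: mean-zero;
directional: positive mean).

Simulation is at the summary level: observed betas are drawn around the
true marginal effects with the analytic standard errors
se = (2·n·f(1−f))^(−1/2) for the continuous trait and
se = (2·f(1−f)·n_cases·n_controls/n)^(−1/2) on the log-odds scale for
binary traits. Allele-coding chaos (label swaps, strand flips,
palindromic pairs) is injected into the outcome table so that
harmonization has real work to undo, and every injection is recorded in
the ground truth for exact bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDTable, SummaryStatTable, write_ld_table, write_sumstats

# non-palindromic allele pairs to draw from
_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
          ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class Pleiotropy:
    frac_invalid: float = 0.0
    mode: str = "balanced"  # or "directional"
    scale: float = 0.0


@dataclass
class AlleleChaos:
    frac_flipped: float = 0.0
    frac_palindromic: float = 0.0
    frac_strand_flipped: float = 0.0


@dataclass
class SimulationParams:
    """Ground-truth knobs for one synthetic three-GWAS study."""

    n_snps_x: int = 47
    n_snps_m: int = 50
    maf_range: tuple[float, float] = (0.05, 0.45)
    var_explained_x: float = 0.0264
    var_explained_m: float = 0.20
    alpha_true: float = 0.6
    beta_true: float = 0.65
    tau_true: float = 0.0357
    n_gwas_x: int = 97_653
    n_gwas_m: int = 216_257
    n_gwas_y: int = 377_277
    cases_m: int = 16_677
    controls_m: int = 199_580
    cases_y: int = 775
    controls_y: int = 376_502
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    allele_chaos: AlleleChaos = field(default_factory=AlleleChaos)
    ld_duplicates: int = 0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi ≤ 0.5")
        for name in ("var_explained_x", "var_explained_m"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1)")
        # a single variant cannot explain more than its 2f(1-f) ceiling
        # allows at the largest permitted effect; cap at 50% per SNP
        if self.var_explained_x / self.n_snps_x > 0.5:
            raise ValueError("var_explained_x unachievable with n_snps_x instruments")
        if self.var_explained_m / self.n_snps_m > 0.5:
            raise ValueError("var_explained_m unachievable with n_snps_m instruments")
        if not (0 <= self.pleiotropy.frac_invalid < 1):
            raise ValueError("frac_invalid must be in [0,1)")


@dataclass
class TruthRecord:
    """Everything the generator knows that an analyst would not."""

    alpha: float
    beta: float
    tau: float
    total: float
    proportion_mediated: float
    realized_r2_x: float
    realized_r2_m: float
    exposure_instruments: list[str]
    mediator_instruments: list[str]
    chaos: dict[str, str]  # variant_id -> injected coding category
    invalid_instruments: list[str]
    per_variant: pd.DataFrame  # variant_id, f, true_x, true_m, true_y

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "per_variant"}
        d["per_variant"] = self.per_variant.to_dict(orient="records")
        return json.dumps(d, indent=1)


def _binary_se(f: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n = n_cases + n_controls
    return np.sqrt(1.0 / (2 * f * (1 - f) * n_cases * n_controls / n))


def _continuous_se(f: np.ndarray, n: int) -> np.ndarray:
    return np.sqrt(1.0 / (2 * n * f * (1 - f)))


def _draw_effects(rng, n, var_target, f):
    """Per-variant effects with explained-variance shares ~ U(0.5, 1.5).

    Shares bounded away from zero mimic a selected instrument panel
    (every retained GWAS hit is individually strong, as published
    instrument sets are); squared-normal shares would put half the panel
    below genome-wide significance at realistic sample sizes.
    """
    shares = rng.uniform(0.5, 1.5, size=n)
    r2 = var_target * shares / shares.sum()
    signs = rng.choice([-1.0, 1.0], size=n)
    return signs * np.sqrt(r2 / (2 * f * (1 - f))), r2


def simulate_study(
    params: SimulationParams,
) -> tuple[SummaryStatTable, SummaryStatTable, SummaryStatTable, LDTable, TruthRecord]:
    """Generate (exposure, mediator, outcome) tables, an LD table, and truth.

    Deterministic given ``params.seed``. Every variant appears in all
    three tables; exposure instruments carry no direct mediator effect
    and mediator instruments no exposure effect, matching the
    disjoint-instrument design two-step mediation requires.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nx, nm = params.n_snps_x, params.n_snps_m
    n_all = nx + nm
    ids = [f"rsx{i+1:04d}" for i in range(nx)] + [f"rsm{k+1:04d}" for k in range(nm)]
    f = rng.uniform(*params.maf_range, size=n_all)

    gamma, r2x = _draw_effects(rng, nx, params.var_explained_x, f[:nx])
    delta, r2m = _draw_effects(rng, nm, params.var_explained_m, f[nx:])

    true_x = np.concatenate([gamma, np.zeros(nm)])
    true_m = np.concatenate([gamma * params.alpha_true, delta])
    total = params.tau_true + params.alpha_true * params.beta_true
    true_y = np.concatenate([gamma * total, delta * params.beta_true])

    # exclusion-restriction violations: additive direct path to the outcome,
    # oriented to the exposure-increasing allele
    n_invalid = int(round(params.pleiotropy.frac_invalid * nx))
    invalid_idx = rng.choice(nx, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    if n_invalid:
        s = params.pleiotropy.scale
        if params.pleiotropy.mode == "directional":
            pleio = rng.normal(s, s / 2, size=n_invalid)
        elif params.pleiotropy.mode == "balanced":
            pleio = rng.normal(0.0, s, size=n_invalid)
        else:
            raise ValueError(f"unknown pleiotropy mode {params.pleiotropy.mode!r}")
        true_y[invalid_idx] += np.sign(gamma[invalid_idx]) * pleio

    # allele coding: mutually exclusive chaos categories per variant
    chaos = _assign_chaos(rng, ids, params.allele_chaos)
    ea = np.empty(n_all, object)
    oa = np.empty(n_all, object)
    for i, vid in enumerate(ids):
        if chaos[vid].startswith("palindromic"):
            ea[i], oa[i] = _PALINDROMES[rng.integers(len(_PALINDROMES))]
        else:
            ea[i], oa[i] = _PAIRS[rng.integers(len(_PAIRS))]

    chrom = np.array([(i % 22) + 1 for i in range(n_all)], dtype=int)
    pos = np.array([20_000_000 * (i // 22 + 1) for i in range(n_all)], dtype=int)

    se_x = _continuous_se(f, params.n_gwas_x)
    se_m = _binary_se(f, params.cases_m, params.controls_m)
    se_y = _binary_se(f, params.cases_y, params.controls_y)
    beta_x = rng.normal(true_x, se_x)
    beta_m = rng.normal(true_m, se_m)
    beta_y = rng.normal(true_y, se_y)

    def _table(beta, se, n, trait, ttype, cases=None, controls=None, chaosify=False):
        b = beta.copy()
        eaf = f.copy()
        a1 = ea.copy()
        a2 = oa.copy()
        if chaosify:
            for i, vid in enumerate(ids):
                cat = chaos[vid]
                if cat == "flipped":
                    a1[i], a2[i] = a2[i], a1[i]
                    b[i] = -b[i]
                    eaf[i] = 1 - eaf[i]
                elif cat == "strand_flipped":
                    a1[i], a2[i] = _COMP[a1[i]], _COMP[a2[i]]
                elif cat == "palindromic_flipped":
                    # a strand flip of a palindromic pair looks like a label
                    # swap; only frequency can reveal it
                    b[i] = -b[i]
                    eaf[i] = 1 - eaf[i]
        z = np.abs(b / se)
        p = np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
        df = pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": chrom.astype(str),
                "pos": pos,
                "effect_allele": a1,
                "other_allele": a2,
                "eaf": eaf,
                "beta": b,
                "se": se,
                "pvalue": p,
                "n": float(n),
                "n_cases": float(cases) if cases else np.nan,
                "n_controls": float(controls) if controls else np.nan,
            }
        )
        return SummaryStatTable(df, trait, ttype)

    exposure = _table(beta_x, se_x, params.n_gwas_x, "exposure", "continuous")
    mediator = _table(
        beta_m, se_m, params.n_gwas_m, "mediator", "binary",
        params.cases_m, params.controls_m,
    )
    outcome = _table(
        beta_y, se_y, params.n_gwas_y, "outcome", "binary",
        params.cases_y, params.controls_y, chaosify=True,
    )

    ld = LDTable()
    if params.ld_duplicates:
        ld, exposure = _add_ld_duplicates(rng, params, exposure, ld)

    truth = TruthRecord(
        alpha=params.alpha_true,
        beta=params.beta_true,
        tau=params.tau_true,
        total=total,
        proportion_mediated=(
            params.alpha_true * params.beta_true / total if total != 0 else float("nan")
        ),
        realized_r2_x=float(r2x.sum()),
        realized_r2_m=float(r2m.sum()),
        exposure_instruments=ids[:nx],
        mediator_instruments=ids[nx:],
        chaos=chaos,
        invalid_instruments=[ids[i] for i in sorted(invalid_idx)],
        per_variant=pd.DataFrame(
            {"variant_id": ids, "f": f, "true_x": true_x, "true_m": true_m, "true_y": true_y}
        ),
    )
    return exposure, mediator, outcome, ld, truth


def _assign_chaos(rng, ids, chaos: AlleleChaos) -> dict[str, str]:
    n = len(ids)
    n_flip = int(round(chaos.frac_flipped * n))
    n_pal = int(round(chaos.frac_palindromic * n))
    n_strand = int(round(chaos.frac_strand_flipped * n))
    if n_flip + n_pal + n_strand > n:
        raise ValueError("allele_chaos fractions sum above 1")
    perm = rng.permutation(n)
    cats = {vid: "none" for vid in ids}
    cursor = 0
    for count, label in ((n_flip, "flipped"), (n_pal, "palindromic"), (n_strand, "strand_flipped")):
        for j in perm[cursor : cursor + count]:
            cats[ids[j]] = label
        cursor += count
    # half of the palindromic injections additionally carry a hidden strand
    # flip, which harmonization must infer from frequencies
    pal_ids = [v for v in ids if cats[v] == "palindromic"]
    for v in pal_ids[: len(pal_ids) // 2]:
        cats[v] = "palindromic_flipped"
    return cats


def _add_ld_duplicates(rng, params, exposure, ld):
    """Clone the strongest exposure instruments as tightly linked partners."""
    df = exposure.df.copy()
    clones = []
    top = df.iloc[: params.ld_duplicates]
    for row in top.itertuples(index=False):
        clone = row._asdict()
        clone["variant_id"] = row.variant_id + "_dup"
        clone["pos"] = row.pos + 1000
        clone["beta"] = row.beta + rng.normal(0, row.se * 0.1)
        clone["pvalue"] = float(
            np.clip(2 * stats.norm.sf(abs(clone["beta"] / row.se)), np.finfo(float).tiny, 1)
        )
        clones.append(clone)
        ld.set(row.variant_id, clone["variant_id"], 0.95)
    df = pd.concat([df, pd.DataFrame(clones)], ignore_index=True)
    return ld, SummaryStatTable(df, exposure.trait_name, exposure.trait_type)


PRESETS = ("paper_like", "null", "directional_pleiotropy", "invalid_30pct")


def preset(name: str, seed: int = 0) -> SimulationParams:
    """Documented parameter bundles for the study conditions.

    ``paper_like`` mirrors the seed study's shape: a 97,653-sample
    continuous-exposure GWAS with 47 instruments explaining 2.64% of
    variance, a 16,677/199,580 case/control mediator GWAS with 50
    instruments, a 775/376,502 rare-outcome GWAS, α=0.6, β=0.65,
    τ=0.0357 (total ln-OR 0.4257 ≈ ln 1.53, proportion mediated 0.916),
    and no pleiotropy. ``null`` zeroes all three paths. The two
    pleiotropy presets make 30% of exposure instruments invalid with an
    additive outcome path of scale 0.03 (directional vs balanced).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    p = SimulationParams(seed=seed)
    p.allele_chaos = AlleleChaos(frac_flipped=0.25, frac_palindromic=0.0,
                                 frac_strand_flipped=0.10)
    if name == "null":
        p.alpha_true = p.beta_true = p.tau_true = 0.0
    elif name == "directional_pleiotropy":
        p.pleiotropy = Pleiotropy(frac_invalid=0.30, mode="directional", scale=0.03)
    elif name == "invalid_30pct":
        p.pleiotropy = Pleiotropy(frac_invalid=0.30, mode="balanced", scale=0.03)
    return p


def write_study(out_dir: str | Path, params: SimulationParams) -> dict[str, Path]:
    """Simulate and write the three TSVs, the LD TSV, and the truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, mediator, outcome, ld, truth = simulate_study(params)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "mediator": out_dir / "mediator.tsv",
        "outcome": out_dir / "outcome.tsv",
        "ld": out_dir / "ld.tsv",
        "truth": out_dir / "truth.json",
    }
    write_sumstats(exposure, paths["exposure"])
    write_sumstats(mediator, paths["mediator"])
    write_sumstats(outcome, paths["outcome"])
    write_ld_table(ld, paths["ld"])
    paths["truth"].write_text(truth.to_json())
    return paths
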