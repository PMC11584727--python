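"""Allele harmonization between two GWAS summary-statistic tables.

Two-sample MR requires each variant's exposure and outcome associations
to be expressed relative to the same effect allele. GWAS resources do
not report strand consistently, so three situations must be undone:

* swapped allele labels (effect/other exchanged) — flip the outcome
  beta's sign and complement its frequency;
* strand flips (alleles reported as their reverse complement) —
  complement, then align as usual;
* palindromic variants (A/T or C/G), where strand cannot be resolved
  from alleles at all — resolve from allele frequencies when both are
  far from 0.5, drop as ambiguous otherwise.

The exposure table's coding always wins: the outcome is re-expressed in
the exposure's effect-allele frame.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .sumstats import SummaryStatTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = (
    "kept",
    "flipped",
    "palindrome_inferred",
    "dropped_ambiguous",
    "dropped_incompatible",
)

DEFAULT_FREQ_WINDOW = (0.42, 0.58)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return COMPLEMENT[effect_allele] == other_allele


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


@dataclass
class HarmonizedSet:
    """Variants shared by an exposure and an outcome GWAS, on one frame.

    ``df`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    gamma / se_x (SNP–exposure), Gamma / se_y (SNP–outcome), eaf_x,
    eaf_y, p_x, p_y, n_x, n_y, action. Only retained records are kept in
    ``df``; ``audit`` counts every common variant by the action taken.
    """

    df: pd.DataFrame
    exposure_name: str
    outcome_name: str
    audit: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def subset(self, ids) -> "HarmonizedSet":
        ids = set(ids)
        return HarmonizedSet(
            self.df[self.df["variant_id"].isin(ids)].reset_index(drop=True),
            self.exposure_name,
            self.outcome_name,
            Counter(self.audit),
        )


def orient_to_frame(
    ea_x: str,
    oa_x: str,
    ea_y: str,
    oa_y: str,
    eaf_x: float | None,
    eaf_y: float | None,
    freq_window: tuple[float, float] = DEFAULT_FREQ_WINDOW,
) -> tuple[str, int]:
    """Decide how a second study's coding maps onto the reference frame.

    Returns ``(action, sign)`` where ``sign`` multiplies the second
    study's beta (and flips its frequency when −1). ``action`` is one of
    the audit categories.
    """
    lo, hi = freq_window
    if is_palindromic(ea_x, oa_x):
        # Allele labels carry no strand information for palindromes; the
        # pair must at least match (A/T vs A/T, C/G vs C/G).
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "dropped_incompatible", 0
        if eaf_x is None or eaf_y is None or pd.isna(eaf_x) or pd.isna(eaf_y):
            return "dropped_ambiguous", 0
        x_in = lo <= eaf_x <= hi
        y_in = lo <= eaf_y <= hi
        if x_in or y_in:
            return "dropped_ambiguous", 0
        same_side = (eaf_x < 0.5) == (eaf_y < 0.5)
        if same_side:
            return "kept", 1
        return "palindrome_inferred", -1

    if (ea_y, oa_y) == (ea_x, oa_x):
        return "kept", 1
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flipped", -1
    # try the reverse-complement strand
    cea, coa = _complement_pair(ea_y, oa_y)
    if (cea, coa) == (ea_x, oa_x):
        return "kept", 1
    if (cea, coa) == (oa_x, ea_x):
        return "flipped", -1
    return "dropped_incompatible", 0


def align_record(
    exp: pd.Series,
    out: pd.Series,
    freq_window: tuple[float, float] = DEFAULT_FREQ_WINDOW,
) -> dict:
    """Harmonize one variant's outcome association to the exposure frame.

    ``exp`` and ``out`` are canonical summary-stat rows for the same
    variant. Returns a dict with the harmonized fields plus ``action``.
    """
    if exp["variant_id"] != out["variant_id"]:
        raise ValueError(
            f"variant_id mismatch: {exp['variant_id']} vs {out['variant_id']}"
        )
    action, sign = orient_to_frame(
        exp["effect_allele"],
        exp["other_allele"],
        out["effect_allele"],
        out["other_allele"],
        exp.get("eaf"),
        out.get("eaf"),
        freq_window,
    )
    rec = {
        "variant_id": exp["variant_id"],
        "chrom": exp["chrom"],
        "pos": exp["pos"],
        "effect_allele": exp["effect_allele"],
        "other_allele": exp["other_allele"],
        "gamma": exp["beta"],
        "se_x": exp["se"],
        "eaf_x": exp.get("eaf"),
        "p_x": exp["pvalue"],
        "n_x": exp.get("n"),
        "action": action,
    }
    if sign == 0:
        rec.update(Gamma=None, se_y=None, eaf_y=None, p_y=None, n_y=None)
        return rec
    eaf_y = out.get("eaf")
    if eaf_y is not None and not pd.isna(eaf_y) and sign == -1:
        eaf_y = 1.0 - eaf_y
    rec.update(
        Gamma=sign * out["beta"],
        se_y=out["se"],
        eaf_y=eaf_y,
        p_y=out["pvalue"],
        n_y=out.get("n"),
    )
    return rec


def harmonize_tables(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    freq_window: tuple[float, float] = DEFAULT_FREQ_WINDOW,
    whitelist: set[str] | None = None,
) -> HarmonizedSet:
    """Harmonize every variant common to both tables.

    Optionally restrict to a variant whitelist first (e.g. HapMap3).
    Output rows are ordered by (chrom, pos); the audit counts each common
    variant exactly once.
    """
    common = exposure.variant_ids & outcome.variant_ids
    if whitelist is not None:
        common &= whitelist
    audit: Counter = Counter({a: 0 for a in ACTIONS})
    if not common:
        logger.warning(
            "no variants shared between %s and %s", exposure.trait_name, outcome.trait_name
        )
        return HarmonizedSet(
            pd.DataFrame(columns=_HARMONIZED_COLUMNS), exposure.trait_name,
            outcome.trait_name, audit,
        )
    exp_rows = exposure.df[exposure.df["variant_id"].isin(common)]
    out_rows = outcome.df.set_index("variant_id", drop=False)
    records = []
    for exp in exp_rows.itertuples(index=False):
        exp = pd.Series(exp._asdict())
        rec = align_record(exp, out_rows.loc[exp["variant_id"]], freq_window)
        audit[rec["action"]] += 1
        if not rec["action"].startswith("dropped"):
            records.append(rec)
    df = pd.DataFrame(records, columns=_HARMONIZED_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return HarmonizedSet(df, exposure.trait_name, outcome.trait_name, audit)


_HARMONIZED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "gamma",
    "se_x",
    "eaf_x",
    "p_x",
    "n_x",
    "Gamma",
    "se_y",
    "eaf_y",
    "p_y",
    "n_y",
    "action",
]
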