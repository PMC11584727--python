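"""GWAS summary-statistic tables and LD / annotation side tables.

The canonical on-disk form is a tab-separated file with a header, dot
decimals and one row per variant. Foreign headers (every consortium uses
its own) are adapted with a ``column_map`` at read time, so the rest of
the package sees a single schema:

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se
    pvalue  n  [n_cases  n_controls]

Positions are 1-based. Alleles are single nucleotides over {A,C,G,T};
no strand column is modelled — strand is inferred downstream from allele
pairs and frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "n_cases",
    "n_controls",
]

MANDATORY = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
]

_VALID_ALLELES = frozenset("ACGT")


class SumstatsError(ValueError):
    """Malformed or unusable summary-statistic input."""


@dataclass
class SummaryStatTable:
    """One trait's per-variant association statistics.

    ``df`` holds the canonical columns; ``variant_id`` is unique within a
    table. ``trait_type`` is 'continuous' or 'binary'; betas for binary
    traits are log odds ratios per allele.
    """

    df: pd.DataFrame
    trait_name: str
    trait_type: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise SumstatsError(f"duplicate variant_id(s): {list(dups[:5])}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> set[str]:
        return set(self.df["variant_id"])

    def subset(self, ids: Iterable[str]) -> "SummaryStatTable":
        """Rows for the given variant ids, original order preserved."""
        ids = set(ids)
        return SummaryStatTable(
            self.df[self.df["variant_id"].isin(ids)].reset_index(drop=True),
            self.trait_name,
            self.trait_type,
        )

    def lookup(self, variant_id: str) -> pd.Series:
        rows = self.df[self.df["variant_id"] == variant_id]
        if rows.empty:
            raise KeyError(variant_id)
        return rows.iloc[0]


def _validate_rows(df: pd.DataFrame, trait_type: str) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the record invariants; never alter survivors."""
    ok = pd.Series(True, index=df.index)
    ok &= df["se"] > 0
    ok &= (df["pvalue"] > 0) & (df["pvalue"] <= 1)
    ok &= df["pos"] >= 1
    ok &= df["effect_allele"].isin(_VALID_ALLELES)
    ok &= df["other_allele"].isin(_VALID_ALLELES)
    ok &= df["effect_allele"] != df["other_allele"]
    has_eaf = df["eaf"].notna()
    ok &= ~has_eaf | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    if trait_type == "binary":
        cc = df["n_cases"].notna() & df["n_controls"].notna() & df["n"].notna()
        ok &= ~cc | (np.isclose(df["n_cases"] + df["n_controls"], df["n"]))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) violating record invariants", n_dropped)
    return df[ok].reset_index(drop=True), n_dropped


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
) -> SummaryStatTable:
    """Read a summary-statistic TSV into the canonical schema.

    Parameters
    ----------
    path
        Tab-separated file with a header line.
    column_map
        Maps canonical names to the file's column names, e.g.
        ``{"variant_id": "SNP", "beta": "b"}``. Canonical names absent
        from the map are assumed to appear verbatim in the header.
    trait_type
        'continuous' or 'binary'.

    Rows violating the per-record invariants (se ≤ 0, invalid alleles,
    out-of-range eaf/p, ...) are dropped and counted on the returned
    table's ``n_dropped``; surviving rows are never altered beyond
    allele upper-casing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY if c not in raw.columns]
    if missing:
        raise SumstatsError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"header was {list(raw.columns)}"
        )
    df = pd.DataFrame(index=raw.index)
    for col in CANONICAL_COLUMNS:
        if col in raw.columns:
            df[col] = raw[col]
        else:
            df[col] = np.nan
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("n", "n_cases", "n_controls"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    if df["eaf"].isna().any():
        logger.warning(
            "%s: %d record(s) lack eaf; they are excluded from palindrome "
            "inference and Steiger R² computation",
            path,
            int(df["eaf"].isna().sum()),
        )
    df, n_dropped = _validate_rows(df, trait_type)
    if len(df) == 0:
        raise SumstatsError(f"{path}: no valid rows after filtering")
    return SummaryStatTable(df, trait_name or path.stem, trait_type, n_dropped)


def write_sumstats(table: SummaryStatTable, path: str | Path) -> None:
    """Write the canonical TSV; round-trips through read_sumstats exactly."""
    df = table.df.copy()
    out = pd.DataFrame()
    for col in CANONICAL_COLUMNS:
        out[col] = df[col]
    # %.12g preserves ≥10 significant digits and is byte-stable
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fields = []
            for col, val in zip(CANONICAL_COLUMNS, row):
                if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
                    fields.append("NA")
                elif col in ("variant_id", "chrom", "effect_allele", "other_allele"):
                    fields.append(str(val))
                elif col in ("pos", "n", "n_cases", "n_controls"):
                    fields.append(str(int(val)))
                else:
                    fields.append(format(float(val), ".12g"))
            fh.write("\t".join(fields) + "\n")


@dataclass
class LDTable:
    """Pairwise r² lookups; symmetric; absent pairs are treated as 0."""

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r² out of range: {r2}")
        self.pairs[(a, b)] = r2
        self.pairs[(b, a)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get((a, b), 0.0)

    def __len__(self) -> int:
        return len(self.pairs) // 2


def read_ld_table(path: str | Path) -> LDTable:
    """Read a three-column (id1, id2, r2) TSV; rows with r² ∉ [0,1] rejected."""
    table = LDTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[-1].lower() in ("r2", "r^2", "rsq"):
                continue  # optional header
            if len(parts) != 3:
                raise SumstatsError(f"{path}:{lineno}: expected 3 columns")
            a, b, val = parts
            try:
                r2 = float(val)
            except ValueError as exc:
                raise SumstatsError(f"{path}:{lineno}: bad r² {val!r}") from exc
            if not (0.0 <= r2 <= 1.0):
                logger.warning("%s:%d: r²=%s outside [0,1]; row rejected", path, lineno, val)
                continue
            table.set(a, b, r2)
    return table


def write_ld_table(table: LDTable, path: str | Path) -> None:
    seen = set()
    with open(path, "w") as fh:
        fh.write("id1\tid2\tr2\n")
        for (a, b), r2 in sorted(table.pairs.items()):
            if (b, a) in seen:
                continue
            seen.add((a, b))
            fh.write(f"{a}\t{b}\t{format(r2, '.12g')}\n")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Variant→trait annotations standing in for a PhenoScanner lookup.

    Two-column TSV (variant_id, trait); one row per association.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "variant_id" not in cols or "trait" not in cols:
        raise SumstatsError(f"{path}: expected columns variant_id, trait")
    df.columns = cols
    return df[["variant_id", "trait"]]


def read_whitelist(path: str | Path) -> set[str]:
    """One variant_id per line (e.g. a HapMap3 restriction list)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
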