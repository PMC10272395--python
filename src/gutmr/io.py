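"""Reading, validating and writing GWAS summary-statistic tables.

Tables are tab-separated UTF-8 text with ``.`` for missing values, one row
per variant, following GWAS-SSF-style column names::

    rsid  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Only ``rsid``, ``effect_allele``, ``other_allele``, ``beta``, ``se`` and
``pval`` are mandatory. Effects (``beta``) are per effect-allele; for binary
outcomes they are on the log-odds scale. Rows that cannot be instruments —
non-ACGT alleles (indels, multi-allelic codes), non-positive standard errors,
p-values outside (0, 1] — are dropped at read time and tallied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyInputError, FormatError

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order for summary-statistic tables.
CANONICAL_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

MANDATORY_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")

TAXON_LEVELS = ("phylum", "class", "order", "family", "genus")


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G).

    Palindromic variants read the same on both strands, so the effect allele
    cannot be matched between two studies from the alleles alone; the
    harmonization step drops them unconditionally.
    """
    a1, a2 = a1.upper(), a2.upper()
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"alleles must be one of A/C/G/T, got {a1!r}/{a2!r}")
    if a1 == a2:
        raise ValueError(f"identical alleles {a1!r}/{a2!r} do not form a variant")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association record in one GWAS."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: alleles must be A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be positive")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.rsid}: pval must lie in (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie in [0, 1]")
        implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if implied > 0 and not (0.1 <= self.pval / implied <= 10.0):
            warnings.warn(
                f"{self.rsid}: pval {self.pval:g} differs from the normal "
                f"approximation {implied:g} by more than a factor of 10",
                stacklevel=2,
            )


@dataclass
class SummaryTable:
    """A validated GWAS summary-statistics table plus trait metadata.

    ``records`` is a DataFrame with the canonical columns, unique by rsid.
    ``taxon_level`` is present exactly for exposure (microbial-taxon) tables.
    """

    trait_name: str
    trait_kind: str  # "exposure" | "outcome"
    records: pd.DataFrame
    taxon_level: str | None = None
    tally: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_kind not in ("exposure", "outcome"):
            raise ValueError(f"trait_kind must be exposure|outcome, got {self.trait_kind!r}")
        if self.trait_kind == "exposure":
            if self.taxon_level not in TAXON_LEVELS:
                raise ValueError(
                    f"exposure table {self.trait_name!r} needs a taxon_level in {TAXON_LEVELS}"
                )
        elif self.taxon_level is not None:
            raise ValueError("outcome tables carry no taxon_level")
        df = self.records
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.records = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        if self.records["rsid"].duplicated().any():
            dups = self.records.loc[self.records["rsid"].duplicated(), "rsid"].tolist()
            raise FormatError(f"duplicate rsid(s): {', '.join(map(str, dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, mask) -> "SummaryTable":
        """A new table with the same metadata and the selected rows."""
        return SummaryTable(
            trait_name=self.trait_name,
            trait_kind=self.trait_kind,
            taxon_level=self.taxon_level,
            records=self.records.loc[mask].reset_index(drop=True).copy(),
        )

    def to_records(self) -> list[VariantAssoc]:
        out = []
        for row in self.records.itertuples(index=False):
            out.append(
                VariantAssoc(
                    rsid=row.rsid,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=row.beta,
                    se=row.se,
                    pval=row.pval,
                    chrom=None if pd.isna(row.chrom) else str(row.chrom),
                    pos=None if pd.isna(row.pos) else int(row.pos),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    n=None if pd.isna(row.n) else int(row.n),
                )
            )
        return out


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_name: str | None = None,
    trait_kind: str = "exposure",
    taxon_level: str | None = None,
) -> SummaryTable:
    """Read a TSV summary-statistics file into a validated :class:`SummaryTable`.

    ``column_map`` maps file column names to canonical ones. Rows with
    non-ACGT alleles, non-positive SE or p-values outside (0, 1] are dropped
    and counted in the returned table's ``tally``.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"rsid": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype("string").astype(object)

    tally: dict[str, int] = {}
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    ok_alleles = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(
        VALID_ALLELES
    ) & (df["effect_allele"] != df["other_allele"])
    tally["non_acgt_alleles"] = int((~ok_alleles).sum())
    ok_se = df["se"] > 0
    tally["nonpositive_se"] = int((ok_alleles & ~ok_se).sum())
    ok_p = (df["pval"] > 0) & (df["pval"] <= 1)
    tally["invalid_pval"] = int((ok_alleles & ok_se & ~ok_p).sum())
    df = df.loc[ok_alleles & ok_se & ok_p].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid records after validation")

    implied = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(implied > 0, df["pval"] / implied, 1.0)
    bad = (ratio < 0.1) | (ratio > 10.0)
    if bad.any():
        warnings.warn(
            f"{path}: {int(bad.sum())} row(s) have p-values inconsistent with "
            "(beta, se) under the two-sided normal approximation (>10x off)",
            stacklevel=2,
        )

    if trait_name is None:
        import os

        trait_name = os.path.splitext(os.path.basename(str(path)))[0]
    table = SummaryTable(
        trait_name=trait_name,
        trait_kind=trait_kind,
        taxon_level=taxon_level,
        records=df,
    )
    table.tally = tally
    return table


def write_summary_table(table: SummaryTable, path) -> str:
    """Write a table as canonical TSV (full float precision, stable row order)."""
    df = table.records.loc[:, list(CANONICAL_COLUMNS)].copy()
    # repr() round-trips doubles exactly; pandas' default str() does too on py3
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return str(path)
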