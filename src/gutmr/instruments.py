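"""Instrument selection, exclusion filters and allele harmonization.

The filter chain for one exposure follows the usual two-sample MR recipe:
genome-wide suggestive significance (p < 1e-5), greedy LD clumping (10,000 kb
window at r^2 >= 0.001), instrument strength (F = beta^2/se^2 >= 10), removal
of variants already associated with the outcome (p < 1e-5) or annotated with
a confounder trait (e.g. smoking), and finally harmonization of exposure and
outcome effects onto a shared effect-allele orientation with unconditional
removal of palindromic variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import SummaryTable, is_palindromic

logger = logging.getLogger(__name__)


@dataclass
class LDInfo:
    """Pairwise linkage disequilibrium supplied as data.

    ``positions`` maps rsid -> (chrom, pos); ``r2`` maps an unordered rsid
    pair (frozenset) to r^2 in [0, 1]. Absent pairs are treated as r^2 = 0;
    r^2 of a variant with itself is implicitly 1.
    """

    positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    r2: dict[frozenset, float] = field(default_factory=dict)

    def get_r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.r2.get(frozenset((a, b)), 0.0)

    def set_r2(self, a: str, b: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {value}")
        self.r2[frozenset((a, b))] = value

    @classmethod
    def from_tsv(cls, pairs_path, positions: Mapping[str, tuple[str, int]]) -> "LDInfo":
        """Load pairwise r^2 from a TSV of (rsid_a, rsid_b, r2)."""
        df = pd.read_csv(pairs_path, sep="\t")
        info = cls(positions=dict(positions))
        for row in df.itertuples(index=False):
            info.set_r2(str(row.rsid_a), str(row.rsid_b), float(row.r2))
        return info

    def to_tsv(self, pairs_path) -> None:
        rows = [
            {"rsid_a": a, "rsid_b": b, "r2": v}
            for (a, b), v in sorted((tuple(sorted(k)), v) for k, v in self.r2.items())
        ]
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
            pairs_path, sep="\t", index=False
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An instrument after allele alignment.

    ``gamma``/``se_gamma`` are the SNP-exposure association, ``Gamma_out``/
    ``se_Gamma`` the SNP-outcome association (log-odds), both expressed for
    the same effect allele. ``f_stat`` = gamma^2/se_gamma^2.
    """

    rsid: str
    gamma: float
    se_gamma: float
    Gamma_out: float
    se_Gamma: float
    f_stat: float

    def __post_init__(self) -> None:
        if not (self.se_gamma > 0 and self.se_Gamma > 0):
            raise ValueError(f"{self.rsid}: standard errors must be positive")
        expected = self.gamma**2 / self.se_gamma**2
        if abs(self.f_stat - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError(f"{self.rsid}: f_stat inconsistent with gamma^2/se_gamma^2")


@dataclass
class InstrumentSet:
    """Harmonized instruments for one exposure-outcome pair with provenance."""

    exposure: str
    outcome: str
    taxon_level: str | None = None
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rsids = [i.rsid for i in self.instruments]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate instrument rsids")

    @property
    def j(self) -> int:
        return len(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [i.rsid for i in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, se_gamma, Gamma_out, se_Gamma) as float arrays."""
        g = np.array([i.gamma for i in self.instruments], dtype=float)
        sg = np.array([i.se_gamma for i in self.instruments], dtype=float)
        G = np.array([i.Gamma_out for i in self.instruments], dtype=float)
        sG = np.array([i.se_Gamma for i in self.instruments], dtype=float)
        return g, sg, G, sG

    def subset(self, rsids: Iterable[str]) -> "InstrumentSet":
        keep = set(rsids)
        return InstrumentSet(
            exposure=self.exposure,
            outcome=self.outcome,
            taxon_level=self.taxon_level,
            instruments=[i for i in self.instruments if i.rsid in keep],
            provenance=dict(self.provenance),
        )

    def drop(self, rsids: Iterable[str]) -> "InstrumentSet":
        omit = set(rsids)
        return self.subset([r for r in self.rsids if r not in omit])


def select_significant(exposure: SummaryTable, p_threshold: float = 1e-5) -> SummaryTable:
    """Keep variants with exposure p strictly below ``p_threshold``."""
    mask = exposure.records["pval"] < p_threshold
    out = exposure.subset(mask)
    logger.info(
        "%s: significance filter kept %d/%d", exposure.trait_name, len(out), len(exposure)
    )
    return out


def clump(
    candidates: SummaryTable,
    ld: LDInfo,
    window_kb: int = 10_000,
    r2_threshold: float = 0.001,
) -> SummaryTable:
    """Greedy LD clumping: keep p-value-ordered index variants, discard their
    same-chromosome neighbours within ``window_kb`` at r^2 >= ``r2_threshold``.

    Ties on p are broken by (chrom, pos) then rsid for determinism.
    """
    missing = [r for r in candidates.records["rsid"] if r not in ld.positions]
    if missing:
        raise ConfigurationError(f"rsid(s) missing from LD positions: {', '.join(missing)}")
    df = candidates.records
    order = sorted(
        range(len(df)),
        key=lambda i: (
            df["pval"].iat[i],
            ld.positions[df["rsid"].iat[i]],
            df["rsid"].iat[i],
        ),
    )
    window_bp = window_kb * 1000
    kept: list[str] = []
    removed: set[str] = set()
    for i in order:
        rsid = df["rsid"].iat[i]
        if rsid in removed:
            continue
        kept.append(rsid)
        chrom_i, pos_i = ld.positions[rsid]
        for k in order:
            other = df["rsid"].iat[k]
            if other == rsid or other in removed or other in kept:
                continue
            chrom_k, pos_k = ld.positions[other]
            if chrom_k == chrom_i and abs(pos_k - pos_i) <= window_bp:
                if ld.get_r2(rsid, other) >= r2_threshold:
                    removed.add(other)
    keep_mask = df["rsid"].isin(kept)
    return candidates.subset(keep_mask)


def f_filter(candidates: SummaryTable, f_min: float = 10.0) -> SummaryTable:
    """Remove weak instruments with F = beta^2/se^2 below ``f_min``."""
    df = candidates.records
    f = (df["beta"] / df["se"]) ** 2
    return candidates.subset(f >= f_min)


def exclude_outcome_associated(
    candidates: SummaryTable, outcome: SummaryTable, p_threshold: float = 1e-5
) -> SummaryTable:
    """Remove candidates significantly associated with the outcome itself.

    A variant with outcome p < threshold likely acts on the outcome through a
    pathway of its own, violating the exclusion-restriction assumption.
    """
    if outcome.trait_kind != "outcome":
        raise ValueError("second argument must be an outcome-kind table")
    sig = set(
        outcome.records.loc[outcome.records["pval"] < p_threshold, "rsid"]
    )
    mask = ~candidates.records["rsid"].isin(sig)
    dropped = candidates.records.loc[~mask, "rsid"].tolist()
    if dropped:
        logger.info("removed outcome-associated variants: %s", ", ".join(dropped))
    return candidates.subset(mask)


def exclude_confounder_associated(
    candidates: SummaryTable,
    annotations: Mapping[str, set],
    confounder_traits: Iterable[str],
) -> SummaryTable:
    """Remove candidates annotated with any configured confounder trait.

    ``annotations`` is an offline rsid -> {trait labels} lookup standing in
    for an interactive phenotype-scan query.
    """
    confounders = set(confounder_traits)
    bad = {
        rsid
        for rsid, traits in annotations.items()
        if set(traits) & confounders
    }
    mask = ~candidates.records["rsid"].isin(bad)
    dropped = candidates.records.loc[~mask, "rsid"].tolist()
    if dropped:
        logger.info("removed confounder-associated variants: %s", ", ".join(dropped))
    return candidates.subset(mask)


def harmonize(exposure_instruments: SummaryTable, outcome: SummaryTable) -> InstrumentSet:
    """Align exposure and outcome effects onto a shared effect allele.

    Per instrument: identical allele pairs are kept as-is; swapped pairs have
    the outcome beta negated (and eaf complemented); palindromic pairs are
    dropped unconditionally (strand ambiguity); irreconcilable allele sets and
    instruments absent from the outcome table are dropped with a logged
    reason.
    """
    out_by_rsid = {
        row.rsid: row for row in outcome.records.itertuples(index=False)
    }
    instruments: list[HarmonizedInstrument] = []
    drops = {"absent_from_outcome": 0, "palindromic": 0, "irreconcilable": 0}
    for row in exposure_instruments.records.itertuples(index=False):
        orow = out_by_rsid.get(row.rsid)
        if orow is None:
            drops["absent_from_outcome"] += 1
            continue
        e1, e2 = row.effect_allele, row.other_allele
        o1, o2 = orow.effect_allele, orow.other_allele
        if is_palindromic(e1, e2):
            drops["palindromic"] += 1
            continue
        if (o1, o2) == (e1, e2):
            gamma_out = float(orow.beta)
        elif (o1, o2) == (e2, e1):
            gamma_out = -float(orow.beta)
        else:
            drops["irreconcilable"] += 1
            logger.info("%s: alleles %s/%s vs %s/%s irreconcilable", row.rsid, e1, e2, o1, o2)
            continue
        instruments.append(
            HarmonizedInstrument(
                rsid=row.rsid,
                gamma=float(row.beta),
                se_gamma=float(row.se),
                Gamma_out=gamma_out,
                se_Gamma=float(orow.se),
                f_stat=float(row.beta) ** 2 / float(row.se) ** 2,
            )
        )
    return InstrumentSet(
        exposure=exposure_instruments.trait_name,
        outcome=outcome.trait_name,
        taxon_level=exposure_instruments.taxon_level,
        instruments=instruments,
        provenance={f"harmonize_dropped_{k}": v for k, v in drops.items()},
    )
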