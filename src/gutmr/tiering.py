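"""Evidence-tier classification with per-taxonomic-level Bonferroni correction.

A taxon-outcome association is graded from the p-values of the three main MR
analyses (IVW, weighted median, MR-PRESSO):

* ``highly_probable`` — the IVW p survives the Bonferroni threshold for the
  taxon's level, 0.05/n where n is the number of taxa tested at that level
  (defaults: phylum 9, class 16, order 20, family 32, genus 119).
* ``probable`` — all three main analyses are available and nominally
  significant (p < 0.05) but the IVW p does not survive Bonferroni.
* ``possible`` — at least one of the three is nominally significant.
* ``none`` — otherwise.

A classified taxon is then struck to ``none`` if any sensitivity analysis
fails: Egger-intercept or PRESSO-global p < 0.05 (pleiotropy), Cochran or
Rucker Q p < 0.05 (heterogeneity), or an inconsistent leave-one-out refit.
Only the IVW p enters the Bonferroni comparison; an absent MR-PRESSO result
(J < 4) counts as non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

TIERS = ("none", "possible", "probable", "highly_probable")

#: Number of taxa tested per taxonomic level in the default exposure panel
#: (after removing unclassified groups).
DEFAULT_LEVEL_COUNTS: dict[str, int] = {
    "phylum": 9,
    "class": 16,
    "order": 20,
    "family": 32,
    "genus": 119,
}

EXCLUSION_REASONS = ("pleiotropy", "heterogeneity", "pleiotropy_or_heterogeneity", "loo_inconsistent")


@dataclass
class TierResult:
    """A taxon-outcome pair's evidence tier with exclusions and direction."""

    taxon: str
    level: str
    outcome: str
    tier: str
    direction: str  # "risk" | "protective" (from the IVW OR vs 1)
    exclusions: frozenset = field(default_factory=frozenset)
    final_tier: str = "none"

    def __post_init__(self) -> None:
        if self.exclusions and self.final_tier != "none":
            raise ValueError("final_tier must be 'none' whenever exclusions apply")


def bonferroni_threshold(level: str, counts: Mapping[str, int] | None = None) -> float:
    """0.05 divided by the number of taxa tested at ``level``."""
    counts = DEFAULT_LEVEL_COUNTS if counts is None else counts
    if level not in counts:
        raise ValueError(f"unknown taxonomic level {level!r}")
    n = counts[level]
    if n < 1:
        raise ValueError(f"level count must be >= 1, got {n}")
    return 0.05 / n


def _check_p(name: str, p: float | None) -> None:
    if p is not None and not (0.0 < p <= 1.0):
        raise ValueError(f"{name} must lie in (0, 1], got {p}")


def classify_tier(
    p_ivw: float,
    p_wm: float | None,
    p_presso: float | None,
    level: str,
    counts: Mapping[str, int] | None = None,
) -> str:
    """Grade one association from the three main-analysis p-values."""
    if p_ivw is None:
        raise ValueError("p_ivw is required")
    for name, p in (("p_ivw", p_ivw), ("p_wm", p_wm), ("p_presso", p_presso)):
        _check_p(name, p)
    if p_ivw < bonferroni_threshold(level, counts):
        return "highly_probable"
    three = (p_ivw, p_wm, p_presso)
    if all(p is not None and p < 0.05 for p in three):
        return "probable"
    if any(p is not None and p < 0.05 for p in three):
        return "possible"
    return "none"


def apply_exclusions(
    tier_in: str,
    egger_intercept_p: float | None = None,
    presso_global_p: float | None = None,
    q_p: float | None = None,
    rucker_p: float | None = None,
    loo_consistent: bool = True,
) -> tuple[frozenset, str]:
    """Sensitivity-based exclusions; absent tests are treated as passing.

    Returns (exclusions, final_tier) where final_tier is ``tier_in`` if no
    exclusion applies and ``none`` otherwise.
    """
    for name, p in (
        ("egger_intercept_p", egger_intercept_p),
        ("presso_global_p", presso_global_p),
        ("q_p", q_p),
        ("rucker_p", rucker_p),
    ):
        _check_p(name, p)
    exclusions = set()
    if (egger_intercept_p is not None and egger_intercept_p < 0.05) or (
        presso_global_p is not None and presso_global_p < 0.05
    ):
        exclusions.add("pleiotropy")
    if (q_p is not None and q_p < 0.05) or (rucker_p is not None and rucker_p < 0.05):
        exclusions.add("heterogeneity")
    if not loo_consistent:
        exclusions.add("loo_inconsistent")
    final = tier_in if not exclusions else "none"
    return frozenset(exclusions), final


def summarize(results: Iterable[TierResult]) -> pd.DataFrame:
    """Per-outcome counts of surviving taxa, split by effect direction.

    Columns: probable_or_above / possible, each split into risk and
    protective, plus totals. Ordering is stable by outcome name.
    """
    rows = []
    by_outcome: dict[str, list[TierResult]] = {}
    for r in sorted(results, key=lambda r: (r.outcome, r.level, r.taxon)):
        by_outcome.setdefault(r.outcome, []).append(r)
    for outcome, items in sorted(by_outcome.items()):
        counts = {
            "probable_or_above_risk": 0,
            "probable_or_above_protective": 0,
            "possible_risk": 0,
            "possible_protective": 0,
        }
        for r in items:
            if r.final_tier in ("highly_probable", "probable"):
                counts[f"probable_or_above_{r.direction}"] += 1
            elif r.final_tier == "possible":
                counts[f"possible_{r.direction}"] += 1
        rows.append(
            {
                "outcome": outcome,
                "probable_or_above": counts["probable_or_above_risk"]
                + counts["probable_or_above_protective"],
                "possible": counts["possible_risk"] + counts["possible_protective"],
                **counts,
            }
        )
    columns = [
        "outcome",
        "probable_or_above",
        "possible",
        "probable_or_above_risk",
        "probable_or_above_protective",
        "possible_risk",
        "possible_protective",
    ]
    return pd.DataFrame(rows, columns=columns)
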