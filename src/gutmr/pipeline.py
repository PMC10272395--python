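"""End-to-end orchestration of the two-sample MR workflow.

For every exposure-outcome pair: instrument selection -> LD clumping ->
strength filter -> outcome-association and confounder exclusions ->
harmonization -> the four estimators -> MR-PRESSO -> Q statistics -> Egger
intercept -> leave-one-out -> tier classification with sensitivity-based
exclusions. Configuration fails fast; a single degenerate pair fails soft
(reported with its reason, the run continues).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import estimators, presso as presso_mod, reference_data, sensitivity, tiering
from .exceptions import GutmrError
from .instruments import (
    InstrumentSet,
    LDInfo,
    clump,
    exclude_confounder_associated,
    exclude_outcome_associated,
    f_filter,
    harmonize,
    select_significant,
)
from .io import SummaryTable, read_summary_table
from .simulate import taxon_seed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, paths and seeds for one pipeline run."""

    seed: int
    output_dir: str
    exposure_manifest: str | None = None
    outcome_paths: list[str] = field(default_factory=list)
    ld_path: str | None = None
    confounder_path: str | None = None
    confounder_traits: list[str] = field(
        default_factory=lambda: ["smoking", "occupational exposure"]
    )
    p_select: float = 1e-5
    p_outcome: float = 1e-5
    f_min: float = 10.0
    window_kb: int = 10_000
    r2_threshold: float = 0.001
    alpha: float = 0.05
    level_counts: dict[str, int] = field(
        default_factory=lambda: dict(tiering.DEFAULT_LEVEL_COUNTS)
    )
    n_boot: int = 1000
    n_sim: int = 1000

    def __post_init__(self) -> None:
        for name in ("p_select", "p_outcome", "f_min", "r2_threshold", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.window_kb <= 0 or self.n_boot <= 0 or self.n_sim <= 0:
            raise ValueError("window_kb, n_boot and n_sim must be positive")
        if self.seed is None:
            raise ValueError("a master seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair."""

    exposure: str
    level: str | None
    outcome: str
    instruments: InstrumentSet | None = None
    estimates: dict[str, estimators.MREstimate] = field(default_factory=dict)
    presso: presso_mod.PressoResult | None = None
    cochran: sensitivity.QResult | None = None
    rucker: sensitivity.QResult | None = None
    loo: sensitivity.LooResult | None = None
    tier: tiering.TierResult | None = None
    provenance: dict[str, int] = field(default_factory=dict)
    skipped_reason: str | None = None


def analyze_pair(
    exposure: SummaryTable,
    outcome: SummaryTable,
    ld: LDInfo,
    annotations: Mapping[str, set] | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> PairResult:
    """Run the full per-pair analysis in memory."""
    config = config or PipelineConfig(seed=0, output_dir=".")
    seed = config.seed if seed is None else seed
    annotations = annotations or {}
    result = PairResult(
        exposure=exposure.trait_name, level=exposure.taxon_level, outcome=outcome.trait_name
    )
    prov = result.provenance
    prov["input"] = len(exposure)

    stage = select_significant(exposure, config.p_select)
    prov["removed_not_significant"] = prov["input"] - len(stage)
    if len(stage) == 0:
        result.skipped_reason = "no genome-wide suggestive instruments"
        return result
    before = len(stage)
    stage = clump(stage, ld, config.window_kb, config.r2_threshold)
    prov["removed_clumped"] = before - len(stage)
    before = len(stage)
    stage = f_filter(stage, config.f_min)
    prov["removed_weak"] = before - len(stage)
    before = len(stage)
    stage = exclude_outcome_associated(stage, outcome, config.p_outcome)
    prov["removed_outcome_associated"] = before - len(stage)
    before = len(stage)
    stage = exclude_confounder_associated(stage, annotations, config.confounder_traits)
    prov["removed_confounder_associated"] = before - len(stage)
    if len(stage) == 0:
        result.skipped_reason = "all instruments removed by QC filters"
        return result

    inst = harmonize(stage, outcome)
    prov.update(inst.provenance)
    prov["harmonized"] = inst.j
    result.instruments = inst
    if inst.j == 0:
        result.skipped_reason = "no instruments survived harmonization"
        return result

    est = result.estimates
    est["ivw"] = estimators.ivw(inst)
    if inst.j >= 3:
        est["weighted_median"] = estimators.weighted_median(
            inst, n_boot=config.n_boot, seed=seed
        )
        slope, intercept = estimators.egger(inst)
        est["egger_slope"] = slope
        est["egger_intercept"] = intercept
        result.rucker = sensitivity.rucker_q(inst)
        result.loo = sensitivity.leave_one_out(inst, config.alpha)
    if inst.j >= 2:
        result.cochran = sensitivity.cochran_q(inst)
    result.presso = presso_mod.presso(inst, n_sim=config.n_sim, seed=seed)
    if result.presso.applicable:
        est["presso_raw"] = result.presso.raw
        if result.presso.corrected is not None:
            est["presso_corrected"] = result.presso.corrected

    # tier classification: MR-PRESSO contributes the outlier-corrected p when
    # outliers were removed, the raw (IVW-equal) p otherwise, nothing if J < 4
    p_presso = None
    if result.presso.applicable:
        chosen = result.presso.corrected or result.presso.raw
        p_presso = chosen.pval
    p_wm = est["weighted_median"].pval if "weighted_median" in est else None
    level = exposure.taxon_level
    tier = tiering.classify_tier(
        est["ivw"].pval, p_wm, p_presso, level, config.level_counts
    )
    exclusions, final = tiering.apply_exclusions(
        tier,
        egger_intercept_p=est["egger_intercept"].pval if "egger_intercept" in est else None,
        presso_global_p=result.presso.global_pval if result.presso.applicable else None,
        q_p=result.cochran.pval if result.cochran else None,
        rucker_p=result.rucker.pval if result.rucker else None,
        loo_consistent=result.loo.consistent if result.loo else True,
    )
    result.tier = tiering.TierResult(
        taxon=exposure.trait_name,
        level=level,
        outcome=outcome.trait_name,
        tier=tier,
        direction="risk" if est["ivw"].beta > 0 else "protective",
        exclusions=exclusions,
        final_tier=final,
    )
    prov["post_sensitivity"] = inst.j if not exclusions else 0
    return result


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "."
    if isinstance(x, float):
        return format(x, ".10g")
    return str(x)


def _estimates_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for method, e in sorted(r.estimates.items()):
            rows.append(
                {
                    "exposure": r.exposure,
                    "level": r.level,
                    "outcome": r.outcome,
                    "method": method,
                    "n_snps": e.n_snps,
                    "beta": e.beta,
                    "se": e.se,
                    "or": float(np.exp(e.beta)),
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "pval": e.pval,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "level", "outcome", "method", "n_snps",
            "beta", "se", "or", "ci_low", "ci_high", "pval",
        ],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow from files and write the results bundle.

    Emits, under ``config.output_dir``: estimates.tsv, tiers.tsv, loo.tsv,
    summary.tsv, presso.json and provenance.json. Returns the in-memory
    bundle keyed the same way.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.exposure_manifest is None or not config.outcome_paths:
        raise GutmrError("exposure_manifest and outcome_paths are required")
    manifest = pd.read_csv(config.exposure_manifest, sep="\t")
    for col in ("taxon", "level", "file"):
        if col not in manifest.columns:
            raise GutmrError(f"manifest lacks column {col!r}")
    base = Path(config.exposure_manifest).parent
    exposures = [
        read_summary_table(
            base / row.file, trait_name=row.taxon, trait_kind="exposure",
            taxon_level=row.level,
        )
        for row in manifest.itertuples(index=False)
    ]
    outcomes = [
        read_summary_table(p, trait_kind="outcome") for p in config.outcome_paths
    ]
    positions: dict[str, tuple[str, int]] = {}
    for table in exposures:
        for row in table.records.itertuples(index=False):
            if not pd.isna(row.chrom) and not pd.isna(row.pos):
                positions[row.rsid] = (str(row.chrom), int(row.pos))
    if config.ld_path:
        ld = LDInfo.from_tsv(config.ld_path, positions)
    else:
        ld = LDInfo(positions=positions)
    annotations: dict[str, set] = {}
    if config.confounder_path:
        ann = pd.read_csv(config.confounder_path, sep="\t")
        for row in ann.itertuples(index=False):
            annotations.setdefault(str(row.rsid), set()).add(str(row.trait))

    results: list[PairResult] = []
    for exposure in exposures:
        for outcome in outcomes:
            pair_seed = taxon_seed(config.seed, f"{exposure.trait_name}|{outcome.trait_name}")
            try:
                results.append(
                    analyze_pair(exposure, outcome, ld, annotations, config, seed=pair_seed)
                )
            except GutmrError as exc:  # fail soft per pair
                logger.warning("%s x %s: %s", exposure.trait_name, outcome.trait_name, exc)
                results.append(
                    PairResult(
                        exposure=exposure.trait_name,
                        level=exposure.taxon_level,
                        outcome=outcome.trait_name,
                        skipped_reason=str(exc),
                    )
                )

    estimates = _estimates_frame(results)
    tier_rows = []
    loo_rows = []
    presso_side = {}
    provenance = {}
    for r in results:
        key = f"{r.exposure}|{r.outcome}"
        provenance[key] = dict(r.provenance)
        if r.skipped_reason:
            provenance[key]["skipped_reason"] = r.skipped_reason
        if r.tier:
            tier_rows.append(
                {
                    "taxon": r.tier.taxon,
                    "level": r.tier.level,
                    "outcome": r.tier.outcome,
                    "tier": r.tier.tier,
                    "direction": r.tier.direction,
                    "exclusions": ";".join(sorted(r.tier.exclusions)) or ".",
                    "final_tier": r.tier.final_tier,
                }
            )
        if r.loo:
            for rsid, e in sorted(r.loo.records.items()):
                loo_rows.append(
                    {
                        "exposure": r.exposure,
                        "outcome": r.outcome,
                        "left_out_rsid": rsid,
                        "beta": e.beta,
                        "se": e.se,
                        "pval": e.pval,
                        "flag": "failing" if rsid in r.loo.failing_rsids else "ok",
                    }
                )
        if r.presso and r.presso.applicable:
            presso_side[key] = {
                "rss_obs": r.presso.rss_obs,
                "global_pval": r.presso.global_pval,
                "outlier_pvals": r.presso.outlier_pvals,
                "outliers": sorted(r.presso.outliers),
                "distortion_pval": r.presso.distortion_pval,
                "n_sim": r.presso.n_sim,
            }
    tiers = pd.DataFrame(
        tier_rows,
        columns=["taxon", "level", "outcome", "tier", "direction", "exclusions", "final_tier"],
    )
    loo = pd.DataFrame(
        loo_rows,
        columns=["exposure", "outcome", "left_out_rsid", "beta", "se", "pval", "flag"],
    )
    summary = tiering.summarize([r.tier for r in results if r.tier])

    for name, frame in (
        ("estimates.tsv", estimates),
        ("tiers.tsv", tiers),
        ("loo.tsv", loo),
        ("summary.tsv", summary),
    ):
        out = frame.copy()
        for col in out.columns:
            if out[col].dtype == float:
                out[col] = out[col].map(_fmt)
        out.to_csv(outdir / name, sep="\t", index=False)
    with open(outdir / "presso.json", "w") as fh:
        json.dump(presso_side, fh, indent=1, sort_keys=True)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)

    return {
        "results": results,
        "estimates": estimates,
        "tiers": tiers,
        "loo": loo,
        "summary": summary,
        "provenance": provenance,
    }


REASON_EXCLUSIONS = {
    "pleiotropy": frozenset({"pleiotropy"}),
    "heterogeneity": frozenset({"heterogeneity"}),
    "pleiotropy_or_heterogeneity": frozenset({"pleiotropy_or_heterogeneity"}),
    "loo_inconsistent": frozenset({"loo_inconsistent"}),
}


def tier_reported_outcome(outcome: str) -> list[tiering.TierResult]:
    """Classify the bundled published table for one disease outcome."""
    table = reference_data.load_reported_associations(outcome)
    excl = reference_data.load_reported_exclusions()
    excl = excl.loc[excl["outcome"] == outcome]
    reasons = dict(zip(excl["taxon"], excl["reason"]))
    results = []
    for row in table.itertuples(index=False):
        tier = tiering.classify_tier(
            row.p_ivw,
            None if pd.isna(row.p_wm) else row.p_wm,
            None if pd.isna(row.p_presso) else row.p_presso,
            row.level,
        )
        reason = reasons.get(row.taxon)
        exclusions = REASON_EXCLUSIONS[reason] if reason else frozenset()
        results.append(
            tiering.TierResult(
                taxon=row.taxon,
                level=row.level,
                outcome=outcome,
                tier=tier,
                direction="risk" if row.or_ivw > 1 else "protective",
                exclusions=exclusions,
                final_tier=tier if not exclusions else "none",
            )
        )
    return results


def replicate_tables() -> pd.DataFrame:
    """Per-disease evidence-tier counts from the bundled published tables.

    Applies the tier rules to the printed IVW/WM/MR-PRESSO p-values, strikes
    the taxa the source study excluded after sensitivity analysis, and counts
    probable-or-above and possible taxa per disease, plus totals.
    """
    frames = []
    for outcome in reference_data.OUTCOMES:
        results = tier_reported_outcome(outcome)
        frames.append(tiering.summarize(results))
    summary = pd.concat(frames, ignore_index=True)
    summary["outcome"] = pd.Categorical(
        summary["outcome"], categories=list(reference_data.OUTCOMES), ordered=True
    )
    summary = summary.sort_values("outcome").reset_index(drop=True)
    total = {
        col: int(summary[col].sum()) for col in summary.columns if col != "outcome"
    }
    total["outcome"] = "total"
    summary["outcome"] = summary["outcome"].astype(str)
    return pd.concat([summary, pd.DataFrame([total])], ignore_index=True)
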