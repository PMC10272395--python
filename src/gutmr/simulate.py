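"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data model of a microbiota-exposure MR study: a
quantitative exposure measured in one cohort (default n = 18,340, the size of
the largest published gut-microbiota GWAS) and a binary, log-odds-scale
outcome from an independent case-control meta-analysis (defaults 54,606 cases
/ 887,000 controls, a COPD-scale biobank meta-analysis). Standard errors use
the standard 1/sqrt(2 maf (1-maf) n) approximation (effective n for binary
traits), so no individual-level genotypes are simulated.

True SNP-exposure effects are scaled-normal draws oriented so the effect
allele increases the exposure (gamma_j = se_gamma_j * |N(0, k^2)| with
k = ``instrument_strength``), the convention under which "directional"
pleiotropy (mean mu) is well defined. The default k = 7 puts the expected
per-SNP F statistic near 50, above the suggestive-selection regime
(p < 1e-5 corresponds to F around 20), with enough between-SNP spread in
gamma that MR-Egger's no-measurement-error condition holds to a good
approximation (I^2_GX around 95%). Invalid instruments receive
direct effects alpha_j ~ Normal(mu, pleio_sd^2), correlated with gamma when
``inside_violation`` is set; the true outcome effect is Gamma_j =
theta * gamma_j + alpha_j.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import SummaryTable
from .instruments import LDInfo

#: Taxon counts of the full default exposure panel (before removing the
#: unclassified groups: 12 genera and 3 families, leaving 196 of 211).
FULL_PANEL_COUNTS: dict[str, int] = {
    "phylum": 9,
    "class": 16,
    "order": 20,
    "family": 35,
    "genus": 131,
}
UNKNOWN_COUNTS: dict[str, int] = {"family": 3, "genus": 12}

_NON_PALINDROMIC_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration for one exposure-outcome pair."""

    seed: int
    J: int = 10
    theta: float = 0.0
    prop_invalid: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    inside_violation: bool = False
    n_exposure: int = 18_340
    n_case: int = 54_606
    n_control: int = 887_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_strength: float = 7.0
    outlier_count: int = 0
    outlier_scale: float = 0.0
    palindromic_fraction: float = 0.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    trait_name: str = "simulated_taxon"
    taxon_level: str = "genus"
    outcome_name: str = "simulated_outcome"
    rsid_start: int = 1

    def validate(self) -> None:
        if self.J < 1 or self.n_exposure < 1 or self.n_case < 1 or self.n_control < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ValueError("prop_invalid must lie in [0, 1]")
        if self.pleio_sd < 0:
            raise ValueError("pleio_sd must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not self.instrument_strength > 0:
            raise ValueError("instrument_strength must be positive")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ValueError("palindromic_fraction must lie in [0, 1]")
        if self.outlier_count < 0 or self.outlier_count > self.J:
            raise ValueError("outlier_count must lie in [0, J]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")


@dataclass
class SimTruth:
    """What the generator actually planted."""

    theta: float
    invalid_rsids: set[str] = field(default_factory=set)
    outlier_rsids: set[str] = field(default_factory=set)
    gamma: dict[str, float] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)


def _positions(config: SimConfig) -> tuple[list[str], list[str], list[int]]:
    """rsids plus (chrom, pos) laying LD blocks far apart (> any clump window)."""
    rsids, chroms, positions = [], [], []
    for j in range(config.J):
        block = j // config.ld_block_size
        within = j % config.ld_block_size
        rsids.append(f"rs{config.rsid_start + j}")
        chroms.append(str(block % 22 + 1))
        positions.append(1_000_000 + (block // 22) * 30_000_000 + within * 50_000)
    return rsids, chroms, positions


def simulate_pair(config: SimConfig) -> tuple[SummaryTable, SummaryTable, LDInfo, SimTruth]:
    """One exposure table, one outcome table, their LD map and the truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.J
    rsids, chroms, positions = _positions(config)

    maf = rng.uniform(*config.maf_range, size=j)
    se_gamma = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    # effect allele oriented to increase the exposure
    gamma_true = se_gamma * np.abs(rng.normal(0.0, config.instrument_strength, size=j))
    gamma_hat = rng.normal(gamma_true, se_gamma)

    n_invalid = round(config.prop_invalid * j)
    invalid_idx = np.sort(rng.choice(j, size=n_invalid, replace=False))
    alpha_true = np.zeros(j)
    if n_invalid:
        z = rng.standard_normal(n_invalid)
        if config.inside_violation and n_invalid > 1 and np.std(gamma_true[invalid_idx]) > 0:
            gs = (gamma_true[invalid_idx] - gamma_true[invalid_idx].mean()) / np.std(
                gamma_true[invalid_idx]
            )
            corr = 0.8
            mix = corr * gs + np.sqrt(1 - corr**2) * z
        else:
            mix = z
        alpha_true[invalid_idx] = config.pleio_mean + config.pleio_sd * mix

    n_eff = config.n_case * config.n_control / (config.n_case + config.n_control)
    se_Gamma = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)
    Gamma_true = config.theta * gamma_true + alpha_true
    Gamma_hat = rng.normal(Gamma_true, se_Gamma)

    outlier_idx = np.sort(rng.choice(j, size=config.outlier_count, replace=False))
    Gamma_hat[outlier_idx] += config.outlier_scale * se_Gamma[outlier_idx]

    n_palin = round(config.palindromic_fraction * j)
    palin_idx = set(np.sort(rng.choice(j, size=n_palin, replace=False)).tolist())
    pairs = []
    for k in range(j):
        pool = _PALINDROMIC_PAIRS if k in palin_idx else _NON_PALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    effect_alleles = [p[0] for p in pairs]
    other_alleles = [p[1] for p in pairs]

    def table(beta, se, kind, name, level, n):
        return SummaryTable(
            trait_name=name,
            trait_kind=kind,
            taxon_level=level,
            records=pd.DataFrame(
                {
                    "rsid": rsids,
                    "chrom": chroms,
                    "pos": positions,
                    "effect_allele": effect_alleles,
                    "other_allele": other_alleles,
                    "eaf": maf,
                    "beta": beta,
                    "se": se,
                    "pval": np.maximum(
                        2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny
                    ),
                    "n": n,
                }
            ),
        )

    exposure = table(
        gamma_hat, se_gamma, "exposure", config.trait_name, config.taxon_level,
        config.n_exposure,
    )
    outcome = table(
        Gamma_hat, se_Gamma, "outcome", config.outcome_name, None,
        config.n_case + config.n_control,
    )

    ld = LDInfo(positions={r: (c, p) for r, c, p in zip(rsids, chroms, positions)})
    if config.ld_rho > 0 and config.ld_block_size > 1:
        for a in range(j):
            for b in range(a + 1, j):
                if a // config.ld_block_size == b // config.ld_block_size:
                    ld.set_r2(rsids[a], rsids[b], config.ld_rho)

    truth = SimTruth(
        theta=config.theta,
        invalid_rsids={rsids[i] for i in invalid_idx},
        outlier_rsids={rsids[i] for i in outlier_idx},
        gamma={r: float(v) for r, v in zip(rsids, gamma_true)},
        alpha={r: float(v) for r, v in zip(rsids, alpha_true)},
    )
    return exposure, outcome, ld, truth


def taxon_seed(master_seed: int, taxon: str) -> int:
    """Stable per-taxon stream seed, independent of generation order."""
    return (int(master_seed) + zlib.crc32(taxon.encode("utf-8"))) % (2**31)


def simulate_panel(
    levels: Mapping[str, int] | None = None,
    template: SimConfig | None = None,
    seed: int = 0,
    exclude_unknown: bool = False,
) -> tuple[pd.DataFrame, dict[str, SummaryTable], SummaryTable, LDInfo, dict[str, SimTruth]]:
    """A whole taxonomy panel of exposure tables plus one pooled outcome.

    Default level counts mirror a 211-taxon panel; ``exclude_unknown`` drops
    the 15 unclassified groups (12 genera, 3 families), leaving 196. Each
    taxon draws from its own seed stream; rsids are disjoint across taxa, so
    the per-taxon outcome records pool into a single outcome table.

    Returns (manifest, exposures-by-taxon, outcome, pooled LD, truths).
    """
    levels = dict(FULL_PANEL_COUNTS if levels is None else levels)
    template = template if template is not None else SimConfig(seed=0)
    manifest_rows = []
    exposures: dict[str, SummaryTable] = {}
    truths: dict[str, SimTruth] = {}
    outcome_frames = []
    ld = LDInfo()
    index = 0
    for level in sorted(levels):
        count = levels[level]
        if count < 1:
            raise ValueError(f"taxon count for {level} must be positive")
        n_unknown = UNKNOWN_COUNTS.get(level, 0) if exclude_unknown else 0
        for i in range(count):
            unknown = i >= count - n_unknown
            taxon = f"{level}_{'unknown_' if unknown else ''}{i + 1:03d}"
            index += 1
            if unknown:
                continue
            cfg = replace(
                template,
                seed=taxon_seed(seed, taxon),
                trait_name=taxon,
                taxon_level=level,
                rsid_start=index * 10**6,
            )
            exposure, outcome, pair_ld, truth = simulate_pair(cfg)
            exposures[taxon] = exposure
            truths[taxon] = truth
            outcome_frames.append(outcome.records)
            ld.positions.update(pair_ld.positions)
            ld.r2.update(pair_ld.r2)
            manifest_rows.append({"taxon": taxon, "level": level})
    outcome = SummaryTable(
        trait_name=template.outcome_name,
        trait_kind="outcome",
        records=pd.concat(outcome_frames, ignore_index=True),
    )
    manifest = pd.DataFrame(manifest_rows, columns=["taxon", "level"])
    return manifest, exposures, outcome, ld, truths


def make_confounder_annotations(
    truth: SimTruth, labeled_fraction: float, seed: int
) -> dict[str, set[str]]:
    """Label a seeded random subset of SNPs with the trait "smoking".

    An offline stand-in for a phenotype-scan lookup, sized by rounding
    ``labeled_fraction * J``.
    """
    if not (0.0 <= labeled_fraction <= 1.0):
        raise ValueError("labeled_fraction must lie in [0, 1]")
    rsids = sorted(truth.gamma)
    k = round(labeled_fraction * len(rsids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(rsids), size=k, replace=False)
    return {rsids[i]: {"smoking"} for i in sorted(chosen)}
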