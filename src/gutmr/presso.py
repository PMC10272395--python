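"""MR-PRESSO: pleiotropy residual sum and outlier test via parametric resampling.

Three stages on a harmonized instrument set:

1. **Global test** — the observed residual sum of squares, built from
   leave-one-out IVW predictions, is compared with its parametric-resampling
   null distribution; a small empirical p signals horizontal pleiotropy
   somewhere in the set.
2. **Outlier test** — each SNP's weighted squared residual gets an empirical
   p from the same resampling, Bonferroni-multiplied by J; adjusted p below
   the significance level flags the SNP as a pleiotropic outlier.
3. **Distortion test** — the percent change of the IVW slope after removing
   the outliers is compared with the change from removing random subsets of
   the same size.

Fewer than 4 instruments leave the leave-one-out slope under-determined, so
the test reports itself inapplicable (mirroring the NA entries such tools
print for 3-SNP exposures) rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import estimators
from .exceptions import ContractViolationError
from .instruments import InstrumentSet


@dataclass
class PressoResult:
    """Global, per-SNP outlier and distortion test results."""

    applicable: bool
    n_sim: int
    rss_obs: float | None = None
    global_pval: float | None = None
    outlier_pvals: dict[str, float] = field(default_factory=dict)
    outliers: set[str] = field(default_factory=set)
    raw: estimators.MREstimate | None = None
    corrected: estimators.MREstimate | None = None
    distortion_pval: float | None = None


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope with each instrument left out in turn; w = 1/se_Gamma^2.

    Supports batches: g, G, w of shape (..., J) give slopes of shape (..., J).
    """
    sxy = (w * g * G).sum(axis=-1, keepdims=True)
    sxx = (w * g * g).sum(axis=-1, keepdims=True)
    return (sxy - w * g * G) / (sxx - w * g * g)


def presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int | None = None,
    sig: float = 0.05,
) -> PressoResult:
    """Run the global, outlier and distortion tests on one instrument set.

    Empirical p-values use the add-one rule (#exceedances + 1)/(K + 1), so
    they are never zero and are bounded below by 1/(K + 1).
    """
    if seed is None:
        raise ContractViolationError("presso requires an explicit seed")
    j = instruments.j
    if j < 4:
        return PressoResult(applicable=False, n_sim=n_sim)

    g, sg, G, sG = instruments.arrays()
    w = 1.0 / sG**2
    rng = np.random.default_rng(seed)

    b_loo = _loo_slopes(g, G, w)
    r2_obs = w * (G - b_loo * g) ** 2
    rss_obs = float(r2_obs.sum())

    # parametric resampling under the no-pleiotropy null:
    # gamma* ~ N(gamma_hat, se_gamma), Gamma* ~ N(b_(-j) * gamma_hat, se_Gamma)
    g_star = rng.normal(g, sg, size=(n_sim, j))
    G_star = rng.normal(b_loo * g, sG, size=(n_sim, j))
    b_loo_star = _loo_slopes(g_star, G_star, np.broadcast_to(w, (n_sim, j)))
    r2_star = w * (G_star - b_loo_star * g_star) ** 2
    rss_star = r2_star.sum(axis=1)

    global_pval = float((np.sum(rss_star >= rss_obs) + 1) / (n_sim + 1))

    per_snp = (np.sum(r2_star >= r2_obs, axis=0) + 1) / (n_sim + 1)
    adjusted = np.minimum(1.0, per_snp * j)
    rsids = instruments.rsids
    outlier_pvals = {rsid: float(p) for rsid, p in zip(rsids, adjusted)}
    outliers = {rsid for rsid, p in outlier_pvals.items() if p < sig}

    raw = estimators.ivw(instruments)
    result = PressoResult(
        applicable=True,
        n_sim=n_sim,
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        raw=raw,
    )

    if outliers and j - len(outliers) >= 2:
        kept = instruments.drop(outliers)
        corrected = estimators.ivw(kept)
        result.corrected = estimators.MREstimate(
            method="presso_corrected",
            beta=corrected.beta,
            se=corrected.se,
            ci_low=corrected.ci_low,
            ci_high=corrected.ci_high,
            pval=corrected.pval,
            n_snps=corrected.n_snps,
            overdispersion=corrected.overdispersion,
        )
        if raw.beta != 0:
            m = len(outliers)
            d_obs = 100.0 * (corrected.beta - raw.beta) / abs(raw.beta)
            idx = np.arange(j)
            d_null = np.empty(n_sim)
            sxy = (w * g * G).sum()
            sxx = (w * g * g).sum()
            for k in range(n_sim):
                drop = rng.choice(idx, size=m, replace=False)
                b_sub = (sxy - (w[drop] * g[drop] * G[drop]).sum()) / (
                    sxx - (w[drop] * g[drop] ** 2).sum()
                )
                d_null[k] = 100.0 * (b_sub - raw.beta) / abs(raw.beta)
            result.distortion_pval = float(
                (np.sum(np.abs(d_null) >= abs(d_obs)) + 1) / (n_sim + 1)
            )
    return result
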