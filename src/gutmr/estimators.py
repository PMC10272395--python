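"""The four causal-effect estimators for two-sample MR.

Notation: per instrument j, (gamma_j, se_gamma_j) is the SNP-exposure
association and (Gamma_j, se_Gamma_j) the SNP-outcome association on a shared
effect allele. The Wald ratio beta_j = Gamma_j/gamma_j is the per-SNP causal
estimate; the inverse-variance-weighted (IVW) estimate pools ratios with
weights w_j = gamma_j^2/se_Gamma_j^2, which is algebraically the weighted
regression of Gamma on gamma through the origin.

Conventions (stated because the field's tools differ quietly):

* Wald-ratio SEs are first-order (exposure uncertainty ignored).
* IVW and Egger use multiplicative random effects: the fixed-effect SE is
  scaled by sqrt(phi), phi = max(1, Q/df), so heterogeneity can widen but
  never narrow the interval.
* p-values are two-sided normal for IVW and the weighted median, and
  two-sided t(J-2) for both Egger coefficients.
* The weighted-median SE comes from a seeded parametric bootstrap.
* 95% intervals on the odds-ratio scale use exp(beta +/- 1.959964*se).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    ContractViolationError,
    DegenerateInstrumentError,
    EmptyInputError,
    InsufficientInstrumentsError,
)
from .instruments import HarmonizedInstrument, InstrumentSet

Z95 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate (or Egger intercept) with its uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    overdispersion: float = 1.0

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if not self.ci_low < self.ci_high:
            raise ValueError("ci_low must be below ci_high")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError("pval must lie in (0, 1]")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def _clamp_p(pval: float) -> float:
    # two-sided tail probabilities can underflow to 0 for extreme z
    return max(float(pval), np.finfo(float).tiny)


def _slope_estimate(method: str, beta: float, se: float, pval: float, j: int, phi: float = 1.0) -> MREstimate:
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        pval=_clamp_p(pval),
        n_snps=j,
        overdispersion=phi,
    )


def wald_ratio(inst: HarmonizedInstrument, method: str = "wald") -> MREstimate:
    """Single-instrument causal estimate Gamma/gamma with first-order SE."""
    if inst.gamma == 0:
        raise DegenerateInstrumentError(f"{inst.rsid}: gamma = 0")
    beta = inst.Gamma_out / inst.gamma
    se = inst.se_Gamma / abs(inst.gamma)
    pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    return _slope_estimate(method, beta, se, pval, 1)


def _ratio_weights(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    g, _, G, sG = instruments.arrays()
    if np.any(g == 0):
        bad = [i.rsid for i in instruments.instruments if i.gamma == 0]
        raise DegenerateInstrumentError(f"gamma = 0 for {', '.join(bad)}")
    return G / g, g**2 / sG**2


def ivw(instruments: InstrumentSet) -> MREstimate:
    """Random-effect inverse-variance-weighted estimate.

    With a single instrument this reduces exactly to the Wald ratio.
    """
    j = instruments.j
    if j == 0:
        raise EmptyInputError("no instruments")
    if j == 1:
        return wald_ratio(instruments.instruments[0], method="ivw")
    ratios, w = _ratio_weights(instruments)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    phi = max(1.0, q / (j - 1))
    se = se_fixed * phi**0.5
    pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    return _slope_estimate("ivw", beta, se, pval, j, phi)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``values`` with positive weights."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def weighted_median(
    instruments: InstrumentSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator: consistent if >=50% of weight is valid.

    SE via parametric bootstrap: redraw (gamma*, Gamma*) from normal
    distributions centred at the observed effects and recompute the weighted
    median ``n_boot`` times with the mandatory ``seed``.
    """
    if instruments.j < 3:
        raise InsufficientInstrumentsError("weighted median needs J >= 3")
    if seed is None:
        raise ContractViolationError("weighted_median requires an explicit seed")
    g, sg, G, sG = instruments.arrays()
    ratios, w = _ratio_weights(instruments)
    beta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gs = rng.normal(g, sg)
        Gs = rng.normal(G, sG)
        gs = np.where(gs == 0, np.finfo(float).tiny, gs)
        boots[b] = _weighted_median(Gs / gs, gs**2 / sG**2)
    se = float(np.std(boots, ddof=1))
    if se == 0:  # degenerate bootstrap (e.g. tiny n_boot); fall back to IVW-scale SE
        se = float(np.sum(w) ** -0.5)
    pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    return _slope_estimate("weighted_median", beta, se, pval, instruments.j)


def _egger_fit(g: np.ndarray, G: np.ndarray, sG: np.ndarray):
    """Weighted Egger regression via explicit 2x2 normal equations.

    Orients instruments so gamma >= 0 first (the intercept is
    orientation-dependent; ratio-based estimators are not). Returns
    (alpha, beta, se_alpha, se_beta, q_prime, df, phi).
    """
    j = len(g)
    s = np.where(g < 0, -1.0, 1.0)
    x = g * s
    y = G * s
    w = 1.0 / sG**2
    sw = w.sum()
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    denom = sw * swxx - swx**2
    if denom <= 0 or np.ptp(x) == 0:
        raise CollinearityError("no variation in gamma; Egger fit is rank deficient")
    beta = (sw * swxy - swx * swy) / denom
    alpha = (swy - beta * swx) / sw
    resid = y - alpha - beta * x
    q_prime = float((w * resid**2).sum())
    df = j - 2
    phi = max(1.0, q_prime / df)
    var_beta = sw / denom * phi
    var_alpha = swxx / denom * phi
    return float(alpha), float(beta), float(var_alpha**0.5), float(var_beta**0.5), q_prime, df, phi


def egger(instruments: InstrumentSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger weighted regression: (slope, intercept) estimates.

    The slope is robust to directional pleiotropy under the InSIDE
    assumption; the intercept estimates the average direct (pleiotropic)
    effect and its t(J-2) test is the pleiotropy diagnostic.
    """
    j = instruments.j
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs J >= 3")
    g, _, G, sG = instruments.arrays()
    alpha, beta, se_a, se_b, _, df, phi = _egger_fit(g, G, sG)
    p_slope = float(2.0 * stats.t.sf(abs(beta) / se_b, df))
    p_int = float(2.0 * stats.t.sf(abs(alpha) / se_a, df))
    slope = _slope_estimate("egger_slope", beta, se_b, p_slope, j, phi)
    intercept = MREstimate(
        method="egger_intercept",
        beta=alpha,
        se=se_a,
        ci_low=alpha - Z95 * se_a,  # additive scale: the intercept is not a log-OR per exposure unit
        ci_high=alpha + Z95 * se_a,
        pval=_clamp_p(p_int),
        n_snps=j,
        overdispersion=phi,
    )
    return slope, intercept
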