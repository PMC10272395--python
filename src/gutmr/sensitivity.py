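"""Heterogeneity, pleiotropy and leave-one-out sensitivity analyses.

* Cochran's Q (on the IVW fit, df = J-1) and Rucker's Q' (on the Egger fit,
  df = J-2) test whether the per-SNP ratio estimates scatter more than their
  sampling errors allow; p < 0.05 on either flags heterogeneity.
* The Egger intercept t-test flags directional horizontal pleiotropy.
* Leave-one-out refits the IVW estimate J times with one SNP removed; the
  result is "consistent" only if no single removal flips the sign of the
  estimate or destroys nominal significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import estimators
from .exceptions import InsufficientInstrumentsError
from .instruments import InstrumentSet


@dataclass(frozen=True)
class QResult:
    statistic: float
    df: int
    pval: float
    flavor: str  # "cochran" | "rucker"


@dataclass
class LooResult:
    full: estimators.MREstimate
    records: dict[str, estimators.MREstimate]
    consistent: bool
    failing_rsids: set[str] = field(default_factory=set)


def cochran_q(instruments: InstrumentSet) -> QResult:
    """Cochran's Q for the IVW fit: Q = sum w_j (beta_j - beta_ivw)^2."""
    j = instruments.j
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs J >= 2")
    ratios, w = estimators._ratio_weights(instruments)
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = j - 1
    return QResult(statistic=q, df=df, pval=float(stats.chi2.sf(q, df)), flavor="cochran")


def rucker_q(instruments: InstrumentSet) -> QResult:
    """Rucker's Q': the weighted residual sum of squares of the Egger fit."""
    j = instruments.j
    if j < 3:
        raise InsufficientInstrumentsError("Rucker's Q needs J >= 3")
    g, _, G, sG = instruments.arrays()
    _, _, _, _, q_prime, df, _ = estimators._egger_fit(g, G, sG)
    return QResult(
        statistic=q_prime, df=df, pval=float(stats.chi2.sf(q_prime, df)), flavor="rucker"
    )


def egger_intercept_test(instruments: InstrumentSet) -> estimators.MREstimate:
    """The Egger intercept with its t(J-2) two-sided p.

    p < 0.05 is read downstream as evidence of horizontal pleiotropy.
    """
    _, intercept = estimators.egger(instruments)
    return intercept


def leave_one_out(instruments: InstrumentSet, alpha: float = 0.05) -> LooResult:
    """Refit IVW leaving each instrument out once.

    Consistency demands, for every left-out SNP j: the refit keeps the sign
    of the full estimate, and if the full estimate is nominally significant
    the refit must remain so.
    """
    j = instruments.j
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out needs J >= 3")
    full = estimators.ivw(instruments)
    records: dict[str, estimators.MREstimate] = {}
    failing: set[str] = set()
    for rsid in instruments.rsids:
        est = estimators.ivw(instruments.drop([rsid]))
        records[rsid] = est
        sign_flip = np.sign(est.beta) != np.sign(full.beta)
        lost_sig = full.pval < alpha and est.pval >= alpha
        if sign_flip or lost_sig:
            failing.add(rsid)
    return LooResult(full=full, records=records, consistent=not failing, failing_rsids=failing)
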