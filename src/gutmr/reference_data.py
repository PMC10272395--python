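"""Bundled published association tables for five chronic respiratory diseases.

These fixtures transcribe, from a published gut-microbiota MR study, the
per-taxon odds ratios and p-values of the four MR methods (IVW, weighted
median, MR-PRESSO, MR-Egger) for COPD, asthma, idiopathic pulmonary fibrosis,
sarcoidosis and pneumoconiosis, together with the study's named
sensitivity-based exclusions (pleiotropy, heterogeneity, inconsistent
leave-one-out refits). They let the tier-classification rules be exercised
and validated end-to-end without access to the underlying GWAS downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

OUTCOMES = ("copd", "asthma", "ipf", "sarcoidosis", "pneumoconiosis")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("gutmr.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_reported_associations(outcome: str | None = None) -> pd.DataFrame:
    """The per-taxon method p-values/ORs for one outcome (or all, stacked)."""
    if outcome is not None:
        if outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
        df = _read(f"{outcome}.tsv")
        df.insert(0, "outcome", outcome)
        return df
    return pd.concat(
        [load_reported_associations(o) for o in OUTCOMES], ignore_index=True
    )


def load_reported_exclusions() -> pd.DataFrame:
    """Named taxa excluded per outcome, with the reported reason."""
    return _read("exclusions.tsv")
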