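import numpy as np
import pandas as pd
import pytest

from gutmr.instruments import HarmonizedInstrument, InstrumentSet
from gutmr.io import SummaryTable


def build_instrument_set(gamma, se_gamma, Gamma, se_Gamma, exposure="exp", outcome="out"):
    instruments = [
        HarmonizedInstrument(
            rsid=f"rs{i + 1}",
            gamma=float(g),
            se_gamma=float(sg),
            Gamma_out=float(G),
            se_Gamma=float(sG),
            f_stat=float(g) ** 2 / float(sg) ** 2,
        )
        for i, (g, sg, G, sG) in enumerate(zip(gamma, se_gamma, Gamma, se_Gamma))
    ]
    return InstrumentSet(
        exposure=exposure, outcome=outcome, taxon_level="genus", instruments=instruments
    )


def random_instrument_set(rng, j=6, theta=0.3, het=0.0):
    """A generic instrument set with optional extra ratio heterogeneity."""
    gamma = rng.uniform(0.05, 0.2, j) * rng.choice([-1, 1], j)
    se_gamma = rng.uniform(0.01, 0.03, j)
    se_Gamma = rng.uniform(0.005, 0.02, j)
    Gamma = theta * gamma + het * rng.standard_normal(j) * se_Gamma + rng.normal(0, se_Gamma)
    return build_instrument_set(gamma, se_gamma, Gamma, se_Gamma)


def make_table(rows, trait_name="taxon", trait_kind="exposure", taxon_level="genus"):
    """Build a SummaryTable from dict rows with sensible defaults."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.02,
        "pval": 1e-6,
        "n": 18340,
    }
    records = pd.DataFrame([{**defaults, **row} for row in rows])
    return SummaryTable(
        trait_name=trait_name,
        trait_kind=trait_kind,
        taxon_level=taxon_level if trait_kind == "exposure" else None,
        records=records,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230602)


@pytest.fixture
def small_set(rng):
    return random_instrument_set(rng, j=6)
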