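import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import (
    HarmonizedInstrumentSet,
    SummaryStatsTable,
    VariantAssociation,
)


def make_hset(beta_exp, beta_out, se_out=None, se_exp=None, exposure="X", outcome="Y"):
    """Build a HarmonizedInstrumentSet from plain arrays."""
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    k = len(beta_exp)
    se_out = np.full(k, 0.05) if se_out is None else np.asarray(se_out, float)
    se_exp = np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, float)
    rows = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(k)],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_exp": np.full(k, 0.3),
            "eaf_out": np.full(k, 0.3),
        }
    )
    return HarmonizedInstrumentSet(exposure, outcome, rows)


def make_variant(
    variant_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=1e-6,
    n=10000,
):
    return VariantAssociation(
        variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n
    )


def make_table(records, trait_id="trait", trait_label=None):
    return SummaryStatsTable(trait_id, trait_label or trait_id, list(records))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
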