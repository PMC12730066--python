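import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from protmr import HarmonizedSet, SumStatsTable, make_table

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def row(snp_id="rs1", chrom="1", pos=1_000_000, ea="A", oa="G", eaf=0.3,
        beta=0.1, se=0.05, pval=None, n=10_000.0):
    from scipy import stats
    if pval is None:
        pval = float(np.clip(2 * stats.norm.sf(abs(beta / se)),
                             np.finfo(float).tiny, 1.0)) if se > 0 else 1.0
    return dict(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval, n=n)


def table(rows, trait_id="trait", trait_type="quantitative") -> SumStatsTable:
    return make_table(pd.DataFrame(rows), trait_id, trait_type)


def hset(beta_exp, se_exp, beta_out, se_out, n_exp=50_000.0,
         n_out=60_000.0) -> HarmonizedSet:
    """Directly assemble a HarmonizedSet from effect arrays."""
    be = np.asarray(beta_exp, dtype=float)
    k = len(be)
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(k)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": be, "se_exp": np.broadcast_to(se_exp, (k,)).astype(float),
        "pval_exp": 1e-9, "eaf_exp": 0.3, "n_exp": n_exp,
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.broadcast_to(se_out, (k,)).astype(float),
        "pval_out": 0.5, "eaf_out": 0.3, "n_out": n_out,
    })
    return HarmonizedSet("exp", "out", df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
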