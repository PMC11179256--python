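import numpy as np
import pandas as pd
import pytest


def make_sumstats(
    n=5,
    snp=None,
    a1="A",
    a2="G",
    af=0.3,
    beta=0.1,
    se=0.05,
    pval=0.05,
    nsamp=10_000,
    start_bp=1_000,
):
    """Small well-formed canonical sumstats table."""
    snp = snp if snp is not None else [f"rs{i + 1}" for i in range(n)]
    n = len(snp)

    def col(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return pd.DataFrame(
        {
            "SNP": snp,
            "CHR": ["1"] * n,
            "BP": np.arange(start_bp, start_bp + n * 100, 100)[:n],
            "A1": col(a1),
            "A2": col(a2),
            "AF": col(af),
            "B": col(beta),
            "SE": col(se),
            "P": col(pval),
            "N": col(nsamp),
        }
    )


@pytest.fixture
def sumstats5():
    return make_sumstats(5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
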