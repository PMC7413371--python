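import numpy as np
import pandas as pd
import pytest

from methylwas import synthio


@pytest.fixture(scope="session")
def small_panel():
    """Two LD blocks, 1000 samples."""
    return synthio.simulate_genotypes(1000, [(20, 0.6), (20, 0.1)], seed=11)


@pytest.fixture(scope="session")
def covariates(small_panel):
    return synthio.simulate_covariates(small_panel.sample_ids, seed=12)


@pytest.fixture(scope="session")
def methylome_truth(small_panel, covariates):
    return synthio.simulate_methylome(
        small_panel, 30, 0.4, 2, covariates, seed=13
    )


def make_gwas(snp_ids, chrom="chr1", beta=0.1, se=0.05, a1="A", a2="G",
              frq=0.3, n=1000):
    """Hand-built canonical GWAS frame for harmonization tests."""
    k = len(snp_ids)
    as_list = lambda v: list(v) if isinstance(v, (list, tuple)) else [v] * k
    betas = as_list(beta)
    ses = as_list(se)
    from scipy.stats import norm

    p = [2 * norm.sf(abs(b / s)) if s > 0 else 1.0
         for b, s in zip(betas, ses)]
    return pd.DataFrame(
        {
            "SNP": snp_ids,
            "CHR": as_list(chrom),
            "POS": np.arange(1, k + 1) * 1000,
            "A1": as_list(a1),
            "A2": as_list(a2),
            "FRQ": as_list(frq),
            "BETA": betas,
            "SE": ses,
            "P": p,
            "N": as_list(n),
        }
    )
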