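import numpy as np
import pandas as pd
import pytest

from mtgp.grm import GRM
from mtgp.simulate import simulate_breeding_values, vanraden_grm


def make_kernel(n: int, n_snps: int = 800, seed: int = 0) -> GRM:
    """A realistic full-rank GRM from random biallelic genotypes."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, n_snps)
    X = rng.binomial(2, p, size=(n, n_snps))
    return GRM(vanraden_grm(X))


def make_blup_data(
    n: int,
    h2: tuple[float, float] = (0.5, 0.35),
    rg: float = 0.9,
    seed: int = 0,
    n_snps: int = 800,
):
    """Family-level two-trait phenotypes with known breeding values.

    Emulates the stage-2 entry point: y_t = u_t + e_t with
    var(u_t) = 1 and var(e_t) = (1 − h2_t)/h2_t, so the family-mean
    heritability of y_t equals h2_t.
    """
    K = make_kernel(n, n_snps=n_snps, seed=seed)
    G0 = np.array([[1.0, rg], [rg, 1.0]])
    u = simulate_breeding_values(K.values, G0, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    e_sd = np.sqrt([(1 - h2[0]) / h2[0], (1 - h2[1]) / h2[1]])
    Y = u + rng.standard_normal((n, 2)) * e_sd
    Ydf = pd.DataFrame(Y, index=K.sample_ids, columns=["primary", "secondary"])
    udf = pd.DataFrame(u, index=K.sample_ids, columns=["primary", "secondary"])
    return Ydf, K, udf


@pytest.fixture(scope="session")
def kernel60() -> GRM:
    return make_kernel(60, seed=11)


@pytest.fixture(scope="session")
def blup_data_300():
    return make_blup_data(300, h2=(0.5, 0.35), rg=0.9, seed=5)
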