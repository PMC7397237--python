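import numpy as np
import pandas as pd
import pytest

from ssgblup.grm import GenotypeSet
from ssgblup.io_formats import RawPedigree
from ssgblup.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def desk_dataset():
    """Default desk-scale preset (3000 animals, 2000 SNPs), shared across
    tests that only read it."""
    return simulate_population(SimConfig(seed=123))


@pytest.fixture(scope="session")
def small_dataset():
    """A 240-animal dataset with genotypes for the last two generations."""
    cfg = SimConfig(
        n_founders=80, n_generations=2, n_offspring=80, n_sires=10, n_dams=40,
        n_snps=400, n_qtl=20, seed=11, genotyped_generations=(1, 2),
    )
    return simulate_population(cfg)


@pytest.fixture
def trio():
    """Child listed first: S and D are founders."""
    return RawPedigree([("C", "S", "D"), ("S", "0", "0"), ("D", "0", "0")])


def random_pedigree(rng, n, p_known=0.8):
    """Random valid pedigree: parents drawn from earlier animals."""
    recs = []
    for i in range(n):
        s = d = "0"
        if i >= 2:
            if rng.random() < p_known:
                s = str(rng.integers(1, i + 1))
            if rng.random() < p_known:
                d = str(rng.integers(1, i + 1))
                if d == s:
                    d = "0"
        recs.append((str(i + 1), s, d))
    return RawPedigree(recs)


def fullrank_genotypes(rng, n, m, ids=None):
    """Genotypes plus 'base' frequencies distinct from the observed ones,
    so G = ZZ'k is nonsingular (needed for exact GBLUP/SNP-BLUP algebra)."""
    pf = rng.uniform(0.1, 0.9, m)
    M = rng.binomial(2, pf, size=(n, m)).astype(float)
    if ids is None:
        ids = [str(i + 1) for i in range(n)]
    return GenotypeSet(ids=list(ids), M=M), pf


def gblup_frame(rng, gset, mu=2.0):
    sex = rng.integers(1, 3, size=gset.n_animals).astype(str)
    y = mu * (sex == "1") + rng.normal(size=gset.n_animals)
    return pd.DataFrame({"animal": gset.ids, "sex": sex, "y": y})
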