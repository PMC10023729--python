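"""Shared fixtures: small seeded pools, codebooks and specificity models."""

import numpy as np
import pandas as pd
import pytest

from seerfish import codebook as cb
from seerfish import hybridization as hyb


@pytest.fixture(scope="session")
def pool_r8hd4() -> cb.CodebookPool:
    """Greedy 3-color, 8-round pool at minimal Hamming distance 4."""
    return cb.generate_pool(3, 8, 4, seed=11, restarts=8)


@pytest.fixture(scope="session")
def codebook12(pool_r8hd4) -> cb.Codebook:
    """A 12-taxon codebook drawn from the R8HD4 pool."""
    return cb.draw_codebook(pool_r8hd4, 12, seed=7)


@pytest.fixture(scope="session")
def diagonal_model(codebook12) -> hyb.SpecificityModel:
    """Perfect specificity: own probe specific, all others background."""
    return hyb.SpecificityModel.diagonal(codebook12.taxa)


def nonspecific_dg(taxa, seed: int = 0, offdiag_fraction: float = 0.25) -> pd.DataFrame:
    """Diagonal specific probes plus a fraction of off-target pairs in the
    non-specific free-energy band (-13.0, -7.3) kcal/mol."""
    rng = np.random.default_rng(seed)
    taxa = list(taxa)
    dg = pd.DataFrame(-5.0, index=taxa, columns=taxa)
    np.fill_diagonal(dg.values, -14.0)
    n = len(taxa)
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    pick = rng.choice(len(off), size=int(round(offdiag_fraction * len(off))),
                      replace=False)
    for p in pick:
        i, j = off[p]
        dg.iat[i, j] = rng.uniform(-12.9, -7.4)
    return dg


@pytest.fixture(scope="session")
def nonspecific_model(codebook12) -> hyb.SpecificityModel:
    return hyb.SpecificityModel.from_dg(nonspecific_dg(codebook12.taxa, seed=3))


@pytest.fixture(scope="session")
def tiny_codebook() -> cb.Codebook:
    """Three taxa at pairwise distance 4: {1111, 2222, 3333}."""
    return cb.Codebook.from_mapping({"A": "1111", "B": "2222", "C": "3333"})
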