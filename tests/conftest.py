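import numpy as np
import pandas as pd
import pytest

from crabflow.genio import GenotypeMatrix, _default_metadata


def make_matrix(calls, individual_ids=None, locus_ids=None, sites=None,
                species=None, lat=None, lon=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list of (a1, a2) call pairs."""
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    ids = individual_ids or [f"i{k + 1}" for k in range(n)]
    loci = locus_ids or [f"L{k + 1}" for k in range(L)]
    meta = _default_metadata(ids)
    if sites is not None:
        meta["site_id"] = list(sites)
    if species is not None:
        meta["species_label"] = list(species)
    if lat is not None:
        meta["latitude"] = list(lat)
    if lon is not None:
        meta["longitude"] = list(lon)
    return GenotypeMatrix(ids, loci, calls, meta)


def random_pool_matrix(rng, n, n_loci, n_alleles=4, sites=None, missing=0.0):
    """Single-pool HWE genotypes on allele codes 1..n_alleles."""
    p = rng.dirichlet(np.ones(n_alleles), size=n_loci)
    calls = np.zeros((n, n_loci, 2), dtype=np.int32)
    for l in range(n_loci):
        calls[:, l, :] = rng.choice(
            np.arange(1, n_alleles + 1), size=(n, 2), p=p[l]
        )
    if missing:
        mask = rng.random((n, n_loci)) < missing
        calls[mask] = 0
    return make_matrix(calls, sites=sites)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def genepop_text_3digit():
    return (
        "test title\n"
        "LocA\n"
        "LocB\n"
        "POP\n"
        "ind1 , 101103 205205\n"
        "ind2 , 103103 000000\n"
        "POP\n"
        "ind3 , 101101 205207\n"
        "ind4 , 105103 207207\n"
    )


@pytest.fixture
def paper_cohort_w():
    """Membership vector matching the study's printed category counts."""
    return np.concatenate([
        np.full(436, 0.5),   # hybrids
        np.full(77, 0.05),   # misidentified crop
        np.full(1376, 0.95), # pure wild
    ])
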