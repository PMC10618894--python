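import numpy as np
import pytest

from clonalpop.genotype_io import MISSING, MicrosatDataset


def make_dataset(genotypes, sites=None, periods=None, ids=None, xy=None,
                 locus_names=None):
    """Build a MicrosatDataset from a nested list [(a,b) per locus] per sample."""
    geno = np.asarray(genotypes, dtype=np.int64)
    n = geno.shape[0]
    return MicrosatDataset(
        sample_ids=ids or [f"s{i+1}" for i in range(n)],
        sites=sites or ["site1"] * n,
        periods=periods or ["all"] * n,
        locus_names=locus_names or [f"L{j+1}" for j in range(geno.shape[1])],
        genotypes=geno,
        easting=None if xy is None else np.asarray(xy, float)[:, 0],
        northing=None if xy is None else np.asarray(xy, float)[:, 1],
    )


def random_dataset(rng, n=12, loci=4, alleles=(100, 104, 108, 112),
                   n_sites=2, missing_rate=0.0, periods=("pre", "post")):
    geno = rng.choice(alleles, size=(n, loci, 2)).astype(np.int64)
    if missing_rate:
        mask = rng.random((n, loci)) < missing_rate
        mask[mask.all(axis=1), 0] = False
        geno[mask] = MISSING
    sites = [f"site{1 + i % n_sites}" for i in range(n)]
    pers = [periods[i % len(periods)] for i in range(n)]
    xy = rng.uniform(0, 1000, size=(n, 2))
    return make_dataset(geno, sites=sites, periods=pers, xy=xy)


@pytest.fixture(scope="session")
def paper_like():
    from clonalpop.synthetic_data import make_paper_like

    ds, truth = make_paper_like(seed=11)
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
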