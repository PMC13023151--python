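import numpy as np
import pandas as pd
import pytest

from pigiris import simdata
from pigiris.containers import GenotypeMatrix, Pedigree, SimTruth


@pytest.fixture(scope="session")
def small_pedigree() -> Pedigree:
    """4 founders, 2 generations, 2 offspring per mating (12 animals)."""
    return simdata.simulate_pedigree(4, 2, 2, seed=3)


@pytest.fixture(scope="session")
def small_genotypes(small_pedigree) -> GenotypeMatrix:
    return simdata.simulate_genotypes(
        small_pedigree, 40, 0.1, 0.5, [("1", 1, 20_000_000)], seed=5
    )


@pytest.fixture()
def default_truth() -> SimTruth:
    return SimTruth()


def make_genotypes(dosages, chrom="1", phased=False, pos=None, **variant_cols):
    """Hand-build a GenotypeMatrix from a dosage (or haplotype) array."""
    dosages = np.asarray(dosages)
    haps = None
    if phased:
        haps = dosages
        dosages = haps.sum(axis=1)
    n, m = dosages.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "C", **variant_cols}
    )
    samples = pd.DataFrame({"id": [f"S{i}" for i in range(n)]})
    return GenotypeMatrix(samples, variants, dosages, haps)
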