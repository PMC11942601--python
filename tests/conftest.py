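import numpy as np
import pandas as pd
import pytest

from rohped.io_qc import GenotypeMatrix, MarkerMap, _recode_minor
from rohped.synthetic import SimConfig, simulate


def make_gm(calls, positions=None, chroms=None, samples=None, spacing=50_000):
    """Handcraft a GenotypeMatrix from a dosage array.

    Dosages are canonicalized to the within-dataset minor allele (the
    library's storage convention); homozygosity, heterozygosity and r2 are
    unaffected.
    """
    calls = np.asarray(calls, dtype=np.int8)
    a1 = np.full(calls.shape[1], "A", dtype=object)
    a2 = np.full(calls.shape[1], "B", dtype=object)
    calls, a1, a2 = _recode_minor(calls, a1, a2)
    n, L = calls.shape
    if positions is None:
        positions = (np.arange(L) + 1) * spacing
    if chroms is None:
        chroms = np.ones(L, dtype=int)
    mdf = pd.DataFrame({
        "chrom": chroms,
        "snp_id": [f"s{i}" for i in range(L)],
        "pos_bp": positions,
        "a1": a1, "a2": a2,
    })
    if samples is None:
        samples = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, markers=MarkerMap(mdf), calls=calls)


@pytest.fixture(scope="session")
def sim_population():
    """A pedigreed random-mating population with IBD truth (desk scale)."""
    return simulate(SimConfig(
        n_chrom=5, snps_per_chrom=800, founder_count=40,
        offspring_per_generation=40, n_generations=4, seed=7,
    ))


@pytest.fixture(scope="session")
def sim_genotypes(sim_population):
    return sim_population[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
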