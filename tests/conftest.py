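import numpy as np
import pandas as pd
import pytest

from wildhyb.dataset import Dataset, concat_datasets
from wildhyb.synthetic_data import PopModel, simulate_hybrids, simulate_parental_pops


@pytest.fixture(scope="session")
def pop_model():
    return PopModel(n_loci=22, alleles_per_locus=8, divergence=0.15)


@pytest.fixture(scope="session")
def two_pop(pop_model):
    """Two diverged parental populations (100 + 100) and their true freqs."""
    return simulate_parental_pops(pop_model, {"A": 100, "B": 100}, seed=11)


@pytest.fixture(scope="session")
def two_pop_with_f1(pop_model, two_pop):
    ds, freqs = two_pop
    f1 = simulate_hybrids(freqs["A"], freqs["B"], "F1", 30, 12, loci=pop_model.locus_names)
    return concat_datasets([ds, f1]), freqs, list(f1.ids)


@pytest.fixture
def tiny_dataset():
    """3 individuals x 3 loci with one missing genotype and metadata."""
    geno = np.array(
        [
            [[1, 1], [2, 3], [5, 5]],
            [[1, 2], [3, 3], [-1, -1]],
            [[2, 2], [2, 3], [5, 6]],
        ]
    )
    meta = pd.DataFrame(
        {
            "population": ["NE_wild", "NE_wild", "NE_domestic"],
            "morphology": ["silvestris", "silvestris", "catus"],
            "sex": ["F", "M", "F"],
            "x": [100.0, 200.0, np.nan],
            "y": [50.0, 60.0, np.nan],
            "material": ["feces", "hair", "blood"],
        },
        index=["w1", "w2", "d1"],
    )
    return Dataset(ids=["w1", "w2", "d1"], loci=["Fca1", "Fca2", "Fca3"], genotypes=geno, meta=meta)


def fixed_difference_freqs(n_loci=10):
    """Parental pools fixed for different alleles at every locus."""
    fa = [{1: 1.0} for _ in range(n_loci)]
    fb = [{2: 1.0} for _ in range(n_loci)]
    return fa, fb
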