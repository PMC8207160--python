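import numpy as np
import pandas as pd
import pytest

from fluctasym.simulate import LandmarkModel, gen_landmark_dataset
from fluctasym.gpa import gpa_align, reflect_side
from fluctasym.popgen import GenotypeTable


@pytest.fixture(scope="session")
def tiny_model():
    """3 individuals x 2 sides x 2 images x 2 digitizings, k=4: small enough
    for brute-force oracles, with every variance component active."""
    return LandmarkModel(
        mean_shape=np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.3, -0.8]]),
        sigma_ind=0.03,
        sigma_fa=0.02,
        sigma_image=0.005,
        sigma_digit=0.01,
        n_individuals=3,
        n_images=2,
        n_digitizings=2,
        scale=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_aligned(tiny_model):
    ds = gen_landmark_dataset(tiny_model)
    return gpa_align(reflect_side(ds, "right"))


def make_genotype_table(calls_by_locus: dict, population: str = "p") -> GenotypeTable:
    """Build a GenotypeTable from {locus: [(a, b), ...]} call lists."""
    loci = list(calls_by_locus)
    n = len(next(iter(calls_by_locus.values())))
    alleles = np.zeros((n, len(loci), 2), dtype=int)
    for j, locus in enumerate(loci):
        alleles[:, j, :] = np.asarray(calls_by_locus[locus])
    individuals = pd.DataFrame(
        {"individual_id": [f"i{k + 1}" for k in range(n)], "population": population}
    )
    return GenotypeTable(individuals, loci, alleles)
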