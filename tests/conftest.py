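import numpy as np
import pandas as pd
import pytest

from ssgblup.types import GenotypeMatrix


def make_pedigree(rows):
    """rows: (animal, sire, dam, birth_year, breed_fraction)."""
    return pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "birth_year", "breed_fraction"]
    )


@pytest.fixture
def trio_pedigree():
    """Two unrelated non-inbred parents and one offspring."""
    return make_pedigree(
        [(1, 0, 0, 2000, 0.0), (2, 0, 0, 2000, 1.0), (3, 1, 2, 2001, 0.5)]
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Parents, two full sibs, and an offspring of the full-sib mating."""
    return make_pedigree(
        [
            (1, 0, 0, 2000, 0.0),
            (2, 0, 0, 2000, 1.0),
            (3, 1, 2, 2001, 0.5),
            (4, 1, 2, 2001, 0.5),
            (5, 3, 4, 2002, 0.5),
        ]
    )


def make_genotypes(codes, chrom=None, bp=None):
    """GenotypeMatrix from a plain (animals x markers) array."""
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    if chrom is None:
        chrom = ["1"] * m
    if bp is None:
        bp = list(range(1000, 1000 + 1000 * m, 1000))
    marker_map = pd.DataFrame(
        {"marker": [f"SNP{j + 1}" for j in range(m)], "chrom": chrom, "bp": bp}
    )
    return GenotypeMatrix(
        animal_ids=np.arange(1, n + 1),
        marker_ids=marker_map["marker"].to_numpy(),
        marker_map=marker_map,
        codes=codes,
    )


def make_traits(animal_ids, values, trait="MARB", year=2000, age=None, rng=None):
    """One-trait phenotype table for MME tests."""
    n = len(animal_ids)
    if age is None:
        rng = rng or np.random.default_rng(0)
        age = rng.normal(550, 40, n)
    return pd.DataFrame(
        {
            "animal_id": animal_ids,
            "birth_year": year if np.ndim(year) else [year] * n,
            "age_at_slaughter": age,
            trait: values,
        }
    )
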