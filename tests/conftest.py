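"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from svqtl import (
    GeneticMap,
    GenotypeMatrix,
    PhenotypeModel,
    SVLocusSpec,
    make_dh_population,
    simulate_founders,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return GeneticMap.dense({"A01": 2_000_000, "A02": 1_500_000}, spacing_bp=50_000)


@pytest.fixture(scope="session")
def nam_population(small_map):
    """7-founder NAM population with one planted 288 bp deletion."""
    sv = SVLocusSpec("SVX", "A01", 900_000, 900_288, "DEL", carriers=["P2", "P4", "P6"])
    founders = simulate_founders(7, small_map, [sv], seed=11)
    pop = make_dh_population(founders, seed=12)
    return pop


@pytest.fixture(scope="session")
def nam_phenotypes(nam_population):
    model = PhenotypeModel(qtl_effects={"SVX": -0.88}, var_ge=0.0, var_e=2.0)
    return simulate_phenotypes(nam_population, model, n_env=5, n_reps=2, seed=13)


def toy_matrix(calls, subfamilies=None, chrom="A01"):
    """Build a GenotypeMatrix from a small integer array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_m, n_i = calls.shape
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "bp": np.arange(1, n_m + 1) * 1000,
            "cm": np.arange(n_m, dtype=float),
        },
        index=pd.Index([f"m{i + 1}" for i in range(n_m)], name="marker"),
    )
    if subfamilies is None:
        subfamilies = ["fam1"] * n_i
    individuals = pd.DataFrame(
        {"subfamily": subfamilies}, index=pd.Index([f"i{j + 1}" for j in range(n_i)], name="individual")
    )
    return GenotypeMatrix(calls, markers, individuals)
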