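import numpy as np
import pandas as pd
import pytest

from sgqtl import (
    CrossPopulation,
    GeneticMap,
    SimConfig,
    SimQTL,
    default_map,
    simulate_f2_population,
)


@pytest.fixture
def tiny_map() -> GeneticMap:
    """Three markers on one chromosome at 0, 10, 20 cM."""
    return GeneticMap({"1": pd.Series([0.0, 10.0, 20.0], index=["m1", "m2", "m3"])})


@pytest.fixture
def small_map() -> GeneticMap:
    """Three 60-cM chromosomes with 10-cM marker spacing."""
    return default_map(n_chromosomes=3, chrom_length_cm=60.0, marker_spacing_cm=10.0)


def make_population(
    gmap: GeneticMap,
    genotypes: np.ndarray,
    protein: np.ndarray,
    oil: np.ndarray | None = None,
    population_id: str = "test",
) -> CrossPopulation:
    """Assemble a CrossPopulation from raw arrays (ints, -1 = missing)."""
    n = len(protein)
    idx = [f"{population_id}_{i + 1:03d}" for i in range(n)]
    if oil is None:
        oil = np.full(n, 180.0)
    pheno = pd.DataFrame({"protein": protein, "oil": oil}, index=idx)
    geno = pd.DataFrame(
        np.asarray(genotypes, dtype=np.int8), index=idx, columns=gmap.marker_names
    )
    return CrossPopulation(population_id, pheno, geno, gmap)


@pytest.fixture
def clean_population(small_map) -> CrossPopulation:
    """Fully genotyped null population (no QTL) on the small map."""
    cfg = SimConfig(
        map=small_map,
        n_progeny=200,
        qtls=[],
        residual_sd={"protein": 5.0, "oil": 5.0},
        bimorphic_fraction=1.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_f2_population(cfg)


@pytest.fixture
def qtl_population(small_map) -> CrossPopulation:
    """Population with one additive protein QTL (a = 6 g/kg) at 30 cM on
    chromosome 2."""
    cfg = SimConfig(
        map=small_map,
        n_progeny=250,
        qtls=[SimQTL("2", 30.0, a_protein=6.0, a_oil=-3.0)],
        residual_sd={"protein": 5.0, "oil": 5.0},
        bimorphic_fraction=1.0,
        missing_rate=0.0,
        seed=17,
    )
    return simulate_f2_population(cfg)
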