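"""Synthetic F2 / F2:3-mean populations for selective-genotyping studies.

The generator emulates a biparental soybean mating between a high-protein
germplasm accession (female, contributing the B allele) and an agronomic
cultivar of ordinary protein (male, A allele): a 20-chromosome genome of
~2,156 cM genotyped with a dense SNP panel of which only a bimorphic subset
segregates in any given mating, ~224 progeny phenotyped for seed protein and
oil (g/kg) with a strong negative residual correlation, and QTL acting
additively/dominantly on one or both traits.

Meiosis follows a no-interference (Poisson) crossover process on the cM
scale, so the recombination fraction between positions d cM apart equals the
Haldane value (1 - e^(-2d/100))/2 — the same map function the analysis uses.

Under ``generation = "F2:3-mean"`` the phenotype attributed to an F2 plant
is its selfed-family mean, which halves the dominance contribution of
heterozygotes (a heterozygous family segregates 1:2:1, so its mean genotypic
value is d/2) while leaving homozygote values at +/- a.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross_io import MISSING, CrossPopulation, GeneticMap
from .linkage import haldane

#: Default parent trait means in g/kg: a high-protein accession female and a
#: high-yield / ordinary-protein male, typical of the germplasm extremes
#: such surveys mate together.
DEFAULT_TRAIT_MEANS: dict[str, dict[str, float]] = {
    "female": {"protein": 505.0, "oil": 160.0},
    "male": {"protein": 415.0, "oil": 190.0},
}

__all__ = [
    "SimQTL",
    "SimConfig",
    "ParentalReplicates",
    "default_map",
    "simulate_meiosis",
    "simulate_f2_population",
    "simulate_parental_replicates",
    "DEFAULT_TRAIT_MEANS",
]


def default_map(
    n_chromosomes: int = 20,
    chrom_length_cm: float = 107.8,
    marker_spacing_cm: float = 1.4,
) -> GeneticMap:
    """Deterministic dense-panel map: evenly spaced markers on equal-length
    chromosomes (defaults: 20 x 107.8 cM = 2,156 cM at 1.4-cM spacing,
    ~1,560 markers — a full-chip analogue of which ~29% segregate per
    mating, leaving ~450 informative SNPs at ~4.8-cM effective spacing)."""
    positions = {}
    counter = 1
    for c in range(1, n_chromosomes + 1):
        cm = np.round(np.arange(0.0, chrom_length_cm + 1e-9, marker_spacing_cm), 6)
        names = [f"S{counter + j:05d}" for j in range(cm.size)]
        counter += cm.size
        positions[str(c)] = pd.Series(cm, index=names, dtype=float)
    return GeneticMap(positions)


@dataclass(frozen=True)
class SimQTL:
    """A simulated QTL with per-trait additive and dominance effects (g/kg).

    ``a > 0`` means the female-parent B allele increases the trait."""

    chromosome: str
    position: float
    a_protein: float = 0.0
    d_protein: float = 0.0
    a_oil: float = 0.0
    d_oil: float = 0.0

    def effects(self, trait: str) -> tuple[float, float]:
        if trait == "protein":
            return self.a_protein, self.d_protein
        if trait == "oil":
            return self.a_oil, self.d_oil
        raise KeyError(trait)


@dataclass
class SimConfig:
    """Study conditions for one simulated mating."""

    map: GeneticMap = field(default_factory=default_map)
    n_progeny: int = 224
    qtls: Sequence[SimQTL] = field(default_factory=list)
    trait_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_MEANS.items()}
    )
    residual_sd: Mapping[str, float] = field(
        default_factory=lambda: {"protein": 3.0, "oil": 3.1}
    )
    residual_correlation: float = -0.78
    bimorphic_fraction: float = 0.293
    missing_rate: float = 0.01
    generation: str = "F2:3-mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 2:
            raise ValueError("n_progeny must be >= 2")
        if not 0.0 <= self.bimorphic_fraction <= 1.0:
            raise ValueError("bimorphic_fraction must lie in [0, 1]")
        if abs(self.residual_correlation) > 1.0:
            raise ValueError("|residual_correlation| must be <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.generation not in ("F2", "F2:3-mean"):
            raise ValueError("generation must be 'F2' or 'F2:3-mean'")
        for q in self.qtls:
            lo, hi = self.map.span(q.chromosome)
            if not lo <= q.position <= hi:
                raise ValueError(
                    f"QTL at {q.position} cM lies off chromosome "
                    f"{q.chromosome} (span {lo}-{hi} cM)"
                )
            for trait in ("protein", "oil"):
                if not all(np.isfinite(q.effects(trait))):
                    raise ValueError("QTL effects must be finite")

    @property
    def traits(self) -> list[str]:
        return list(self.residual_sd)


def _simulate_gametes(
    cm: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_gametes, n_loci) 0/1 parental-origin labels for one chromosome
    under Haldane-consistent (no-interference) meiosis."""
    if cm.size and np.any(np.diff(cm) < 0):
        raise ValueError("marker positions must be sorted (invalid map)")
    state = np.empty((n_gametes, cm.size), dtype=np.int64)
    state[:, 0] = rng.integers(0, 2, size=n_gametes)
    if cm.size > 1:
        r = np.atleast_1d(haldane(np.diff(cm)))
        state[:, 1:] = rng.random((n_gametes, cm.size - 1)) < r[None, :]
        state = np.cumsum(state, axis=1) % 2
    return state.astype(np.int8)


def simulate_meiosis(gmap: GeneticMap, seed: int | np.random.Generator):
    """One gamete: 0/1 parental-origin labels at every marker, per chromosome.

    Crossovers follow a Poisson process on the cM scale, so the recombination
    fraction between loci d cM apart is the Haldane value."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not gmap.chromosomes:
        raise ValueError("map has no chromosomes")
    return {
        chrom: _simulate_gametes(gmap.cm(chrom), 1, rng)[0]
        for chrom in gmap.chromosomes
    }


def _qtl_genotypes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Simulate F2 genotypes (0/1/2 B-allele counts) at all markers and QTL
    jointly, respecting linkage between QTL and flanking markers."""
    n = config.n_progeny
    marker_geno: dict[str, np.ndarray] = {}
    qtl_geno: dict[int, np.ndarray] = {}
    for chrom in config.map.chromosomes:
        cm = config.map.cm(chrom)
        q_here = [(k, q) for k, q in enumerate(config.qtls) if q.chromosome == chrom]
        aug = np.concatenate([cm, [q.position for _, q in q_here]])
        order = np.argsort(aug, kind="stable")
        aug_sorted = aug[order]
        g = (
            _simulate_gametes(aug_sorted, n, rng)
            + _simulate_gametes(aug_sorted, n, rng)
        ).astype(np.int8)
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        g = g[:, inv]  # back to original (markers first, then QTL) order
        marker_geno[chrom] = g[:, : cm.size]
        for pos_k, (k, _) in enumerate(q_here):
            qtl_geno[k] = g[:, cm.size + pos_k]
    return marker_geno, {str(k): v for k, v in qtl_geno.items()}


def _genetic_values(config: SimConfig, qtl_geno: Mapping[str, np.ndarray]) -> pd.DataFrame:
    n = config.n_progeny
    vals = {}
    half_dom = config.generation == "F2:3-mean"
    for trait in config.traits:
        g = np.zeros(n)
        for k, q in enumerate(config.qtls):
            geno = qtl_geno[str(k)]
            a, d = q.effects(trait)
            x = geno.astype(float) - 1.0  # -1, 0, +1
            z = (geno == 1).astype(float)
            if half_dom:
                z = z / 2.0
            g += a * x + d * z
        vals[trait] = g
    return pd.DataFrame(vals)


def simulate_f2_population(
    config: SimConfig, population_id: str | None = None
) -> CrossPopulation:
    """Simulate one mating under ``config``.

    Genotypes are A/H/B with 1:2:1 expectation at segregating markers; a
    random (1 - bimorphic_fraction) subset of markers is monomorphic (both
    parents carried the same allele, so every progeny shows one homozygous
    code); genotype calls then go missing uniformly at ``missing_rate``.
    Phenotypes are midparent mean + QTL genotypic value + a correlated
    bivariate residual.
    """
    rng = np.random.default_rng(config.seed)
    if population_id is None:
        population_id = f"sim{config.seed}"
    n = config.n_progeny
    marker_geno, qtl_geno = _qtl_genotypes(config, rng)

    traits = config.traits
    means = {
        t: 0.5
        * (config.trait_means["female"][t] + config.trait_means["male"][t])
        for t in traits
    }
    genetic = _genetic_values(config, qtl_geno)
    sds = np.array([config.residual_sd[t] for t in traits], dtype=float)
    corr = np.eye(len(traits))
    if len(traits) == 2:
        corr[0, 1] = corr[1, 0] = config.residual_correlation
    cov = np.outer(sds, sds) * corr
    resid = rng.multivariate_normal(np.zeros(len(traits)), cov, size=n, method="svd")
    pheno = pd.DataFrame(
        {t: means[t] + genetic[t].to_numpy() + resid[:, j] for j, t in enumerate(traits)},
        index=[f"{population_id}_{i + 1:03d}" for i in range(n)],
    )

    # monomorphic masking: non-bimorphic SNPs show one parental homozygote
    all_markers = config.map.marker_names
    m_total = len(all_markers)
    mono_mask = rng.random(m_total) >= config.bimorphic_fraction
    mono_code = rng.integers(0, 2, size=m_total) * 2  # A or B, 50/50
    geno_full = np.concatenate(
        [marker_geno[c] for c in config.map.chromosomes], axis=1
    )
    geno_full[:, mono_mask] = mono_code[mono_mask]
    if config.missing_rate > 0:
        miss = rng.random(geno_full.shape) < config.missing_rate
        geno_full[miss] = MISSING
    genotypes = pd.DataFrame(
        geno_full, index=pheno.index, columns=all_markers, dtype=np.int8
    )
    return CrossPopulation(population_id, pheno, genotypes, config.map)


@dataclass
class ParentalReplicates:
    """Replicated phenotypes of the two homozygous parents, per trait.

    ``female`` and ``male`` are DataFrames with one column per trait and one
    row per replicate plant; with inbred parents all within-parent dispersion
    is environmental, which is what makes these replicates usable as an
    indirect estimate of environmental variance."""

    female: pd.DataFrame
    male: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.female) < 2 or len(self.male) < 2:
            raise ValueError("need >= 2 replicates per parent for a variance")
        if list(self.female.columns) != list(self.male.columns):
            raise ValueError("parents measured for different traits")

    @property
    def traits(self) -> list[str]:
        return list(self.female.columns)


def simulate_parental_replicates(
    env_sd: Mapping[str, float] | float,
    n_reps: int,
    seed: int | np.random.Generator = 0,
    trait_means: Mapping[str, Mapping[str, float]] | None = None,
) -> ParentalReplicates:
    """Replicate phenotypes for the homozygous parents with purely
    environmental dispersion ``env_sd`` (g/kg) around each parent mean."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if trait_means is None:
        trait_means = DEFAULT_TRAIT_MEANS
    traits = list(trait_means["female"])
    if np.isscalar(env_sd):
        env_sd = {t: float(env_sd) for t in traits}
    frames = {}
    for parent in ("female", "male"):
        frames[parent] = pd.DataFrame(
            {
                t: trait_means[parent][t] + env_sd[t] * rng.standard_normal(n_reps)
                for t in traits
            }
        )
    return ParentalReplicates(female=frames["female"], male=frames["male"])
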