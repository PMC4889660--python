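"""Multi-population orchestration: surveys, pooling, and design power.

A survey runs the full selective-genotyping pipeline over many simulated
matings — QC, tail selection on the SG trait (protein), genotype masking,
multipoint probabilities, EM scans of both traits on the same selected
individuals, stratified permutation thresholds, and QTL calls — and collects
the per-(population, trait, chromosome) peak summaries into one table (the
machine-readable content of a survey heat map).

Pooling concatenates populations that share a female-parent genotype,
keeping only markers bimorphic in every member; the larger n buys LOD for
QTL shared across members.

Power estimation simulates the design end to end: one QTL of specified
variance share placed at a random map position, SG applied, the genome
scanned, and detection scored only when a significant peak lands on the true
chromosome within 20 cM of the truth (a significant peak elsewhere is a
false positive, not power).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cross_io import MISSING, CrossPopulation, qc_filter
from .inference import (
    call_qtls,
    qtl_records_frame,
    stratified_permutation_threshold,
)
from .linkage import genotype_probabilities
from .scan import scan_em
from .selection import SelectionConfig, apply_selective_genotyping, select_tails
from .simdata import SimConfig, SimQTL, default_map, simulate_f2_population

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "SurveyTable",
    "run_survey",
    "pool_populations",
    "PowerConfig",
    "estimate_power",
]


@dataclass
class PopulationSpec:
    """Settings for one survey member: how to simulate and how to select."""

    sim: SimConfig
    selection: SelectionConfig | None = field(
        default_factory=lambda: SelectionConfig()
    )
    population_id: str | None = None


@dataclass
class SurveyTable:
    """Rows: (population, trait, chromosome) peak LOD, significance, a, d, R^2."""

    table: pd.DataFrame
    failures: list[str] = field(default_factory=list)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def analyze_population(
    pop: CrossPopulation,
    traits: Sequence[str] = ("protein", "oil"),
    step: float = 1.0,
    error_rate: float = 1e-4,
    n_perm: int = 1900,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    reporting_floor: float = 1.0,
    rf_ceiling: float = 0.55,
) -> pd.DataFrame:
    """QC + scan + stratified permutation + QTL calls for one population."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pop_qc, _ = qc_filter(pop, rf_ceiling=rf_ceiling)
    grid = genotype_probabilities(pop_qc, step=step, error_rate=error_rate)
    records = []
    for trait in traits:
        res = scan_em(pop_qc, grid, trait=trait)
        perm = stratified_permutation_threshold(
            pop_qc, trait=trait, n_perm=n_perm, alpha=alpha, seed=rng, grid=grid
        )
        records.extend(
            call_qtls(res, perm, pop_qc, grid, reporting_floor=reporting_floor)
        )
    return qtl_records_frame(records)


def run_survey(
    configs: Sequence[PopulationSpec],
    traits: Sequence[str] = ("protein", "oil"),
    step: float = 1.0,
    error_rate: float = 1e-4,
    n_perm: int = 1900,
    alpha: float = 0.05,
    reporting_floor: float = 1.0,
) -> SurveyTable:
    """Run the SG pipeline over every mating in ``configs``.

    Selection is always on the SG trait (protein); the companion trait is
    scanned on the same selected individuals.  Per-population failures are
    logged and isolated; the survey continues.  Fully deterministic given
    the per-population seeds.
    """
    frames: list[pd.DataFrame] = []
    failures: list[str] = []
    for k, spec in enumerate(configs):
        pid = spec.population_id or f"mating{k + 1:02d}"
        try:
            pop = simulate_f2_population(spec.sim, population_id=pid)
            if spec.selection is not None:
                low, high = select_tails(pop.trait_values("protein"), spec.selection)
                pop = apply_selective_genotyping(pop, low, high)
            frames.append(
                analyze_population(
                    pop,
                    traits=traits,
                    step=step,
                    error_rate=error_rate,
                    n_perm=n_perm,
                    alpha=alpha,
                    seed=spec.sim.seed + 2_000_003,
                    reporting_floor=reporting_floor,
                )
            )
        except Exception as exc:  # per-population isolation
            logger.warning("population %s failed: %s", pid, exc)
            failures.append(f"{pid}: {exc}")
    cols = [
        "population_id", "trait", "chromosome", "position", "lod",
        "threshold", "significant", "a", "d", "r2",
    ]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=cols)
    )
    return SurveyTable(table=table, failures=failures)


def pool_populations(
    pops: Sequence[CrossPopulation],
    center: bool = False,
    population_id: str = "pooled",
) -> CrossPopulation:
    """Concatenate populations sharing a map into one larger population.

    The marker set is the intersection of markers bimorphic (>= 2 observed
    genotype classes) in every member; with ``center=True`` each member's
    phenotypes are mean-centred per trait before pooling, which removes
    male-parent mean differences while leaving within-population ranks
    unchanged.  SG strata flags are preserved.
    """
    if len(pops) < 2:
        raise ValueError("need >= 2 populations to pool")
    gmap = pops[0].map
    for p in pops[1:]:
        if p.map != gmap:
            raise ValueError("populations must share a common map")
    common: set[str] | None = None
    for p in pops:
        vals = p.genotypes.to_numpy()
        bimorphic = {
            m
            for j, m in enumerate(p.genotypes.columns)
            if np.unique(vals[:, j][vals[:, j] != MISSING]).size >= 2
        }
        common = bimorphic if common is None else (common & bimorphic)
    if not common:
        raise ValueError("no marker is bimorphic in every pooled population")
    keep = [m for m in gmap.marker_names if m in common]
    phenos = []
    genos = []
    for p in pops:
        ph = p.phenotypes.copy()
        if center:
            for trait in p.traits:
                ph[trait] = ph[trait] - ph[trait].mean()
        ph.index = [f"{p.population_id}:{i}" for i in ph.index]
        g = p.genotypes[keep].copy()
        g.index = ph.index
        phenos.append(ph)
        genos.append(g)
    return CrossPopulation(
        population_id,
        pd.concat(phenos),
        pd.concat(genos),
        gmap.subset(keep),
    )


@dataclass
class PowerConfig:
    """Monte-Carlo design-power settings for a single-QTL SG experiment."""

    n_phenotyped: int = 224
    tail_fraction: float = 0.10
    marker_spacing_cm: float = 5.0
    qtl_r2: float | None = 0.15
    a: float | None = None
    residual_sd: float = 5.0
    alpha: float = 0.05
    threshold_mode: str = "fixed"  # "fixed" or "permutation"
    fixed_lod: float = 4.0
    n_perm: int = 1000
    n_sim: int = 100
    seed: int = 0
    n_chromosomes: int = 20
    chrom_length_cm: float = 107.8
    locate_within_cm: float = 20.0
    dominance: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sim < 20:
            raise ValueError("n_sim must be >= 20")
        if not 0.0 < self.tail_fraction <= 0.5:
            raise ValueError("tail_fraction must lie in (0, 0.5]")
        if self.threshold_mode not in ("fixed", "permutation"):
            raise ValueError("threshold_mode must be 'fixed' or 'permutation'")
        if self.qtl_r2 is None and self.a is None:
            raise ValueError("give either qtl_r2 or an additive effect a")

    def additive_effect(self) -> float:
        """Additive effect implied by the requested variance share: with an
        additive F2 QTL, var_QTL = a^2/2, so a = sd * sqrt(2 r2 / (1-r2))."""
        if self.a is not None:
            return float(self.a)
        r2 = float(self.qtl_r2)
        if not 0.0 <= r2 < 1.0:
            raise ValueError("qtl_r2 must lie in [0, 1)")
        return self.residual_sd * math.sqrt(2.0 * r2 / (1.0 - r2))


def estimate_power(config: PowerConfig) -> tuple[float, float]:
    """Empirical detection power and its binomial Monte-Carlo SE.

    Each replicate simulates an F2:3-mean population with one QTL at a
    random map position, applies two-tail SG on protein, scans the genome,
    and scores detection when the true chromosome's peak exceeds the
    threshold and lies within ``locate_within_cm`` of the simulated
    position.
    """
    rng = np.random.default_rng(config.seed)
    gmap = default_map(
        n_chromosomes=config.n_chromosomes,
        chrom_length_cm=config.chrom_length_cm,
        marker_spacing_cm=config.marker_spacing_cm,
    )
    a = config.additive_effect()
    hits = 0
    for b in range(config.n_sim):
        chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
        lo, hi = gmap.span(chrom)
        qpos = float(np.round(rng.uniform(lo, hi), 2))
        sim = SimConfig(
            map=gmap,
            n_progeny=config.n_phenotyped,
            qtls=[SimQTL(chromosome=chrom, position=qpos, a_protein=a,
                         d_protein=config.dominance)],
            residual_sd={"protein": config.residual_sd,
                         "oil": config.residual_sd},
            bimorphic_fraction=1.0,
            missing_rate=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pop = simulate_f2_population(sim)
        sel = SelectionConfig(
            stage1_fraction=min(2 * config.tail_fraction, 0.5),
            stage2_fraction=config.tail_fraction,
            remeasure_sd=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        low, high = select_tails(pop.trait_values("protein"), sel)
        pop = apply_selective_genotyping(pop, low, high)
        grid = genotype_probabilities(pop, step=config.marker_spacing_cm)
        res = scan_em(pop, grid, trait="protein")
        if config.threshold_mode == "fixed":
            threshold = config.fixed_lod
        else:
            perm = stratified_permutation_threshold(
                pop,
                trait="protein",
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=rng,
                grid=grid,
            )
            threshold = perm.threshold
        sub = res.table[res.table["chromosome"] == chrom]
        j = int(np.argmax(sub["lod"].to_numpy()))
        peak = sub.iloc[j]
        if (
            peak["lod"] > threshold
            and abs(peak["position"] - qpos) <= config.locate_within_cm
        ):
            hits += 1
    power = hits / config.n_sim
    se = math.sqrt(power * (1.0 - power) / config.n_sim)
    return power, se
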