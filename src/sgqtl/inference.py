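"""Significance thresholds, QTL calls, and effect estimation.

Genome-wise significance under selective genotyping uses *stratified*
permutation: phenotypes are shuffled separately within the genotyped and the
ungenotyped strata, preserving the association between phenotypic extremity
and genotype availability that SG builds into the data.  The threshold is
the empirical (1 - alpha) quantile of the genome-maximum LOD over
permutation replicates.

Additive (a) and dominance (d) effects follow the F2 convention: with class
means (m_AA, m_AB, m_BB),

    a = (m_BB - m_AA) / 2      (a > 0: the female-parent B allele raises
                                the trait)
    d = m_AB - (m_AA + m_BB)/2 (d > 0: heterozygote above the homozygote
                                midpoint)

and the variance explained by a QTL of peak LOD L in n phenotyped progeny is
R^2 = 1 - 10^(-(2/n) L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_io import CrossPopulation
from .linkage import GenoProbGrid, genotype_probabilities
from .scan import ScanResult, scan_em

__all__ = [
    "required_permutations",
    "PermutationResult",
    "stratified_permutation_threshold",
    "estimate_effects",
    "rsq_from_lod",
    "QTLRecord",
    "call_qtls",
    "effect_scan",
]


def required_permutations(alpha: float, target_se: float) -> int:
    """Smallest replicate count n with sqrt(alpha(1-alpha)/n) <= target_se."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if target_se <= 0:
        raise ValueError("target_se must be positive")
    return max(1, math.ceil(alpha * (1.0 - alpha) / target_se**2 - 1e-12))


@dataclass
class PermutationResult:
    """Null distribution of the genome-maximum LOD under permutation."""

    null_max_lods: np.ndarray
    alpha: float
    threshold: float
    se_alpha: float

    @property
    def n_perm(self) -> int:
        return self.null_max_lods.size


def permutation_threshold_from_nulls(
    null_max_lods: np.ndarray, alpha: float
) -> float:
    """Order-statistic threshold at rank ceil((1 - alpha) * (n + 1))."""
    nulls = np.sort(np.asarray(null_max_lods, dtype=float))
    n = nulls.size
    rank = min(n, math.ceil((1.0 - alpha) * (n + 1)))
    return float(nulls[rank - 1])


def stratified_permutation_threshold(
    pop: CrossPopulation,
    trait: str = "protein",
    n_perm: int = 1900,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    grid: GenoProbGrid | None = None,
    step: float = 1.0,
    error_rate: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 4000,
) -> PermutationResult:
    """Genome-wise LOD threshold by SG-stratified permutation.

    Each replicate permutes the trait independently within the genotyped and
    the ungenotyped strata (never across them), re-runs the genome scan on
    cached genotype probabilities, and records the genome-maximum LOD.  With
    a fully genotyped population this reduces to an ordinary unstratified
    shuffle.  An empty stratum is vacuous; a stratum with exactly one
    individual is rejected as degenerate.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if grid is None:
        grid = genotype_probabilities(pop, step=step, error_rate=error_rate)
    genotyped = pop.phenotypes["genotyped"].to_numpy(dtype=bool)
    strata = [np.nonzero(genotyped)[0], np.nonzero(~genotyped)[0]]
    for s in strata:
        if s.size == 1:
            raise ValueError("degenerate stratum of size 1")
    work = pop.copy()
    y = pop.trait_values(trait)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        yp = y.copy()
        for s in strata:
            if s.size:
                yp[s] = y[s][rng.permutation(s.size)]
        work.phenotypes[trait] = yp
        res = scan_em(work, grid, trait=trait, tol=tol, max_iter=max_iter)
        null_max[b] = res.genome_max_lod
    threshold = permutation_threshold_from_nulls(null_max, alpha)
    se_alpha = math.sqrt(alpha * (1.0 - alpha) / n_perm)
    return PermutationResult(null_max, alpha, threshold, se_alpha)


def _weighted_class_means(
    y: np.ndarray, w: np.ndarray, min_weight: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype-probability-weighted phenotype means and their SEs.

    ``w`` is (N, 3).  Reduces to raw class means when genotypes are observed
    (degenerate weights).  Raises if a class's total weight falls below
    ``min_weight`` (effectively empty class).
    """
    totals = w.sum(axis=0)
    if np.any(totals < min_weight):
        raise ValueError(
            f"effective class weight below {min_weight}: {np.round(totals, 3)}"
        )
    means = (w * y[:, None]).sum(axis=0) / totals
    se2 = (w**2 * (y[:, None] - means[None, :]) ** 2).sum(axis=0) / totals**2
    return means, np.sqrt(se2)


def estimate_effects(
    pop: CrossPopulation,
    grid: GenoProbGrid,
    chromosome: str,
    position: float,
    trait: str = "protein",
) -> tuple[float, float, np.ndarray]:
    """Additive and dominance effects at a grid position.

    Returns ``(a, d, class_means)`` with class means computed as genotype-
    probability-weighted phenotype means over the phenotyped *genotyped*
    individuals — the multipoint analogue of averaging the phenotypes of
    each observed A/H/B class.  Ungenotyped individuals carry only the
    uninformative 1:2:1 prior; including them would add identical weight to
    all three classes and shrink the contrasts toward zero, so they are
    excluded here (they still contribute to LOD scores through the mixture
    likelihood).  Under selective genotyping these class contrasts inherit
    the design's upward bias on |a| among significant calls.
    """
    j = grid.position_index(chromosome, position)
    y_all = pop.trait_values(trait)
    keep = np.isfinite(y_all) & pop.phenotypes["genotyped"].to_numpy(dtype=bool)
    w = grid.probs[chromosome][keep, j, :]
    means, _ = _weighted_class_means(y_all[keep], w)
    a = (means[2] - means[0]) / 2.0
    d = means[1] - (means[0] + means[2]) / 2.0
    return float(a), float(d), means


def rsq_from_lod(n: int, lod: float) -> float:
    """Fraction of phenotypic variance explained: 1 - 10^(-(2/n) LOD)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if lod < 0:
        raise ValueError("lod must be >= 0")
    return float(1.0 - 10.0 ** (-(2.0 / n) * lod))


@dataclass
class QTLRecord:
    """Peak summary for one chromosome of one population x trait scan."""

    population_id: str
    trait: str
    chromosome: str
    position: float
    lod: float
    threshold: float
    significant: bool
    a: float
    d: float
    r2: float


def call_qtls(
    scan: ScanResult,
    perm: PermutationResult | float,
    pop: CrossPopulation,
    grid: GenoProbGrid,
    reporting_floor: float = 1.0,
    include_all: bool = False,
) -> list[QTLRecord]:
    """One record per chromosome at its peak LOD (lowest-cM tie-break).

    ``perm`` may be a PermutationResult or a fixed LOD threshold.  Records
    with peak LOD below ``reporting_floor`` are suppressed unless
    ``include_all`` — they carry no evidential weight but are available for
    complete tables.
    """
    threshold = perm.threshold if isinstance(perm, PermutationResult) else float(perm)
    records: list[QTLRecord] = []
    for _, row in scan.chromosome_peaks().iterrows():
        lod = float(row["lod"])
        if lod < reporting_floor and not include_all:
            continue
        chrom = row["chromosome"]
        pos = float(row["position"])
        try:
            a, d, _ = estimate_effects(pop, grid, chrom, pos, scan.trait)
        except ValueError:
            a = d = float("nan")
        records.append(
            QTLRecord(
                population_id=pop.population_id,
                trait=scan.trait,
                chromosome=chrom,
                position=pos,
                lod=lod,
                threshold=threshold,
                significant=lod > threshold,
                a=a,
                d=d,
                r2=rsq_from_lod(scan.n_phenotyped, lod),
            )
        )
    return records


def qtl_records_frame(records: list[QTLRecord]) -> pd.DataFrame:
    cols = [
        "population_id", "trait", "chromosome", "position", "lod",
        "threshold", "significant", "a", "d", "r2",
    ]
    return pd.DataFrame([vars(r) for r in records], columns=cols)


def effect_scan(
    pop: CrossPopulation,
    grid: GenoProbGrid,
    chromosome: str,
    trait: str = "protein",
) -> pd.DataFrame:
    """Additive/dominance effect profile along one chromosome.

    Returns a DataFrame with columns position, a, d, se_a, se_d; its
    ``attrs`` record the cM positions of the positive and negative
    additive-effect maxima.  Class means come from the phenotyped genotyped
    individuals (see :func:`estimate_effects`); positions whose effective
    class weights are too small yield NaN effects.
    """
    y_all = pop.trait_values(trait)
    keep = np.isfinite(y_all) & pop.phenotypes["genotyped"].to_numpy(dtype=bool)
    y = y_all[keep]
    W = grid.probs[chromosome][keep]
    rows = []
    for j, cm in enumerate(grid.grid_cm[chromosome]):
        try:
            means, ses = _weighted_class_means(y, W[:, j, :])
        except ValueError:
            rows.append((cm, np.nan, np.nan, np.nan, np.nan))
            continue
        a = (means[2] - means[0]) / 2.0
        d = means[1] - (means[0] + means[2]) / 2.0
        se_a = 0.5 * np.sqrt(ses[0] ** 2 + ses[2] ** 2)
        se_d = np.sqrt(ses[1] ** 2 + 0.25 * (ses[0] ** 2 + ses[2] ** 2))
        rows.append((cm, a, d, se_a, se_d))
    out = pd.DataFrame(rows, columns=["position", "a", "d", "se_a", "se_d"])
    a_vals = out["a"].to_numpy()
    if np.any(np.isfinite(a_vals)):
        pos_max = out["position"][np.nanargmax(a_vals)] if np.nanmax(a_vals) > 0 else np.nan
        neg_max = out["position"][np.nanargmin(a_vals)] if np.nanmin(a_vals) < 0 else np.nan
    else:
        pos_max = neg_max = np.nan
    out.attrs["positive_max_cm"] = float(pos_max) if pos_max == pos_max else np.nan
    out.attrs["negative_max_cm"] = float(neg_max) if neg_max == neg_max else np.nan
    return out
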