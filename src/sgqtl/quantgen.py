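"""Variance components, broad-sense heritability, and phenotype summaries.

An F2 plant cannot be replicated, so its environmental variance is estimated
indirectly from replicated plants of the two homozygous parents grown in the
same nursery row: within-parent dispersion is purely environmental.  The
genetic variance of the progeny is then obtained by subtraction,

    sigma_e^2 = (sigma^2_female + sigma^2_male) / 2
    sigma_g^2 = sigma_p^2 - sigma_e^2
    H^2       = 100 * sigma_g^2 / sigma_p^2   (clamped to [0, 100])

with sample variances on the n-1 denominator throughout.  The symmetric
mean is used for sigma_e^2; optional weights accommodate unbalanced
replication schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cross_io import CrossPopulation
from .simdata import ParentalReplicates

__all__ = [
    "HeritabilityEstimate",
    "environmental_variance",
    "heritability",
    "phenotype_summary",
]


@dataclass(frozen=True)
class HeritabilityEstimate:
    sigma2_p: float
    sigma2_e: float
    sigma2_g: float  # pre-clamp subtraction value
    h2: float  # percent, clamped to [0, 100]
    trait: str = ""


def environmental_variance(
    reps: ParentalReplicates,
    weights: tuple[float, float] = (0.5, 0.5),
) -> pd.Series:
    """Weighted mean of the two parental sample variances, per trait."""
    wf, wm = weights
    if wf < 0 or wm < 0 or abs(wf + wm - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    out = {}
    for trait in reps.traits:
        f = reps.female[trait].to_numpy(dtype=float)
        m = reps.male[trait].to_numpy(dtype=float)
        if f.size < 2 or m.size < 2:
            raise ValueError("need >= 2 replicate values per parent")
        out[trait] = wf * np.var(f, ddof=1) + wm * np.var(m, ddof=1)
    return pd.Series(out)


def heritability(
    progeny_phenotypes: np.ndarray,
    reps: ParentalReplicates,
    trait: str = "protein",
    weights: tuple[float, float] = (0.5, 0.5),
) -> HeritabilityEstimate:
    """Broad-sense heritability of one trait from progeny variance and
    parental-replicate environmental variance.

    When the environmental estimate exceeds the progeny variance the
    subtraction goes negative and H^2 is clamped at 0 (a sampling artefact,
    not evidence of negative genetic variance).
    """
    y = np.asarray(progeny_phenotypes, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 3:
        raise ValueError("need >= 3 progeny phenotypes")
    sigma2_p = float(np.var(y, ddof=1))
    if sigma2_p == 0:
        raise ValueError("zero progeny phenotypic variance; H^2 undefined")
    sigma2_e = float(environmental_variance(reps, weights)[trait])
    sigma2_g = sigma2_p - sigma2_e
    h2 = 100.0 * sigma2_g / sigma2_p
    h2 = float(min(max(h2, 0.0), 100.0))
    return HeritabilityEstimate(sigma2_p, sigma2_e, sigma2_g, h2, trait)


def phenotype_summary(pop: CrossPopulation) -> dict:
    """Descriptive statistics per trait plus the protein-oil correlation.

    Normality is assessed by a standard Shapiro-Wilk routine and reported as
    a p-value only.  A constant trait has undefined correlation and
    normality (reported as NaN).
    """
    if pop.n_individuals < 3:
        raise ValueError("need >= 3 individuals")
    summary: dict = {"population_id": pop.population_id, "n": pop.n_individuals}
    finite: dict[str, np.ndarray] = {}
    for trait in pop.traits:
        y = pop.trait_values(trait)
        y = y[np.isfinite(y)]
        finite[trait] = y
        stats_block = {
            "n": int(y.size),
            "min": float(np.min(y)),
            "max": float(np.max(y)),
            "mean": float(np.mean(y)),
            "variance": float(np.var(y, ddof=1)),
        }
        if np.var(y) > 0 and y.size >= 3:
            stats_block["shapiro_p"] = float(stats.shapiro(y).pvalue)
        else:
            stats_block["shapiro_p"] = float("nan")
        summary[trait] = stats_block
    traits = pop.traits
    if len(traits) == 2:
        a, b = (pop.trait_values(t) for t in traits)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3 and np.var(a[ok]) > 0 and np.var(b[ok]) > 0:
            summary["correlation"] = float(stats.pearsonr(a[ok], b[ok]).statistic)
        else:
            summary["correlation"] = float("nan")
    return summary
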