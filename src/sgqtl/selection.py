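"""Two-stage phenotypic tail selection and selective-genotyping masking.

Selective genotyping (SG) phenotypes the whole population but genotypes only
the extreme tails of one trait's distribution.  The two-stage procedure
mirrors assay-thrifty practice: a single measurement ranks everybody, the
top and bottom ``stage1_fraction`` are re-measured, and the mean of the two
replicates picks the final ``stage2_fraction`` tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cross_io import MISSING, CrossPopulation

__all__ = ["SelectionConfig", "select_tails", "apply_selective_genotyping"]


@dataclass(frozen=True)
class SelectionConfig:
    stage1_fraction: float = 0.20
    stage2_fraction: float = 0.10
    remeasure_sd: float = 0.0  # g/kg noise of the second assay replicate
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.stage2_fraction <= self.stage1_fraction <= 0.5:
            raise ValueError("need 0 < stage2_fraction <= stage1_fraction <= 0.5")


def select_tails(
    phenotypes: np.ndarray, config: SelectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Return (low-tail, high-tail) index arrays of size floor(f2 * n) each.

    Stage 1 ranks the single-replicate values; stage 2 adds ``remeasure_sd``
    noise to the retained fractions, averages the two replicates, and keeps
    the extremes.  Ties are broken by original row order (stable sort), so
    the procedure is reproducible.  With ``remeasure_sd = 0`` it collapses to
    single-stage ranking.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 individuals")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    k1 = int(np.floor(config.stage1_fraction * n))
    k2 = int(np.floor(config.stage2_fraction * n))
    if k2 < 1 or 2 * k1 > n:
        raise ValueError(
            f"tails would overlap or be empty (n={n}, k1={k1}, k2={k2})"
        )
    order = np.argsort(y, kind="stable")
    low1, high1 = order[:k1], order[n - k1:]
    rng = np.random.default_rng(config.seed)
    retained = np.concatenate([low1, high1])
    y2 = y.copy()
    y2[retained] = y[retained] + config.remeasure_sd * rng.standard_normal(retained.size)
    avg = 0.5 * (y + y2)
    low = low1[np.argsort(avg[low1], kind="stable")][:k2]
    high = high1[np.argsort(-avg[high1], kind="stable")][:k2]
    return np.sort(low), np.sort(high)


def apply_selective_genotyping(
    pop: CrossPopulation, low: np.ndarray, high: np.ndarray
) -> CrossPopulation:
    """Mask genotypes of every individual outside ``low``/``high``.

    Phenotypes are never altered — the whole population stays phenotyped;
    only the selected tails keep genotype calls and the ``genotyped`` flag.
    """
    low = np.asarray(low, dtype=int)
    high = np.asarray(high, dtype=int)
    if np.intersect1d(low, high).size:
        raise ValueError("low and high tails must be disjoint")
    out = pop.copy()
    selected = np.zeros(pop.n_individuals, dtype=bool)
    selected[low] = True
    selected[high] = True
    geno = out.genotypes.to_numpy()
    geno[~selected, :] = MISSING
    out.genotypes = out.genotypes.copy()
    out.genotypes.iloc[:, :] = geno
    out.phenotypes["genotyped"] = selected
    return out
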