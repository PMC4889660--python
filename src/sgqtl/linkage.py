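"""Map-function utilities and multipoint F2 genotype probabilities.

Distances are in cM throughout.  The Haldane map function (no crossover
interference) links map distance to recombination fraction, matching the
Poisson crossover process used by the simulator, so simulation and analysis
share a single genetic model.

Multipoint genotype probabilities are computed on a pseudo-marker grid by a
forward-backward (hidden Markov) recursion over the three F2 genotypes
(AA, AB, BB) with prior (1/4, 1/2, 1/4), transition matrices built from
Haldane recombination fractions between adjacent grid points, and an
emission model allowing a small genotyping-error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cross_io import MISSING, CrossPopulation

F2_PRIOR = np.array([0.25, 0.5, 0.25])

__all__ = ["haldane", "inverse_haldane", "f2_transition", "GenoProbGrid",
           "genotype_probabilities"]


def haldane(d) -> np.ndarray | float:
    """Recombination fraction for a distance ``d`` in cM: (1 - e^(-2d/100))/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def inverse_haldane(r) -> np.ndarray | float:
    """Map distance in cM for a recombination fraction ``r`` < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def f2_transition(r: float) -> np.ndarray:
    """3x3 transition matrix between F2 genotypes at loci with gamete
    recombination fraction ``r`` (two independent gametes)."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def _emission(obs: np.ndarray, error_rate: float) -> np.ndarray:
    """(n, 3) emission weights for one marker's observed codes."""
    n = obs.shape[0]
    em = np.ones((n, 3))
    seen = obs != MISSING
    if error_rate == 0.0:
        em[seen] = 0.0
        em[seen, obs[seen]] = 1.0
    else:
        em[seen] = error_rate / 2.0
        em[seen, obs[seen]] = 1.0 - error_rate
    return em


@dataclass
class GenoProbGrid:
    """Genotype probabilities on a marker + pseudo-marker grid.

    ``probs[chrom]`` has shape (n_individuals, n_positions, 3) over
    (AA, AB, BB); ``grid_cm[chrom]`` gives positions in cM and
    ``is_marker[chrom]`` flags true marker columns.
    """

    individuals: list[str]
    grid_cm: Mapping[str, np.ndarray]
    is_marker: Mapping[str, np.ndarray]
    probs: Mapping[str, np.ndarray]
    step: float
    error_rate: float

    @property
    def chromosomes(self) -> list[str]:
        return list(self.grid_cm)

    def position_index(self, chrom: str, position: float, tol: float = 1e-6) -> int:
        grid = self.grid_cm[chrom]
        j = int(np.argmin(np.abs(grid - position)))
        if abs(grid[j] - position) > tol:
            raise ValueError(
                f"position {position} cM not on the {chrom} grid "
                f"(nearest {grid[j]:.4f})"
            )
        return j

    def nearest_index(self, chrom: str, position: float) -> int:
        return int(np.argmin(np.abs(self.grid_cm[chrom] - position)))

    def to_frames(self):
        """Tab-friendly dump: one DataFrame per chromosome (debugging aid)."""
        import pandas as pd

        out = {}
        for chrom in self.chromosomes:
            p = self.probs[chrom]
            rows = []
            for j, cm in enumerate(self.grid_cm[chrom]):
                for i, ind in enumerate(self.individuals):
                    rows.append((ind, cm, *p[i, j]))
            out[chrom] = pd.DataFrame(
                rows, columns=["individual", "cm", "pAA", "pAB", "pBB"]
            )
        return out


def _chromosome_grid(marker_cm: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Union of marker positions and a regular ``step`` grid (markers always
    kept as grid points)."""
    lo, hi = marker_cm[0], marker_cm[-1]
    regular = np.arange(lo, hi + step / 2, step)
    grid = np.concatenate([marker_cm, regular])
    grid = np.unique(np.round(grid, 6))
    is_marker = np.isin(grid, np.round(marker_cm, 6))
    return grid, is_marker


def genotype_probabilities(
    pop: CrossPopulation,
    step: float = 1.0,
    error_rate: float = 1e-4,
) -> GenoProbGrid:
    """Multipoint genotype probabilities for every individual of ``pop``.

    Individuals with no genotype calls at all receive the F2 prior
    (0.25, 0.50, 0.25) at every grid position; with ``error_rate = 0`` and an
    observed call the probability is degenerate on that call at the marker.
    """
    if step <= 0:
        raise ValueError("grid step must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    grid_cm: dict[str, np.ndarray] = {}
    is_marker: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    n = pop.n_individuals
    for chrom in pop.map.chromosomes:
        marker_cm = pop.map.cm(chrom)
        if marker_cm.size == 0:
            warnings.warn(f"chromosome {chrom!r} has no markers; skipped")
            continue
        grid, mk = _chromosome_grid(marker_cm, step)
        P = grid.size
        obs = pop.geno(chrom)  # (n, m)
        # emission per grid column; pseudo-markers emit nothing (all ones)
        marker_col = {}
        rounded = np.round(marker_cm, 6)
        for j, g in enumerate(np.round(grid, 6)):
            hits = np.nonzero(rounded == g)[0]
            if hits.size:
                marker_col[j] = hits
        emis = np.ones((P, n, 3))
        for j, hits in marker_col.items():
            for h in hits:  # co-located markers multiply their emissions
                emis[j] *= _emission(obs[:, h], error_rate)
        trans = [f2_transition(haldane(grid[j + 1] - grid[j])) for j in range(P - 1)]
        # scaled forward-backward, vectorized over individuals
        alpha = np.empty((P, n, 3))
        a = F2_PRIOR[None, :] * emis[0]
        norm = a.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        alpha[0] = a / norm
        for j in range(1, P):
            a = (alpha[j - 1] @ trans[j - 1]) * emis[j]
            norm = a.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            alpha[j] = a / norm
        beta = np.empty((P, n, 3))
        beta[-1] = 1.0
        for j in range(P - 2, -1, -1):
            b = (emis[j + 1] * beta[j + 1]) @ trans[j].T
            norm = b.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            beta[j] = b / norm
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        grid_cm[chrom] = grid
        is_marker[chrom] = mk
        probs[chrom] = np.ascontiguousarray(post.transpose(1, 0, 2))
    return GenoProbGrid(
        individuals=list(pop.phenotypes.index),
        grid_cm=grid_cm,
        is_marker=is_marker,
        probs=probs,
        step=step,
        error_rate=error_rate,
    )
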