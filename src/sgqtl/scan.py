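"""EM maximum-likelihood interval mapping: genome scans of LOD scores.

At every grid position the phenotype is modelled as a 3-component normal
mixture whose component weights are each individual's multipoint genotype
probabilities (AA, AB, BB).  Class means and a common residual SD are fitted
by EM; the LOD score is log10 of the ratio of the fitted mixture likelihood
to a single-normal null fitted to the same individuals.  Individuals with
missing genotypes still contribute through their prior/multipoint weights,
which is what lets a selectively genotyped population use every phenotype.

All positions of a chromosome are iterated in lockstep (vectorized EM with a
per-position convergence mask), which keeps permutation tests and power
simulations tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross_io import CrossPopulation
from .linkage import GenoProbGrid

LOG10 = np.log(10.0)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

__all__ = ["ScanResult", "scan_em", "null_loglik", "em_fit_single"]


def null_loglik(y: np.ndarray) -> tuple[float, float, float]:
    """Log-likelihood, mean and MLE sd of the single-normal null model."""
    n = y.size
    mu = float(np.mean(y))
    var = float(np.mean((y - mu) ** 2))
    if var <= 0:
        return np.inf, mu, 0.0
    sd = np.sqrt(var)
    ll = -n * (_HALF_LOG_2PI + np.log(sd)) - 0.5 * n
    return float(ll), mu, sd


@dataclass
class ScanResult:
    """Genome scan output on the pseudo-marker grid.

    ``table`` has one row per grid position: chromosome, cM position, LOD,
    fitted class means (AA, AB, BB), residual SD, EM iteration count and a
    convergence flag."""

    table: pd.DataFrame
    trait: str
    n_phenotyped: int
    null_ll: float = field(default=np.nan, repr=False)

    @property
    def genome_max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self) -> pd.Series:
        """Genome-wide peak row (lowest-cM tie-break)."""
        lod = self.table["lod"].to_numpy()
        return self.table.iloc[int(np.argmax(lod))]

    def chromosome_peaks(self) -> pd.DataFrame:
        """Per-chromosome peak rows (lowest-cM tie-break via first argmax)."""
        rows = []
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            rows.append(sub.iloc[int(np.argmax(sub["lod"].to_numpy()))])
        return pd.DataFrame(rows).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table[["chromosome", "position", "lod"]].to_csv(
            path, sep="\t", index=False
        )


def _em_vectorized(
    y: np.ndarray,
    W: np.ndarray,
    tol: float,
    max_iter: int,
    min_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM at all P positions simultaneously.

    Parameters: ``y`` (N,), ``W`` (P, N, 3) genotype-probability weights.
    Returns (mu (P,3), sd (P,), ll (P,), n_iter (P,), converged (P,)).
    """
    P, N, _ = W.shape
    ybar = float(np.mean(y))
    # init: genotype-probability-weighted class means
    wsum = W.sum(axis=1)  # (P, 3)
    safe = wsum > 1e-9
    mu = np.where(safe, np.einsum("png,n->pg", W, y) / np.where(safe, wsum, 1.0), ybar)
    resid2 = (y[None, :, None] - mu[:, None, :]) ** 2
    var = np.einsum("png,png->p", W, resid2) / N
    sd = np.sqrt(np.maximum(var, min_sd**2))

    ll = np.full(P, -np.inf)
    n_iter = np.zeros(P, dtype=int)
    converged = np.zeros(P, dtype=bool)
    active = np.arange(P)
    mu_a, sd_a, ll_a = mu, sd, ll[active]
    W_a = W
    for it in range(1, max_iter + 1):
        z = (y[None, :, None] - mu_a[:, None, :]) / sd_a[:, None, None]
        dens = np.exp(-0.5 * z * z) / sd_a[:, None, None]
        num = W_a * dens  # (p, N, 3)
        mix = num.sum(axis=2)  # (p, N)
        mix = np.maximum(mix, 1e-300)
        ll_new = np.log(mix).sum(axis=1) - N * _HALF_LOG_2PI
        post = num / mix[:, :, None]
        ng = post.sum(axis=1)  # (p, 3)
        safe = ng > 1e-9
        mu_a = np.where(
            safe, np.einsum("png,n->pg", post, y) / np.where(safe, ng, 1.0), ybar
        )
        var = np.einsum("png,png->p", post, (y[None, :, None] - mu_a[:, None, :]) ** 2) / N
        sd_a = np.sqrt(np.maximum(var, min_sd**2))
        done = np.abs(ll_new - ll_a) < tol
        ll_a = ll_new
        n_iter[active] = it
        mu[active] = mu_a
        sd[active] = sd_a
        ll[active] = ll_a
        if done.any():
            converged[active[done]] = True
            keep = ~done
            if not keep.any():
                break
            active = active[keep]
            mu_a, sd_a, ll_a = mu_a[keep], sd_a[keep], ll_a[keep]
            W_a = W_a[keep]
    return mu, sd, ll, n_iter, converged


def em_fit_single(
    y: np.ndarray,
    w: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 4000,
) -> dict:
    """EM fit at one position, returning the log-likelihood trajectory.

    A thin single-position wrapper over the same vectorized E/M steps the
    genome scan uses; mainly for inspection and testing of EM monotonicity.
    """
    y = np.asarray(y, dtype=float)
    trace: list[float] = []
    scale = float(np.std(y)) or 1.0
    min_sd = 1e-8 * scale
    W = w[None, :, :]
    mu, sd, ll, n_iter, conv = _em_vectorized(y, W, tol=np.inf, max_iter=1, min_sd=min_sd)
    trace.append(float(ll[0]))
    for _ in range(max_iter):
        # warm-start each subsequent iteration from the previous parameters
        z = (y[None, :, None] - mu[:, None, :]) / sd[:, None, None]
        dens = np.exp(-0.5 * z * z) / sd[:, None, None]
        num = W * dens
        mix = np.maximum(num.sum(axis=2), 1e-300)
        ll_new = float(np.log(mix).sum() - y.size * _HALF_LOG_2PI)
        post = num / mix[:, :, None]
        ng = post.sum(axis=1)
        safe = ng > 1e-9
        ybar = float(np.mean(y))
        mu = np.where(safe, np.einsum("png,n->pg", post, y) / np.where(safe, ng, 1.0), ybar)
        var = np.einsum("png,png->p", post, (y[None, :, None] - mu[:, None, :]) ** 2) / y.size
        sd = np.sqrt(np.maximum(var, min_sd**2))
        if trace and abs(ll_new - trace[-1]) < tol:
            trace.append(ll_new)
            break
        trace.append(ll_new)
    return {"mu": mu[0], "sd": float(sd[0]), "loglik_trace": np.array(trace)}


def scan_em(
    pop: CrossPopulation,
    grid: GenoProbGrid,
    trait: str = "protein",
    tol: float = 1e-6,
    max_iter: int = 4000,
) -> ScanResult:
    """EM interval-mapping scan of ``trait`` over the genotype-probability grid.

    All individuals with a non-missing phenotype contribute (including those
    never genotyped, through their prior weights).  LOD = log10(mixture
    likelihood / single-normal null likelihood), floored at 0.
    """
    y_all = pop.trait_values(trait)
    keep = np.isfinite(y_all)
    y = y_all[keep]
    if y.size < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    rows: list[pd.DataFrame] = []
    ll0, _, null_sd = null_loglik(y)
    if null_sd == 0:
        warnings.warn("zero phenotypic variance; LOD is 0 everywhere")
        for chrom in grid.chromosomes:
            g = grid.grid_cm[chrom]
            rows.append(
                pd.DataFrame(
                    {
                        "chromosome": chrom,
                        "position": g,
                        "lod": 0.0,
                        "mean_AA": y[0],
                        "mean_AB": y[0],
                        "mean_BB": y[0],
                        "resid_sd": 0.0,
                        "n_iter": 0,
                        "converged": True,
                    }
                )
            )
        table = pd.concat(rows, ignore_index=True)
        return ScanResult(table, trait, int(y.size), null_ll=np.inf)
    scale = float(np.std(y))
    min_sd = 1e-8 * scale
    for chrom in grid.chromosomes:
        W = grid.probs[chrom][keep]  # (N, P, 3) -> need (P, N, 3)
        W = np.ascontiguousarray(W.transpose(1, 0, 2))
        mu, sd, ll, n_iter, converged = _em_vectorized(y, W, tol, max_iter, min_sd)
        if not converged.all():
            warnings.warn(
                f"{int((~converged).sum())} position(s) on chromosome {chrom!r} "
                f"did not converge in {max_iter} iterations; last iterate reported"
            )
        lod = np.maximum((ll - ll0) / LOG10, 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "position": grid.grid_cm[chrom],
                    "lod": lod,
                    "mean_AA": mu[:, 0],
                    "mean_AB": mu[:, 1],
                    "mean_BB": mu[:, 2],
                    "resid_sd": sd,
                    "n_iter": n_iter,
                    "converged": converged,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return ScanResult(table, trait, int(y.size), null_ll=float(ll0))
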