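"""Cross-population containers, csvr I/O and marker quality control.

The central objects are :class:`GeneticMap` (ordered marker positions in cM
per chromosome) and :class:`CrossPopulation` (a phenotype table plus an
A/H/B/- genotype matrix for one biparental F2 mating).  Genotypes are stored
internally as small integers: 0 = A (homozygous for the male-parent allele),
1 = H (heterozygous), 2 = B (homozygous for the female-parent allele),
-1 = missing.

Cross files use the "csvr" comma-separated layout: phenotype rows first
(name followed by two empty chromosome/position cells, then one value per
individual), then one row per marker (name, chromosome, cM position,
genotype codes).  Both the ASCII hyphen and the en dash parse as missing.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1
CODE_TO_INT = {"A": 0, "H": 1, "B": 2, "-": MISSING, "–": MISSING}
INT_TO_CODE = {0: "A", 1: "H", 2: "B", MISSING: "-"}

__all__ = [
    "MISSING",
    "GeneticMap",
    "CrossPopulation",
    "CrossParseError",
    "QCReport",
    "read_csvr",
    "write_csvr",
    "pairwise_recombination_fraction",
    "qc_filter",
]


class CrossParseError(ValueError):
    """Raised when a csvr file violates the expected layout or coding."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker names and cM positions per chromosome.

    Parameters
    ----------
    positions
        Mapping ``chromosome -> pandas.Series`` whose index holds marker
        names (unique genome-wide) and whose values are cM positions,
        non-decreasing within each chromosome.
    """

    positions: Mapping[str, pd.Series]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, series in self.positions.items():
            pos = np.asarray(series.values, dtype=float)
            if pos.size and np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"marker positions on chromosome {chrom!r} are not sorted"
                )
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite position on chromosome {chrom!r}")
            dup = seen.intersection(series.index)
            if dup:
                raise ValueError(f"duplicate marker name(s): {sorted(dup)!r}")
            seen.update(series.index)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    @property
    def marker_names(self) -> list[str]:
        names: list[str] = []
        for series in self.positions.values():
            names.extend(series.index)
        return names

    @property
    def n_markers(self) -> int:
        return sum(len(s) for s in self.positions.values())

    @property
    def total_length(self) -> float:
        """Summed map span (last minus first marker) over chromosomes, cM."""
        return float(
            sum(s.values[-1] - s.values[0] for s in self.positions.values() if len(s))
        )

    def markers(self, chrom: str) -> list[str]:
        return list(self.positions[chrom].index)

    def cm(self, chrom: str) -> np.ndarray:
        return np.asarray(self.positions[chrom].values, dtype=float)

    def chromosome_of(self, marker: str) -> str:
        for chrom, series in self.positions.items():
            if marker in series.index:
                return chrom
        raise KeyError(marker)

    def span(self, chrom: str) -> tuple[float, float]:
        pos = self.cm(chrom)
        return float(pos[0]), float(pos[-1])

    def subset(self, markers: Iterable[str]) -> "GeneticMap":
        """Restrict the map to ``markers``, preserving order; empty
        chromosomes are dropped."""
        keep = set(markers)
        out = {}
        for chrom, series in self.positions.items():
            sub = series[[m for m in series.index if m in keep]]
            if len(sub):
                out[chrom] = sub
        return GeneticMap(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        if self.chromosomes != other.chromosomes:
            return False
        return all(
            self.positions[c].index.equals(other.positions[c].index)
            and np.allclose(self.positions[c].values, other.positions[c].values)
            for c in self.chromosomes
        )


@dataclass
class CrossPopulation:
    """One biparental F2 (or F2:3-mean) mating.

    ``phenotypes`` is indexed by individual and carries the trait columns
    (g/kg) plus a boolean ``genotyped`` flag; ``genotypes`` shares the same
    index and has one int8 column per mapped marker.
    """

    population_id: str
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    map: GeneticMap

    def __post_init__(self) -> None:
        if not self.phenotypes.index.equals(self.genotypes.index):
            raise ValueError("phenotype and genotype tables index different individuals")
        mapped = self.map.marker_names
        if list(self.genotypes.columns) != mapped:
            missing = set(self.genotypes.columns) - set(mapped)
            if missing:
                raise ValueError(f"genotype columns not on the map: {sorted(missing)!r}")
            # enforce map order
            self.genotypes = self.genotypes[mapped]
        vals = self.genotypes.to_numpy()
        bad = ~np.isin(vals, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes outside {A,H,B,-}")
        if "genotyped" not in self.phenotypes.columns:
            self.phenotypes = self.phenotypes.assign(
                genotyped=(vals != MISSING).any(axis=1)
            )

    @property
    def n_individuals(self) -> int:
        return len(self.phenotypes)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c != "genotyped"]

    def trait_values(self, trait: str) -> np.ndarray:
        return self.phenotypes[trait].to_numpy(dtype=float)

    def geno(self, chrom: str) -> np.ndarray:
        """(n_individuals, n_markers) int array for one chromosome."""
        return self.genotypes[self.map.markers(chrom)].to_numpy(dtype=np.int8)

    def copy(self) -> "CrossPopulation":
        return CrossPopulation(
            self.population_id,
            self.phenotypes.copy(),
            self.genotypes.copy(),
            self.map,
        )

    def drop_markers(self, markers: Iterable[str]) -> "CrossPopulation":
        drop = set(markers)
        keep = [m for m in self.genotypes.columns if m not in drop]
        return CrossPopulation(
            self.population_id,
            self.phenotypes.copy(),
            self.genotypes[keep].copy(),
            self.map.subset(keep),
        )


def _format_number(x: float) -> str:
    if not np.isfinite(x):
        return "-"
    return f"{x:.10g}"


def write_csvr(pop: CrossPopulation, path, header_comment: str | None = None) -> None:
    """Write ``pop`` as a csvr cross file (optionally with ``#`` header)."""
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    writer = csv.writer(buf, lineterminator="\n")
    for trait in pop.traits:
        writer.writerow(
            [trait, "", ""] + [_format_number(v) for v in pop.phenotypes[trait]]
        )
    for chrom in pop.map.chromosomes:
        series = pop.map.positions[chrom]
        for marker in series.index:
            codes = [INT_TO_CODE[int(g)] for g in pop.genotypes[marker]]
            writer.writerow([marker, chrom, _format_number(series[marker])] + codes)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_csvr(path, population_id: str | None = None) -> CrossPopulation:
    """Read a csvr cross file into a validated :class:`CrossPopulation`.

    Phenotype rows (empty chromosome/position cells) must precede marker
    rows.  Individuals whose genotypes are all missing keep their phenotypes
    and are flagged ``genotyped = False``.
    """
    if population_id is None:
        population_id = str(path).rsplit("/", 1)[-1].removesuffix(".csv")
    pheno_rows: list[tuple[str, list[float]]] = []
    marker_rows: list[tuple[str, str, float, list[int]]] = []
    n_cols: int | None = None
    seen_markers: set[str] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) < 4:
                raise CrossParseError(f"row {lineno}: fewer than 4 cells")
            if n_cols is None:
                n_cols = len(row)
            elif len(row) != n_cols:
                raise CrossParseError(
                    f"row {lineno} ({row[0]!r}): ragged row "
                    f"({len(row)} cells, expected {n_cols})"
                )
            name, chrom, pos = row[0].strip(), row[1].strip(), row[2].strip()
            if chrom == "" and pos == "":
                if marker_rows:
                    raise CrossParseError(
                        f"row {lineno}: phenotype row {name!r} after marker rows"
                    )
                vals = []
                for cell in row[3:]:
                    cell = cell.strip()
                    vals.append(
                        np.nan if cell in ("", "-", "–", "NA") else float(cell)
                    )
                pheno_rows.append((name, vals))
            else:
                if name in seen_markers:
                    raise CrossParseError(f"row {lineno}: duplicate marker {name!r}")
                seen_markers.add(name)
                try:
                    cm = float(pos)
                except ValueError as exc:
                    raise CrossParseError(
                        f"row {lineno} ({name!r}): bad cM position {pos!r}"
                    ) from exc
                codes = []
                for col, cell in enumerate(row[3:], start=4):
                    cell = cell.strip()
                    if cell not in CODE_TO_INT:
                        raise CrossParseError(
                            f"row {lineno} (marker {name!r}), column {col}: "
                            f"unknown genotype code {cell!r}"
                        )
                    codes.append(CODE_TO_INT[cell])
                marker_rows.append((name, chrom, cm, codes))
    if not pheno_rows:
        raise CrossParseError("no phenotype rows found")
    n_ind = len(pheno_rows[0][1])
    individuals = [f"{population_id}_{i + 1:03d}" for i in range(n_ind)]
    phenotypes = pd.DataFrame(
        {name: vals for name, vals in pheno_rows}, index=individuals
    )
    chrom_order: list[str] = []
    by_chrom: dict[str, list[tuple[str, float]]] = {}
    geno_cols: dict[str, list[int]] = {}
    for name, chrom, cm, codes in marker_rows:
        if chrom not in by_chrom:
            by_chrom[chrom] = []
            chrom_order.append(chrom)
        by_chrom[chrom].append((name, cm))
        geno_cols[name] = codes
    try:
        gmap = GeneticMap(
            {
                chrom: pd.Series(
                    [cm for _, cm in entries],
                    index=[nm for nm, _ in entries],
                    dtype=float,
                )
                for chrom, entries in ((c, by_chrom[c]) for c in chrom_order)
            }
        )
    except ValueError as exc:
        raise CrossParseError(str(exc)) from exc
    genotypes = pd.DataFrame(geno_cols, index=individuals, dtype=np.int8)
    genotypes = genotypes[gmap.marker_names]
    return CrossPopulation(population_id, phenotypes, genotypes, gmap)


def pairwise_recombination_fraction(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> float:
    """Maximum-likelihood two-point recombination fraction for an F2 cross.

    EM over the 9-cell joint genotype table: each individual carries two
    gametes; all cells have a known recombinant-gamete count except the
    double heterozygote, which mixes zero- and two-recombinant phases with
    posterior odds ``(1-r)^2 : r^2``.  The estimate lives in [0, 1]; values
    above 0.5 indicate phase (or assay) problems rather than true linkage.
    """
    g1 = np.asarray(g1, dtype=int)
    g2 = np.asarray(g2, dtype=int)
    if g1.shape != g2.shape:
        raise ValueError("genotype columns differ in length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 10:
        raise ValueError(
            f"insufficient data: only {int(ok.sum())} jointly non-missing pairs"
        )
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1[ok], g2[ok]), 1)
    n = counts.sum()
    # fixed recombinant-gamete counts for the 8 unambiguous cells
    fixed = np.array([[0, 1, 2], [1, np.nan, 1], [2, 1, 0]], dtype=float)
    n_hh = counts[1, 1]
    r = 0.33
    for _ in range(max_iter):
        s = 1.0 - r
        denom = s * s + r * r
        e_hh = 0.0 if denom == 0 else 2.0 * r * r / denom
        exp_rec = np.nansum(counts * fixed) + n_hh * e_hh
        r_new = exp_rec / (2.0 * n)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(min(max(r, 0.0), 1.0))


@dataclass
class QCReport:
    """Markers removed by QC plus per-marker segregation-distortion tests."""

    removed: pd.DataFrame  # columns: marker, chromosome, reason, detail
    distortion: pd.DataFrame  # columns: marker, chromosome, chisq, p
    flagged_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["marker1", "marker2", "chromosome", "rf"]
        )
    )

    def to_tsv(self, path) -> None:
        self.removed.to_csv(path, sep="\t", index=False)


def _segregation_distortion(col: np.ndarray) -> tuple[float, float]:
    obs = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()], dtype=float)
    total = obs.sum()
    if total == 0:
        return np.nan, np.nan
    expected = total * np.array([0.25, 0.5, 0.25])
    chisq, p = stats.chisquare(obs, expected)
    return float(chisq), float(p)


def qc_filter(
    pop: CrossPopulation,
    rf_ceiling: float = 0.55,
    distortion_alpha: float = 0.05,
) -> tuple[CrossPopulation, QCReport]:
    """Marker quality control for one population.

    Drops monomorphic markers (no linkage information), then removes markers
    whose two-point recombination fraction with every computable physically
    adjacent marker exceeds ``rf_ceiling`` — the signature of a phase-flipped
    or otherwise corrupted assay, which pairs "far above the expected 0.50
    maximum" with both neighbours while each innocent neighbour retains one
    clean flank.  Segregation distortion (chi-square against 1:2:1) is
    reported per marker but never triggers removal.
    """
    removed: list[dict] = []
    flagged: list[dict] = []
    distortion: list[dict] = []
    mono: set[str] = set()
    for chrom in pop.map.chromosomes:
        geno = pop.geno(chrom)
        for j, marker in enumerate(pop.map.markers(chrom)):
            col = geno[:, j]
            observed = col[col != MISSING]
            codes = np.unique(observed)
            chisq, p = _segregation_distortion(col)
            distortion.append(
                {"marker": marker, "chromosome": chrom, "chisq": chisq, "p": p}
            )
            if len(codes) <= 1:
                mono.add(marker)
                removed.append(
                    {
                        "marker": marker,
                        "chromosome": chrom,
                        "reason": "monomorphic",
                        "detail": f"{len(observed)} calls",
                    }
                )
    # adjacency rf screen among the markers that survived the monomorphism cut
    bad_rf: set[str] = set()
    for chrom in pop.map.chromosomes:
        markers = [m for m in pop.map.markers(chrom) if m not in mono]
        if len(markers) < 2:
            continue
        cols = {m: pop.genotypes[m].to_numpy(dtype=int) for m in markers}
        pair_rf: dict[tuple[str, str], float] = {}
        for m1, m2 in zip(markers[:-1], markers[1:]):
            try:
                rf = pairwise_recombination_fraction(cols[m1], cols[m2])
            except ValueError:
                continue
            pair_rf[(m1, m2)] = rf
            if rf > rf_ceiling:
                flagged.append(
                    {"marker1": m1, "marker2": m2, "chromosome": chrom, "rf": rf}
                )
        for i, m in enumerate(markers):
            adjacent = []
            if i > 0 and (markers[i - 1], m) in pair_rf:
                adjacent.append(pair_rf[(markers[i - 1], m)])
            if i < len(markers) - 1 and (m, markers[i + 1]) in pair_rf:
                adjacent.append(pair_rf[(m, markers[i + 1])])
            if adjacent and all(rf > rf_ceiling for rf in adjacent):
                bad_rf.add(m)
                removed.append(
                    {
                        "marker": m,
                        "chromosome": chrom,
                        "reason": "rf_above_ceiling",
                        "detail": f"max adjacent rf {max(adjacent):.3f}",
                    }
                )
    filtered = pop.drop_markers(mono | bad_rf)
    report = QCReport(
        removed=pd.DataFrame(
            removed, columns=["marker", "chromosome", "reason", "detail"]
        ),
        distortion=pd.DataFrame(
            distortion, columns=["marker", "chromosome", "chisq", "p"]
        ).assign(distorted=lambda df: df["p"] < distortion_alpha),
        flagged_pairs=pd.DataFrame(
            flagged, columns=["marker1", "marker2", "chromosome", "rf"]
        ),
    )
    return filtered, report
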