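"""Packaged table of the survey's parent lines.

48 high seed-protein germplasm accessions (female parents, one per mating)
and the 7 agronomic cultivars (male parents, shared within maturity group),
with their repository (GRIN) seed protein and oil values in g/kg on a
zero-moisture basis.  Four entries have no repository phenotype record;
their protein/oil cells are empty.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_parent_table", "parent_protein_extremes"]


def load_parent_table() -> pd.DataFrame:
    """Parent lines with columns mating, parent_code, role, maturity_group,
    protein, oil, accession, name, origin."""
    ref = resources.files("sgqtl").joinpath("data/parent_lines.tsv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"mating": "Int64"})
    return df


def parent_protein_extremes(table: pd.DataFrame | None = None) -> dict:
    """Min/max of recorded parental protein values (g/kg) by parent role."""
    if table is None:
        table = load_parent_table()
    out = {}
    for role in ("female", "male"):
        vals = table.loc[table["role"] == role, "protein"].dropna()
        out[role] = {"min": float(vals.min()), "max": float(vals.max())}
    return out
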