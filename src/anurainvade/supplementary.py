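"""Loader for the published supplementary introduction tables.

Two trait-filtered variants of the species-jurisdiction table exist:
the body/clutch-complete table (385 rows, 85 species, 37 genera) and
the larger table without those traits (408 rows, 99 species, 42
genera).  The files are distributed with the original article and are
NOT bundled here; place them under ``data/external/`` as ``sd2.csv``
and ``sd3.csv`` to reproduce the published counts and model ranking.

Because the published column headers are not fixed by this package, a
column mapping (canonical name -> file header) adapts the loader; the
canonical schema is the analysis-table layout of :mod:`.dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["CANONICAL_COLUMNS", "SupplementarySummary", "load_supplementary"]

#: canonical column -> description (all lowercase snake case)
CANONICAL_COLUMNS = {
    "species": "binomial species name",
    "genus": "genus",
    "family": "family",
    "jurisdiction": "introduction jurisdiction (country/island/US state)",
    "outcome": "establishment success (1) / failure (0)",
    "body_size": "log min body size (SVL mm); absent in the reduced table",
    "clutch_size": "log min clutch size; absent in the reduced table",
    "congeneric": "native congener present (0/1)",
    "distance": "log great-circle distance between range centroids",
    "habitat_breadth": "log habitat count",
    "intentionality": "intentional / unintentional / unknown",
    "island": "island (1) vs mainland (0)",
    "climate_match": "DOMAIN climate-matching score",
    "range_size": "log native range (km^2)",
    "larval_stage": "free-living aquatic larva present (0/1)",
}


@dataclass
class SupplementarySummary:
    n_rows: int
    n_species: int
    n_genera: int


def load_supplementary(path: str | Path,
                       column_map: dict[str, str] | None = None
                       ) -> tuple[pd.DataFrame, SupplementarySummary]:
    """Load one supplementary table into the canonical schema.

    ``column_map`` maps canonical names to the file's actual headers;
    headers already matching canonical names (case-insensitive) are
    picked up automatically.  Returns the table plus its row/species/
    genus counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary table not found at {path}; the published file must "
            "be placed there by hand (it is not distributed with this package)")
    raw = pd.read_csv(path)
    lower = {c.lower().strip().replace(" ", "_"): c for c in raw.columns}
    column_map = dict(column_map or {})
    out = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, lower.get(canon))
        if src is not None and src in raw.columns:
            out[canon] = raw[src]
    df = pd.DataFrame(out)
    for req in ("species", "genus", "outcome", "jurisdiction"):
        if req not in df.columns:
            raise ValueError(f"cannot resolve required column {req!r} in {path.name}; "
                             "supply a column_map")
    summary = SupplementarySummary(
        n_rows=len(df),
        n_species=int(df["species"].nunique()),
        n_genera=int(df["genus"].nunique()),
    )
    return df, summary
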