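"""Assembly of the species-jurisdiction analysis table.

The unit of analysis is one species introduced to one jurisdiction
(country, island, or US state), with a binary establishment outcome.
Ten candidate factors are carried, coded 1-10 throughout the package:

  1 min body size        6 intentionality of release
  2 congeneric presence  7 island vs mainland
  3 min clutch size      8 climate matching
  4 distance             9 range size
  5 habitat breadth     10 free-living larval stage

Numeric factors are standardized to mean 0, SD 0.5 on the *final*
filtered table (so a coefficient of 1 corresponds to a two-SD change
in the predictor and is comparable in magnitude to the coefficient of
an untransformed binary factor).  Categorical factors — intentionality
(3 levels, reference "intentional"), island, larval stage, congeneric
presence — are left untouched.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTENTIONAL_TAGS = frozenset({"biocontrol", "food", "experimental", "intentional_release"})
UNINTENTIONAL_TAGS = frozenset(
    {"cargo_stowaway", "pet_trade", "nursery_trade", "aquaculture_contaminant"}
)
PATHWAY_VOCABULARY = INTENTIONAL_TAGS | UNINTENTIONAL_TAGS | {"unknown"}

#: factor code -> analysis-table column
FACTORS = {
    1: "body_size",
    2: "congeneric",
    3: "clutch_size",
    4: "distance",
    5: "habitat_breadth",
    6: "intentionality",
    7: "island",
    8: "climate_match",
    9: "range_size",
    10: "larval_stage",
}
FACTOR_CODES = {v: k for k, v in FACTORS.items()}

NUMERIC_FACTORS = ("body_size", "clutch_size", "distance", "habitat_breadth",
                   "climate_match", "range_size")
CATEGORICAL_FACTORS = ("congeneric", "intentionality", "island", "larval_stage")
GROUPING_COLUMNS = ("family", "genus", "species", "location")

__all__ = [
    "FACTORS", "FACTOR_CODES", "NUMERIC_FACTORS", "CATEGORICAL_FACTORS",
    "GROUPING_COLUMNS", "PATHWAY_VOCABULARY",
    "classify_intentionality", "congeneric_presence", "drop_incomplete",
    "standardize", "collinearity_screen", "assemble_dataset",
]


def classify_intentionality(pathways) -> str:
    """Classify a pair's pathway tags as intentional / unintentional / unknown.

    A single deliberate-release tag (biocontrol, food, experimental,
    intentional release) makes the pair intentional; pairs reporting
    only accidental pathways are unintentional; anything else (no tags,
    or only "unknown") is unknown.
    """
    tags = set(pathways)
    unrecognized = tags - PATHWAY_VOCABULARY
    if unrecognized:
        raise ValueError(f"unrecognized pathway tag(s): {sorted(unrecognized)}")
    if tags & INTENTIONAL_TAGS:
        return "intentional"
    if tags and tags <= UNINTENTIONAL_TAGS:
        return "unintentional"
    return "unknown"


def congeneric_presence(genus: str, jurisdiction_id: str,
                        native_genera: dict[str, set]) -> int:
    """1 iff the species' genus is native to the jurisdiction."""
    if jurisdiction_id not in native_genera:
        raise KeyError(f"unknown jurisdiction {jurisdiction_id!r}")
    return int(genus in native_genera[jurisdiction_id])


def drop_incomplete(rows: pd.DataFrame, required: list[str]):
    """Drop rows missing any required column; keep an exclusion log.

    Returns (filtered rows, exclusion log DataFrame with one row per
    dropped record and the column that caused the drop).  Raises when
    nothing survives.
    """
    missing_cols = [c for c in required if c not in rows.columns]
    if missing_cols:
        raise KeyError(f"required column(s) absent from table: {missing_cols}")
    log_entries = []
    mask = pd.Series(True, index=rows.index)
    for col in required:
        bad = rows[col].isna() & mask
        for idx in rows.index[bad]:
            log_entries.append({
                "species_id": rows.at[idx, "species_id"] if "species_id" in rows else idx,
                "jurisdiction_id": rows.at[idx, "jurisdiction_id"] if "jurisdiction_id" in rows else "",
                "reason": f"missing {col}",
            })
        mask &= ~bad
    kept = rows[mask].copy()
    if kept.empty:
        raise ValueError("no complete rows survive the missing-data filter")
    if log_entries:
        logger.info("dropped %d incomplete row(s)", len(log_entries))
    return kept, pd.DataFrame(log_entries, columns=["species_id", "jurisdiction_id", "reason"])


def standardize(values) -> np.ndarray:
    """Center to mean 0 and rescale to sample SD 0.5 (Gelman scaling)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean()) / sd * 0.5


def collinearity_screen(columns: pd.DataFrame, r_threshold: float = 0.7) -> pd.DataFrame:
    """Report (not drop) predictor pairs with |Pearson r| >= threshold."""
    if len(columns) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    num = columns.select_dtypes(include=[np.number])
    flagged = []
    for a, b in itertools.combinations(num.columns, 2):
        r = num[a].corr(num[b])
        if np.isfinite(r) and abs(r) >= r_threshold:
            flagged.append({"var_a": a, "var_b": b, "r": float(r)})
    return pd.DataFrame(flagged, columns=["var_a", "var_b", "r"])


def assemble_dataset(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    scores: pd.DataFrame,
    distances: pd.DataFrame,
    jurisdictions: pd.DataFrame,
    include_size_traits: bool = True,
):
    """Join records, traits, climate scores, distances and jurisdiction
    attributes into the analysis table.

    Parameters
    ----------
    records : species_id, jurisdiction_id, outcome, pathways
        (pathways either a semicolon-joined string or a set per row).
    traits : species_id, family, genus, min_body_size_mm, min_clutch_size,
        larval_stage, range_km2, habitat_count (sizes/counts on the raw
        scale; logs are taken here).
    scores : species_id, jurisdiction_id, score (climate match; NaN when
        undefined).
    distances : species_id, jurisdiction_id, distance_km.
    jurisdictions : jurisdiction_id, is_island, native_genera
        (semicolon-joined genus list, may be empty).
    include_size_traits : when True, body and clutch size are required
        (the smaller, trait-complete table); when False they are omitted
        entirely so species missing them are retained.

    Returns (analysis table, exclusion log).
    """
    if traits.empty:
        raise ValueError("empty trait table")
    if records.empty:
        raise ValueError("empty records table")

    df = records.copy()
    df["outcome"] = df["outcome"].astype(int)
    if not df["outcome"].isin((0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    if df.duplicated(["species_id", "jurisdiction_id"]).any():
        raise ValueError("duplicate species-jurisdiction pair in records")

    def _tags(cell):
        if isinstance(cell, str):
            return {t for t in cell.split(";") if t}
        return set(cell)

    df["intentionality"] = [classify_intentionality(_tags(p)) for p in df["pathways"]]

    tr = traits.set_index("species_id")
    with np.errstate(divide="ignore"):
        body = np.log(tr["min_body_size_mm"].astype(float))
        clutch = np.log(tr["min_clutch_size"].astype(float))
        range_sz = np.log(tr["range_km2"].astype(float))
        habitat = np.log(tr["habitat_count"].astype(float))
    df["family"] = df["species_id"].map(tr["family"])
    df["genus"] = df["species_id"].map(tr["genus"])
    df["species"] = df["species_id"]
    df["location"] = df["jurisdiction_id"]
    df["body_size"] = df["species_id"].map(body)
    df["clutch_size"] = df["species_id"].map(clutch)
    df["range_size"] = df["species_id"].map(range_sz)
    df["habitat_breadth"] = df["species_id"].map(habitat)
    df["larval_stage"] = df["species_id"].map(tr["larval_stage"].astype(float))

    ju = jurisdictions.set_index("jurisdiction_id")
    native = {
        jid: {g for g in str(row.get("native_genera", "") or "").split(";") if g}
        for jid, row in ju.iterrows()
    }
    df["island"] = df["jurisdiction_id"].map(ju["is_island"].astype(float))
    if df["island"].isna().any():
        bad = df.loc[df["island"].isna(), "jurisdiction_id"].unique()
        raise KeyError(f"unknown jurisdiction(s) in records: {list(bad)[:5]}")
    df["congeneric"] = [
        congeneric_presence(g, j, native)
        for g, j in zip(df["genus"], df["jurisdiction_id"])
    ]

    score_map = scores.set_index(["species_id", "jurisdiction_id"])["score"]
    dist_map = distances.set_index(["species_id", "jurisdiction_id"])["distance_km"]
    keys = pd.MultiIndex.from_frame(df[["species_id", "jurisdiction_id"]])
    df["climate_match"] = score_map.reindex(keys).to_numpy()
    dist_km = dist_map.reindex(keys).to_numpy()
    with np.errstate(invalid="ignore"):
        df["distance"] = np.log1p(dist_km)

    required = ["outcome", "intentionality", "island", "congeneric", "larval_stage",
                "climate_match", "distance", "range_size", "habitat_breadth",
                "family", "genus"]
    kept_factors = list(FACTORS.values())
    if include_size_traits:
        required += ["body_size", "clutch_size"]
    else:
        kept_factors = [f for f in kept_factors if f not in ("body_size", "clutch_size")]

    df, exclusion_log = drop_incomplete(df, required)

    for col in NUMERIC_FACTORS:
        if col in kept_factors:
            df[col] = standardize(df[col].to_numpy())

    columns = (["species_id", "jurisdiction_id", "outcome"] + kept_factors
               + list(GROUPING_COLUMNS))
    table = df[columns].reset_index(drop=True)
    for col in ("congeneric", "island", "larval_stage"):
        table[col] = table[col].astype(int)
    return table, exclusion_log
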