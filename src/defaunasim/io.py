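"""Census and trait table I/O.

Canonical interchange format is plain CSV with a header row:

* census:  ``tag, species, dbh[, x, y]`` — one row per living main stem,
  dbh in cm, optional coordinates in m;
* traits:  ``species, genus, family, wsg, wsg_source, dispersal_groups``
  with pipe-delimited group codes (e.g. ``gibbon|smaller_birds``).

Column names in foreign census files can be remapped through a small YAML
"dialect" mapping (canonical name -> actual name).  ForestGEO full-table
quirks (multi-stem rows, status codes) are expected to be reduced upstream
to one row per living main stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .classification import DispersalGroup

__all__ = [
    "ReadReport",
    "read_census",
    "write_census",
    "read_traits",
    "write_traits",
    "filter_min_dbh",
    "resolve_species",
    "load_yaml_config",
]

CENSUS_COLUMNS = ("tag", "species", "dbh")
OPTIONAL_CENSUS_COLUMNS = ("x", "y")
TRAIT_COLUMNS = ("species", "genus", "family", "wsg", "wsg_source", "dispersal_groups")

#: sentinel for trait rows whose WSG awaits imputation
WSG_SOURCES = ("species_db", "field_sample", "genus_median", "family_median")


@dataclass
class ReadReport:
    """Accept/reject accounting for a census read."""

    n_accepted: int = 0
    n_rejected: int = 0
    rejected: list = field(default_factory=list)  # (row index, tag, reason)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if not dialect:
        return df
    rename = {actual: canonical for canonical, actual in dialect.items()}
    return df.rename(columns=rename)


def read_census(
    path, dialect: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a stem census CSV into the canonical frame.

    Every input row either becomes a record or is logged in the returned
    :class:`ReadReport` with a reason.  A missing mandatory column or a
    duplicated tag is fatal.
    """
    raw = pd.read_csv(path, dtype={"tag": str, "species": str})
    raw = _apply_dialect(raw, dialect)
    missing = [c for c in CENSUS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"census file {path} is missing mandatory column(s): {', '.join(missing)}")

    report = ReadReport()
    dbh = pd.to_numeric(raw["dbh"], errors="coerce")
    bad_dbh = dbh.isna()
    nonpos = ~bad_dbh & (dbh <= 0)
    for idx in raw.index[bad_dbh]:
        report.rejected.append((int(idx), raw.at[idx, "tag"], "non-numeric dbh"))
    for idx in raw.index[nonpos]:
        report.rejected.append((int(idx), raw.at[idx, "tag"], "non-positive dbh"))
    keep = ~(bad_dbh | nonpos)

    out = raw.loc[keep, [c for c in (*CENSUS_COLUMNS, *OPTIONAL_CENSUS_COLUMNS) if c in raw.columns]].copy()
    out["dbh"] = dbh[keep].astype(float)
    out["tag"] = out["tag"].astype(str)
    out["species"] = out["species"].astype(str)

    dup = out["tag"][out["tag"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate stem tag(s) in census: {', '.join(dup.unique()[:5])}")

    out = out.reset_index(drop=True)
    report.n_accepted = len(out)
    report.n_rejected = len(report.rejected)
    return out, report


def write_census(census: pd.DataFrame, path) -> None:
    cols = [c for c in (*CENSUS_COLUMNS, *OPTIONAL_CENSUS_COLUMNS) if c in census.columns]
    census[cols].to_csv(path, index=False)


def _parse_groups(cell, empty_groups: str) -> frozenset:
    if pd.isna(cell) or str(cell).strip() == "":
        if empty_groups == "unclassified":
            return frozenset({DispersalGroup.UNCLASSIFIED})
        raise ValueError("empty dispersal_groups cell (set empty_groups='unclassified' to coerce)")
    return frozenset(DispersalGroup.from_code(tok) for tok in str(cell).split("|") if tok.strip())


def read_traits(path, empty_groups: str = "error") -> pd.DataFrame:
    """Read the species-trait CSV.

    WSG cells may be empty (missing, to be imputed later).  Dispersal group
    codes are pipe-delimited; an unknown code is fatal and named in the
    error.  ``empty_groups`` is either ``"error"`` (default) or
    ``"unclassified"`` to coerce empty cells to the unclassified group.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in ("species", "genus", "family") if c not in raw.columns]
    if missing:
        raise ValueError(f"traits file {path} is missing mandatory column(s): {', '.join(missing)}")
    out = pd.DataFrame(
        {
            "species": raw["species"].astype(str),
            "genus": raw["genus"].astype(str),
            "family": raw["family"].astype(str),
            "wsg": pd.to_numeric(raw.get("wsg"), errors="coerce"),
            "wsg_source": raw.get("wsg_source", pd.Series([""] * len(raw))).fillna(""),
            "dispersal_groups": raw.get("dispersal_groups", pd.Series([np.nan] * len(raw))).map(
                lambda cell: _parse_groups(cell, empty_groups)
            ),
        }
    )
    dup = out["species"][out["species"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate species code(s) in traits: {', '.join(dup.unique()[:5])}")
    bad = out["wsg"].notna() & ~((out["wsg"] > 0) & (out["wsg"] < 1.5))
    if bad.any():
        raise ValueError(
            f"wsg outside (0, 1.5) for species: {', '.join(out.loc[bad, 'species'].head())}"
        )
    return out


def write_traits(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out["dispersal_groups"] = out["dispersal_groups"].map(
        lambda s: "|".join(sorted(g.value for g in s))
    )
    out[list(TRAIT_COLUMNS)].to_csv(path, index=False)


def filter_min_dbh(census: pd.DataFrame, min_dbh: float = 5.0) -> pd.DataFrame:
    """Keep stems with dbh >= min_dbh (inclusive); input order preserved."""
    if min_dbh <= 0:
        raise ValueError("min_dbh must be positive")
    return census[census["dbh"] >= min_dbh].reset_index(drop=True)


def resolve_species(
    census: pd.DataFrame, traits: pd.DataFrame, on_unresolved: str = "error"
) -> tuple[pd.DataFrame, list[str]]:
    """Check every census species against the trait table.

    Unresolvable codes abort by default (silent drops would bias carbon
    totals); ``on_unresolved="drop"`` drops those stems and returns the
    offending codes for logging.
    """
    known = set(traits["species"])
    unresolved = sorted(set(census["species"]) - known)
    if unresolved:
        if on_unresolved == "error":
            raise ValueError(
                f"{len(unresolved)} species code(s) missing from trait table: "
                + ", ".join(unresolved[:10])
            )
        census = census[census["species"].isin(known)].reset_index(drop=True)
    return census, unresolved
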