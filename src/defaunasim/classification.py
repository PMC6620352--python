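"""Seed-disperser groups and the analysis categories built on them.

Each tree species carries a set of disperser groups (a species may be
dispersed by several agents).  Two derived groupings drive the rest of the
pipeline:

* the large-bodied frugivore (LBF) guild — gibbons, macaques,
  hornbills/large pigeons and terrestrial mammals (deer, elephants,
  bears) — which defines the removal target sets of the defaunation
  scenarios, and
* the mutually exclusive carbon-share categories P (primate-dispersed),
  TB (large-bodied terrestrial mammals and birds) and O (all others).
"""

from __future__ import annotations

import enum
from typing import Iterable

import pandas as pd

__all__ = [
    "DispersalGroup",
    "DispersalCategory",
    "LBF_GROUPS",
    "PRIMATE_GROUPS",
    "is_lbf",
    "is_primate_dispersed",
    "share_category",
    "lbf_mask",
    "primate_mask",
    "category_series",
]


class DispersalGroup(enum.Enum):
    """The eight disperser groups a species' agents are classified into.

    The codes (``.value``) are stable and used for CSV serialization.
    """

    GIBBON = "gibbon"
    MACAQUE = "macaque"
    HORNBILLS_LARGE_PIGEONS = "hornbills_large_pigeons"
    SMALLER_BIRDS = "smaller_birds"
    TERRESTRIAL_MAMMALS = "terrestrial_mammals"
    UNKNOWN_ANIMALS = "unknown_animals"
    UNCLASSIFIED = "unclassified"
    WIND = "wind"

    @classmethod
    def from_code(cls, code: str) -> "DispersalGroup":
        try:
            return cls(code.strip())
        except ValueError:
            valid = ", ".join(g.value for g in cls)
            raise ValueError(
                f"unknown dispersal-group code {code!r}; valid codes: {valid}"
            ) from None


class DispersalCategory(enum.Enum):
    """Mutually exclusive carbon-share categories.

    P  — primate-dispersed (gibbon and/or macaque among the agents);
    TB — dispersed by large terrestrial mammals or large birds but not
         primates;
    O  — everything else (small birds, unknown, unclassified, wind).
    """

    P = "P"
    TB = "TB"
    O = "O"


#: Groups whose presence makes a species LBF-dispersed.  Explicit whitelist:
#: unknown/unclassified agents do NOT count as LBF.
LBF_GROUPS = frozenset(
    {
        DispersalGroup.GIBBON,
        DispersalGroup.MACAQUE,
        DispersalGroup.HORNBILLS_LARGE_PIGEONS,
        DispersalGroup.TERRESTRIAL_MAMMALS,
    }
)

PRIMATE_GROUPS = frozenset({DispersalGroup.GIBBON, DispersalGroup.MACAQUE})

_TB_GROUPS = frozenset(
    {DispersalGroup.HORNBILLS_LARGE_PIGEONS, DispersalGroup.TERRESTRIAL_MAMMALS}
)


def _as_set(groups: Iterable[DispersalGroup]) -> frozenset:
    s = frozenset(groups)
    if not s:
        raise ValueError("dispersal_groups must be non-empty")
    return s


def is_lbf(groups: Iterable[DispersalGroup]) -> bool:
    """True iff the species has at least one large-bodied frugivore agent."""
    return bool(_as_set(groups) & LBF_GROUPS)


def is_primate_dispersed(groups: Iterable[DispersalGroup]) -> bool:
    """True iff a gibbon or macaque is among the species' dispersal agents."""
    return bool(_as_set(groups) & PRIMATE_GROUPS)


def share_category(
    groups: Iterable[DispersalGroup], primates_alone: bool = False
) -> DispersalCategory:
    """Assign the exclusive share category with priority P > TB > O.

    With ``primates_alone=True`` the P category is restricted to species
    whose agent set is a subset of {gibbon, macaque}; species shared with
    other agents then fall through to TB or O.
    """
    s = _as_set(groups)
    if primates_alone:
        primate = bool(s & PRIMATE_GROUPS) and s <= PRIMATE_GROUPS
    else:
        primate = bool(s & PRIMATE_GROUPS)
    if primate:
        return DispersalCategory.P
    if s & _TB_GROUPS:
        return DispersalCategory.TB
    return DispersalCategory.O


# -- vectorized helpers over a traits table ---------------------------------

def lbf_mask(traits: pd.DataFrame) -> pd.Series:
    """Boolean Series (indexed like *traits*) marking LBF-dispersed species."""
    return traits["dispersal_groups"].map(is_lbf)


def primate_mask(traits: pd.DataFrame) -> pd.Series:
    return traits["dispersal_groups"].map(is_primate_dispersed)


def category_series(traits: pd.DataFrame, primates_alone: bool = False) -> pd.Series:
    """Per-species share category as a Series of DispersalCategory."""
    return traits["dispersal_groups"].map(
        lambda g: share_category(g, primates_alone=primates_alone)
    )
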