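"""Species-level trait comparisons between disperser groupings.

The predicted carbon loss is driven by trait differences between guilds,
so the pipeline reports two-sample t-tests of wood specific gravity and
maximum attained dbh between (a) LBF-dispersed species and all others and
(b) primate-dispersed species and the rest.  The unit of analysis is the
species: one WSG value and one maximum dbh per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import lbf_mask, primate_mask
from .io import filter_min_dbh

__all__ = ["TraitComparison", "species_max_dbh", "t_test", "compare_groupings"]


@dataclass(frozen=True)
class TraitComparison:
    grouping: str  # lbf_vs_others | primates_vs_others
    trait: str  # wsg | max_dbh
    t: float
    p: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    median1: float
    median2: float


def species_max_dbh(
    census: pd.DataFrame, traits: pd.DataFrame | None = None, min_dbh: float = 5.0
) -> pd.Series:
    """Maximum dbh (cm) per species over stems passing the dbh filter.

    Species with no stems >= min_dbh are simply absent from the result
    (callers decide how to handle them).
    """
    c = filter_min_dbh(census, min_dbh)
    out = c.groupby("species")["dbh"].max()
    if traits is not None:
        out = out[out.index.isin(set(traits["species"]))]
    return out


def t_test(
    values_a, values_b, grouping: str = "", trait: str = "", welch: bool = True
) -> TraitComparison:
    """Two-sample t-test; Welch (unequal variances) by default.

    Sign convention: t > 0 when group A's mean exceeds group B's.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TraitComparison(
        grouping=grouping,
        trait=trait,
        t=float(res.statistic),
        p=float(res.pvalue),
        n1=a.size,
        n2=b.size,
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        median1=float(np.median(a)),
        median2=float(np.median(b)),
    )


def compare_groupings(
    census: pd.DataFrame, traits: pd.DataFrame, min_dbh: float = 5.0, welch: bool = True
) -> pd.DataFrame:
    """The four headline comparisons: {LBF, primate} x {WSG, max dbh}.

    Group A is always the focal guild, so positive t means the guild's
    species have the larger mean.  Medians are reported alongside.
    """
    maxd = species_max_dbh(census, traits, min_dbh=min_dbh)
    tr = traits[traits["species"].isin(maxd.index)].reset_index(drop=True)
    wsg = tr["wsg"].to_numpy(float)
    md = maxd.reindex(tr["species"]).to_numpy(float)
    rows = []
    for grouping, mask in (
        ("lbf_vs_others", lbf_mask(tr).to_numpy()),
        ("primates_vs_others", primate_mask(tr).to_numpy()),
    ):
        for trait, vals in (("wsg", wsg), ("max_dbh", md)):
            rows.append(
                t_test(vals[mask], vals[~mask], grouping=grouping, trait=trait, welch=welch)
            )
    return pd.DataFrame([r.__dict__ for r in rows])
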