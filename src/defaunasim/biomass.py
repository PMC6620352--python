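"""Allometric above-ground biomass / carbon and wood-density imputation.

Per-stem above-ground biomass (kg) for moist-forest trees follows the
wood-density × diameter allometry

    AGB = rho * exp(-1.499 + 2.148 ln D + 0.207 (ln D)^2 - 0.0281 (ln D)^3)

with rho the wood specific gravity (g/cm^3) and D the diameter at breast
height (cm, >= 5).  Above-ground carbon is taken as half of AGB.  Plot
totals are reported in Mg (metric tons) and Mg/ha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import DispersalCategory, category_series

__all__ = [
    "agb_single",
    "agb_shape",
    "stem_agc_kg",
    "total_agc",
    "agc_shares",
    "impute_wsg",
]

_C0, _C1, _C2, _C3 = -1.499, 2.148, 0.207, -0.0281
KG_PER_MG = 1000.0


def agb_shape(dbh, allow_small: bool = False):
    """Diameter-only factor of the allometry: exp(polynomial in ln D), kg.

    AGB is exactly this factor times the wood specific gravity; separating
    it lets the simulation pre-compute the expensive part per stem.
    """
    d = np.asarray(dbh, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be positive")
    if not allow_small and np.any(d < 5):
        raise ValueError("dbh < 5 cm is outside the analysis filter (set allow_small=True to override)")
    ln = np.log(d)
    return np.exp(_C0 + _C1 * ln + _C2 * ln**2 + _C3 * ln**3)


def agb_single(wsg, dbh, allow_small: bool = False):
    """Above-ground biomass (kg) of one stem; vectorizes over arrays.

    Exactly linear in ``wsg``; strictly increasing in ``dbh`` over the
    range relevant here (5–300 cm).
    """
    w = np.asarray(wsg, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wsg must be positive")
    return w * agb_shape(dbh, allow_small=allow_small)


def _stem_wsg(census: pd.DataFrame, traits: pd.DataFrame) -> np.ndarray:
    lut = traits.set_index("species")["wsg"]
    missing = sorted(set(census["species"]) - set(lut.index))
    if missing:
        raise ValueError(f"species missing from trait table: {', '.join(missing[:10])}")
    w = lut.reindex(census["species"]).to_numpy(dtype=float)
    if np.isnan(w).any():
        bad = sorted(census["species"][np.isnan(w)].unique())
        raise ValueError(f"species with missing WSG (impute first): {', '.join(bad[:10])}")
    return w


def stem_agc_kg(census: pd.DataFrame, traits: pd.DataFrame) -> np.ndarray:
    """Per-stem above-ground carbon in kg (half of AGB)."""
    return 0.5 * agb_single(_stem_wsg(census, traits), census["dbh"].to_numpy(float))


def total_agc(
    census: pd.DataFrame, traits: pd.DataFrame, plot_area_ha: float = 30.0
) -> tuple[float, float]:
    """Plot AGC total in Mg and density in Mg/ha."""
    if len(census) == 0:
        return 0.0, 0.0
    total_mg = stem_agc_kg(census, traits).sum() / KG_PER_MG
    return total_mg, total_mg / plot_area_ha


def agc_shares(
    census: pd.DataFrame, traits: pd.DataFrame, primates_alone: bool = False
) -> pd.DataFrame:
    """AGC total (Mg) and share (%) per dispersal category P / TB / O.

    Categories are exclusive (priority P > TB > O); shares sum to 100.
    """
    cat = category_series(traits, primates_alone=primates_alone)
    lut = pd.Series(cat.to_numpy(), index=traits["species"])
    stem_cat = lut.reindex(census["species"]).to_numpy()
    agc = stem_agc_kg(census, traits) / KG_PER_MG
    rows = []
    total = agc.sum()
    for c in DispersalCategory:
        mg = float(agc[stem_cat == c].sum())
        rows.append(
            {"category": c.value, "agc_mg": mg, "share_pct": 100.0 * mg / total if total else 0.0}
        )
    return pd.DataFrame(rows)


def impute_wsg(
    traits: pd.DataFrame,
    reference: pd.DataFrame,
    field_samples: pd.DataFrame | None = None,
    stat: str = "median",
) -> pd.DataFrame:
    """Fill missing WSG values and record the provenance of every value.

    Precedence per species:

    1. ``species_db``    — species-level value in the reference database;
    2. ``field_sample``  — locally measured value (``field_samples`` frame
       with columns species, wsg);
    3. ``genus_median``  — median of the reference database's species-level
       values within the genus;
    4. ``family_median`` — same at family level.

    Rows that already carry a wsg *and* a wsg_source are left untouched.
    ``stat`` may be ``"mean"`` to aggregate genus/family values with the
    mean instead of the median.  A species with no value at any level is
    fatal and listed in the error.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    agg = np.median if stat == "median" else np.mean
    src_suffix = f"{stat}"

    ref_sp = reference.set_index("species")["wsg"]
    ref_genus = reference.groupby("genus")["wsg"]
    ref_family = reference.groupby("family")["wsg"]
    genus_vals = {g: v.to_numpy(float) for g, v in ref_genus}
    family_vals = {f: v.to_numpy(float) for f, v in ref_family}
    field = (
        field_samples.set_index("species")["wsg"]
        if field_samples is not None
        else pd.Series(dtype=float)
    )

    out = traits.copy()
    unresolved = []
    for i in out.index:
        if pd.notna(out.at[i, "wsg"]) and str(out.at[i, "wsg_source"]).strip():
            continue
        sp, genus, family = out.at[i, "species"], out.at[i, "genus"], out.at[i, "family"]
        if sp in ref_sp.index and pd.notna(ref_sp[sp]):
            out.at[i, "wsg"], out.at[i, "wsg_source"] = float(ref_sp[sp]), "species_db"
        elif sp in field.index and pd.notna(field[sp]):
            out.at[i, "wsg"], out.at[i, "wsg_source"] = float(field[sp]), "field_sample"
        elif genus in genus_vals and len(genus_vals[genus]):
            out.at[i, "wsg"] = float(agg(genus_vals[genus]))
            out.at[i, "wsg_source"] = f"genus_{src_suffix}"
        elif family in family_vals and len(family_vals[family]):
            out.at[i, "wsg"] = float(agg(family_vals[family]))
            out.at[i, "wsg_source"] = f"family_{src_suffix}"
        else:
            unresolved.append(sp)
    if unresolved:
        raise ValueError(
            "no WSG value at any level for species: " + ", ".join(unresolved[:10])
        )
    return out
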