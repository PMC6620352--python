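"""Filling missing wood specific gravity from a reference database.

Species without a species-level WSG value get, in order of preference:
a locally measured field sample, the genus median of the reference
database's species-level values, then the family median.  The provenance
of every value is recorded in wsg_source.
"""

import numpy as np
import pandas as pd

from defaunasim.biomass import impute_wsg
from defaunasim.classification import DispersalGroup

traits = pd.DataFrame(
    {
        "species": ["Neph_mel", "Prun_jav", "Aglaia_sp", "Syzy_sp"],
        "genus": ["Nephelium", "Prunus", "Aglaia", "Syzygium"],
        "family": ["Sapindaceae", "Rosaceae", "Meliaceae", "Myrtaceae"],
        "wsg": [np.nan] * 4,
        "wsg_source": [""] * 4,
        "dispersal_groups": [frozenset({DispersalGroup.GIBBON})] * 4,
    }
)
reference = pd.DataFrame(
    {
        "species": ["Neph_mel", "Prun_a", "Prun_b", "Prun_c", "Euge_a", "Euge_b"],
        "genus": ["Nephelium", "Prunus", "Prunus", "Prunus", "Eugenia", "Eugenia"],
        "family": ["Sapindaceae", "Rosaceae", "Rosaceae", "Rosaceae", "Myrtaceae", "Myrtaceae"],
        "wsg": [0.83, 0.52, 0.60, 0.71, 0.64, 0.70],
    }
)
field = pd.DataFrame({"species": ["Aglaia_sp"], "wsg": [0.66]})

out = impute_wsg(traits, reference, field_samples=field)
print(out[["species", "wsg", "wsg_source"]].to_string(index=False))
# Neph_mel comes straight from the database, Aglaia_sp from the field
# sample, Prun_jav from its genus median, Syzy_sp from its family median.
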