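"""Treatment-coded fixed-effect design matrices for the two models.

Reference cell: 0 h exposure, *A. texanum* mother, *A. texanum* father.
Columns are emitted in a deterministic order: intercept, exposure-time
dummies (ascending hours), mother, father, then interaction terms in the
order the term list names them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DARKNESS_TERMS",
    "COMPOSITION_TERMS",
    "build_design_matrix",
]

REF_GENOTYPE = "texanum"
NONREF_GENOTYPE = "barbouri"

DARKNESS_TERMS = ("time", "mother", "father", "mother:father")
COMPOSITION_TERMS = (
    "time",
    "mother",
    "father",
    "mother:father",
    "mother:time",
    "father:time",
)


def _time_levels(design: pd.DataFrame) -> list:
    return sorted(design["exposure_h"].unique().tolist())


def build_design_matrix(design: pd.DataFrame, terms=DARKNESS_TERMS):
    """Return ``(X, colnames, clutch_idx, clutch_ids)`` for `design`.

    `X` always starts with an intercept column.  `clutch_idx` maps each
    row to an integer clutch index into `clutch_ids` (sorted order).
    """
    design = design.reset_index(drop=True)
    n = len(design)
    levels = _time_levels(design)
    nonref_levels = [h for h in levels if h != levels[0]]

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    time_d = {
        h: (design["exposure_h"] == h).to_numpy(float) for h in nonref_levels
    }
    mother = (design["mother"] == NONREF_GENOTYPE).to_numpy(float)
    father = (design["father"] == NONREF_GENOTYPE).to_numpy(float)

    for term in terms:
        if term == "time":
            for h in nonref_levels:
                cols[f"time[{h}h]"] = time_d[h]
        elif term == "mother":
            cols[f"mother[{NONREF_GENOTYPE}]"] = mother
        elif term == "father":
            cols[f"father[{NONREF_GENOTYPE}]"] = father
        elif term == "mother:father":
            cols["mother:father"] = mother * father
        elif term == "mother:time":
            for h in nonref_levels:
                cols[f"mother:time[{h}h]"] = mother * time_d[h]
        elif term == "father:time":
            for h in nonref_levels:
                cols[f"father:time[{h}h]"] = father * time_d[h]
        else:
            raise ValueError(f"unknown model term: {term!r}")

    X = np.column_stack(list(cols.values()))
    clutch_ids = sorted(design["clutch_id"].unique().tolist())
    lookup = {c: i for i, c in enumerate(clutch_ids)}
    clutch_idx = design["clutch_id"].map(lookup).to_numpy(int)
    return X, list(cols.keys()), clutch_idx, clutch_ids
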