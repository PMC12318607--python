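"""Factorial experimental design and UVR dosage bookkeeping.

The experiment crosses three fixed factors — UVR exposure time (0, 1, 4,
12 h), mother genotype and father genotype (*Ambystoma barbouri* or
*A. texanum*) — with larval clutch nested in the mother x father pairing
as the grouping factor: by default 4 pairings x 3 clutches x 4 exposure
levels x 6 larvae = 288 larvae.

Dosages were logged per wavelength band under the treatment lamp; the 1-h
column below is the measured baseline and dosage scales linearly with
exposure time.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "EXPOSURE_LEVELS_H",
    "DOSAGE_1H_KJ_M2",
    "total_uvr",
    "total_par",
    "dosage_table",
    "generate_design",
]

GENOTYPES = ("barbouri", "texanum")
EXPOSURE_LEVELS_H = (0, 1, 4, 12)

# Measured 1-h dosages (kJ/m^2) per band under the T8 ReptiSun 10.0 bulb
# at 15.24 cm; UVR bands are 305, 320 and 380 nm, PAR is 400-700 nm.
DOSAGE_1H_KJ_M2 = {
    "305nm": 0.1428,
    "320nm": 0.48,
    "380nm": 0.036,
    "PAR": 1.9158,
}


def total_uvr(hours: float) -> float:
    """Total UVR dosage (kJ/m^2) after `hours` of exposure: the sum of the
    305, 320 and 380 nm bands, scaled linearly with time."""
    per_h = sum(v for k, v in DOSAGE_1H_KJ_M2.items() if k != "PAR")
    return per_h * hours


def total_par(hours: float) -> float:
    """Photosynthetically active radiation dosage (kJ/m^2) after `hours`."""
    return DOSAGE_1H_KJ_M2["PAR"] * hours


def dosage_table(hours=(1, 4, 12)) -> pd.DataFrame:
    """Per-band, total-UVR and PAR dosages for the given exposure times."""
    rows = {}
    for band, v in DOSAGE_1H_KJ_M2.items():
        if band == "PAR":
            continue
        rows[band] = [v * h for h in hours]
    rows["Total UVR"] = [total_uvr(h) for h in hours]
    rows["PAR"] = [total_par(h) for h in hours]
    return pd.DataFrame(rows, index=[f"{h} h" for h in hours]).T


def generate_design(
    n_clutches_per_pairing: int = 3,
    n_larvae_per_cell: int = 6,
    exposure_levels=EXPOSURE_LEVELS_H,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build the fully crossed design table, one row per larva.

    Every clutch appears at every exposure level with
    `n_larvae_per_cell` larvae, so the row count is
    ``4 pairings x n_clutches_per_pairing x len(exposure_levels) x
    n_larvae_per_cell``.

    Parameters
    ----------
    n_clutches_per_pairing : int
        Clutches sampled from each mother x father pairing.
    n_larvae_per_cell : int
        Larvae per clutch at each exposure level.
    exposure_levels : sequence of numbers
        Distinct exposure times in hours.
    seed : int, optional
        Unused (the design is deterministic); accepted so callers can
        thread a single seed through the whole simulation.

    Returns
    -------
    pandas.DataFrame
        Columns ``larva_id, mother, father, clutch_id, exposure_h``.
    """
    if n_clutches_per_pairing < 1 or n_larvae_per_cell < 1:
        raise ValueError("clutch and larva counts must be >= 1")
    levels = list(exposure_levels)
    if len(levels) == 0 or len(set(levels)) != len(levels):
        raise ValueError("exposure levels must be non-empty and distinct")

    rows = []
    for mother, father in itertools.product(GENOTYPES, GENOTYPES):
        pairing = f"{mother[0]}x{father[0]}"
        for ci in range(1, n_clutches_per_pairing + 1):
            clutch = f"{pairing}-c{ci}"
            for h in levels:
                for li in range(1, n_larvae_per_cell + 1):
                    rows.append(
                        {
                            "larva_id": f"{clutch}-h{h}-l{li}",
                            "mother": mother,
                            "father": father,
                            "clutch_id": clutch,
                            "exposure_h": h,
                        }
                    )
    df = pd.DataFrame(rows)
    df["exposure_h"] = df["exposure_h"].astype(np.asarray(levels).dtype)
    return df
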