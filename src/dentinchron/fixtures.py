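"""Packaged reference dataset: seven beluga GLGs from three Chukchi Sea whales.

Only per-GLG summaries exist for this dataset (the raw individual
spacings were never deposited), so the tables ship as published:
specimen metadata with per-GLG spacing statistics, and the matching
published day estimates and deposition-rate predictions. The ground
(non-demineralized) section contributes a single aggregate mean.
"""

from __future__ import annotations

import math
from importlib.resources import files

import pandas as pd

from .model import GLGRecord, GLGSummary

# One untreated ground section, measured for comparison with the
# demineralized preparations (demineralization shrinks the tissue).
GROUND_SECTION_MEAN_UM = 2.31
GROUND_SECTION_THREE_SE_UM = 0.36
GROUND_SECTION_N = 13

# Shrinkage band reported for demineralized vs untreated human dentin.
DEAN_SHRINK_BAND = (0.25, 0.29)


def _data(name: str) -> pd.DataFrame:
    with (files("dentinchron.data") / name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def beluga_glg_table() -> pd.DataFrame:
    """Per-GLG metadata and spacing summaries (7 rows)."""
    return _data("beluga_seven_glgs.csv")


def beluga_day_table() -> pd.DataFrame:
    """Published per-GLG predictions and day estimates (7 rows)."""
    return _data("beluga_seven_glgs_days.csv")


def beluga_records() -> list[GLGRecord]:
    df = beluga_glg_table()
    return [
        GLGRecord(
            specimen_id=str(r.specimen_id),
            glg_label=str(r.glg_label),
            thickness_um=float(r.thickness_um),
            sex=str(r.sex),
            tooth_position=int(r.tooth_position),
            whale_length_cm=float(r.whale_length_cm),
            preparation=str(r.preparation),
        )
        for r in df.itertuples()
    ]


def beluga_summaries() -> dict[tuple[str, str], GLGSummary]:
    """GLGSummary per GLG, with SD back-derived from the published 3·SE.

    The published table reports mean, 3·SE, summed readable length and
    n; ``sd = (3·SE / 3) * sqrt(n)`` recovers the sample SD implied by
    those (at the table's 2 d.p. rounding).
    """
    out: dict[tuple[str, str], GLGSummary] = {}
    for r in beluga_glg_table().itertuples():
        n = int(r.n)
        se = float(r.three_se_um) / 3.0
        out[(str(r.specimen_id), str(r.glg_label))] = GLGSummary(
            n=n,
            mean_um=float(r.mean_um),
            sd_um=se * math.sqrt(n),
            se_um=se,
            three_se_um=float(r.three_se_um),
            sum_um=float(r.sum_um),
        )
    return out
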