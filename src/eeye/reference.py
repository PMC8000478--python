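"""Packaged reference parameters for the 25-sample tequila study.

The shipped CSV holds, for each of 25 commercial 100%-agave tequilas
(8 Silver, 12 Aged, 5 Extra-aged), the per-channel mean and replicate
standard deviation of both the raw RGB intensities and the blank-referenced
absorbances, plus the reported total absorbance.  These numbers
parameterise the synthetic generator (:mod:`eeye.synthetic`) and serve as
the deterministic input of the in-table reproduction checks.

The blank cuvette (deionised water) channel intensities are
``(255, 251, 253)``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .absorbance import AbsorbanceVector, DatasetTable, SampleRecord

__all__ = [
    "REFERENCE_BLANK",
    "reference_table",
    "reference_samples",
    "reference_dataset",
]

REFERENCE_BLANK: tuple[float, float, float] = (255.0, 251.0, 253.0)

_CSV = "tequila_reference.csv"


def reference_table() -> pd.DataFrame:
    """The packaged per-sample parameter table as a DataFrame (25 rows)."""
    with resources.files("eeye.data").joinpath(_CSV).open("r") as fh:
        return pd.read_csv(fh)


def reference_samples() -> list["SampleParams"]:
    """Reference rows as generator parameter objects."""
    from .synthetic import SampleParams  # local import: synthetic depends on this module

    table = reference_table()
    return [
        SampleParams(
            tag=row.tag,
            category=row.category,
            intensity_mean=(row.mean_R, row.mean_G, row.mean_B),
            intensity_sd=(row.sd_R, row.sd_G, row.sd_B),
            absorbance_mean=(row.absmean_R, row.absmean_G, row.absmean_B),
            absorbance_sd=(row.abssd_R, row.abssd_G, row.abssd_B),
        )
        for row in table.itertuples()
    ]


def reference_dataset() -> DatasetTable:
    """The reference table as a one-replicate-per-sample absorbance dataset.

    Each sample contributes a single :class:`AbsorbanceVector` holding its
    reported mean channel absorbances; totals are recomputed as the channel
    mean.  Useful for the deterministic aggregate checks (class averages,
    fingerprints) that need no simulation.
    """
    records = [
        SampleRecord(
            tag=row.tag,
            category=row.category,
            replicates=[AbsorbanceVector(row.absmean_R, row.absmean_G, row.absmean_B)],
        )
        for row in reference_table().itertuples()
    ]
    return DatasetTable.from_records(records, provenance="packaged reference parameters")
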