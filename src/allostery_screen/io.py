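"""Tabular input/output.

TSV is the canonical interchange format.  Floats are written at 12
significant digits so that every numeric output round-trips losslessly
through the writers and readers and pipeline reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve
from .dsf import MeltCurve
from .spr import SPRSeries

__all__ = [
    "write_table",
    "read_table",
    "write_json",
    "read_midas_measurements",
    "melt_curves_to_table",
    "table_to_melt_curves",
    "table_to_dose_curves",
    "table_to_spr_series",
]

FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_midas_measurements(path: str | Path) -> pd.DataFrame:
    """Read dialysis measurements in wide or long chamber format.

    Long format has a ``chamber`` column in {protein, metabolite} and an
    ``abundance`` column; it is pivoted to one row per replicate with
    protein_chamber_abundance / metabolite_chamber_abundance columns.
    """
    df = read_table(path)
    if "chamber" not in df.columns:
        return df
    keys = [c for c in ("protein_id", "metabolite_id", "pool_id", "replicate") if c in df.columns]
    wide = df.pivot_table(index=keys, columns="chamber", values="abundance").reset_index()
    wide.columns.name = None
    return wide.rename(
        columns={"protein": "protein_chamber_abundance", "metabolite": "metabolite_chamber_abundance"}
    )


def melt_curves_to_table(curves: list[MeltCurve]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "well_id": c.well_id,
                "ligand_id": c.ligand_id,
                "ligand_concentration_M": c.ligand_concentration,
                "temperature_C": c.temperatures,
                "fluorescence": c.fluorescence,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


def table_to_melt_curves(df: pd.DataFrame) -> list[MeltCurve]:
    curves = []
    for (well, ligand, conc), grp in df.groupby(
        ["well_id", "ligand_id", "ligand_concentration_M"], sort=True
    ):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                str(well), str(ligand), float(conc),
                grp["temperature_C"].to_numpy(float),
                grp["fluorescence"].to_numpy(float),
            )
        )
    return curves


def table_to_dose_curves(df: pd.DataFrame) -> list[DoseResponseCurve]:
    curves = []
    for (inhibitor, rep), grp in df.groupby(["inhibitor_id", "replicate"], sort=True):
        curves.append(
            DoseResponseCurve(
                str(inhibitor),
                grp["concentration_M"].to_numpy(float),
                grp["activity_percent"].to_numpy(float),
                replicate=int(rep),
            )
        )
    return curves


def table_to_spr_series(df: pd.DataFrame) -> list[tuple[int, SPRSeries]]:
    out = []
    for (analyte, construct, rep), grp in df.groupby(
        ["analyte_id", "construct_id", "replicate"], sort=True
    ):
        out.append(
            (
                int(rep),
                SPRSeries(
                    str(analyte), str(construct),
                    grp["concentration_M"].to_numpy(float),
                    grp["req_RU"].to_numpy(float),
                ),
            )
        )
    return out
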