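"""Plain-text readers/writers for the pipeline's tabular interchange formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from heliastress.genotypes import GenotypeMatrix
from heliastress.synth.climate import ClimateSeries, SoilProfile
from heliastress.water import PotCalibration

__all__ = [
    "write_marker_csv",
    "read_marker_csv",
    "write_climate_csv",
    "read_climate_csv",
    "write_soil_yaml",
    "read_soil_yaml",
    "write_calibration_yaml",
    "read_calibration_yaml",
]


def write_marker_csv(geno: GenotypeMatrix, path) -> None:
    """Marker matrix CSV: rows = markers, map columns then one column per line."""
    df = geno.map.copy()
    calls = pd.DataFrame(geno.calls, columns=geno.line_ids)
    pd.concat([df, calls], axis=1).to_csv(path, index=False)


def read_marker_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    map_cols = ["marker", "linkage_group", "pos_bp"]
    line_ids = [c for c in df.columns if c not in map_cols]
    return GenotypeMatrix(
        calls=df[line_ids].to_numpy(dtype=np.int8),
        map=df[map_cols],
        line_ids=line_ids,
    )


def write_climate_csv(series: ClimateSeries, path) -> None:
    """One row per day: day, tmean, rad, pet, precip (+ identifying header cols)."""
    pd.DataFrame(
        {
            "location_id": series.location_id,
            "year": series.year,
            "day": np.arange(1, series.n_days + 1),
            "tmean": series.tmean,
            "rad": series.radiation,
            "pet": series.pet,
            "precip": series.precip,
        }
    ).to_csv(path, index=False)


def read_climate_csv(path) -> ClimateSeries:
    df = pd.read_csv(path)
    return ClimateSeries(
        location_id=str(df["location_id"].iloc[0]),
        year=int(df["year"].iloc[0]),
        tmean=df["tmean"].to_numpy(),
        radiation=df["rad"].to_numpy(),
        pet=df["pet"].to_numpy(),
        precip=df["precip"].to_numpy(),
    )


def write_soil_yaml(soil: SoilProfile, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "depth": soil.depth,
                "awc": soil.awc,
                "n_mineralization": soil.n_mineralization,
                "initial_water_fraction": soil.initial_water_fraction,
                "initial_n": soil.initial_n,
            }
        )
    )


def read_soil_yaml(path) -> SoilProfile:
    return SoilProfile(**yaml.safe_load(Path(path).read_text()))


def write_calibration_yaml(cal: PotCalibration, path) -> None:
    Path(path).write_text(yaml.safe_dump({"w_max": cal.w_max, "ttsw": cal.ttsw}))


def read_calibration_yaml(path) -> PotCalibration:
    return PotCalibration(**yaml.safe_load(Path(path).read_text()))
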