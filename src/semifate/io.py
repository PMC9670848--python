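"""CSV/JSON input and output.

Decay CSVs carry the columns ``time_s, concentration, compound`` (header
required); one file may hold several compounds.  Trend CSVs carry
``time_d, ibp_w, ibap_w, ibap_g``.  Round trips preserve full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .chamber_kinetics import DecaySeries
from .fate_model import TimeTrends

__all__ = [
    "read_decay_csv",
    "write_decay_csv",
    "read_trends_csv",
    "write_trends_csv",
    "write_json_report",
]

_DECAY_COLUMNS = ["time_s", "concentration", "compound"]


def read_decay_csv(path: Union[str, Path]) -> dict[str, DecaySeries]:
    """Read one or more decay series, keyed by compound label."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _DECAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[
        df["time_s"].isna() | df["concentration"].isna() | df["compound"].isna()
    ]
    if len(bad):
        # +2: one for the header row, one for 0- vs 1-based indexing
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    out: dict[str, DecaySeries] = {}
    for compound, group in df.groupby("compound", sort=False):
        group = group.sort_values("time_s")
        out[str(compound)] = DecaySeries(
            str(compound),
            group["time_s"].to_numpy(dtype=float),
            group["concentration"].to_numpy(dtype=float),
        )
    return out


def write_decay_csv(series: list[DecaySeries], path: Union[str, Path]) -> None:
    """Write decay series to CSV at full float precision."""
    frames = [
        pd.DataFrame(
            {
                "time_s": s.times,
                "concentration": s.concentrations,
                "compound": s.compound_id,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_trends_csv(t: TimeTrends, path: Union[str, Path]) -> None:
    t.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trends_csv(path: Union[str, Path]) -> TimeTrends:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["time_d", "ibp_w", "ibap_w", "ibap_g"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return TimeTrends(
        times=df["time_d"].to_numpy(dtype=float),
        ibp_w=df["ibp_w"].to_numpy(dtype=float),
        ibap_w=df["ibap_w"].to_numpy(dtype=float),
        ibap_g=df["ibap_g"].to_numpy(dtype=float),
    )


def write_json_report(report: dict, path: Union[str, Path]) -> None:
    """Write a machine-diffable JSON report (sorted keys, stable bytes)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
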