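"""CSV/JSON readers and writers for time courses, sensorgrams and configs.

Time-course CSV dialect: columns ``replicate_id, time_min, value_pct``.
Sensorgram CSV dialect: columns ``time_s, response_riu, conc_M, phase``.
Configuration JSON uses unit-tagged keys (``*_per_uM_s``, ``*_per_s``,
``*_uM``) so values in mixed molar/micromolar sources cannot be confused.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .model import RateParameters, TimeCourse, Totals
from .spr import Sensorgram

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_sensorgrams",
    "write_sensorgrams",
    "params_from_config",
    "params_to_config",
    "read_config",
]

_TC_COLUMNS = ["replicate_id", "time_min", "value_pct"]


class TimeCourseFormatError(ValueError):
    """Malformed time-course file; the message names the offending row."""


def read_timecourse(path) -> TimeCourse:
    """Read a replicate time-course CSV, validating the schema row by row."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TimeCourseFormatError(f"{path}: file is empty") from None
    missing = [c for c in _TC_COLUMNS if c not in df.columns]
    if missing:
        raise TimeCourseFormatError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise TimeCourseFormatError(f"{path}: no data rows")
    for col in ("time_min", "value_pct"):
        bad = pd.to_numeric(df[col], errors="coerce")
        nonfinite = ~np.isfinite(bad.to_numpy(dtype=float, na_value=np.nan))
        if nonfinite.any():
            row = int(np.flatnonzero(nonfinite)[0]) + 2  # 1-based + header
            raise TimeCourseFormatError(
                f"{path}: non-numeric or non-finite {col} at line {row}"
            )
        df[col] = bad
    for rep, sub in df.groupby("replicate_id", sort=False):
        t = sub["time_min"].to_numpy()
        dec = np.flatnonzero(np.diff(t) <= 0)
        if len(dec):
            row = int(sub.index[dec[0] + 1]) + 2
            raise TimeCourseFormatError(
                f"{path}: times not strictly increasing in replicate {rep!r} "
                f"at line {row}"
            )
    return TimeCourse.from_frame(df)


def write_timecourse(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False, float_format="%.8g")


def write_sensorgrams(sensorgrams: List[Sensorgram], path) -> None:
    frames = []
    for sg in sensorgrams:
        phase = np.where(sg.times <= sg.t_assoc, "association", "dissociation")
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.times,
                    "response_riu": sg.response,
                    "conc_M": sg.analyte_concentration,
                    "phase": phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_sensorgrams(path) -> List[Sensorgram]:
    df = pd.read_csv(path)
    needed = {"time_s", "response_riu", "conc_M", "phase"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: sensorgram CSV needs columns {sorted(needed)}")
    out = []
    for conc, sub in df.groupby("conc_M", sort=True):
        t = sub["time_s"].to_numpy(float)
        assoc = sub.loc[sub["phase"] == "association", "time_s"]
        t_assoc = float(assoc.max()) if len(assoc) else 0.0
        out.append(
            Sensorgram(
                times=t,
                response=sub["response_riu"].to_numpy(float),
                analyte_concentration=float(conc),
                t_assoc=t_assoc,
                t_dissoc=float(t.max()) - t_assoc,
            )
        )
    return out


# --- configuration -------------------------------------------------------

_RATE_KEYS = {
    "k_on1_per_uM_s": "k_on1",
    "k_off1_per_s": "k_off1",
    "k_on2_per_uM_s": "k_on2",
    "k_off2_per_s": "k_off2",
    "k_cat_4ebp_per_s": "k_cat_4ebp",
    "k_lys_4ebp_per_s": "k_lys_4ebp",
    "k_cat_protein_per_s": "k_cat_protein",
}
_TOTAL_KEYS = {
    "total_4ebp_uM": "total_4ebp",
    "total_eif4e_uM": "total_eif4e",
    "total_eif4g_uM": "total_eif4g",
}


def params_from_config(cfg: dict) -> tuple[RateParameters, Totals]:
    """Parse unit-tagged configuration keys into parameter objects.

    Keys not present fall back to the canonical unfertilized values.
    """
    from .model import TABLE1_TOTALS, UNFERTILIZED_RATES

    rates = {v: getattr(UNFERTILIZED_RATES, v) for v in _RATE_KEYS.values()}
    totals = {v: getattr(TABLE1_TOTALS, v) for v in _TOTAL_KEYS.values()}
    for key, val in cfg.items():
        if key in _RATE_KEYS:
            rates[_RATE_KEYS[key]] = float(val)
        elif key in _TOTAL_KEYS:
            totals[_TOTAL_KEYS[key]] = float(val)
    return RateParameters(**rates), Totals(**totals)


def params_to_config(params: RateParameters, totals: Totals) -> dict:
    cfg = {k: getattr(params, v) for k, v in _RATE_KEYS.items()}
    cfg.update({k: getattr(totals, v) for k, v in _TOTAL_KEYS.items()})
    return cfg


def read_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
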