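"""CSV file formats and configuration.

No standard bioformat exists for fluorescence time courses, so the
package defines three small long-format CSV dialects with unit-bearing
column names, versioned by a leading comment line:

* fluorescence time course — ``time_h, value, construct, condition,
  temperature_c, replicate``
* abundance time course — ``time_h, A_SpT, A_pSpT, A_pST, A_ST, replicate``
* spectra — ``wavelength_nm, intensity, sample, construct, state,
  replicate, temperature_c``

Readers validate, sort by the independent variable, and renormalize
abundance rows within the documented tolerance (logged); writers and
readers are mutually inverse.  Configuration is flat YAML with an
explicit ``rng_seed`` key.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .containers import AbundanceTimeCourse, EmissionSpectrum, FluorescenceTimeCourse
from .states import STATES, ValidationError

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "load_config",
    "save_config",
]

logger = logging.getLogger("kaifluor")

DIALECT_HEADER = "# kaifluor csv v1"

FLUOR_COLUMNS = ["time_h", "value", "construct", "condition", "temperature_c",
                 "replicate"]
ABUND_COLUMNS = ["time_h", "A_SpT", "A_pSpT", "A_pST", "A_ST", "replicate"]
SPECTRA_COLUMNS = ["wavelength_nm", "intensity", "sample", "construct", "state",
                   "replicate", "temperature_c"]

#: Gel-quantification row-sum tolerance for abundance ingestion.
ABUNDANCE_ROW_SUM_TOL = 0.02

_FLOAT_FMT = "%.12g"


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_csv(df: pd.DataFrame, path) -> None:
    buf = StringIO()
    buf.write(DIALECT_HEADER + "\n")
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def read_timecourse_csv(
    path,
) -> Union[FluorescenceTimeCourse, AbundanceTimeCourse, list]:
    """Read a time-course CSV, detecting the schema from the header.

    Returns a single object when the file holds one replicate, else a
    list of objects (one per replicate, in file order).
    """
    df = _read_csv(path)
    cols = set(df.columns)
    if set(ABUND_COLUMNS[:-1]).issubset(cols):
        return _parse_abundance(df, path)
    if {"time_h", "value"}.issubset(cols):
        return _parse_fluorescence(df, path)
    raise ValidationError(
        f"{path}: unrecognized header {sorted(cols)}; expected one of "
        f"{FLUOR_COLUMNS} or {ABUND_COLUMNS}"
    )


def _single_or_list(objs: list):
    return objs[0] if len(objs) == 1 else objs


def _parse_fluorescence(df: pd.DataFrame, path) -> Union[FluorescenceTimeCourse, list]:
    objs = []
    reps = df["replicate"] if "replicate" in df else pd.Series(1, index=df.index)
    for _, sub in df.groupby(reps, sort=False):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"{path}: non-monotone or duplicated time_h values")
        objs.append(FluorescenceTimeCourse(
            times=times,
            f_app=sub["value"].to_numpy(float),
            construct=str(sub["construct"].iloc[0]) if "construct" in sub else "WT",
            condition=str(sub["condition"].iloc[0]) if "condition" in sub
            else "KaiC-alone",
            temperature=float(sub["temperature_c"].iloc[0])
            if "temperature_c" in sub else 30.0,
        ))
    return _single_or_list(objs)


def _parse_abundance(df: pd.DataFrame, path) -> Union[AbundanceTimeCourse, list]:
    objs = []
    reps = df["replicate"] if "replicate" in df else pd.Series(1, index=df.index)
    for _, sub in df.groupby(reps, sort=False):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"{path}: non-monotone or duplicated time_h values")
        A = sub[[f"A_{s}" for s in STATES]].to_numpy(float)
        sums = A.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > ABUNDANCE_ROW_SUM_TOL)[0]
        if bad.size:
            row = int(sub.index[bad[0]])
            raise ValidationError(
                f"{path}: abundance row {row} sums to {sums[bad[0]]:.4g}, outside "
                f"tolerance {ABUNDANCE_ROW_SUM_TOL}"
            )
        objs.append(AbundanceTimeCourse(
            times=times, abundances=A, row_sum_tol=ABUNDANCE_ROW_SUM_TOL
        ))
    return _single_or_list(objs)


def write_timecourse_csv(obj, path, replicate: int = 1) -> None:
    """Write a FluorescenceTimeCourse / AbundanceTimeCourse (or a list of
    them, numbered as replicates) in the documented dialect."""
    objs = obj if isinstance(obj, list) else [obj]
    frames = []
    for i, o in enumerate(objs, start=replicate):
        if isinstance(o, FluorescenceTimeCourse):
            frames.append(pd.DataFrame({
                "time_h": o.times,
                "value": o.f_app,
                "construct": o.construct,
                "condition": o.condition,
                "temperature_c": o.temperature,
                "replicate": i,
            }))
        elif isinstance(o, AbundanceTimeCourse):
            data = {"time_h": o.times}
            for j, s in enumerate(STATES):
                data[f"A_{s}"] = o.abundances[:, j]
            data["replicate"] = i
            frames.append(pd.DataFrame(data))
        else:
            raise ValidationError(f"cannot write object of type {type(o).__name__}")
    _write_csv(pd.concat(frames, ignore_index=True), path)


def read_spectra_csv(path) -> list[EmissionSpectrum]:
    """Read a long-format spectra CSV; one EmissionSpectrum per
    (sample, replicate) group."""
    df = _read_csv(path)
    if not {"wavelength_nm", "intensity"}.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {SPECTRA_COLUMNS}"
        )
    keys = [c for c in ("sample", "replicate") if c in df.columns]
    groups = df.groupby(keys, sort=False) if keys else [((), df)]
    out = []
    for _, sub in groups:
        sub = sub.sort_values("wavelength_nm")
        meta = {c: sub[c].iloc[0] for c in
                ("sample", "construct", "state", "replicate", "temperature_c")
                if c in sub.columns}
        out.append(EmissionSpectrum(
            wavelengths=sub["wavelength_nm"].to_numpy(float),
            intensities=sub["intensity"].to_numpy(float),
            meta=meta,
        ))
    return out


def write_spectra_csv(spectra: list[EmissionSpectrum], path) -> None:
    frames = []
    for i, s in enumerate(spectra, start=1):
        frames.append(pd.DataFrame({
            "wavelength_nm": s.wavelengths,
            "intensity": s.intensities,
            "sample": s.meta.get("sample", f"spectrum{i}"),
            "construct": s.meta.get("construct", ""),
            "state": s.meta.get("state", ""),
            "replicate": s.meta.get("replicate", i),
            "temperature_c": s.meta.get("temperature_c", 30.0),
        }))
    _write_csv(pd.concat(frames, ignore_index=True), path)


def load_config(path) -> dict:
    """Load a flat YAML config.  Must contain ``rng_seed``."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
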