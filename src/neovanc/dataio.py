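"""NONMEM-style longitudinal dataset I/O.

One CSV row per event: dose rows (EVID=1) carry AMT (mg) and DUR (h);
observation rows (EVID=0) carry DV (mg/L), KIND and an EXCL flag set for
records outside the 2-50 mg/L assay calibration range.  Covariates are
repeated on every row of a subject.  Times are hours since the
subject's first dose and must be non-decreasing within a subject.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .model import (
    CALIBRATION_RANGE,
    Covariates,
    DoseEvent,
    Observation,
    Subject,
    ValidationError,
    within_calibration,
)

__all__ = ["read_dataset", "write_dataset", "EVENT_COLUMNS"]

EVENT_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "KIND", "EXCL"]


def write_dataset(subjects: Sequence[Subject], path) -> None:
    """Write subjects to a NONMEM-style CSV (lossless round trip)."""
    cov_names = sorted({k for s in subjects for k in s.covariates})
    rows = []
    for s in subjects:
        events = [("dose", d.start_time, d) for d in s.doses]
        events += [("obs", o.time, o) for o in s.observations]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "obs" else 1))
        for kind, t, ev in events:
            row = {"ID": s.id, "TIME": repr(float(t))}
            if kind == "dose":
                row.update({"EVID": 1, "AMT": repr(float(ev.amount)),
                            "DUR": repr(float(ev.duration)),
                            "DV": "", "MDV": 1, "KIND": "", "EXCL": 0})
            else:
                row.update({"EVID": 0, "AMT": "", "DUR": "",
                            "DV": repr(float(ev.concentration)), "MDV": 0,
                            "KIND": ev.kind, "EXCL": int(ev.excluded)})
            for c in cov_names:
                v = s.covariates.get(c)
                row[c] = repr(float(v)) if v is not None else ""
            rows.append(row)
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS + cov_names)
    frame.to_csv(path, index=False)


def read_dataset(path, calibration=CALIBRATION_RANGE) -> list[Subject]:
    """Read a NONMEM-style CSV back into subjects.

    Observation rows are re-checked against the calibration range: a DV
    outside it is flagged excluded regardless of the stored EXCL value.
    Violations (missing columns, non-monotone TIME, dose rows with DV)
    raise :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"ID": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty dataset")
        return []
    if frame.empty:
        warnings.warn(f"{path}: empty dataset")
        return []
    required = {"ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    aux = {"KIND", "EXCL"}
    cov_names = [c for c in frame.columns if c not in set(EVENT_COLUMNS) | aux]

    subjects = []
    for sid, grp in frame.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValidationError(f"subject {sid}: TIME not non-decreasing")
        doses, observations = [], []
        for ridx, row in grp.iterrows():
            evid = int(row["EVID"])
            if evid == 1:
                if not pd.isna(row["DV"]):
                    raise ValidationError(f"row {ridx}: dose row carries a DV")
                if pd.isna(row["AMT"]) or pd.isna(row["DUR"]):
                    raise ValidationError(f"row {ridx}: dose row missing AMT/DUR")
                doses.append(DoseEvent(float(row["TIME"]), float(row["AMT"]),
                                       float(row["DUR"])))
            elif evid == 0:
                if pd.isna(row["DV"]):
                    raise ValidationError(f"row {ridx}: observation row missing DV")
                dv = float(row["DV"])
                stored = bool(int(row["EXCL"])) if "EXCL" in grp.columns and not pd.isna(row.get("EXCL")) else False
                kind = row.get("KIND")
                kind = kind if isinstance(kind, str) and kind else "other"
                observations.append(Observation(
                    time=float(row["TIME"]), concentration=dv, kind=kind,
                    excluded=stored or not within_calibration(dv, calibration),
                ))
            else:
                raise ValidationError(f"row {ridx}: unknown EVID {evid}")
        first = grp.iloc[0]
        cov = {}
        for c in cov_names:
            v = first[c]
            if not pd.isna(v):
                cov[c] = float(v)
        subjects.append(Subject(str(sid), tuple(doses), tuple(observations),
                                Covariates(**cov)))
    return subjects
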