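"""File formats: HDF5 containers for recordings/epochs, CSV/TSV tables.

Recordings live in HDF5 with datasets ``/data`` (regions × samples),
``/fs`` and ``/roi_names``; epoch sets under ``/epochs`` with per-epoch
quality attributes.  Tabular outputs are RFC 4180 CSV (UTF-8, empty cell
= missing, floats at 17 significant digits); the parcellation is a
two-column TSV (roi, network).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epoching import EpochQuality, EpochSet
from .synthdata import CohortTable, SourceRecording

__all__ = [
    "write_recording", "read_recording",
    "write_epochset", "read_epochset",
    "write_cohort", "read_cohort",
    "write_parcellation", "read_parcellation",
]

FLOAT_FMT = "%.17g"

#: columns a cohort CSV must provide
MANDATORY_COHORT_COLS = ("subject_id", "group", "age", "gender")
#: full documented column dictionary
COHORT_COLUMNS = {
    "subject_id": "unique subject token",
    "group": "CN (cognitively normal) or CI (cognitively impaired)",
    "age": "years at recording",
    "gender": "F/M",
    "education": "years of education",
    "MMSE": "Mini-Mental State Examination total (0-30)",
    "fluency": "letter fluency, words produced",
    "TMTB": "Trail Making Test B, seconds",
    "CERAD": "CERAD battery total score",
    "cCAQ": "current cognitive-activity composite (1-5)",
    "pCAQ": "past cognitive-activity composite (1-5)",
}
_TEXT_COLS = {"subject_id", "group", "gender"}


def write_recording(rec: SourceRecording, path) -> None:
    with h5py.File(path, "a") as fh:
        grp = fh.require_group(rec.subject_id)
        for name in ("data", "fs", "roi_names"):
            if name in grp:
                del grp[name]
        grp.create_dataset("data", data=rec.data)
        grp.create_dataset("fs", data=float(rec.fs))
        grp.create_dataset("roi_names",
                           data=np.array(rec.roi_names, dtype=h5py.string_dtype()))


def read_recording(path, subject_id: str) -> SourceRecording:
    with h5py.File(path, "r") as fh:
        grp = fh[subject_id]
        return SourceRecording(
            subject_id=subject_id,
            fs=float(grp["fs"][()]),
            roi_names=[s.decode() if isinstance(s, bytes) else str(s)
                       for s in grp["roi_names"][()]],
            data=grp["data"][()],
        )


def list_subjects(path) -> list[str]:
    with h5py.File(path, "r") as fh:
        return sorted(fh.keys())


def write_epochset(eset: EpochSet, path) -> None:
    with h5py.File(path, "a") as fh:
        grp = fh.require_group(f"{eset.subject_id}/epochs")
        for key in list(grp.keys()):
            del grp[key]
        grp.attrs["fs"] = float(eset.fs)
        grp.attrs["epoch_len"] = int(eset.epoch_len)
        for k, (ep, start) in enumerate(zip(eset.epochs, eset.start_indices)):
            ds = grp.create_dataset(f"epoch{k:03d}", data=ep)
            ds.attrs["start_index"] = int(start)
            if eset.quality:
                q = eset.quality[k]
                ds.attrs.update(
                    max_abs_z=q.max_abs_z, epoch_ipf=q.epoch_ipf,
                    alpha1_occ_rbp=q.alpha1_occ_rbp,
                    rejected=q.rejected, reason=q.reason,
                )


def read_epochset(path, subject_id: str) -> EpochSet:
    with h5py.File(path, "r") as fh:
        grp = fh[f"{subject_id}/epochs"]
        keys = sorted(grp.keys())
        epochs, starts, quality = [], [], []
        for k in keys:
            ds = grp[k]
            epochs.append(ds[()])
            starts.append(int(ds.attrs["start_index"]))
            if "max_abs_z" in ds.attrs:
                quality.append(EpochQuality(
                    max_abs_z=float(ds.attrs["max_abs_z"]),
                    epoch_ipf=float(ds.attrs["epoch_ipf"]),
                    alpha1_occ_rbp=float(ds.attrs["alpha1_occ_rbp"]),
                    rejected=bool(ds.attrs["rejected"]),
                    reason=str(ds.attrs["reason"]),
                ))
        return EpochSet(
            subject_id=subject_id, fs=float(grp.attrs["fs"]),
            epoch_len=int(grp.attrs["epoch_len"]),
            epochs=epochs, start_indices=starts, quality=quality,
        )


def write_cohort(cohort: CohortTable, path) -> None:
    """Cohort to CSV (missing = empty cell); questionnaire to ``*_caq.csv``."""
    path = Path(path)
    df = cohort.data.reset_index()
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    cohort.caq.to_csv(path.with_name(path.stem + "_caq.csv"), index=False)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV, rebuilding the missingness mask.

    Unknown columns warn; missing mandatory columns abort; a malformed
    numeric cell raises with its row number.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COHORT_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory column(s): {missing}")
    unknown = [c for c in raw.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"unknown cohort column(s): {unknown}", UserWarning)
    data = {}
    for col in raw.columns:
        if col in _TEXT_COLS:
            data[col] = raw[col]
            continue
        vals = []
        for row, cell in enumerate(raw[col]):
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError as err:
                raise ValueError(
                    f"{path.name}, row {row + 2}, column {col!r}: "
                    f"malformed numeric cell {cell!r}"
                ) from err
        data[col] = vals
    df = pd.DataFrame(data).set_index("subject_id")
    mask = df.isna()
    caq_path = path.with_name(path.stem + "_caq.csv")
    caq = pd.read_csv(caq_path) if caq_path.exists() else pd.DataFrame(
        columns=["subject_id", "activity", "age", "response"])
    return CohortTable(data=df, mask=mask, caq=caq)


def write_parcellation(rsn_map: pd.Series, path) -> None:
    rsn_map.rename("network").rename_axis("roi").reset_index().to_csv(
        path, sep="\t", index=False)


def read_parcellation(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"roi", "network"} <= set(df.columns):
        raise ValueError("parcellation TSV needs 'roi' and 'network' columns")
    return df.set_index("roi")["network"]
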