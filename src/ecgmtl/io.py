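"""Dataset readers and writers for the two emulated layouts.

PTB-XL style: PhysioNet-like record pairs (text header ``<id>.hea`` plus a
16-bit little-endian interleaved signal file ``<id>.dat``, fixed gain in
ADC units per millivolt) under ``records/``, with a ``metadata.csv`` table
carrying the label sets and the 10-fold tag.  Only the subset of the
header format the package writes is parsed back — signal format 16 with a
per-record sampling rate.

CPSC style: one MATLAB ``.mat`` matrix per record (key ``ECG``, leads ×
samples, millivolts) plus a ``REFERENCE.csv`` with up to three labels per
record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .preprocessing import EcgRecord
from .taxonomy import LabelHierarchy, derive_aux_labels

__all__ = [
    "write_wfdb_record", "read_wfdb_record", "write_wfdb_dataset",
    "read_wfdb_dataset", "write_mat_dataset", "read_mat_dataset",
]

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")
_GAIN = 1000.0  # ADC units per millivolt


def write_wfdb_record(rec: EcgRecord, directory: str | Path) -> None:
    """Write ``<id>.hea`` + ``<id>.dat`` (format 16, gain 1000/mV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_sig, n_samp = rec.signal.shape
    lines = [f"{rec.record_id} {n_sig} {rec.rate:g} {n_samp}"]
    for i in range(n_sig):
        lead = LEAD_NAMES[i % len(LEAD_NAMES)]
        lines.append(f"{rec.record_id}.dat 16 {_GAIN:g}/mV 16 0 0 0 0 {lead}")
    (directory / f"{rec.record_id}.hea").write_text("\n".join(lines) + "\n")
    adc = np.clip(np.round(rec.signal * _GAIN), -32768, 32767).astype("<i2")
    adc.T.tofile(directory / f"{rec.record_id}.dat")  # sample-major frames


def read_wfdb_record(path: str | Path) -> EcgRecord:
    """Read a header+signal pair; ``path`` is the record path without suffix."""
    path = Path(path)
    header = (path.parent / f"{path.name}.hea").read_text().strip().splitlines()
    rid, n_sig, rate, n_samp = header[0].split()[:4]
    n_sig, rate, n_samp = int(n_sig), float(rate), int(n_samp)
    gains = []
    for line in header[1:1 + n_sig]:
        fields = line.split()
        if fields[1] != "16":
            raise ValueError(f"unsupported signal format {fields[1]!r}")
        gains.append(float(fields[2].split("/")[0]))
    raw = np.fromfile(path.parent / f"{rid}.dat", dtype="<i2")
    signal = raw.reshape(n_samp, n_sig).T / np.asarray(gains)[:, None]
    return EcgRecord(record_id=rid, signal=signal, rate=rate)


def write_wfdb_dataset(records: list[EcgRecord], metadata: pd.DataFrame,
                       directory: str | Path) -> None:
    directory = Path(directory)
    for rec in records:
        write_wfdb_record(rec, directory / "records")
    metadata.to_csv(directory / "metadata.csv", index=False)


def read_wfdb_dataset(directory: str | Path,
                      hierarchy: LabelHierarchy | None = None
                      ) -> tuple[list[EcgRecord], pd.DataFrame]:
    """Load records and reattach labels/folds from ``metadata.csv``."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.csv")
    records = []
    for row in meta.itertuples():
        rec = read_wfdb_record(directory / "records" / str(row.record_id))
        rec.main_labels = set(str(row.labels).split("|"))
        if hierarchy is not None:
            rec.aux_labels = derive_aux_labels(rec.main_labels, hierarchy)
        elif "aux_labels" in meta.columns and isinstance(row.aux_labels, str):
            rec.aux_labels = set(row.aux_labels.split("|"))
        if "fold" in meta.columns:
            rec.fold = int(row.fold)
        records.append(rec)
    return records, meta


def write_mat_dataset(records: list[EcgRecord], directory: str | Path) -> None:
    """CPSC-style layout: per-record MAT matrices plus ``REFERENCE.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        savemat(directory / f"{rec.record_id}.mat",
                {"ECG": rec.signal, "fs": rec.rate})
        labels = sorted(rec.main_labels)[:3]
        rows.append({
            "Recording": rec.record_id,
            "First_label": labels[0] if labels else "",
            "Second_label": labels[1] if len(labels) > 1 else "",
            "Third_label": labels[2] if len(labels) > 2 else "",
        })
    pd.DataFrame(rows).to_csv(directory / "REFERENCE.csv", index=False)


def read_mat_dataset(directory: str | Path,
                     hierarchy: LabelHierarchy | None = None,
                     rate: float | None = None) -> list[EcgRecord]:
    directory = Path(directory)
    ref = pd.read_csv(directory / "REFERENCE.csv", keep_default_na=False)
    records = []
    for row in ref.itertuples():
        mat = loadmat(directory / f"{row.Recording}.mat")
        labels = {v for v in (row.First_label, row.Second_label,
                              row.Third_label) if v}
        fs = float(np.squeeze(mat["fs"])) if "fs" in mat else rate
        if fs is None:
            raise ValueError("sampling rate missing from MAT file; pass rate=")
        rec = EcgRecord(record_id=str(row.Recording), signal=mat["ECG"],
                        rate=fs, main_labels=labels)
        if hierarchy is not None:
            rec.aux_labels = derive_aux_labels(labels, hierarchy)
        records.append(rec)
    return records
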